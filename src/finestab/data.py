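"""Domain containers and file I/O for stability-guided fine-mapping.

The central container is :class:`GenotypeMatrix`: an ``N x P`` dosage matrix
with variant metadata (IDs, chromosome, 1-based positions), sample IDs and
optional per-sample population labels.  Population labels define the data
"slices" (subpopulations) over which stability-guided selection runs the
fine-mapper.

Readers accept VCF 4.x (``GT`` field, via cyvcf2) or a plain TSV dosage
matrix; phenotypes and labels are two-column TSVs.  A synthetic genotype
generator (:func:`synth_genotypes`) produces block-LD dosage matrices over
five labelled subpopulations so that every downstream module is testable
without external downloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, ParameterError, ParseError

logger = logging.getLogger(__name__)

#: Default subpopulation names and sizes (1000 Genomes cohorts used by GEUVADIS).
DEFAULT_POPULATIONS = ("TSI", "GBR", "FIN", "CEU", "YRI")
DEFAULT_POP_SIZES = (91, 86, 92, 89, 87)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """An ``N x P`` dosage matrix with variant and sample metadata.

    Parameters
    ----------
    dosages
        Allele counts per individual: values in {0, 1, 2} for genotypes or
        {0, 1} for haplotypes.  Stored as float64.
    variant_ids
        P unique variant identifiers.
    positions
        P base-pair coordinates, 1-based.
    chrom
        P chromosome names (a scalar is broadcast).
    sample_ids
        N sample identifiers.
    population_labels
        Optional N categorical labels defining slices E_1..E_K.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    sample_ids: np.ndarray
    population_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D array")
        n, p = self.dosages.shape
        if n < 1 or p < 1:
            raise EmptyInputError("genotype matrix must have >= 1 sample and variant")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        chrom = np.asarray(self.chrom, dtype=object)
        if chrom.ndim == 0:
            chrom = np.repeat(chrom[None], p)
        self.chrom = chrom
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.variant_ids) != p or len(self.positions) != p or len(self.chrom) != p:
            raise ParameterError("variant metadata length mismatch")
        if len(self.sample_ids) != n:
            raise ParameterError("sample_ids length mismatch")
        if len(set(self.variant_ids)) != p:
            raise ParameterError("variant_ids must be unique")
        if self.population_labels is not None:
            self.population_labels = np.asarray(self.population_labels, dtype=object)
            if len(self.population_labels) != n:
                raise ParameterError("population_labels length mismatch")

    # -- basic properties ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        if self.population_labels is None:
            return []
        return list(pd.unique(self.population_labels))

    def slice_indices(self) -> dict[str, np.ndarray]:
        """Row indices E_k for each population label."""
        if self.population_labels is None:
            return {}
        return {
            pop: np.flatnonzero(self.population_labels == pop)
            for pop in self.populations
        }

    # -- subsetting ---------------------------------------------------------

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variant_ids=self.variant_ids[idx],
            positions=self.positions[idx],
            chrom=self.chrom[idx],
            sample_ids=self.sample_ids,
            population_labels=self.population_labels,
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        labels = None if self.population_labels is None else self.population_labels[idx]
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variant_ids=self.variant_ids,
            positions=self.positions,
            chrom=self.chrom,
            sample_ids=self.sample_ids[idx],
            population_labels=labels,
        )

    # -- summaries ----------------------------------------------------------

    def allele_frequencies(self, ploidy: int = 2) -> np.ndarray:
        """ALT-allele frequency per variant (dosage mean / ploidy)."""
        return self.dosages.mean(axis=0) / ploidy

    def population_allele_frequencies(self, ploidy: int = 2) -> pd.DataFrame:
        """ALT-allele frequency per (population, variant)."""
        rows = {
            pop: self.dosages[idx].mean(axis=0) / ploidy
            for pop, idx in self.slice_indices().items()
        }
        return pd.DataFrame(rows, index=self.variant_ids).T


@dataclass
class PhenotypeVector:
    """Per-sample phenotype values, optionally PC-residualized."""

    values: np.ndarray
    residualized: bool = False
    n_pcs_removed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("phenotype values must be finite")
        if self.n_pcs_removed < 0:
            raise ParameterError("n_pcs_removed must be >= 0")


@dataclass
class PosteriorVector:
    """Sparse posterior over one potential set: variant indices -> probability.

    ``support`` holds locus-level variant indices, ``probs`` the matching
    probabilities and ``lead_index`` the lead SNP of the set.  For the PICS
    fine-mapper probabilities are normalized to sum to one over the support
    (``kind='pics'``); for SuSiE-style backends they are posterior inclusion
    probabilities and need not sum to one (``kind='pip'``).  ``n_variants``
    records the number of variants included in the fine-mapping run that
    produced the vector (the PIP support rule thresholds at 1/n_variants).
    """

    support: np.ndarray
    probs: np.ndarray
    lead_index: int
    kind: str = "pics"
    n_variants: int | None = None

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape:
            raise ParameterError("support/probs shape mismatch")
        if np.any(self.probs < 0):
            raise ParameterError("posterior probabilities must be >= 0")
        if int(self.lead_index) not in set(self.support.tolist()):
            raise ParameterError("lead_index must belong to the support")
        if self.kind == "pics" and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"PICS posterior must sum to 1 (got {self.probs.sum()!r})"
            )

    def prob_of(self, index: int) -> float:
        """Probability of a locus-level variant index (0 if unsupported)."""
        hit = np.flatnonzero(self.support == index)
        return float(self.probs[hit[0]]) if hit.size else 0.0

    def as_dense(self, n_variants: int) -> np.ndarray:
        dense = np.zeros(n_variants)
        dense[self.support] = self.probs
        return dense


@dataclass
class FineMapResult:
    """Pooled and (optionally) per-slice fine-mapping output for one locus.

    ``pooled`` is a list of C potential-set posterior vectors from the full
    sample; ``per_slice`` maps each population label to the (possibly
    shorter) list from that slice.  ``variant_ids`` / ``positions`` give the
    locus-level variant metadata the support indices refer to.
    """

    pooled: list[PosteriorVector]
    variant_ids: np.ndarray
    positions: np.ndarray
    per_slice: dict[str, list[PosteriorVector]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pooled) < 1:
            raise EmptyInputError("FineMapResult needs >= 1 potential set")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        # PICS potential sets are disjoint by construction; PIP-style vectors
        # (credible sets) legitimately share support and are exempt.
        seen: set[int] = set()
        for vec in self.pooled:
            if vec.kind != "pics":
                continue
            overlap = seen.intersection(vec.support.tolist())
            if overlap:
                raise ParameterError(
                    f"potential sets must have disjoint supports (overlap {overlap})"
                )
            seen.update(vec.support.tolist())

    @property
    def n_sets(self) -> int:
        return len(self.pooled)


SCENARIOS = (
    "homogeneous",
    "t=0",
    "t=8",
    "t=16",
    "t=128",
    "t=256",
    "smooth_mean",
    "spiked_mean",
)


@dataclass
class SimulationSpec:
    """Parameters of one simulated cis-eQTL phenotype.

    ``phi`` is the proportion of phenotypic variance explained by the causal
    genotypes; the implied signal-to-noise ratio is ``phi / (1 - phi)``.
    """

    n_causal: int = 1
    phi: float = 0.2
    effect_sd: float = 0.6
    scenario: str = "homogeneous"
    seed: int | None = None
    window_bp: int = 1_000_000
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.phi < 1:
            raise ParameterError("phi must be in (0, 1)")
        if self.n_causal < 1:
            raise ParameterError("n_causal must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )


@dataclass
class SimulatedPhenotype:
    """A simulated phenotype with its generating truth."""

    values: np.ndarray
    causal_indices: np.ndarray
    effects: np.ndarray
    sigma2: float
    per_sample_noise_mean: np.ndarray
    per_sample_noise_var: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.sigma2 <= 0:
            raise ParameterError("sigma2 must be > 0")
        off = np.ones(len(self.effects), dtype=bool)
        off[self.causal_indices] = False
        if np.any(self.effects[off] != 0):
            raise ParameterError("effects must be zero outside causal_indices")

    def as_phenotype(self) -> PhenotypeVector:
        return PhenotypeVector(values=self.values)


@dataclass
class SetSelection:
    """The variant chosen for one potential set by one selection strategy.

    ``stable_set_ids`` records the candidate set S_c (variants attaining the
    maximal support count) when the stability rule produced the selection.
    """

    set_index: int
    variant_index: int
    variant_id: str
    pooled_prob: float
    support_count: int = 1
    in_yri_support: bool = False
    stable_set_ids: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.pooled_prob <= 1:
            raise ParameterError("pooled_prob must be in (0, 1]")
        if self.support_count < 1:
            raise ParameterError("support_count must be >= 1")


@dataclass
class SelectionOutcome:
    """Per-potential-set chosen variants for one selection strategy."""

    method: str
    selections: list[SetSelection]
    n_pcs_removed: int = 0

    METHODS = ("plain", "top", "stable", "combined")

    def __post_init__(self) -> None:
        if self.method not in self.METHODS:
            raise ParameterError(f"method must be one of {self.METHODS}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "set_index": s.set_index,
                "variant_id": s.variant_id,
                "variant_index": s.variant_index,
                "pooled_prob": s.pooled_prob,
                "support_count": s.support_count,
                "in_yri_support": s.in_yri_support,
            }
            for s in self.selections
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "method",
                "set_index",
                "variant_id",
                "variant_index",
                "pooled_prob",
                "support_count",
                "in_yri_support",
            ],
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    try:
        chrom, span = region.split(":")
        start, end = span.replace(",", "").split("-")
        return chrom, int(start), int(end)
    except Exception as exc:  # noqa: BLE001 - uniform parse error
        raise ParameterError(
            f"region {region!r} not in 'chrom:start-end' form"
        ) from exc


def read_genotypes(
    path: str | Path,
    region: str | None = None,
    labels: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a dosage matrix from a VCF (``GT`` field) or a TSV dosage file.

    ``region`` is ``chrom:start-end``, 1-based inclusive.  Missing genotypes
    are imputed to the per-variant mean dosage rounded to the nearest integer
    (the count is logged).  Multiallelic VCF records keep the first ALT with
    a warning.  ``labels`` optionally maps sample_id -> population.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if ".vcf" in suffixes:
        gm = _read_vcf(path, region)
    else:
        gm = _read_genotype_tsv(path, region)
    if labels is not None:
        gm.population_labels = np.asarray(
            [labels.get(str(s)) for s in gm.sample_ids], dtype=object
        )
    return gm


def _impute_missing(dosages: np.ndarray, missing: np.ndarray) -> int:
    """Mean-impute (rounded) missing cells in place; returns the count."""
    n_missing = int(missing.sum())
    if n_missing == 0:
        return 0
    for j in np.flatnonzero(missing.any(axis=0)):
        col_missing = missing[:, j]
        observed = dosages[~col_missing, j]
        fill = float(np.round(observed.mean())) if observed.size else 0.0
        dosages[col_missing, j] = fill
    return n_missing


def _read_vcf(path: Path, region: str | None) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ParseError("cyvcf2 is required to read VCF files") from exc

    want = _parse_region(region) if region else None
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    miss: list[np.ndarray] = []
    ids: list[str] = []
    positions: list[int] = []
    chroms: list[str] = []
    for v in vcf:
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if len(v.ALT) > 1:
            warnings.warn(
                f"multiallelic record {v.CHROM}:{v.POS} — keeping first ALT",
                stacklevel=2,
            )
        gt = np.asarray(v.gt_types)  # 0/1/2 dosage, 3 = missing (gts012)
        cols.append(np.where(gt == 3, 0, gt).astype(float))
        miss.append(gt == 3)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        ids.append(vid)
        positions.append(v.POS)
        chroms.append(v.CHROM)
    if not cols:
        raise EmptyInputError(f"no variants read from {path} (region={region})")
    dosages = np.column_stack(cols)
    missing = np.column_stack(miss)
    dosages[missing] = np.nan
    missing_mask = np.isnan(dosages)
    dosages[missing_mask] = 0
    n_imputed = _impute_missing(dosages, missing_mask)
    if n_imputed:
        logger.info("imputed %d missing genotype calls in %s", n_imputed, path)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.asarray(ids, dtype=object),
        positions=np.asarray(positions),
        chrom=np.asarray(chroms, dtype=object),
        sample_ids=np.asarray(samples, dtype=object),
    )


def _read_genotype_tsv(path: Path, region: str | None) -> GenotypeMatrix:
    """TSV layout: columns variant_id, chrom, pos, then one column per sample."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not parse genotype TSV {path}: {exc}") from exc
    required = ["variant_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"genotype TSV must start with columns {required}, got {list(df.columns[:3])}"
        )
    if region is not None:
        chrom, start, end = _parse_region(region)
        df = df[(df["chrom"] == chrom) & df["pos"].between(start, end)]
    if df.empty:
        raise EmptyInputError(f"no variants in {path} (region={region})")
    samples = list(df.columns[3:])
    if not samples:
        raise ParseError(f"genotype TSV {path} has no sample columns")
    dosages = df[samples].to_numpy(dtype=float).T  # samples x variants
    missing = np.isnan(dosages)
    n_imputed = _impute_missing(np.nan_to_num(dosages, copy=False), missing)
    if n_imputed:
        logger.info("imputed %d missing dosages in %s", n_imputed, path)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=df["variant_id"].to_numpy(dtype=object),
        positions=df["pos"].to_numpy(dtype=np.int64),
        chrom=df["chrom"].to_numpy(dtype=object),
        sample_ids=np.asarray(samples, dtype=object),
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage layout read by :func:`read_genotypes`."""
    cols = {"variant_id": gm.variant_ids, "chrom": gm.chrom, "pos": gm.positions}
    cols.update(
        {str(sid): gm.dosages[i] for i, sid in enumerate(gm.sample_ids)}
    )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, value) -> Series indexed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"phenotype TSV {path} needs columns (sample_id, value)")
    return pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str)
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"label TSV {path} needs columns (sample_id, population)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def phenotype_for(gm: GenotypeMatrix, series: pd.Series) -> PhenotypeVector:
    """Align a phenotype Series with the genotype sample order."""
    try:
        values = series.loc[[str(s) for s in gm.sample_ids]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ParseError(f"phenotype missing samples: {exc}") from exc
    return PhenotypeVector(values=values)


# ---------------------------------------------------------------------------
# cis-window restriction
# ---------------------------------------------------------------------------


def cis_window(gm: GenotypeMatrix, tss: int, window_bp: int = 1_000_000) -> GenotypeMatrix:
    """Restrict to variants with ``|position - tss| <= window_bp`` (inclusive)."""
    keep = np.flatnonzero(np.abs(gm.positions - int(tss)) <= int(window_bp))
    if keep.size == 0:
        raise EmptyInputError(
            f"no variants within {window_bp} bp of position {tss}"
        )
    return gm.subset_variants(keep)


# ---------------------------------------------------------------------------
# Synthetic genotypes
# ---------------------------------------------------------------------------


def synth_genotypes(
    n_per_pop: Sequence[int] = DEFAULT_POP_SIZES,
    n_variants: int = 80,
    ld_block_size: int = 10,
    ld_rho: float = 0.85,
    maf_range: tuple[float, float] = (0.05, 0.5),
    fst_like_drift: float = 0.02,
    seed: int | None = None,
    pop_names: Sequence[str] = DEFAULT_POPULATIONS,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing_bp: int = 2_000,
    ploidy: int = 2,
) -> GenotypeMatrix:
    """Simulate a block-LD dosage matrix over labelled subpopulations.

    Ancestral ALT frequencies are drawn uniformly from ``maf_range``; each
    population's frequencies drift away via a Balding–Nichols Beta
    perturbation with differentiation parameter ``fst_like_drift`` (0 means
    identical frequencies in all populations).  Haplotypes come from a
    latent-Gaussian copula: within each block of ``ld_block_size`` adjacent
    variants the latent variables follow an AR(1) process with parameter
    ``ld_rho``, and are thresholded at the frequency-matched normal quantile
    so marginal ALT frequencies are exact.  Dosages are sums of ``ploidy``
    independent haplotypes (Hardy–Weinberg within population).
    """
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ParameterError("maf_range must be within (0, 0.5]")
    if not 0 <= ld_rho < 1:
        raise ParameterError("ld_rho must be in [0, 1)")
    if fst_like_drift < 0 or fst_like_drift >= 1:
        raise ParameterError("fst_like_drift must be in [0, 1)")
    if ld_block_size < 1 or n_variants < 1:
        raise ParameterError("n_variants and ld_block_size must be >= 1")
    if len(n_per_pop) != len(pop_names):
        raise ParameterError("n_per_pop and pop_names length mismatch")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(maf_range[0], maf_range[1], size=n_variants)

    pop_freqs = []
    for _ in pop_names:
        if fst_like_drift == 0:
            pop_freqs.append(p_anc.copy())
        else:
            f = fst_like_drift
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs.append(np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4))

    n_total = int(sum(n_per_pop))
    dosages = np.zeros((n_total, n_variants))
    labels = np.empty(n_total, dtype=object)
    sample_ids = np.empty(n_total, dtype=object)
    block_start = np.arange(n_variants) % ld_block_size == 0

    row = 0
    for pop, n_pop, freqs in zip(pop_names, n_per_pop, pop_freqs):
        thresholds = stats.norm.ppf(freqs)
        for _ in range(ploidy):
            # AR(1) latent Gaussians, restarting at each block boundary
            eps = rng.standard_normal((n_pop, n_variants))
            z = np.empty_like(eps)
            z[:, 0] = eps[:, 0]
            scale = np.sqrt(1 - ld_rho**2)
            for j in range(1, n_variants):
                if block_start[j]:
                    z[:, j] = eps[:, j]
                else:
                    z[:, j] = ld_rho * z[:, j - 1] + scale * eps[:, j]
            dosages[row : row + n_pop] += (z < thresholds).astype(float)
        labels[row : row + n_pop] = pop
        for i in range(n_pop):
            sample_ids[row + i] = f"{pop}_{i:03d}"
        row += n_pop

    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.asarray([f"v{j:04d}" for j in range(n_variants)], dtype=object),
        positions=start_pos + spacing_bp * np.arange(n_variants),
        chrom=chrom,
        sample_ids=sample_ids,
        population_labels=labels,
    )


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "kind",
    "method",
    "slice",
    "set_index",
    "variant_id",
    "probability",
    "is_lead",
    "support_count",
    "in_yri_support",
]


def _finemap_rows(result: FineMapResult) -> list[dict]:
    rows = []
    groups = [("pooled", result.pooled)]
    groups += [(label, vecs) for label, vecs in result.per_slice.items()]
    for label, vecs in groups:
        for c, vec in enumerate(vecs):
            for idx, prob in zip(vec.support, vec.probs):
                rows.append(
                    {
                        "kind": "finemap",
                        "method": vec.kind,
                        "slice": label,
                        "set_index": c,
                        "variant_id": result.variant_ids[idx],
                        "probability": float(prob),
                        "is_lead": bool(idx == vec.lead_index),
                        "support_count": "",
                        "in_yri_support": "",
                    }
                )
    return rows


def write_result(
    result: "FineMapResult | SelectionOutcome | pd.DataFrame",
    path: str | Path,
    params: dict | None = None,
) -> None:
    """Write a TSV (one row per potential set x variant) plus a JSON sidecar.

    The sidecar ``<path>.json`` records run parameters (including any seed).
    Probabilities are written with 17 significant digits so a read/write
    round trip is lossless to double precision.
    """
    path = Path(path)
    if isinstance(result, FineMapResult):
        df = pd.DataFrame(_finemap_rows(result), columns=_RESULT_COLUMNS)
        sidecar = dict(result.params)
    elif isinstance(result, SelectionOutcome):
        sel = result.to_frame()
        df = pd.DataFrame(
            {
                "kind": "selection",
                "method": sel["method"],
                "slice": "pooled",
                "set_index": sel["set_index"],
                "variant_id": sel["variant_id"],
                "probability": sel["pooled_prob"],
                "is_lead": "",
                "support_count": sel["support_count"],
                "in_yri_support": sel["in_yri_support"],
            },
            columns=_RESULT_COLUMNS,
        )
        sidecar = {"method": result.method, "n_pcs_removed": result.n_pcs_removed}
    elif isinstance(result, pd.DataFrame):
        df = result
        sidecar = {}
    else:
        raise ParameterError(f"cannot serialize {type(result).__name__}")
    if params:
        sidecar.update(params)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        Path(str(path) + ".json").write_text(
            json.dumps(_jsonable(sidecar), indent=2, sort_keys=True)
        )
    except OSError as exc:
        raise OSError(f"cannot write result to {path}: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def read_result(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a result TSV and its JSON sidecar (if present)."""
    df = pd.read_csv(path, sep="\t")
    sidecar_path = Path(str(path) + ".json")
    params = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return df, params
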