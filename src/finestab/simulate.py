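"""Synthetic cis-eQTL phenotypes over a genotype matrix.

The homogeneous model draws a phenotype ``y ~ N(X b, sigma^2 I)`` where a
small set of causal variants carries effects ``b_j ~ N(0, effect_sd^2)``
(default SD 0.6) and the noise scale is chosen so that the genotypes
explain a target proportion ``phi`` of phenotypic variance; the implied
signal-to-noise ratio is ``SNR = var(Xb)/sigma^2 = phi/(1-phi)``.

Six environmental-heterogeneity scenarios perturb the exogenous noise by
ancestry (population order TSI, GBR, FIN, CEU, YRI):

* variance heterogeneity ``t in {8, 16, 128, 256}`` — per-population noise
  variances ``sigma^2(t) = 5 sigma^2 alpha(t)`` where ``alpha(t)`` are the
  population sizes raised to the power ``t`` and normalized to sum to one
  (``t=0`` recovers the homogeneous model exactly);
* ``smooth_mean`` — noise means ``(2s, 0, s, s, 2s)`` with ``s = sigma``,
  raising expression of everyone but GBR by varying amounts;
* ``spiked_mean`` — noise means ``(0, 2s, 0, 0, 0)``, raising expression of
  GBR individuals only.
"""

from __future__ import annotations

import hashlib
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_POP_SIZES,
    DEFAULT_POPULATIONS,
    GenotypeMatrix,
    SimulatedPhenotype,
    SimulationSpec,
    SCENARIOS,
)
from .errors import (
    DegenerateSignalError,
    EmptyInputError,
    LabelError,
    ParameterError,
)

__all__ = [
    "draw_effects",
    "sigma2_for_phi",
    "alpha",
    "simulate_phenotype",
    "simulation_grid",
    "iterate_grid",
    "SCENARIOS",
]


def draw_effects(
    n_variants: int,
    n_causal: int,
    effect_sd: float = 0.6,
    rng: np.random.Generator | None = None,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample causal indices uniformly and Gaussian effects on them.

    Returns ``(causal_indices, effects)`` with ``effects`` a length-P vector
    that is zero off the causal set.  ``eligible`` optionally restricts the
    candidate indices (e.g. to common variants).
    """
    rng = rng or np.random.default_rng()
    pool = np.arange(n_variants) if eligible is None else np.asarray(eligible)
    if n_causal > pool.size:
        raise ParameterError(
            f"n_causal={n_causal} exceeds {pool.size} eligible variants"
        )
    causal = np.sort(rng.choice(pool, size=n_causal, replace=False))
    effects = np.zeros(n_variants)
    effects[causal] = rng.normal(0.0, effect_sd, size=n_causal)
    return causal, effects


def sigma2_for_phi(
    genotypes: GenotypeMatrix | np.ndarray, effects: np.ndarray, phi: float
) -> float:
    """Noise variance achieving a target proportion of variance explained.

    ``sigma^2 = var(Xb) (1-phi)/phi`` with the empirical (N-1) variance of
    the genetic values, so that ``SNR = var(Xb)/sigma^2 = phi/(1-phi)``.
    """
    if not 0 < phi < 1:
        raise ParameterError("phi must be in (0, 1)")
    X = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    g = X @ np.asarray(effects, dtype=float)
    var_g = float(np.var(g, ddof=1))
    if var_g == 0:
        raise DegenerateSignalError(
            "X @ b is constant (monomorphic causal variants?)"
        )
    return var_g * (1.0 - phi) / phi


def alpha(t: float, pop_sizes: Sequence[int] = DEFAULT_POP_SIZES) -> np.ndarray:
    """Exponentiated population-size proportions ``N_k^t / sum_j N_j^t``.

    Computed in log space so large exponents (t up to 256) do not overflow.
    ``t=0`` gives the uniform vector.
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    sizes = np.asarray(pop_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ParameterError("population sizes must be positive")
    logw = t * np.log(sizes)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _population_index(
    gm: GenotypeMatrix, pop_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample index into ``pop_order`` and per-population counts."""
    if gm.population_labels is None:
        raise LabelError("heterogeneity scenarios require population labels")
    lookup = {pop: k for k, pop in enumerate(pop_order)}
    idx = np.empty(gm.n_samples, dtype=np.int64)
    for i, lab in enumerate(gm.population_labels):
        if lab not in lookup:
            raise LabelError(
                f"sample {gm.sample_ids[i]!r} has label {lab!r} not in {list(pop_order)}"
            )
        idx[i] = lookup[lab]
    counts = np.bincount(idx, minlength=len(pop_order))
    if np.any(counts == 0):
        missing = [p for p, c in zip(pop_order, counts) if c == 0]
        raise LabelError(f"populations absent from the data: {missing}")
    return idx, counts


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    spec: SimulationSpec,
    pop_order: Sequence[str] = DEFAULT_POPULATIONS,
) -> SimulatedPhenotype:
    """Draw one phenotype under the requested scenario.

    Causal variants are drawn among variants with minor-allele frequency at
    least ``spec.min_maf`` (degenerate monomorphic picks would make ``phi``
    unattainable).  Noise draws are independent across individuals in every
    scenario; per-sample noise means and variances are recorded.
    """
    rng = np.random.default_rng(spec.seed)
    X = genotypes.dosages
    n, p = X.shape

    freq = genotypes.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero(maf >= spec.min_maf)
    if eligible.size == 0:
        raise EmptyInputError(f"no variants with MAF >= {spec.min_maf}")
    causal, effects = draw_effects(
        p, spec.n_causal, spec.effect_sd, rng, eligible=eligible
    )
    sigma2 = sigma2_for_phi(genotypes, effects, spec.phi)
    sigma = np.sqrt(sigma2)
    g = X @ effects

    if spec.scenario == "homogeneous":
        noise_mean = np.zeros(n)
        noise_var = np.full(n, sigma2)
    elif spec.scenario.startswith("t="):
        t = float(spec.scenario[2:])
        pop_idx, counts = _population_index(genotypes, pop_order)
        # group (5 * alpha) first so t=0 reproduces sigma2 bit-exactly
        var_by_pop = sigma2 * (5.0 * alpha(t, counts))
        noise_mean = np.zeros(n)
        noise_var = var_by_pop[pop_idx]
    elif spec.scenario == "smooth_mean":
        pop_idx, _ = _population_index(genotypes, pop_order)
        mu_by_pop = np.asarray([2 * sigma, 0.0, sigma, sigma, 2 * sigma])
        noise_mean = mu_by_pop[pop_idx]
        noise_var = np.full(n, sigma2)
    elif spec.scenario == "spiked_mean":
        pop_idx, _ = _population_index(genotypes, pop_order)
        mu_by_pop = np.asarray([0.0, 2 * sigma, 0.0, 0.0, 0.0])
        noise_mean = mu_by_pop[pop_idx]
        noise_var = np.full(n, sigma2)
    else:  # pragma: no cover - SimulationSpec already validates
        raise ParameterError(f"unknown scenario {spec.scenario!r}")

    y = g + rng.normal(noise_mean, np.sqrt(noise_var))
    return SimulatedPhenotype(
        values=y,
        causal_indices=causal,
        effects=effects,
        sigma2=sigma2,
        per_sample_noise_mean=noise_mean,
        per_sample_noise_var=noise_var,
    )


# ---------------------------------------------------------------------------
# Simulation grids
# ---------------------------------------------------------------------------


def _cell_seed(master_seed: int, *parts) -> int:
    """Deterministic per-cell seed (< 2^31) from the master seed and cell key."""
    key = "|".join(str(p) for p in (master_seed, *parts))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def simulation_grid(
    gene_ids: Sequence[str],
    n_causal_set: Sequence[int] = (1, 2, 3),
    phi_set: Sequence[float] = (0.05, 0.1, 0.2, 0.4),
    replicates: int = 2,
    scenarios: Sequence[str] = ("homogeneous",),
    seed: int = 0,
    manifest_path=None,
) -> pd.DataFrame:
    """Enumerate the (gene, n_causal, phi, replicate, scenario) grid.

    Returns a manifest with one row per dataset and a derived per-cell seed;
    fresh effects are drawn per replicate.  Optionally written as TSV.
    """
    if len(gene_ids) == 0:
        raise EmptyInputError("gene list is empty")
    for s in scenarios:
        if s not in SCENARIOS:
            raise ParameterError(f"unknown scenario {s!r}")
    rows = []
    for scenario in scenarios:
        for gene in gene_ids:
            for n_causal in n_causal_set:
                for phi in phi_set:
                    for rep in range(replicates):
                        rows.append(
                            {
                                "dataset_id": f"{scenario}:{gene}:C{n_causal}:phi{phi}:rep{rep}",
                                "scenario": scenario,
                                "gene": gene,
                                "n_causal": n_causal,
                                "phi": phi,
                                "replicate": rep,
                                "seed": _cell_seed(
                                    seed, gene, n_causal, phi, rep, scenario
                                ),
                            }
                        )
    manifest = pd.DataFrame(rows)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest


def iterate_grid(
    manifest: pd.DataFrame,
    loci: Mapping[str, GenotypeMatrix],
    effect_sd: float = 0.6,
    min_maf: float = 0.01,
) -> Iterator[tuple[pd.Series, GenotypeMatrix, SimulatedPhenotype]]:
    """Yield ``(manifest row, locus genotypes, simulated phenotype)`` triples."""
    for _, row in manifest.iterrows():
        gm = loci[row["gene"]]
        spec = SimulationSpec(
            n_causal=int(row["n_causal"]),
            phi=float(row["phi"]),
            effect_sd=effect_sd,
            scenario=str(row["scenario"]),
            seed=int(row["seed"]),
            min_maf=min_maf,
        )
        yield row, gm, simulate_phenotype(gm, spec)
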