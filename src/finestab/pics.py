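"""PICS: a permutation-based, non-parametric fine-mapping posterior.

Given a locus dosage matrix ``X`` (N x P) and a phenotype ``y``, PICS asks,
for each variant ``j`` in LD with the lead SNP, how often the observed lead
SNP would still emerge as the lead if ``j`` were the causal variant.  The
null ensemble is a set of *constrained* row permutations of ``X`` that leave
the focal variant's column — and hence its marginal association with ``y``
and every pairwise column correlation — exactly unchanged: rows are shuffled
only within strata of equal focal dosage.  By Bayes' rule,

    P(j causal | lead) ∝ P(lead | j causal) * P(j causal),

where the likelihood term is the fraction of constrained permutations in
which the observed lead stays the lead, and the prior defaults to uniform.
The per-variant products are normalized to a probability vector over the
lead SNP's LD neighborhood (one "potential set").  The full algorithm
repeats this for ``C`` potential sets, removing each neighborhood from the
locus before the next round, so successive sets are disjoint.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data import FineMapResult, GenotypeMatrix, PhenotypeVector, PosteriorVector
from .errors import DegenerateInputError, EmptyInputError, ParameterError

__all__ = [
    "PicsParams",
    "PicsFineMapper",
    "marginal_assoc",
    "lead_snp",
    "neighborhood",
    "constrained_permutation",
    "enumerate_constrained_permutations",
    "pics_posterior",
    "pics",
]


@dataclass
class PicsParams:
    """Tuning parameters of the PICS fine-mapper.

    Defaults follow common practice for cis-eQTL loci: LD threshold
    ``|r| = 0.5``, ``C = 3`` potential sets, ``R = 500`` permutations and a
    uniform causal prior.
    """

    r_threshold: float = 0.5
    n_permutations: int = 500
    n_potential_sets: int = 3
    prior: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ParameterError("r_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ParameterError("n_permutations (R) must be >= 1")
        if self.n_potential_sets < 1:
            raise ParameterError("n_potential_sets (C) must be >= 1")
        if self.prior is not None:
            self.prior = np.asarray(self.prior, dtype=float)
            if np.any(self.prior < 0):
                raise ParameterError("prior entries must be >= 0")
            total = float(self.prior.sum())
            if total <= 0:
                raise ParameterError("prior must have positive mass")
            # normalize: posteriors are invariant to the prior's scale
            self.prior = self.prior / total


def _as_arrays(
    genotypes: GenotypeMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (dosages, positions, variant_ids) for either input form."""
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosages, genotypes.positions, genotypes.variant_ids
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2:
        raise ParameterError("genotype array must be 2-D")
    p = X.shape[1]
    return X, np.arange(1, p + 1), np.asarray([f"v{j:04d}" for j in range(p)], dtype=object)


def _phenotype_values(phenotype: PhenotypeVector | np.ndarray) -> np.ndarray:
    if isinstance(phenotype, PhenotypeVector):
        return phenotype.values
    return np.asarray(phenotype, dtype=float).ravel()


# ---------------------------------------------------------------------------
# Marginal association and lead SNP
# ---------------------------------------------------------------------------


def marginal_assoc(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
) -> np.ndarray:
    """Squared Pearson correlation of each variant's dosage with the phenotype.

    Monomorphic variants get statistic 0.  Ranking by r^2 is equivalent to
    ranking by the simple-regression F statistic (both are monotone in each
    other for fixed N), so the choice of statistic does not affect which
    variant leads.
    """
    X, _, _ = _as_arrays(genotypes)
    y = _phenotype_values(phenotype)
    if X.shape[0] != y.shape[0]:
        raise ParameterError("genotypes and phenotype sample-count mismatch")
    if X.shape[0] < 3:
        raise ParameterError("need at least 3 samples for association")
    yc = y - y.mean()
    ssy = float(yc @ yc)
    if ssy == 0:
        raise DegenerateInputError("phenotype is constant")
    Xc = X - X.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    num = Xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ssx > 0, num**2 / np.where(ssx > 0, ssx, 1.0) / ssy, 0.0)
    return np.clip(r2, 0.0, 1.0)


def _tie_order(positions: np.ndarray, variant_ids: np.ndarray) -> np.ndarray:
    """Indices sorted by (position, variant_id): the deterministic tie rule."""
    ids = np.asarray(variant_ids, dtype=str)
    return np.lexsort((ids, np.asarray(positions)))


def lead_snp(
    assoc: np.ndarray,
    positions: np.ndarray | None = None,
    variant_ids: np.ndarray | None = None,
) -> int:
    """Index of the maximal association statistic.

    Ties are broken by smallest genomic position, then lexicographic
    variant ID.  All-zero statistics trigger a warning and fall back to the
    tie rule alone.
    """
    assoc = np.asarray(assoc, dtype=float)
    if assoc.size == 0:
        raise EmptyInputError("empty association vector")
    if positions is None:
        positions = np.arange(assoc.size)
    if variant_ids is None:
        variant_ids = np.asarray([f"v{j:04d}" for j in range(assoc.size)], dtype=object)
    if np.all(assoc == 0):
        warnings.warn("all association statistics are zero", stacklevel=2)
    order = _tie_order(positions, variant_ids)
    best = order[np.argmax(assoc[order])]  # argmax keeps first (= tie-rule) max
    return int(best)


def neighborhood(
    genotypes: GenotypeMatrix | np.ndarray,
    lead: int,
    r_threshold: float = 0.5,
) -> np.ndarray:
    """Variant indices with squared correlation to the lead above threshold.

    Returns ``{k : cor(A_k, A_lead)^2 > r_threshold^2}``; the lead itself is
    always included.
    """
    X, _, _ = _as_arrays(genotypes)
    if not 0 <= lead < X.shape[1]:
        raise ParameterError("lead index out of range")
    Xc = X - X.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    lead_col = Xc[:, lead]
    ssl = float(lead_col @ lead_col)
    if ssl == 0:
        return np.asarray([lead], dtype=np.int64)
    num = Xc.T @ lead_col
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ssx > 0, num**2 / np.where(ssx > 0, ssx, 1.0) / ssl, 0.0)
    keep = r2 > r_threshold**2
    keep[lead] = True
    return np.flatnonzero(keep).astype(np.int64)


# ---------------------------------------------------------------------------
# Constrained permutations
# ---------------------------------------------------------------------------


def _strata(column: np.ndarray) -> list[np.ndarray]:
    """Row-index groups of equal dosage in the focal column."""
    values = np.unique(column)
    return [np.flatnonzero(column == v) for v in values]


def constrained_permutation(
    genotypes: GenotypeMatrix | np.ndarray,
    focal: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One uniform draw from the focal-preserving row-permutation group.

    Rows are permuted only within strata of equal focal dosage, so the focal
    column is unchanged as a vector (its association with any fixed
    phenotype is exactly invariant) and every pairwise column correlation is
    preserved.  Returns the row permutation as an index array ``perm`` such
    that the permuted matrix is ``X[perm]``.
    """
    X, _, _ = _as_arrays(genotypes)
    if not 0 <= focal < X.shape[1]:
        raise ParameterError("focal index out of range")
    perm = np.arange(X.shape[0])
    for idx in _strata(X[:, focal]):
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def enumerate_constrained_permutations(
    column: np.ndarray, limit: int = 1_000_000
) -> list[np.ndarray]:
    """All row permutations preserving the focal column (exhaustive oracle).

    The group is the direct product of symmetric groups on each dosage
    stratum; its size is the product of stratum factorials.  Raises if that
    exceeds ``limit``.
    """
    groups = _strata(np.asarray(column))
    size = math.prod(math.factorial(len(g)) for g in groups)
    if size > limit:
        raise ParameterError(f"constrained group has {size} elements (> {limit})")
    per_group = [list(itertools.permutations(g)) for g in groups]
    perms = []
    n = sum(len(g) for g in groups)
    for combo in itertools.product(*per_group):
        perm = np.empty(n, dtype=np.int64)
        for idx, shuffled in zip(groups, combo):
            perm[idx] = shuffled
        perms.append(perm)
    return perms


# ---------------------------------------------------------------------------
# Posterior over one potential set
# ---------------------------------------------------------------------------


def _permuted_phenotypes(
    y: np.ndarray, focal_column: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """N x R matrix of phenotypes under constrained row permutations.

    Permuting rows of X against a fixed y is equivalent to permuting y by
    the inverse permutation against a fixed X; the constrained family is a
    group (closed under inversion), so drawing within-stratum shuffles of y
    samples the same null.  This keeps the heavy work in one matrix product.
    """
    Y = np.tile(y[:, None], (1, n_perm))
    for idx in _strata(focal_column):
        if idx.size < 2:
            continue
        keys = rng.random((idx.size, n_perm))
        order = np.argsort(keys, axis=0)
        Y[idx, :] = y[idx][order]
    return Y


def _lead_fraction(
    Xc: np.ndarray,
    ssx: np.ndarray,
    Y: np.ndarray,
    lead_pos: int,
) -> float:
    """Fraction of permuted phenotypes for which column ``lead_pos`` leads.

    ``Xc`` holds centered neighborhood columns ordered by the tie rule;
    ``Y`` holds centered permuted phenotypes.  The per-permutation lead is
    the first (tie-rule-preferred) column attaining the maximal r^2.
    """
    num = Xc.T @ Y  # m x R
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = num**2 / np.where(ssx > 0, ssx, 1.0)[:, None]
    r2[ssx == 0, :] = 0.0
    winners = np.argmax(r2, axis=0)
    return float(np.mean(winners == lead_pos))


def pics_posterior(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    lead: int,
    params: PicsParams | None = None,
    rng: np.random.Generator | None = None,
    members: np.ndarray | None = None,
    exhaustive: bool = False,
) -> PosteriorVector:
    """Posterior probability vector over the lead SNP's neighborhood.

    For each focal variant ``j`` in the neighborhood, the unnormalized
    posterior is ``prior_j`` times the fraction of constrained permutations
    (focal = ``j``) in which ``lead`` re-emerges as the lead among the
    neighborhood; the vector is normalized to sum to one.  With
    ``exhaustive=True`` the fraction is computed over the full constrained
    permutation group instead of ``R`` Monte-Carlo draws (small strata only).
    """
    params = params or PicsParams()
    X, positions, variant_ids = _as_arrays(genotypes)
    y = _phenotype_values(phenotype)
    if members is None:
        members = neighborhood(genotypes, lead, params.r_threshold)
    members = np.asarray(members, dtype=np.int64)
    if members.size == 0:
        raise EmptyInputError("empty neighborhood")
    if lead not in members:
        raise ParameterError("lead must belong to its neighborhood")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    # order neighborhood columns by the tie rule so argmax == tie-rule lead
    order = _tie_order(positions[members], variant_ids[members])
    members_ord = members[order]
    lead_pos = int(np.flatnonzero(members_ord == lead)[0])
    Xn = X[:, members_ord]
    Xc = Xn - Xn.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)

    prior = params.prior
    if prior is None:
        prior_members = np.full(members.size, 1.0 / X.shape[1])
    else:
        if prior.size != X.shape[1]:
            raise ParameterError("prior length must equal the locus variant count")
        prior_members = prior[members_ord]

    yc = y - y.mean()
    unnorm = np.zeros(members.size)
    for m, j in enumerate(members_ord):
        if exhaustive:
            perms = enumerate_constrained_permutations(X[:, j])
            # apply inverse permutations to y (same group, exact count)
            Y = np.column_stack([yc[np.argsort(perm)] for perm in perms])
        else:
            Y = _permuted_phenotypes(yc, X[:, j], params.n_permutations, rng)
        frac = _lead_fraction(Xc, ssx, Y, lead_pos)
        unnorm[m] = frac * prior_members[m]

    total = unnorm.sum()
    if total == 0:
        # no permutation kept the lead for any focal: fall back to lead mass 1
        probs = np.zeros(members.size)
        probs[lead_pos] = 1.0
    else:
        probs = unnorm / total
    return PosteriorVector(
        support=members_ord,
        probs=probs,
        lead_index=int(lead),
        kind="pics",
        n_variants=int(X.shape[1]),
    )


# ---------------------------------------------------------------------------
# Full potential-set loop
# ---------------------------------------------------------------------------


def pics(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    params: PicsParams | None = None,
) -> FineMapResult:
    """Run the full fine-mapper: up to C disjoint potential sets.

    Each round finds the lead SNP among remaining columns, computes the
    posterior over its LD neighborhood, then removes the neighborhood.
    Stops early (with fewer sets) once no polymorphic column remains.
    """
    params = params or PicsParams()
    X, positions, variant_ids = _as_arrays(genotypes)
    y = _phenotype_values(phenotype)
    rng = np.random.default_rng(params.seed)

    remaining = np.arange(X.shape[1])
    vectors: list[PosteriorVector] = []
    for _ in range(params.n_potential_sets):
        if remaining.size == 0:
            break
        Xr = X[:, remaining]
        if np.all(Xr.std(axis=0) == 0):
            break  # only monomorphic columns left
        assoc = marginal_assoc(Xr, y)
        lead_local = lead_snp(assoc, positions[remaining], variant_ids[remaining])
        members_local = neighborhood(Xr, lead_local, params.r_threshold)
        sub_prior = None
        if params.prior is not None:
            sub_prior = params.prior[remaining]
            total = sub_prior.sum()
            sub_prior = sub_prior / total if total > 0 else None
        sub_params = PicsParams(
            r_threshold=params.r_threshold,
            n_permutations=params.n_permutations,
            n_potential_sets=1,
            prior=sub_prior,
        )
        vec_local = pics_posterior(
            GenotypeMatrix(
                dosages=Xr,
                variant_ids=variant_ids[remaining],
                positions=positions[remaining],
                chrom="",
                sample_ids=np.arange(X.shape[0]),
            ),
            y,
            lead_local,
            sub_params,
            rng=rng,
            members=members_local,
        )
        vectors.append(
            PosteriorVector(
                support=remaining[vec_local.support],
                probs=vec_local.probs,
                lead_index=int(remaining[vec_local.lead_index]),
                kind="pics",
                n_variants=int(X.shape[1]),
            )
        )
        drop = set(remaining[members_local].tolist())
        remaining = np.asarray([k for k in remaining if k not in drop], dtype=np.int64)

    if not vectors:
        raise EmptyInputError("no polymorphic variants to fine-map")
    return FineMapResult(
        pooled=vectors,
        variant_ids=variant_ids,
        positions=positions,
        params={
            "r_threshold": params.r_threshold,
            "R": params.n_permutations,
            "C": params.n_potential_sets,
            "prior": "uniform" if params.prior is None else "custom",
            "seed": params.seed,
        },
    )


class PicsFineMapper(BaseEstimator):
    """Scikit-learn style wrapper around the permutation fine-mapper.

    Parameters
    ----------
    r_threshold : float, default 0.5
        LD threshold |r| defining the lead SNP's neighborhood.
    n_permutations : int, default 500
        Constrained permutations per focal variant (R).
    n_potential_sets : int, default 3
        Maximum number of disjoint potential sets (C).
    prior : array of shape (P,), optional
        Causal prior per variant; uniform if omitted.
    random_state : int, optional
        Seed for the single generator driving all permutations.

    Attributes
    ----------
    potential_sets_ : list of PosteriorVector
        One normalized posterior vector per potential set.
    result_ : FineMapResult
        The pooled fine-mapping result.
    n_features_in_ : int
        Number of variants seen during fit.
    """

    def __init__(
        self,
        r_threshold: float = 0.5,
        n_permutations: int = 500,
        n_potential_sets: int = 3,
        prior: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.r_threshold = r_threshold
        self.n_permutations = n_permutations
        self.n_potential_sets = n_potential_sets
        self.prior = prior
        self.random_state = random_state

    def _params(self) -> PicsParams:
        return PicsParams(
            r_threshold=self.r_threshold,
            n_permutations=self.n_permutations,
            n_potential_sets=self.n_potential_sets,
            prior=self.prior,
            seed=self.random_state,
        )

    def fit(self, X: GenotypeMatrix | np.ndarray, y: PhenotypeVector | np.ndarray):
        """Fine-map the locus; stores potential sets as fitted attributes."""
        result = pics(X, y, self._params())
        self.result_ = result
        self.potential_sets_ = result.pooled
        self.n_features_in_ = int(_as_arrays(X)[0].shape[1])
        return self

    def fine_map(
        self, X: GenotypeMatrix | np.ndarray, y: PhenotypeVector | np.ndarray
    ) -> list[PosteriorVector]:
        """Backend-contract entry point: fit and return the posterior vectors."""
        return self.fit(X, y).potential_sets_

    @staticmethod
    def positive_support(vec: PosteriorVector) -> np.ndarray:
        """PICS support rule: strictly positive posterior probability."""
        return vec.probs > 0

    def predict(self, X: GenotypeMatrix | np.ndarray | None = None) -> np.ndarray:
        """Locus-level indices of the per-set maximum-posterior variants."""
        if not hasattr(self, "potential_sets_"):
            raise ParameterError("fit must be called before predict")
        out = []
        for vec in self.potential_sets_:
            out.append(int(vec.support[np.argmax(vec.probs)]))
        return np.asarray(out, dtype=np.int64)
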