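"""Variant-selection strategies over fine-mapping posteriors.

Four strategies are implemented, all reporting one variant per potential
set:

* ``plain`` — maximum pooled posterior, no correction of any kind;
* ``top`` — maximum pooled posterior after residualizing the phenotype on
  the top genotype principal components (the standard population-structure
  correction);
* ``stable`` — run the fine-mapper on the pooled sample *and* on each
  population-labelled slice; among pooled-supported variants keep those
  with positive probability in the greatest number of probability vectors
  (pooled + slices), then take the one with the highest pooled probability;
* ``combined`` — the stable rule applied to the residualized phenotype.

A backend is any object with ``fine_map(genotypes, phenotype) -> list of
PosteriorVector`` and a ``positive_support(vec) -> bool mask`` rule.  The
PICS fine-mapper counts any strictly positive probability as support; for
SuSiE-style PIP vectors, support means PIP at least 1/(number of variants
included), since such backends assign small nonzero probability everywhere.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from sklearn.base import BaseEstimator

from .data import (
    FineMapResult,
    GenotypeMatrix,
    PhenotypeVector,
    PosteriorVector,
    SelectionOutcome,
    SetSelection,
)
from .errors import EmptyInputError, ParameterError
from .pics import PicsFineMapper, _as_arrays, _phenotype_values, _tie_order

logger = logging.getLogger(__name__)

__all__ = [
    "FineMapBackend",
    "residualize",
    "PCResidualizer",
    "choose_n_pcs_elbow",
    "plain_select",
    "top_select",
    "stable_select",
    "combined_select",
    "stable_from_vectors",
    "susie_support_filter",
    "SingleEffectFineMapper",
    "VariantSelector",
]

YRI_LABEL = "YRI"
MIN_SLICE_SIZE = 3


@runtime_checkable
class FineMapBackend(Protocol):
    """Contract a fine-mapper must satisfy to drive the stability wrapper."""

    def fine_map(
        self, genotypes: GenotypeMatrix | np.ndarray, phenotype
    ) -> list[PosteriorVector]: ...

    def positive_support(self, vec: PosteriorVector) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------


def _genotype_pcs(X: np.ndarray, n_pcs: int, scale: bool) -> np.ndarray:
    """Top principal components (left singular vectors) of the centered dosages."""
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if rank < n_pcs:
        warnings.warn(
            f"requested {n_pcs} PCs but genotype matrix has rank {rank}; "
            "dropping collinear components",
            stacklevel=3,
        )
    return U[:, : min(n_pcs, rank)]


def residualize(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: PhenotypeVector | np.ndarray,
    n_pcs: int = 5,
    scale: bool = False,
) -> PhenotypeVector:
    """Regress the top genotype PCs (plus intercept) out of the phenotype.

    With ``n_pcs=0`` this reduces to mean-centering, which leaves all
    correlation-based statistics unchanged.
    """
    X, _, _ = _as_arrays(genotypes)
    y = _phenotype_values(phenotype)
    if n_pcs < 0:
        raise ParameterError("n_pcs must be >= 0")
    if n_pcs >= min(X.shape):
        raise ParameterError("n_pcs must be < min(N, P)")
    resid = y - y.mean()
    if n_pcs > 0:
        U = _genotype_pcs(X, n_pcs, scale)
        # columns of U are orthonormal and orthogonal to the intercept
        resid = resid - U @ (U.T @ resid)
    return PhenotypeVector(values=resid, residualized=True, n_pcs_removed=n_pcs)


class PCResidualizer(BaseEstimator):
    """Transformer that removes top genotype-PC signal from phenotypes.

    ``fit(X)`` learns the PCs from the dosage matrix; ``transform(y)``
    returns residuals of one or more phenotype vectors.
    """

    def __init__(self, n_pcs: int = 5, scale: bool = False):
        self.n_pcs = n_pcs
        self.scale = scale

    def fit(self, X: GenotypeMatrix | np.ndarray, y=None):
        Xd, _, _ = _as_arrays(X)
        if self.n_pcs < 0 or self.n_pcs >= min(Xd.shape):
            raise ParameterError("n_pcs must be in [0, min(N, P))")
        self.components_ = (
            _genotype_pcs(Xd, self.n_pcs, self.scale)
            if self.n_pcs > 0
            else np.empty((Xd.shape[0], 0))
        )
        self.n_features_in_ = Xd.shape[1]
        return self

    def transform(self, y: np.ndarray) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ParameterError("fit must be called before transform")
        Y = np.asarray(y, dtype=float)
        squeeze = Y.ndim == 1
        Y = Y.reshape(Y.shape[0], -1)
        Yc = Y - Y.mean(axis=0)
        U = self.components_
        resid = Yc - U @ (U.T @ Yc)
        return resid.ravel() if squeeze else resid


def choose_n_pcs_elbow(eigenvalues: np.ndarray) -> int:
    """Elbow heuristic: number of PCs up to the largest consecutive drop."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        return ev.size
    drops = ev[:-1] - ev[1:]
    return int(np.argmax(drops)) + 1


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class SingleEffectFineMapper(BaseEstimator):
    """Minimal iterative Bayesian single-effect fine-mapper (PIP backend).

    A lightweight sum-of-single-effects regression for exercising the
    stability wrapper with PIP-style output: ``n_effects`` single-effect
    vectors are fit by coordinate ascent, each assigning one normalized
    inclusion-probability vector over all variants.  This is deliberately
    minimal (fixed prior effect variance, fixed residual variance, no
    credible-set post-processing) and is **not** a numerical-parity
    reimplementation of the reference SuSiE software.

    Attributes
    ----------
    potential_sets_ : list of PosteriorVector
        One ``kind='pip'`` vector per effect, each summing to 1 over all
        included variants.
    """

    def __init__(
        self,
        n_effects: int = 3,
        prior_variance: float = 0.2,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_effects = n_effects
        self.prior_variance = prior_variance
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: GenotypeMatrix | np.ndarray, y):
        Xd, positions, variant_ids = _as_arrays(X)
        yv = _phenotype_values(y)
        n, p = Xd.shape
        Xc = Xd - Xd.mean(axis=0)
        yc = yv - yv.mean()
        ssx = np.einsum("ij,ij->j", Xc, Xc)
        poly = ssx > 0
        sigma2 = float(yc @ yc) / max(n - 1, 1)
        sigma2 = sigma2 if sigma2 > 0 else 1.0
        s0 = self.prior_variance * sigma2

        L = self.n_effects
        alpha = np.full((L, p), 1.0 / max(poly.sum(), 1))
        alpha[:, ~poly] = 0.0
        mu = np.zeros((L, p))
        fitted = np.zeros(n)
        for_l = [Xc @ (alpha[l] * mu[l]) for l in range(L)]
        fitted = np.sum(for_l, axis=0)
        for _ in range(self.max_iter):
            max_change = 0.0
            for l in range(L):
                fitted -= for_l[l]
                r = yc - fitted
                bhat = np.zeros(p)
                bhat[poly] = (Xc[:, poly].T @ r) / ssx[poly]
                s2 = np.full(p, np.inf)
                s2[poly] = sigma2 / ssx[poly]
                post_var = 1.0 / (1.0 / s0 + 1.0 / s2)
                post_mean = post_var * bhat / s2
                with np.errstate(divide="ignore", invalid="ignore"):
                    log_bf = 0.5 * np.log(s2 / (s2 + s0)) + (
                        0.5 * bhat**2 / s2 * (s0 / (s0 + s2))
                    )
                log_bf[~poly] = -np.inf
                w = np.exp(log_bf - np.max(log_bf[poly]))
                w[~poly] = 0.0
                new_alpha = w / w.sum()
                max_change = max(max_change, float(np.abs(new_alpha - alpha[l]).max()))
                alpha[l] = new_alpha
                mu[l] = post_mean
                for_l[l] = Xc @ (alpha[l] * mu[l])
                fitted += for_l[l]
            if max_change < self.tol:
                break

        self.potential_sets_ = []
        order = _tie_order(positions, variant_ids)
        for l in range(L):
            probs = alpha[l][order]
            lead = int(order[np.argmax(probs)])
            self.potential_sets_.append(
                PosteriorVector(
                    support=order.astype(np.int64),
                    probs=probs,
                    lead_index=lead,
                    kind="pip",
                    n_variants=p,
                )
            )
        self.n_features_in_ = p
        return self

    def fine_map(self, X, y) -> list[PosteriorVector]:
        return self.fit(X, y).potential_sets_

    @staticmethod
    def positive_support(vec: PosteriorVector) -> np.ndarray:
        """PIP support rule: probability at least 1/(variants included)."""
        n_inc = vec.n_variants if vec.n_variants else vec.support.size
        return vec.probs >= 1.0 / n_inc


def susie_support_filter(
    pip_vector: np.ndarray | PosteriorVector, n_variants_included: int
) -> np.ndarray:
    """Indices whose PIP is at least ``1 / n_variants_included`` (inclusive).

    For a :class:`PosteriorVector`, returns the retained locus-level support
    indices; for a plain array, positions within the array.
    """
    if n_variants_included < 1:
        raise ParameterError("n_variants_included must be >= 1")
    threshold = 1.0 / n_variants_included
    if isinstance(pip_vector, PosteriorVector):
        return pip_vector.support[pip_vector.probs >= threshold]
    pips = np.asarray(pip_vector, dtype=float)
    return np.flatnonzero(pips >= threshold)


def _resolve_backend(backend, **kwargs) -> FineMapBackend:
    if isinstance(backend, str):
        if backend == "pics":
            return PicsFineMapper(**kwargs)
        if backend == "susie":
            allowed = {"n_effects", "prior_variance", "random_state"}
            return SingleEffectFineMapper(
                **{k: v for k, v in kwargs.items() if k in allowed}
            )
        raise ParameterError(f"unknown backend {backend!r}")
    if isinstance(backend, FineMapBackend):
        return backend
    raise ParameterError("backend must be 'pics', 'susie' or a FineMapBackend")


def _clone_backend_with_seed(backend: FineMapBackend, seed: int | None):
    """Re-seed an estimator backend if it exposes ``random_state``."""
    if isinstance(backend, BaseEstimator) and "random_state" in backend.get_params():
        clone = backend.__class__(**backend.get_params())
        clone.set_params(random_state=seed)
        return clone
    return backend


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------


def _argmax_with_ties(
    candidates: np.ndarray,
    probs: np.ndarray,
    positions: np.ndarray,
    variant_ids: np.ndarray,
) -> int:
    """Candidate with maximal probability; ties by (position, id)."""
    order = _tie_order(positions[candidates], np.asarray(variant_ids)[candidates])
    ordered = candidates[order]
    return int(ordered[np.argmax(probs[order])])


def plain_select(pooled: FineMapResult) -> SelectionOutcome:
    """Per potential set, the variant with maximum pooled probability."""
    selections = []
    for c, vec in enumerate(pooled.pooled):
        local = np.arange(vec.support.size)
        pick = _argmax_with_ties(
            local,
            vec.probs,
            pooled.positions[vec.support],
            pooled.variant_ids[vec.support],
        )
        idx = int(vec.support[pick])
        selections.append(
            SetSelection(
                set_index=c,
                variant_index=idx,
                variant_id=str(pooled.variant_ids[idx]),
                pooled_prob=float(vec.probs[pick]),
            )
        )
    return SelectionOutcome(method="plain", selections=selections)


def stable_from_vectors(
    pooled_vecs: list[PosteriorVector],
    slice_vecs: Mapping[str, list[PosteriorVector]],
    variant_ids: np.ndarray,
    positions: np.ndarray | None = None,
    positive=None,
    yri_label: str = YRI_LABEL,
) -> list[SetSelection | None]:
    """The two-stage stable-variant rule on precomputed probability vectors.

    For each potential set ``c``: candidates are the pooled-supported
    variants (per the support rule); each candidate's *support count* is the
    number of probability vectors — the pooled vector plus every slice that
    produced a set ``c`` — in which it has positive probability; the stable
    set keeps the candidates with maximal count, and among them the variant
    with the highest pooled probability wins (position/ID tie-break).
    Returns ``None`` for a set whose candidate pool is empty.
    """
    variant_ids = np.asarray(variant_ids, dtype=object)
    if positions is None:
        positions = np.arange(1, len(variant_ids) + 1)
    positions = np.asarray(positions)
    if positive is None:
        positive = _default_positive

    out: list[SetSelection | None] = []
    for c, pooled in enumerate(pooled_vecs):
        vectors = [pooled] + [
            vecs[c] for vecs in slice_vecs.values() if len(vecs) > c
        ]
        pooled_mask = positive(pooled)
        candidates = pooled.support[pooled_mask]
        if candidates.size == 0:
            logger.warning("potential set %d has empty positive support", c)
            out.append(None)
            continue
        counts = np.zeros(candidates.size, dtype=int)
        for vec in vectors:
            pos_support = set(vec.support[positive(vec)].tolist())
            counts += np.asarray([v in pos_support for v in candidates])
        stable_set = candidates[counts == counts.max()]
        pooled_probs = np.asarray([pooled.prob_of(v) for v in stable_set])
        local = np.arange(stable_set.size)
        pick = _argmax_with_ties(
            local, pooled_probs, positions[stable_set], variant_ids[stable_set]
        )
        chosen = int(stable_set[pick])
        in_yri = False
        yri = slice_vecs.get(yri_label)
        if yri is not None and len(yri) > c:
            in_yri = chosen in set(yri[c].support[positive(yri[c])].tolist())
        out.append(
            SetSelection(
                set_index=c,
                variant_index=chosen,
                variant_id=str(variant_ids[chosen]),
                pooled_prob=float(pooled.prob_of(chosen)),
                support_count=int(counts.max()),
                in_yri_support=in_yri,
                stable_set_ids=tuple(
                    str(variant_ids[v]) for v in np.sort(stable_set)
                ),
            )
        )
    return out


def _default_positive(vec: PosteriorVector) -> np.ndarray:
    if vec.kind == "pip":
        return SingleEffectFineMapper.positive_support(vec)
    return vec.probs > 0


def _run_slices(
    genotypes: GenotypeMatrix,
    phenotype,
    backend: FineMapBackend,
    seeds: list[int | None],
    min_slice_size: int,
) -> dict[str, list[PosteriorVector]]:
    y = _phenotype_values(phenotype)
    per_slice: dict[str, list[PosteriorVector]] = {}
    for (pop, idx), seed in zip(genotypes.slice_indices().items(), seeds):
        if idx.size < min_slice_size:
            warnings.warn(
                f"slice {pop!r} has {idx.size} samples (< {min_slice_size}); skipped",
                stacklevel=3,
            )
            continue
        sliced = genotypes.subset_samples(idx)
        slice_backend = _clone_backend_with_seed(backend, seed)
        try:
            per_slice[pop] = slice_backend.fine_map(sliced, y[idx])
        except EmptyInputError:
            logger.warning("slice %s produced no potential sets", pop)
            per_slice[pop] = []
    return per_slice


def _seed_chain(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def stable_select(
    genotypes: GenotypeMatrix,
    phenotype,
    labels: np.ndarray | None = None,
    backend: FineMapBackend | str = "pics",
    min_slice_size: int = MIN_SLICE_SIZE,
    seed: int | None = None,
    **backend_kwargs,
) -> tuple[SelectionOutcome, FineMapResult]:
    """Stability-guided selection: pooled + per-slice fine-mapping.

    The fine-mapper runs on the pooled *unresidualized* data and on each
    population slice of at least ``min_slice_size`` samples; the stable
    variant per potential set follows :func:`stable_from_vectors`.  Returns
    the outcome together with the fine-mapping result (pooled + slice
    posteriors, needed downstream by the moderator statistics).
    """
    if labels is not None:
        genotypes = GenotypeMatrix(
            dosages=genotypes.dosages,
            variant_ids=genotypes.variant_ids,
            positions=genotypes.positions,
            chrom=genotypes.chrom,
            sample_ids=genotypes.sample_ids,
            population_labels=np.asarray(labels, dtype=object),
        )
    if genotypes.population_labels is None:
        raise ParameterError("stable_select requires population labels")
    backend = _resolve_backend(backend, **backend_kwargs)
    n_slices = len(genotypes.populations)
    seeds = _seed_chain(seed, n_slices + 1)
    pooled_backend = _clone_backend_with_seed(backend, seeds[0])
    pooled = pooled_backend.fine_map(genotypes, phenotype)
    per_slice = _run_slices(genotypes, phenotype, backend, seeds[1:], min_slice_size)
    positive = getattr(backend, "positive_support", _default_positive)
    picks = stable_from_vectors(
        pooled,
        per_slice,
        genotypes.variant_ids,
        genotypes.positions,
        positive=positive,
    )
    result = FineMapResult(
        pooled=pooled,
        variant_ids=genotypes.variant_ids,
        positions=genotypes.positions,
        per_slice=per_slice,
        params={"seed": seed, "backend": type(backend).__name__},
    )
    outcome = SelectionOutcome(
        method="stable", selections=[s for s in picks if s is not None]
    )
    return outcome, result


def top_select(
    genotypes: GenotypeMatrix,
    phenotype,
    backend: FineMapBackend | str = "pics",
    n_pcs: int = 5,
    seed: int | None = None,
    **backend_kwargs,
) -> tuple[SelectionOutcome, FineMapResult]:
    """Residualization selection: fine-map the PC-residualized phenotype."""
    backend = _resolve_backend(backend, **backend_kwargs)
    backend = _clone_backend_with_seed(backend, _seed_chain(seed, 1)[0])
    y_r = residualize(genotypes, phenotype, n_pcs=n_pcs)
    pooled = backend.fine_map(genotypes, y_r)
    result = FineMapResult(
        pooled=pooled,
        variant_ids=genotypes.variant_ids,
        positions=genotypes.positions,
        params={"seed": seed, "n_pcs": n_pcs, "backend": type(backend).__name__},
    )
    outcome = plain_select(result)
    outcome = SelectionOutcome(
        method="top", selections=outcome.selections, n_pcs_removed=n_pcs
    )
    return outcome, result


def combined_select(
    genotypes: GenotypeMatrix,
    phenotype,
    labels: np.ndarray | None = None,
    backend: FineMapBackend | str = "pics",
    n_pcs: int = 5,
    min_slice_size: int = MIN_SLICE_SIZE,
    seed: int | None = None,
    **backend_kwargs,
) -> tuple[SelectionOutcome, FineMapResult]:
    """Stability-guided selection on the PC-residualized phenotype."""
    y_r = residualize(genotypes, phenotype, n_pcs=n_pcs)
    outcome, result = stable_select(
        genotypes,
        y_r,
        labels=labels,
        backend=backend,
        min_slice_size=min_slice_size,
        seed=seed,
        **backend_kwargs,
    )
    outcome = SelectionOutcome(
        method="combined", selections=outcome.selections, n_pcs_removed=n_pcs
    )
    return outcome, result


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class VariantSelector(BaseEstimator):
    """Fit one selection strategy on a locus; sklearn-compatible facade.

    Parameters
    ----------
    method : {'plain', 'top', 'stable', 'combined'}
    backend : {'pics', 'susie'} or FineMapBackend
    n_pcs : int, default 5
        PCs removed for 'top'/'combined'.
    r_threshold, n_permutations, n_potential_sets
        Forwarded to the PICS backend when ``backend='pics'``.
    min_slice_size : int, default 3
        Slices smaller than this are skipped with a warning.
    random_state : int, optional

    Attributes
    ----------
    outcome_ : SelectionOutcome
    result_ : FineMapResult
        Pooled (and, for stability methods, per-slice) posterior vectors.
    """

    def __init__(
        self,
        method: str = "stable",
        backend: str = "pics",
        n_pcs: int = 5,
        r_threshold: float = 0.5,
        n_permutations: int = 500,
        n_potential_sets: int = 3,
        min_slice_size: int = MIN_SLICE_SIZE,
        random_state: int | None = None,
    ):
        self.method = method
        self.backend = backend
        self.n_pcs = n_pcs
        self.r_threshold = r_threshold
        self.n_permutations = n_permutations
        self.n_potential_sets = n_potential_sets
        self.min_slice_size = min_slice_size
        self.random_state = random_state

    def _backend_kwargs(self) -> dict:
        if self.backend == "pics":
            return {
                "r_threshold": self.r_threshold,
                "n_permutations": self.n_permutations,
                "n_potential_sets": self.n_potential_sets,
            }
        if self.backend == "susie":
            return {"n_effects": self.n_potential_sets}
        return {}

    def fit(self, X: GenotypeMatrix, y, labels: np.ndarray | None = None):
        if self.method not in SelectionOutcome.METHODS:
            raise ParameterError(f"unknown method {self.method!r}")
        kwargs = self._backend_kwargs()
        if self.method == "plain":
            backend = _resolve_backend(self.backend, **kwargs)
            backend = _clone_backend_with_seed(
                backend, _seed_chain(self.random_state, 1)[0]
            )
            pooled = backend.fine_map(X, y)
            result = FineMapResult(
                pooled=pooled,
                variant_ids=X.variant_ids,
                positions=X.positions,
                params={"seed": self.random_state},
            )
            outcome = plain_select(result)
        elif self.method == "top":
            outcome, result = top_select(
                X, y, backend=self.backend, n_pcs=self.n_pcs,
                seed=self.random_state, **kwargs,
            )
        elif self.method == "stable":
            outcome, result = stable_select(
                X, y, labels=labels, backend=self.backend,
                min_slice_size=self.min_slice_size,
                seed=self.random_state, **kwargs,
            )
        else:  # combined
            outcome, result = combined_select(
                X, y, labels=labels, backend=self.backend, n_pcs=self.n_pcs,
                min_slice_size=self.min_slice_size,
                seed=self.random_state, **kwargs,
            )
        self.outcome_ = outcome
        self.result_ = result
        self.n_features_in_ = X.n_variants if isinstance(X, GenotypeMatrix) else X.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Selected variant IDs, one per potential set."""
        if not hasattr(self, "outcome_"):
            raise ParameterError("fit must be called before predict")
        return np.asarray(
            [s.variant_id for s in self.outcome_.selections], dtype=object
        )
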