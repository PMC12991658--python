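"""Annotation-based comparison of fine-mapped variants.

Given a user-supplied variant-by-annotation score table, this module
implements the downstream statistics for contrasting selection strategies:

* one-sided Wilcoxon tests — unpaired rank-sum for matching vs non-matching
  variant groups, paired signed-rank for top-vs-stable pairs per gene —
  with Benjamini–Hochberg adjustment applied jointly across annotations and
  potential sets within a comparison family;
* the six per-gene moderator statistics (degree of stability, population
  diversity and differentiation among supporting subpopulations, Yoruba
  support flags, top-variant posterior probability);
* trend tests of the stable-minus-top annotation differences against each
  moderator: permutation Jonckheere–Terpstra for the ordinal moderator,
  Pearson correlation tests for continuous ones, unpaired Wilcoxon for the
  binary flags — BH-adjusted within moderator.

Computation of the annotation scores themselves (Enformer tracks, CADD,
FAVOR-mined scores, ...) is out of scope: the table is an input.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FineMapResult, GenotypeMatrix, SelectionOutcome
from .errors import ParameterError
from .selection import _default_positive

__all__ = [
    "bh_adjust",
    "wilcoxon_compare",
    "hudson_fst",
    "moderators",
    "jonckheere_test",
    "trend_tests",
]


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _one_sided_rank_sum(a: np.ndarray, b: np.ndarray, direction: str) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        warnings.warn("all values tied; rank-sum p set to 1", stacklevel=3)
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative=direction).pvalue)


def _one_sided_signed_rank(a: np.ndarray, b: np.ndarray, direction: str) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    d = a[ok] - b[ok]
    d = d[d != 0]
    if d.size < 2:
        warnings.warn("fewer than 2 informative pairs; signed-rank p set to 1",
                      stacklevel=3)
        return 1.0
    return float(stats.wilcoxon(d, alternative=direction).pvalue)


def wilcoxon_compare(
    tables: dict[int, tuple[pd.DataFrame, pd.DataFrame]],
    paired: bool = False,
    direction: str = "greater",
) -> pd.DataFrame:
    """One-sided Wilcoxon tests per annotation, BH-adjusted across the family.

    ``tables`` maps a potential-set index to a pair of score DataFrames with
    identical annotation columns: for the unpaired comparison these are the
    two groups (e.g. matching vs non-matching variants); for the paired
    comparison they are row-aligned per gene (e.g. stable vs top).  The
    alternative ``direction`` ('greater'/'less') tests enrichment of the
    first table over the second.  BH is applied jointly across all
    annotations and all potential sets, mirroring one comparison family.
    """
    if direction not in ("greater", "less"):
        raise ParameterError("direction must be 'greater' or 'less'")
    rows = []
    for set_index, (table_a, table_b) in tables.items():
        cols = [c for c in table_a.columns if c in table_b.columns]
        if not cols:
            raise ParameterError("score tables share no annotation columns")
        for col in cols:
            a = table_a[col].to_numpy(dtype=float)
            b = table_b[col].to_numpy(dtype=float)
            if paired:
                if len(a) != len(b):
                    raise ParameterError("paired tables must be row-aligned")
                p = _one_sided_signed_rank(a, b, direction)
                n = int(np.sum(~(np.isnan(a) | np.isnan(b))))
            else:
                p = _one_sided_rank_sum(a, b, direction)
                n = int(np.sum(~np.isnan(a)) + np.sum(~np.isnan(b)))
            rows.append(
                {
                    "set_index": set_index,
                    "annotation": col,
                    "n": n,
                    "direction": direction,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# Moderators
# ---------------------------------------------------------------------------


def hudson_fst(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's two-population per-SNP F_ST estimator.

    ``p1, p2`` are allele frequencies; ``n1, n2`` the numbers of sampled
    chromosomes.  Returns NaN when the denominator vanishes (both
    frequencies 0 or both 1).
    """
    if n1 < 2 or n2 < 2:
        return np.nan
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den > 0 else np.nan


def moderators(
    stable_outcome: SelectionOutcome,
    stable_result: FineMapResult,
    top_outcome: SelectionOutcome,
    genotypes: GenotypeMatrix,
    yri_label: str = "YRI",
    ploidy: int = 2,
) -> pd.DataFrame:
    """The six moderator statistics, one row per potential set.

    Subpopulation support comes from the slice posteriors retained by the
    stability run; allele frequencies are per-subpopulation dosage means /
    ploidy; F_ST is Hudson's estimator maximized over pairs of
    subpopulations in which the stable variant has positive probability
    (NA when fewer than two such subpopulations exist).
    """
    if not stable_result.per_slice:
        raise ParameterError("moderators need the slice posteriors of a stability run")
    slices = genotypes.slice_indices()
    top_by_set = {s.set_index: s for s in top_outcome.selections}
    rows = []
    for sel in stable_outcome.selections:
        c = sel.set_index
        v = sel.variant_index
        supporting = []
        for pop, vecs in stable_result.per_slice.items():
            if len(vecs) <= c:
                continue
            vec = vecs[c]
            pos = set(vec.support[_default_positive(vec)].tolist())
            if v in pos:
                supporting.append(pop)
        degree = len(supporting)

        max_af_diff = np.nan
        max_fst = np.nan
        if degree >= 2:
            freqs = {}
            sizes = {}
            for pop in supporting:
                idx = slices[pop]
                freqs[pop] = float(genotypes.dosages[idx, v].mean() / ploidy)
                sizes[pop] = ploidy * idx.size
            diffs, fsts = [], []
            for pa, pb in itertools.combinations(supporting, 2):
                diffs.append(abs(freqs[pa] - freqs[pb]))
                fsts.append(hudson_fst(freqs[pa], sizes[pa], freqs[pb], sizes[pb]))
            max_af_diff = float(np.max(diffs))
            fsts = [f for f in fsts if not np.isnan(f)]
            max_fst = float(np.max(fsts)) if fsts else np.nan

        top_sel = top_by_set.get(c)
        top_in_yri = False
        if top_sel is not None:
            yri_vecs = stable_result.per_slice.get(yri_label, [])
            if len(yri_vecs) > c:
                vec = yri_vecs[c]
                pos = set(vec.support[_default_positive(vec)].tolist())
                top_in_yri = top_sel.variant_index in pos
        rows.append(
            {
                "set_index": c,
                "stable_variant": sel.variant_id,
                "top_variant": top_sel.variant_id if top_sel else None,
                "degree_of_stability": degree,
                "max_af_diff": max_af_diff,
                "max_fst": max_fst,
                "top_in_yri": top_in_yri,
                "stable_in_yri": sel.in_yri_support,
                "top_pooled_prob": top_sel.pooled_prob if top_sel else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trend tests
# ---------------------------------------------------------------------------


def _jt_statistic(values: np.ndarray, group_codes: np.ndarray, levels: np.ndarray) -> float:
    stat = 0.0
    by_level = [values[group_codes == g] for g in levels]
    for i in range(len(by_level)):
        for j in range(i + 1, len(by_level)):
            a, b = by_level[i], by_level[j]
            # Mann-Whitney count of b > a (ties count half)
            stat += np.sum(b[None, :] > a[:, None]) + 0.5 * np.sum(
                b[None, :] == a[:, None]
            )
    return float(stat)


def jonckheere_test(
    values: np.ndarray,
    groups: np.ndarray,
    alternative: str = "increasing",
    n_perm: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation Jonckheere–Terpstra trend test across ordered groups.

    Tests whether ``values`` trend upward ('increasing') or downward
    ('decreasing') across the sorted levels of ``groups``.  Returns
    ``(statistic, p)`` with the permutation p-value computed over
    ``n_perm`` random relabelings (add-one correction).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if levels.size < 3:
        raise ParameterError("Jonckheere–Terpstra needs >= 3 distinct group levels")
    if alternative not in ("increasing", "decreasing"):
        raise ParameterError("alternative must be 'increasing' or 'decreasing'")
    rng = np.random.default_rng(seed)
    observed = _jt_statistic(values, groups, levels)
    count = 0
    for _ in range(n_perm):
        perm_stat = _jt_statistic(rng.permutation(values), groups, levels)
        if alternative == "increasing" and perm_stat >= observed:
            count += 1
        elif alternative == "decreasing" and perm_stat <= observed:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def _pearson_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlation undefined (constant input)", stacklevel=3)
        return np.nan
    return float(stats.pearsonr(x, y, alternative=alternative).pvalue)


def trend_tests(
    deltas: pd.DataFrame,
    moderator: pd.Series,
    kind: str,
    n_perm: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test each annotation's stable-minus-top delta against one moderator.

    ``deltas`` is genes x annotations; ``moderator`` is index-aligned.
    ``kind`` selects the test: 'ordinal' (permutation Jonckheere–Terpstra),
    'continuous' (Pearson correlation test), 'binary' (unpaired rank-sum of
    deltas between the two flag groups).  One-sided p-values are reported in
    both directions and BH-adjusted per direction across annotations.
    """
    if kind not in ("ordinal", "continuous", "binary"):
        raise ParameterError("kind must be 'ordinal', 'continuous' or 'binary'")
    mod = moderator.loc[deltas.index]
    rows = []
    for col in deltas.columns:
        d = deltas[col].to_numpy(dtype=float)
        if kind == "ordinal":
            try:
                _, p_up = jonckheere_test(d, mod.to_numpy(), "increasing", n_perm, seed)
                _, p_dn = jonckheere_test(d, mod.to_numpy(), "decreasing", n_perm, seed)
            except ParameterError:
                p_up = p_dn = np.nan
        elif kind == "continuous":
            m = mod.to_numpy(dtype=float)
            p_up = _pearson_p(m, d, "greater")
            p_dn = _pearson_p(m, d, "less")
        else:
            flag = mod.astype(bool).to_numpy()
            p_up = _one_sided_rank_sum(d[flag], d[~flag], "greater")
            p_dn = _one_sided_rank_sum(d[flag], d[~flag], "less")
        rows.append({"annotation": col, "p_greater": p_up, "p_less": p_dn})
    out = pd.DataFrame(rows)
    out["p_bh_greater"] = bh_adjust(out["p_greater"])
    out["p_bh_less"] = bh_adjust(out["p_less"])
    return out
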