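"""Scoring fine-mapping selections against simulation truth.

Records are tidy DataFrames with one row per (dataset, method, potential
set).  Two senses of "recovered" are computed and kept apart in column
names: ``selected_causal`` (the single reported variant is causal) and
``set_contains_causal`` (the potential set's support contains at least one
causal variant).  Recovery frequencies carry Wald 95% confidence intervals
(1.96 standard errors, truncated to [0, 1]); method-vs-method comparisons
use matching fractions, an exact (binomial) McNemar test on discordant
pairs, and the matching-enrichment contrast of causal-recovery frequency
for matching versus non-matching selections.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .data import FineMapResult, SelectionOutcome
from .errors import EmptyInputError, ParameterError

__all__ = [
    "evaluation_records",
    "recovery",
    "matching",
    "mcnemar",
    "matching_enrichment",
]

RECORD_COLUMNS = [
    "dataset",
    "method",
    "set_index",
    "variant_id",
    "selected_causal",
    "set_contains_causal",
    "pooled_prob",
    "phi",
    "n_causal",
    "scenario",
]


def evaluation_records(
    dataset: str,
    outcome: SelectionOutcome,
    result: FineMapResult,
    causal_indices: np.ndarray,
    phi: float | None = None,
    n_causal: int | None = None,
    scenario: str | None = None,
) -> pd.DataFrame:
    """One row per potential set scoring a selection against the truth."""
    causal = set(np.asarray(causal_indices).tolist())
    rows = []
    for sel in outcome.selections:
        support = set(result.pooled[sel.set_index].support.tolist())
        rows.append(
            {
                "dataset": dataset,
                "method": outcome.method,
                "set_index": sel.set_index,
                "variant_id": sel.variant_id,
                "selected_causal": sel.variant_index in causal,
                "set_contains_causal": bool(support & causal),
                "pooled_prob": sel.pooled_prob,
                "phi": phi,
                "n_causal": n_causal,
                "scenario": scenario,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _wald_ci(freq: float, n: int) -> tuple[float, float]:
    se = np.sqrt(freq * (1 - freq) / n) if n > 0 else np.nan
    return max(0.0, freq - 1.96 * se), min(1.0, freq + 1.96 * se)


def recovery(
    records: pd.DataFrame,
    by: list[str] | None = None,
    flag: str = "set_contains_causal",
) -> pd.DataFrame:
    """Recovery frequency with 95% Wald CIs, per stratum.

    ``by`` lists stratifier columns (e.g. ``['method', 'set_index', 'phi']``).
    """
    if records.empty:
        raise EmptyInputError("no evaluation records")
    if flag not in records.columns:
        raise ParameterError(f"unknown flag column {flag!r}")
    by = by or ["method", "set_index"]
    rows = []
    for key, group in records.groupby(by, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        freq = float(group[flag].mean())
        n = len(group)
        lo, hi = _wald_ci(freq, n)
        rows.append(dict(zip(by, key)) | {"n": n, "frequency": freq, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _paired_selections(
    records: pd.DataFrame, method_a: str, method_b: str
) -> pd.DataFrame:
    a = records[records["method"] == method_a]
    b = records[records["method"] == method_b]
    merged = a.merge(
        b, on=["dataset", "set_index"], suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        raise EmptyInputError(
            f"no shared (dataset, set) pairs between {method_a!r} and {method_b!r}"
        )
    return merged


def matching(
    records: pd.DataFrame, method_a: str, method_b: str
) -> pd.DataFrame:
    """Per potential set: fraction of datasets where both methods pick the
    same variant, with Venn counts (matching / a-only / b-only)."""
    merged = _paired_selections(records, method_a, method_b)
    rows = []
    for set_index, grp in merged.groupby("set_index"):
        match = grp["variant_id_a"] == grp["variant_id_b"]
        n = len(grp)
        n_match = int(match.sum())
        rows.append(
            {
                "set_index": set_index,
                "n": n,
                "n_match": n_match,
                "n_a_only": n - n_match,
                "n_b_only": n - n_match,
                "fraction_match": n_match / n,
            }
        )
    return pd.DataFrame(rows)


def mcnemar(
    records: pd.DataFrame,
    method_a: str,
    method_b: str,
    set_index: int = 0,
    flag: str = "selected_causal",
) -> tuple[float, float]:
    """Exact (binomial) McNemar test on paired correctness outcomes.

    Returns ``(n_discordant, p_value)`` where discordant pairs are datasets
    on which exactly one method's selection is causal.  With zero discordant
    pairs the test is vacuous: p = 1 with a warning.
    """
    merged = _paired_selections(records, method_a, method_b)
    grp = merged[merged["set_index"] == set_index]
    a_ok = grp[f"{flag}_a"].astype(bool).to_numpy()
    b_ok = grp[f"{flag}_b"].astype(bool).to_numpy()
    b_count = int(np.sum(a_ok & ~b_ok))
    c_count = int(np.sum(~a_ok & b_ok))
    if b_count + c_count == 0:
        warnings.warn("no discordant pairs; McNemar test is vacuous", stacklevel=2)
        return 0.0, 1.0
    table = [
        [int(np.sum(a_ok & b_ok)), b_count],
        [c_count, int(np.sum(~a_ok & ~b_ok))],
    ]
    res = _sm_mcnemar(table, exact=True)
    return float(b_count + c_count), float(min(res.pvalue, 1.0))


def matching_enrichment(
    records: pd.DataFrame,
    method_a: str,
    method_b: str,
    set_index: int = 0,
    flag: str = "selected_causal",
) -> pd.DataFrame:
    """Causal-recovery frequency for matching vs non-matching selections.

    Rows: ``matching`` (both methods picked the same variant),
    ``non_matching_a`` and ``non_matching_b`` (each method's pick on the
    datasets where they disagree), with Wald CIs and the fold ratio of the
    matching frequency over each non-matching frequency (NA when a group is
    empty or its frequency is zero).
    """
    merged = _paired_selections(records, method_a, method_b)
    grp = merged[merged["set_index"] == set_index]
    match = grp["variant_id_a"] == grp["variant_id_b"]
    groups = {
        "matching": grp.loc[match, f"{flag}_a"].astype(bool),
        f"non_matching_{method_a}": grp.loc[~match, f"{flag}_a"].astype(bool),
        f"non_matching_{method_b}": grp.loc[~match, f"{flag}_b"].astype(bool),
    }
    freq_match = float(groups["matching"].mean()) if len(groups["matching"]) else np.nan
    rows = []
    for name, flags in groups.items():
        n = len(flags)
        freq = float(flags.mean()) if n else np.nan
        lo, hi = _wald_ci(freq, n) if n else (np.nan, np.nan)
        ratio = np.nan
        if name != "matching" and n and freq > 0 and not np.isnan(freq_match):
            ratio = freq_match / freq
        rows.append(
            {
                "group": name,
                "n": n,
                "frequency": freq,
                "ci_low": lo,
                "ci_high": hi,
                "fold_vs_matching": ratio,
            }
        )
    return pd.DataFrame(rows)
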