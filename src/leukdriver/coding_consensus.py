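"""Consensus combination of per-gene driver P values.

Coding driver discovery in this toolkit is consensus-based: three external
driver-detection methods are run upstream and their per-gene P values are
combined with the harmonic mean, adjusted by Benjamini-Hochberg, and filtered
by a set of simple evidence rules (significant in at least two methods,
expressed in RNA-seq, recurrently mutated). This module implements the
combiner and filters; it does not re-implement the upstream methods.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "harmonic_mean_p",
    "bh_adjust",
    "consensus_filter",
]


def harmonic_mean_p(pvalues: Iterable[float]) -> float:
    """Unweighted harmonic-mean combination of P values.

    HMP = n / sum(1/p_i). Valid as a combined test statistic for small P;
    the asymptotically exact Landau-tail correction is deliberately not
    applied (see docs/methods.md).

    Parameters
    ----------
    pvalues : iterable of float
        P values in (0, 1]. Missing values (NaN) are excluded; at least one
        finite value is required.

    Returns
    -------
    float
        Harmonic mean of the available P values, in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("harmonic_mean_p requires at least one P value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P values must lie in (0, 1]")
    return float(len(p) / np.sum(1.0 / p))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (q values).

    NaN entries are excluded from the number of tests m and returned as NaN.
    q values are monotone non-decreasing in P rank and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if np.any(pv < 0) or np.any(pv > 1):
        raise ValueError("P values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest P downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def consensus_filter(
    genes: pd.DataFrame,
    *,
    p_columns: Sequence[str] = ("p_mutsig", "p_dndscv", "p_oncodrivefml"),
    alpha: float = 0.05,
    min_significant_methods: int = 2,
    min_mutated: int = 5,
    min_tpm: float = 0.02,
    bh_scope: str = "all",
) -> pd.DataFrame:
    """Combine per-method P values and apply the consensus driver filters.

    A gene is retained iff it is significant (P < ``alpha``) in at least
    ``min_significant_methods`` methods, mutated in at least ``min_mutated``
    tumours, and expressed (mean TPM > ``min_tpm``). The harmonic-mean
    combined P is BH-adjusted either over all genes (``bh_scope="all"``,
    default) or over the post-filter subset (``bh_scope="filtered"``); both
    orderings are defensible and the q column for the other ordering is
    reported alongside.

    Parameters
    ----------
    genes : DataFrame
        Columns: ``gene``, the per-method P columns, ``n_mutated``,
        ``mean_tpm``.

    Returns
    -------
    DataFrame with added columns ``p_combined``, ``q_all``, ``q_filtered``,
    ``n_significant``, ``retained``, ``reason``.
    """
    if bh_scope not in {"all", "filtered"}:
        raise ValueError("bh_scope must be 'all' or 'filtered'")
    out = genes.copy()
    pmat = out[list(p_columns)].to_numpy(dtype=float)
    out["p_combined"] = [
        harmonic_mean_p(row[~np.isnan(row)]) if np.any(~np.isnan(row)) else np.nan
        for row in pmat
    ]
    out["n_significant"] = np.nansum(pmat < alpha, axis=1).astype(int)

    reasons = []
    retained = []
    for _, row in out.iterrows():
        why = []
        if pd.isna(row["mean_tpm"]):
            why.append("missing_expression")
        elif row["mean_tpm"] <= min_tpm:
            why.append("not_expressed")
        if row["n_significant"] < min_significant_methods:
            why.append("insufficient_methods")
        if row["n_mutated"] < min_mutated:
            why.append("insufficient_recurrence")
        reasons.append(";".join(why))
        retained.append(not why)
    out["retained"] = retained
    out["reason"] = reasons

    out["q_all"] = bh_adjust(out["p_combined"].to_numpy())
    q_filt = np.full(len(out), np.nan)
    mask = out["retained"].to_numpy()
    if mask.any():
        q_filt[mask] = bh_adjust(out.loc[mask, "p_combined"].to_numpy())
    out["q_filtered"] = q_filt
    out["q"] = out["q_all"] if bh_scope == "all" else out["q_filtered"]
    return out
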