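"""Somatic SNV/indel QC cascade and mutation burden.

Filters are applied in a fixed order -- caller PASS flag, panel of matched
normals, repeat/homopolymer masks, population allele frequency, VAF -- and
each excluded variant is attributed to the first filter it fails, so the
per-filter counts sum to input minus retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "QcThresholds",
    "build_homopolymer_mask",
    "apply_qc_filters",
    "mutation_burden",
    "CASCADE_ORDER",
]

#: filter application (and attribution) order
CASCADE_ORDER = ("non_pass", "panel", "masked_region", "population_af", "low_vaf",
                 "missing_field")


@dataclass
class QcThresholds:
    """Thresholds of the somatic QC cascade.

    popmax_af_max: exclude variants with population allele frequency above
    this (gnomAD POPMAX > 0.001). vaf_min: exclude variants with VAF strictly
    below (VAF < 5%). homopolymer_run_max: mask single-nucleotide runs longer
    than this many bases (>7).
    """

    popmax_af_max: float = 0.001
    vaf_min: float = 0.05
    homopolymer_run_max: int = 7


def build_homopolymer_mask(
    sequences: Mapping[str, str], run_threshold: int = 7
) -> dict[str, IntervalTree]:
    """Find maximal single-nucleotide runs longer than ``run_threshold``.

    Returns per-contig interval trees of 0-based half-open intervals, each a
    maximal run of length >= run_threshold + 1, sorted and non-overlapping
    (maximal runs of a single base cannot overlap).
    """
    masks: dict[str, IntervalTree] = {}
    for contig, seq in sequences.items():
        tree = IntervalTree()
        s = str(seq).upper()
        n = len(s)
        i = 0
        while i < n:
            j = i + 1
            while j < n and s[j] == s[i]:
                j += 1
            if j - i > run_threshold:
                tree.addi(i, j)
            i = j
        masks[contig] = tree
    return masks


def _variant_span(pos: int, ref: str) -> tuple[int, int]:
    """0-based half-open interval of reference bases a variant spans."""
    return pos - 1, pos - 1 + max(1, len(str(ref)))


def apply_qc_filters(
    variants: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    masks: Mapping[str, IntervalTree] | None = None,
    panel: Iterable[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the somatic QC cascade; return retained variants and counts.

    Parameters
    ----------
    variants : DataFrame
        Columns ``contig``, ``pos`` (1-based), ``ref``, ``alt``, ``filter``
        (caller FILTER string; 'PASS' retained), ``vaf`` and optionally
        ``popmax_af`` (NaN = not seen in the population database).
    masks : per-contig IntervalTree of 0-based half-open excluded intervals
        (repeats plus homopolymer runs). A variant is masked if any base of
        its reference span intersects an interval.
    panel : iterable of (contig, pos, ref, alt) tuples (panel of normals);
        matching is exact.

    Returns
    -------
    (retained, counts) where ``counts`` is a Series over the cascade filter
    names (first-failing-filter attribution) satisfying
    ``len(variants) == len(retained) + counts.sum()``.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    panel_set = set(panel) if panel is not None else set()
    counts = {name: 0 for name in CASCADE_ORDER}
    keep = np.ones(len(variants), dtype=bool)

    for i, row in enumerate(variants.itertuples(index=False)):
        filt = getattr(row, "filter", "PASS")
        if pd.notna(filt) and str(filt) not in ("PASS", "."):
            counts["non_pass"] += 1
            keep[i] = False
            continue
        key = (row.contig, int(row.pos), str(row.ref), str(row.alt))
        if key in panel_set:
            counts["panel"] += 1
            keep[i] = False
            continue
        if masks:
            tree = masks.get(row.contig)
            if tree is not None:
                s, e = _variant_span(int(row.pos), row.ref)
                if tree.overlap(s, e):
                    counts["masked_region"] += 1
                    keep[i] = False
                    continue
        af = getattr(row, "popmax_af", np.nan)
        if pd.notna(af) and af > thresholds.popmax_af_max:
            counts["population_af"] += 1
            keep[i] = False
            continue
        vaf = getattr(row, "vaf", np.nan)
        if pd.isna(vaf):
            counts["missing_field"] += 1
            keep[i] = False
            continue
        if vaf < thresholds.vaf_min:
            counts["low_vaf"] += 1
            keep[i] = False
            continue

    retained = variants.loc[keep].reset_index(drop=True)
    return retained, pd.Series(counts, name="excluded")


def mutation_burden(
    variants: pd.DataFrame,
    callable_mb: float,
    sample_ids: Iterable[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample mutation burden (variants per callable Mb) and cohort median.

    ``sample_ids`` lets samples with zero retained variants contribute a
    burden of 0 to the median.
    """
    if callable_mb <= 0:
        raise ValueError("callable genome size must be positive")
    counts = variants.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex(list(sample_ids), fill_value=0)
    burden = counts / callable_mb
    burden.name = "burden_per_mb"
    median = float(burden.median()) if len(burden) else 0.0
    return burden, median
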