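"""Clonal-architecture statistics: cluster QC, heterogeneity, compartments.

Variant clusters with cancer cell fractions (CCFs) are taken as input from
upstream clustering. The maximal-CCF cluster of a sample is clonal iff its
CCF lies strictly in (0.9, 1.1); samples fail QC if any cluster exceeds CCF
1.1 (superclonal), no clonal cluster exists, copy-state-specific variants
failed to cluster at predicted VAFs, or the copy-number solution contains a
homozygous deletion larger than 3 Mb (the latter two are auxiliary input
flags). Intratumour heterogeneity is summarised with the Gini-Simpson index
over disjoint subpopulation fractions derived from the nested CCFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding_consensus import bh_adjust

__all__ = [
    "SampleClonalityQc",
    "classify_clusters",
    "ccf_to_fractions",
    "gini_simpson",
    "simpson_heterogeneity",
    "compartment_driver_enrichment",
    "compartment_mutation_rate",
    "subclone_count_and_ccf_summary",
]

CLONAL_CCF_LOW = 0.9
CLONAL_CCF_HIGH = 1.1
HOMDEL_MAX_MB = 3.0


@dataclass
class SampleClonalityQc:
    sample_id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def classify_clusters(
    clusters: pd.DataFrame,
    *,
    homdel_segments: pd.DataFrame | None = None,
    vaf_mismatch_samples: Iterable[str] | None = None,
    homdel_max_mb: float = HOMDEL_MAX_MB,
) -> tuple[pd.DataFrame, dict[str, SampleClonalityQc]]:
    """Label CCF clusters and gate samples by the clonality QC criteria.

    The maximal-CCF cluster per sample is labelled 'clonal' when its CCF is
    strictly inside (0.9, 1.1), all other clusters 'subclonal' (an input
    ``compartment`` column with 'neutral-tail' labels is passed through).
    Clusters above CCF 1.1 are labelled 'invalid'.

    QC failure reasons per sample: 'superclonal_cluster' (any CCF > 1.1),
    'no_clonal_cluster', 'vaf_cluster_mismatch' (from
    ``vaf_mismatch_samples``), 'large_homozygous_deletion' (a state-0
    segment longer than ``homdel_max_mb`` in ``homdel_segments``).

    ``clusters`` columns: sample_id, cluster_id, ccf, n_variants.
    """
    vaf_bad = set(vaf_mismatch_samples or ())
    homdel_bad: set[str] = set()
    if homdel_segments is not None and len(homdel_segments):
        hd = homdel_segments[homdel_segments["state"] == 0]
        size_mb = (hd["end"] - hd["start"] + 1) / 1e6
        homdel_bad = set(hd.loc[size_mb > homdel_max_mb, "sample_id"])

    out = clusters.copy()
    labels = np.empty(len(out), dtype=object)
    qc: dict[str, SampleClonalityQc] = {}
    for sample, grp in out.groupby("sample_id"):
        ccfs = grp["ccf"].to_numpy(dtype=float)
        imax = grp.index[np.argmax(ccfs)]
        has_clonal = False
        for idx in grp.index:
            ccf = out.at[idx, "ccf"]
            passthrough = (
                out.at[idx, "compartment"] if "compartment" in out.columns else None
            )
            if ccf > CLONAL_CCF_HIGH:
                labels[out.index.get_loc(idx)] = "invalid"
            elif idx == imax and CLONAL_CCF_LOW < ccf < CLONAL_CCF_HIGH:
                labels[out.index.get_loc(idx)] = "clonal"
                has_clonal = True
            elif passthrough == "neutral-tail":
                labels[out.index.get_loc(idx)] = "neutral-tail"
            else:
                labels[out.index.get_loc(idx)] = "subclonal"
        reasons = []
        if np.any(ccfs > CLONAL_CCF_HIGH):
            reasons.append("superclonal_cluster")
        if not has_clonal:
            reasons.append("no_clonal_cluster")
        if sample in vaf_bad:
            reasons.append("vaf_cluster_mismatch")
        if sample in homdel_bad:
            reasons.append("large_homozygous_deletion")
        qc[sample] = SampleClonalityQc(sample, reasons)
    out["compartment"] = labels
    return out, qc


def ccf_to_fractions(ccfs: Sequence[float]) -> np.ndarray:
    """Convert nested CCFs to disjoint subpopulation fractions.

    Assumes linear nesting (each subclone is contained in the next-larger
    one): the disjoint fraction of clone i is its CCF minus its child's,
    floored at 0; the result is renormalized to sum to 1.
    """
    c = np.sort(np.asarray(ccfs, dtype=float))[::-1]
    child = np.append(c[1:], 0.0)
    f = np.maximum(c - child, 0.0)
    total = f.sum()
    if total <= 0:
        raise ValueError("all subpopulation fractions are zero")
    return f / total


def gini_simpson(fractions: Sequence[float]) -> float:
    """Gini-Simpson diversity 1 - sum(f_i^2); higher = more heterogeneous."""
    f = np.asarray(fractions, dtype=float)
    if f.size == 0 or np.any(f < 0):
        raise ValueError("fractions must be non-negative and non-empty")
    f = f / f.sum()
    return float(1.0 - np.sum(f**2))


def simpson_heterogeneity(clusters: pd.DataFrame) -> float:
    """Gini-Simpson heterogeneity of one sample's labelled clusters."""
    ccfs = clusters.loc[clusters["compartment"] != "invalid", "ccf"]
    return gini_simpson(ccf_to_fractions(ccfs.to_numpy()))


def compartment_driver_enrichment(
    variants: pd.DataFrame, driver_genes: set[str]
) -> dict:
    """Test whether driver mutations are enriched in the subclonal compartment.

    Null rate p0 = (subclonal mutations) / (all mutations) over every
    labelled variant; the observation is the number of subclonal driver
    mutations out of all driver mutations; one-sided exact binomial upper
    tail.

    ``variants`` columns: gene, compartment.
    """
    labelled = variants.dropna(subset=["compartment"])
    n_all = len(labelled)
    if n_all == 0:
        raise ValueError("no labelled variants")
    p0 = float((labelled["compartment"] == "subclonal").sum()) / n_all
    drivers = labelled[labelled["gene"].isin(driver_genes)]
    n_driver = len(drivers)
    if n_driver == 0:
        return {"p": np.nan, "n_driver": 0, "k_subclonal": 0, "p0": p0}
    k = int((drivers["compartment"] == "subclonal").sum())
    p = float(stats.binomtest(k, n_driver, p0, alternative="greater").pvalue)
    return {"p": p, "n_driver": n_driver, "k_subclonal": k, "p0": p0}


def compartment_mutation_rate(
    variants: pd.DataFrame,
    nonsynonymous_sites: float,
    gene_set: set[str],
) -> pd.Series:
    """Driver mutation rate per compartment.

    rate = (nonsynonymous variants in the gene set) / (number of
    nonsynonymous sites in the gene set) / (total mutations in the
    compartment). Compartments with no mutations are missing.

    ``variants`` columns: gene, compartment, ``nonsilent`` boolean.
    """
    if nonsynonymous_sites <= 0:
        raise ValueError("site total must be positive")
    rates = {}
    for comp, grp in variants.groupby("compartment"):
        total = len(grp)
        if total == 0:
            continue
        nonsyn = int(
            (grp["gene"].isin(gene_set) & grp["nonsilent"].astype(bool)).sum()
        )
        rates[comp] = nonsyn / nonsynonymous_sites / total
    return pd.Series(rates, name="driver_mutation_rate")


def subclone_count_and_ccf_summary(
    clusters: pd.DataFrame,
    subtypes: Mapping[str, str],
    *,
    ccf_band: tuple[float, float] = (0.7, 0.8),
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-subtype subclone counts and CCF band occupancy, with comparisons.

    For each subtype: median subclone count per sample, fraction of samples
    with at least one subclone CCF inside ``ccf_band`` (inclusive), and a
    two-sided rank-sum comparison of subclone counts against all other
    subtypes, BH adjusted. Subtypes with fewer than ``min_samples`` samples
    are skipped from comparison.
    """
    sub = clusters[clusters["compartment"] == "subclonal"]
    per_sample = sub.groupby("sample_id").agg(
        n_subclones=("cluster_id", "size"),
        in_band=("ccf", lambda c: bool(((c >= ccf_band[0]) & (c <= ccf_band[1])).any())),
    )
    all_samples = clusters["sample_id"].unique()
    per_sample = per_sample.reindex(all_samples).fillna(
        {"n_subclones": 0, "in_band": False}
    )
    per_sample["subtype"] = [subtypes.get(s, "other") for s in per_sample.index]

    rows = []
    for subtype, grp in per_sample.groupby("subtype"):
        rest = per_sample[per_sample["subtype"] != subtype]
        row = {
            "subtype": subtype,
            "n_samples": len(grp),
            "median_subclones": float(grp["n_subclones"].median()),
            "fraction_ccf_band": float(grp["in_band"].mean()),
            "p_vs_rest": np.nan,
        }
        if len(grp) >= min_samples and len(rest) >= min_samples:
            a = grp["n_subclones"].to_numpy(dtype=float)
            b = rest["n_subclones"].to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) > 0:
                row["p_vs_rest"] = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
            else:
                row["p_vs_rest"] = 1.0
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q_vs_rest"] = bh_adjust(out["p_vs_rest"].to_numpy())
    return out
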