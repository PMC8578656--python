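"""Gene-level alteration matrix, pathway roll-up and subtype enrichment.

Alterations from any class (SNV/indel, focal CNV, SV, LOH, expression
disruption) are collapsed non-redundantly into a samples x genes boolean
matrix (a tumour counts once per gene however many alteration types hit
it), rolled up to biological pathways with subtype-defining events excluded,
and each subtype's pathway alteration frequency is compared with the rest
of the cohort by a one-sided exact binomial test.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding_consensus import bh_adjust

__all__ = [
    "load_default_pathways",
    "build_alteration_matrix",
    "pathway_rollup",
    "subtype_overrepresentation",
    "subtype_burden_comparison",
]

#: alteration classes whose CNV rows must be focal to count
_CNV_TYPES = {"amplification", "deletion", "cnv"}


def load_default_pathways() -> dict[str, set[str]]:
    """Default ALL gene-to-pathway map shipped with the package (TSV)."""
    text = (
        resources.files("leukdriver.data").joinpath("pathways_default.tsv").read_text()
    )
    out: dict[str, set[str]] = {}
    for line in text.strip().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        pathway, gene = line.rstrip("\n").split("\t")[:2]
        out.setdefault(pathway, set()).add(gene)
    return out


def build_alteration_matrix(
    calls: pd.DataFrame,
    *,
    samples: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-call records into a non-redundant samples x genes matrix.

    CNV calls only count when focal (arm-level rows are ignored); all other
    classes always count. A cell is True iff the sample has at least one
    qualifying alteration of the gene; the per-cell list of alteration types
    is retained in a parallel matrix for reporting.

    ``calls`` columns: sample_id, gene, alteration_type (snv/indel/
    amplification/deletion/sv/loh/expression), and ``focal`` boolean for CNV
    rows.
    """
    keep = np.ones(len(calls), dtype=bool)
    if "focal" in calls.columns:
        is_cnv = calls["alteration_type"].str.lower().isin(_CNV_TYPES)
        keep &= ~(is_cnv & ~calls["focal"].fillna(True).astype(bool))
    calls = calls.loc[keep]

    sample_list = list(samples) if samples is not None else sorted(
        calls["sample_id"].unique()
    )
    gene_list = list(genes) if genes is not None else sorted(calls["gene"].unique())
    mat = pd.DataFrame(False, index=sample_list, columns=gene_list)
    types = pd.DataFrame("", index=sample_list, columns=gene_list)
    for row in calls.itertuples(index=False):
        if row.sample_id not in mat.index or row.gene not in mat.columns:
            continue
        mat.at[row.sample_id, row.gene] = True
        cur = types.at[row.sample_id, row.gene]
        t = str(row.alteration_type)
        seen = cur.split(";") if cur else []
        if t not in seen:
            types.at[row.sample_id, row.gene] = ";".join(seen + [t])
    return mat, types


def pathway_rollup(
    matrix: pd.DataFrame,
    pathway_map: Mapping[str, set[str]],
    *,
    subtype_labels: Mapping[str, str] | None = None,
    subtype_exclusions: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Roll the gene alteration matrix up to pathways.

    A pathway cell is True iff any member gene is altered, after removing
    subtype-defining genes for samples of that subtype (e.g. ETV6/RUNX1
    alterations do not count towards pathways in ETV6-RUNX1 fusion
    samples).
    """
    out = pd.DataFrame(False, index=matrix.index, columns=sorted(pathway_map))
    for pathway, members in pathway_map.items():
        cols = [g for g in members if g in matrix.columns]
        if not cols:
            continue
        hit = matrix[cols].copy()
        if subtype_labels and subtype_exclusions:
            for sample in matrix.index:
                excl = subtype_exclusions.get(subtype_labels.get(sample, ""), set())
                for g in excl:
                    if g in hit.columns:
                        hit.at[sample, g] = False
        out[pathway] = hit.any(axis=1)
    return out


def subtype_overrepresentation(
    pathway_matrix: pd.DataFrame,
    subtype_labels: Mapping[str, str],
    *,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per (subtype, pathway) exact binomial enrichment vs the rest.

    For subtype s and pathway p, the number of altered samples among the
    subtype's n_s is tested against the alteration frequency in all other
    subtypes (one-sided exact binomial by default). Degenerate background
    (rate 0 with observed alterations) is reported as the limiting P with a
    flag. BH adjustment across all (subtype, pathway) pairs.
    """
    labels = pd.Series({s: subtype_labels.get(s, "other") for s in pathway_matrix.index})
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("at least two subtypes required")
    rows = []
    for subtype in subtypes:
        members = labels[labels == subtype].index
        rest = labels[labels != subtype].index
        for pathway in pathway_matrix.columns:
            k = int(pathway_matrix.loc[members, pathway].sum())
            n = len(members)
            p0 = float(pathway_matrix.loc[rest, pathway].mean())
            degenerate = False
            if p0 <= 0:
                p = 0.0 if k > 0 else 1.0
                degenerate = k > 0
            elif p0 >= 1:
                p = 1.0 if alternative == "greater" else (0.0 if k < n else 1.0)
                degenerate = True
            else:
                p = float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
            rows.append(
                {
                    "subtype": subtype,
                    "pathway": pathway,
                    "k": k,
                    "n": n,
                    "background_rate": p0,
                    "p": p,
                    "degenerate": degenerate,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def subtype_burden_comparison(
    values: pd.Series,
    subtype_labels: Mapping[str, str],
    *,
    min_group: int = 2,
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus and per-subtype-vs-rest rank-sum comparisons.

    ``values`` is a per-sample numeric feature (e.g. mutation burden per
    Mb). Returns (omnibus_p, per-subtype table with BH-adjusted rank-sum
    P). A constant feature yields P = 1 for every test.
    """
    labels = pd.Series({s: subtype_labels.get(s, "other") for s in values.index})
    groups = [
        values[labels == s].to_numpy(dtype=float)
        for s in sorted(labels.unique())
        if (labels == s).sum() >= min_group
    ]
    if len(groups) < 2:
        raise ValueError("need at least two subtypes with enough samples")
    if np.ptp(values.to_numpy(dtype=float)) == 0:
        omnibus = 1.0
    else:
        omnibus = float(stats.kruskal(*groups).pvalue)
    rows = []
    for subtype in sorted(labels.unique()):
        a = values[labels == subtype].to_numpy(dtype=float)
        b = values[labels != subtype].to_numpy(dtype=float)
        if len(a) < min_group or len(b) < min_group:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"subtype": subtype, "n": len(a), "median": float(np.median(a)),
                     "p_vs_rest": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q_vs_rest"] = bh_adjust(table["p_vs_rest"].to_numpy())
    return omnibus, table
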