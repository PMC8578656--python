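"""Karyotype- and fusion-based ALL subtype assignment.

Ploidy subtypes are defined on the modal chromosome count derived from copy
number data: >50 hyperdiploid, <45 hypodiploid, with 24-30 reported as near
haploid (a subset of the hypodiploid range). Fusion subtypes require a
clonal SV joining the two partner gene loci together with expression of the
fusion transcript. iAMP21 is flagged with a simplified, configurable rule on
the RUNX1 region copy state (the full clinical definition involves detailed
chromosome-21 patterns and is deliberately not reproduced here).

Classification precedence is fusion > iAMP21 > ploidy > other: fusions and
RUNX1 amplification are initiating lesions, so they take priority over the
ploidy ranges; the order is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubtypeCall",
    "chromosome_count",
    "classify_ploidy",
    "assign_fusion_subtype",
    "classify_iamp21",
    "classify_sample",
]


@dataclass
class SubtypeCall:
    sample_id: str
    subtype: str
    evidence: dict = field(default_factory=dict)


def chromosome_count(
    segments: pd.DataFrame, contig_lengths: Mapping[str, int]
) -> int:
    """Modal chromosome count: sum of length-weighted modal copy states.

    Each contig models one chromosome pair; a fully diploid genome over 23
    modelled contigs therefore counts 46. Every modelled contig must be
    fully covered by segments; uncovered contigs raise an error listing the
    gaps.

    ``segments`` columns: contig, start, end (1-based inclusive), state.
    """
    gaps = []
    total = 0
    for contig, length in contig_lengths.items():
        grp = segments[segments["contig"] == contig].sort_values("start")
        covered = 0
        weights: dict[int, int] = {}
        prev_end = 0
        for row in grp.itertuples(index=False):
            covered += int(row.end) - int(row.start) + 1
            if int(row.start) > prev_end + 1:
                gaps.append((contig, prev_end + 1, int(row.start) - 1))
            prev_end = max(prev_end, int(row.end))
            state = row.state
            if state is not None and not pd.isna(state):
                w = int(row.end) - int(row.start) + 1
                weights[int(state)] = weights.get(int(state), 0) + w
        if prev_end < length:
            gaps.append((contig, prev_end + 1, length))
        if not weights:
            gaps.append((contig, 1, length))
            continue
        # modal = state with the largest covered length; ties -> lower state
        modal = max(sorted(weights), key=lambda s: weights[s])
        total += modal
    if gaps:
        raise ValueError(f"contigs not fully segmented; gaps: {gaps}")
    return int(total)


def classify_ploidy(count: int) -> str | None:
    """Ploidy subtype from the modal chromosome count.

    >50 hyperdiploid; 24-30 near-haploid; otherwise <45 hypodiploid; counts
    in [45, 50] carry no ploidy subtype. Partitions the positive integers.
    """
    if count < 1:
        raise ValueError("chromosome count must be >= 1")
    if count > 50:
        return "hyperdiploid"
    if 24 <= count <= 30:
        return "near-haploid"
    if count < 45:
        return "hypodiploid"
    return None


def assign_fusion_subtype(
    svs: pd.DataFrame,
    expressed_fusions: set[str],
    rules: Mapping[tuple[str, str], str],
    gene_loci: Mapping[str, tuple[str, int, int]],
    *,
    ccf_min: float = 0.9,
) -> tuple[str | None, dict]:
    """Assign a fusion subtype from clonal SVs plus fusion expression.

    A rule (geneA, geneB) -> subtype fires iff some SV with CCF >=
    ``ccf_min`` has one breakend inside each gene locus (either orientation
    of the pair) AND the fusion 'geneA-geneB' appears in the expression
    table. Conflicting fired rules yield ('other', conflict evidence).

    ``gene_loci`` values are (contig, start, end), 0-based half-open.
    """

    def in_locus(gene, chrom, pos):
        c, s, e = gene_loci[gene]
        return chrom == c and s < int(pos) <= e

    fired = {}
    for (ga, gb), name in rules.items():
        if f"{ga}-{gb}" not in expressed_fusions:
            continue
        if ga not in gene_loci or gb not in gene_loci:
            continue
        for row in svs.itertuples(index=False):
            ccf = getattr(row, "ccf", np.nan)
            if pd.isna(ccf) or ccf < ccf_min:
                continue
            ends = ((row.chrom1, row.pos1), (row.chrom2, row.pos2))
            hit = (in_locus(ga, *ends[0]) and in_locus(gb, *ends[1])) or (
                in_locus(ga, *ends[1]) and in_locus(gb, *ends[0])
            )
            if hit:
                fired[name] = {"genes": (ga, gb), "sv": ends, "ccf": float(ccf)}
                break
    if not fired:
        return None, {}
    if len(fired) > 1:
        return "other", {"conflict": sorted(fired)}
    name, ev = next(iter(fired.items()))
    return f"fusion:{name}", ev


def classify_iamp21(
    segments: pd.DataFrame,
    runx1_region: tuple[str, int, int],
    *,
    min_state: int = 5,
) -> bool:
    """Simplified iAMP21 flag: RUNX1-region modal copy state >= min_state.

    ``runx1_region`` is (contig, start, end) 1-based inclusive. The region
    must be covered by at least one segment.
    """
    contig, rs, re = runx1_region
    grp = segments[segments["contig"] == contig]
    weights: dict[int, int] = {}
    for row in grp.itertuples(index=False):
        ov = min(int(row.end), re) - max(int(row.start), rs) + 1
        if ov > 0 and not pd.isna(row.state):
            weights[int(row.state)] = weights.get(int(row.state), 0) + ov
    if not weights:
        raise ValueError("RUNX1 region not covered by any segment")
    modal = max(sorted(weights), key=lambda s: weights[s])
    return modal >= min_state


def classify_sample(
    sample_id: str,
    *,
    count: int | None = None,
    fusion: tuple[str | None, dict] = (None, {}),
    iamp21: bool = False,
    precedence: Sequence[str] = ("fusion", "iamp21", "ploidy"),
) -> SubtypeCall:
    """Combine evidence into a single subtype call with fixed precedence."""
    evidence: dict = {"chromosome_count": count, "iamp21": iamp21}
    fusion_name, fusion_ev = fusion
    if fusion_ev:
        evidence["fusion"] = fusion_ev
    for kind in precedence:
        if kind == "fusion" and fusion_name is not None:
            return SubtypeCall(sample_id, fusion_name, evidence)
        if kind == "iamp21" and iamp21:
            return SubtypeCall(sample_id, "iAMP21", evidence)
        if kind == "ploidy" and count is not None:
            label = classify_ploidy(count)
            if label is not None:
                return SubtypeCall(sample_id, label, evidence)
    return SubtypeCall(sample_id, "other", evidence)
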