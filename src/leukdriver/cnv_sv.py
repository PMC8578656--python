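"""Copy-number state assignment, SV consensus merging and joint CNV/SV tests.

Covers the structural side of driver discovery: mapping purity-adjusted log2
ratios to integer copy states, arm vs focal classification, multi-caller SV
merging (consensus requires support from at least two callers), SV quality
filters, post-filters for candidate amplified/deleted regions, the
arm-specific SV-enrichment permutation test, and threshold-based
chromothripsis flagging (runs of oscillating copy states with many
interleaved SVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "DEFAULT_STATE_MAP",
    "ArmModel",
    "assign_copy_state",
    "classify_arm_focal",
    "merge_sv_calls",
    "filter_svs",
    "filter_candidate_regions",
    "sv_enrichment_test",
    "detect_chromothripsis",
]

#: Monotone copy-state map: list of (upper bound, strict) cascade rules.
#: state s is assigned at the first rule the log2 ratio satisfies
#: (x < bound if strict else x <= bound); values beyond the last bound get
#: the top state. Default: <-1.1 -> 0, [-1.1,-0.3) -> 1, [-0.3,0.3] -> 2,
#: (0.3,0.7] -> 3, >0.7 -> 4. Fully configurable.
DEFAULT_STATE_MAP: tuple[tuple[float, bool], ...] = (
    (-1.1, True),
    (-0.3, True),
    (0.3, False),
    (0.7, False),
)


def assign_copy_state(
    log2_ratio: float, state_map: Sequence[tuple[float, bool]] = DEFAULT_STATE_MAP
) -> int | None:
    """Map a purity-adjusted log2 ratio to an integer copy state.

    Non-decreasing step function of log2 given a monotone map. NaN input
    returns None (unassigned).
    """
    bounds = [b for b, _ in state_map]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("state map bounds must be strictly increasing")
    x = float(log2_ratio)
    if np.isnan(x):
        return None
    for state, (bound, strict) in enumerate(state_map):
        if (x < bound) if strict else (x <= bound):
            return state
    return len(state_map)


@dataclass
class ArmModel:
    """Mappable p/q-arm intervals per contig.

    ``arms[contig][arm]`` is a list of (start, end) 0-based half-open
    mappable intervals; what counts as mappable is taken as input, not
    derived.
    """

    arms: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)

    def arm_length(self, contig: str, arm: str) -> int:
        return sum(e - s for s, e in self.arms[contig][arm])

    def intervals(self, contig: str, arm: str) -> list[tuple[int, int]]:
        return self.arms[contig][arm]


def _overlap_len(s: int, e: int, intervals: Iterable[tuple[int, int]]) -> int:
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def classify_arm_focal(
    segment: Mapping, arm_model: ArmModel
) -> str:
    """Classify a CNV segment as 'arm' or 'focal'.

    'arm' iff the segment covers more than 80% of either arm's mappable
    length (strictly greater). Segments on unmodelled contigs are focal.
    Segment coordinates are 1-based inclusive.
    """
    contig = segment["contig"]
    if contig not in arm_model.arms:
        return "focal"
    s0, e0 = int(segment["start"]) - 1, int(segment["end"])
    for arm in arm_model.arms[contig]:
        total = arm_model.arm_length(contig, arm)
        if total <= 0:
            continue
        cov = _overlap_len(s0, e0, arm_model.intervals(contig, arm))
        if cov / total > 0.8:
            return "arm"
    return "focal"


# ---------------------------------------------------------------------------
# SV merging & filtering


_SV_KEY = ("chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "svtype")


def merge_sv_calls(
    callsets: Mapping[str, pd.DataFrame],
    *,
    tolerance: int = 200,
    min_support: int = 2,
) -> pd.DataFrame:
    """Merge per-caller SV calls into consensus calls with caller support.

    Two calls merge iff they have the same type, the same breakend
    orientations and contigs, and both breakend positions within
    ``tolerance`` bp; merging is transitive (single-linkage components).
    The consensus breakend position is the median of the merged positions.
    Only clusters supported by at least ``min_support`` distinct callers are
    retained; output is invariant to caller ordering.

    Each callset DataFrame needs columns chrom1, pos1, strand1, chrom2,
    pos2, strand2, svtype, and optionally vaf (consensus vaf = median).
    """
    calls = []
    for caller in sorted(callsets):
        df = callsets[caller]
        for row in df.itertuples(index=False):
            calls.append((caller, row))
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def compatible(a, b):
        return (
            a.svtype == b.svtype
            and a.chrom1 == b.chrom1
            and a.chrom2 == b.chrom2
            and a.strand1 == b.strand1
            and a.strand2 == b.strand2
            and abs(int(a.pos1) - int(b.pos1)) <= tolerance
            and abs(int(a.pos2) - int(b.pos2)) <= tolerance
        )

    for i in range(n):
        for j in range(i + 1, n):
            if compatible(calls[i][1], calls[j][1]):
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    rows = []
    for members in clusters.values():
        callers = sorted({calls[i][0] for i in members})
        if len(callers) < min_support:
            continue
        recs = [calls[i][1] for i in members]
        r0 = recs[0]
        row = {
            "chrom1": r0.chrom1,
            "pos1": int(np.median([int(r.pos1) for r in recs])),
            "strand1": r0.strand1,
            "chrom2": r0.chrom2,
            "pos2": int(np.median([int(r.pos2) for r in recs])),
            "strand2": r0.strand2,
            "svtype": r0.svtype,
            "callers": ",".join(callers),
            "n_callers": len(callers),
        }
        if all(hasattr(r, "vaf") for r in recs):
            row["vaf"] = float(np.median([r.vaf for r in recs]))
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["chrom1", "pos1", "chrom2", "pos2"]).reset_index(
            drop=True
        )
    return out


def filter_svs(
    svs: pd.DataFrame,
    excluded_regions: Mapping[str, IntervalTree] | None = None,
    *,
    vaf_min: float = 0.1,
    panel: Iterable[tuple] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop SVs in excluded regions, with low VAF, or matching a panel.

    An SV is dropped if either breakend falls in an excluded interval
    (centromeric/telomeric/heterochromatic masks), its VAF is strictly below
    ``vaf_min``, or it matches a panel-of-normals record exactly on
    (chrom1, pos1, chrom2, pos2, svtype). Missing VAF is dropped and counted
    under a separate category.
    """
    panel_set = set(panel) if panel is not None else set()
    counts = {"excluded_region": 0, "low_vaf": 0, "panel": 0, "missing_vaf": 0}
    keep = np.ones(len(svs), dtype=bool)
    for i, row in enumerate(svs.itertuples(index=False)):
        if excluded_regions:
            in_excl = False
            for chrom, pos in ((row.chrom1, row.pos1), (row.chrom2, row.pos2)):
                tree = excluded_regions.get(chrom)
                if tree is not None and tree.overlap(int(pos) - 1, int(pos)):
                    in_excl = True
                    break
            if in_excl:
                counts["excluded_region"] += 1
                keep[i] = False
                continue
        vaf = getattr(row, "vaf", np.nan)
        if pd.isna(vaf):
            counts["missing_vaf"] += 1
            keep[i] = False
            continue
        if vaf < vaf_min:
            counts["low_vaf"] += 1
            keep[i] = False
            continue
        key = (row.chrom1, int(row.pos1), row.chrom2, int(row.pos2), row.svtype)
        if key in panel_set:
            counts["panel"] += 1
            keep[i] = False
            continue
    return svs.loc[keep].reset_index(drop=True), pd.Series(counts, name="excluded")


# ---------------------------------------------------------------------------
# candidate-region post-filters


def filter_candidate_regions(
    regions: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    ig_regions: Mapping[str, IntervalTree] | None = None,
    *,
    q_max: float = 0.01,
    deleted_samples: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Post-filter candidate amplified/deleted regions.

    A region is dropped if it overlaps an immunoglobulin locus, contains no
    protein-coding gene, contains no expressed gene (mean TPM over
    non-deleted samples > 0), is flagged both amplified and deleted, or has
    Q > ``q_max``. Regions must carry a ``q`` value.

    Parameters
    ----------
    regions : DataFrame with columns region_id, contig, start, end (0-based
        half-open), ``amplified``/``deleted`` booleans and ``q``.
    gene_annotation : DataFrame with columns gene, contig, start, end,
        ``protein_coding`` boolean.
    expression : genes x samples TPM matrix (optional; expression filter
        skipped when absent).
    deleted_samples : mapping region_id -> samples deleted at the region,
        excluded when computing mean TPM.
    """
    if regions["q"].isna().any():
        raise ValueError("every candidate region must carry a Q value")
    gene_trees: dict[str, IntervalTree] = {}
    for contig, grp in gene_annotation.groupby("contig"):
        tree = IntervalTree()
        for g, s, e, pc in zip(grp["gene"], grp["start"], grp["end"],
                               grp["protein_coding"]):
            if e > s:
                tree.addi(int(s), int(e), (g, bool(pc)))
        gene_trees[str(contig)] = tree

    keep = []
    reasons = []
    for row in regions.itertuples(index=False):
        reason = ""
        if ig_regions:
            tree = ig_regions.get(row.contig)
            if tree is not None and tree.overlap(int(row.start), int(row.end)):
                reason = "immunoglobulin_overlap"
        if not reason and bool(row.amplified) and bool(row.deleted):
            reason = "amplified_and_deleted"
        if not reason and row.q > q_max:
            reason = "q_above_threshold"
        if not reason:
            tree = gene_trees.get(row.contig)
            hits = tree.overlap(int(row.start), int(row.end)) if tree else set()
            genes = [h.data for h in hits]
            if not any(pc for _, pc in genes):
                reason = "no_protein_coding_gene"
            elif expression is not None:
                excl = set() if deleted_samples is None else set(
                    deleted_samples.get(row.region_id, set())
                )
                cols = [c for c in expression.columns if c not in excl]
                expressed = False
                for g, _ in genes:
                    if g in expression.index and cols:
                        if float(expression.loc[g, cols].mean()) > 0:
                            expressed = True
                            break
                if not expressed:
                    reason = "no_expressed_gene"
        keep.append(not reason)
        reasons.append(reason)
    out = regions.copy()
    out["retained"] = keep
    out["drop_reason"] = reasons
    return out


# ---------------------------------------------------------------------------
# SV enrichment permutation test


def sv_enrichment_test(
    region: tuple[int, int],
    sv_intervals: Sequence[tuple[int, int]],
    arm_intervals: Sequence[tuple[int, int]],
    *,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    pseudocount: bool = False,
    p_threshold: float = 0.01,
) -> tuple[float, bool]:
    """Permutation test for SV enrichment over a candidate region.

    Only simple SVs of the matching direction should be passed in (the
    caller pre-filters). Each permutation re-places every SV uniformly over
    the arm's mappable intervals preserving its length (coordinates are
    mapped into the concatenated mappable space); P is the proportion of
    permutations in which the simulated overlap count is >= the observed
    count. With ``pseudocount`` the strictly positive (r+1)/(n+1) variant is
    returned instead.

    Parameters are 0-based half-open intervals on one chromosome arm.

    Returns
    -------
    (p, retained) with retained = (p < p_threshold).
    """
    if rng is None:
        rng = np.random.default_rng()
    arm_intervals = sorted(arm_intervals)
    arm_len = sum(e - s for s, e in arm_intervals)
    # map the region into concatenated mappable coordinates
    offs = []
    acc = 0
    region_parts = []
    for s, e in arm_intervals:
        ov_s, ov_e = max(s, region[0]), min(e, region[1])
        if ov_e > ov_s:
            region_parts.append((acc + (ov_s - s), acc + (ov_e - s)))
        offs.append((s, e, acc))
        acc += e - s
    region_mappable = sum(e - s for s, e in region_parts)
    if region[1] - region[0] > arm_len:
        raise ValueError("region longer than arm")
    if region_mappable == 0:
        return (1.0, False)

    def overlaps_region(starts: np.ndarray, length: int) -> np.ndarray:
        hit = np.zeros(starts.shape, dtype=bool)
        for rs, re in region_parts:
            hit |= (starts < re) & (starts + length > rs)
        return hit

    obs = 0
    lengths = []
    for s, e in sv_intervals:
        length = max(1, e - s)
        lengths.append(length)
        if min(e, region[1]) > max(s, region[0]):
            obs += 1
    lengths = np.asarray(lengths, dtype=int)

    sim_counts = np.zeros(n_perm, dtype=int)
    for length in lengths:
        max_start = max(1, arm_len - int(length))
        starts = rng.integers(0, max_start, size=n_perm)
        sim_counts += overlaps_region(starts, int(length))
    r = int(np.sum(sim_counts >= obs))
    p = (r + 1) / (n_perm + 1) if pseudocount else r / n_perm
    return float(p), bool(p < p_threshold)


# ---------------------------------------------------------------------------
# chromothripsis


def detect_chromothripsis(
    segments: pd.DataFrame,
    svs: pd.DataFrame,
    *,
    min_run: int = 4,
    min_svs: int = 6,
) -> list[dict]:
    """Flag candidate chromothripsis events.

    A candidate is a maximal run of adjacent segments on one contig whose
    copy states alternate between exactly two values, with run length
    strictly greater than 3 (``min_run`` = 4) and strictly more than 5
    (``min_svs`` = 6) SVs having both breakends inside the run's span.
    Breakend orientation is ignored.

    ``segments`` columns: contig, start, end (1-based inclusive), state;
    ``svs`` columns: chrom1, pos1, chrom2, pos2.
    """
    events = []
    for contig, grp in segments.groupby("contig"):
        grp = grp.sort_values("start").reset_index(drop=True)
        states = grp["state"].to_numpy()
        n = len(grp)
        i = 0
        while i < n - 1:
            if states[i + 1] == states[i]:
                i += 1
                continue
            a, b = states[i], states[i + 1]
            j = i + 1
            while j + 1 < n and states[j + 1] == (a if states[j] == b else b) and \
                    states[j + 1] != states[j]:
                j += 1
            run_len = j - i + 1
            if run_len >= min_run:
                span = (int(grp.loc[i, "start"]), int(grp.loc[j, "end"]))
                inside = svs[
                    (svs["chrom1"] == contig)
                    & (svs["chrom2"] == contig)
                    & (svs["pos1"] >= span[0])
                    & (svs["pos1"] <= span[1])
                    & (svs["pos2"] >= span[0])
                    & (svs["pos2"] <= span[1])
                ]
                if len(inside) >= min_svs:
                    events.append(
                        {
                            "contig": contig,
                            "start": span[0],
                            "end": span[1],
                            "n_segments": int(run_len),
                            "states": tuple(int(s) for s in states[i : j + 1]),
                            "n_svs": int(len(inside)),
                        }
                    )
            i = j
    return events
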