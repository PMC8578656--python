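"""Motif content of SV breakpoint flanks.

RAG-mediated rearrangement leaves recombination-signal-sequence motifs (the
canonical heptamer CACAGTG and nonamer ACAAAAACC) at breakpoints, and AID
activity is proxied by the number of core recognition-sequence repeats
(default WRCY and its reverse complement RGYW) in the two 100 bp windows
flanking an SV's breakends; more than 10 repeats is taken as indicative of
AID activity. Enrichment of a motif at breakpoints is tested against
dinucleotide-shuffled background sequences with a one-sided Fisher exact
test, and discovered position weight matrices are annotated against
reference and candidate motif sets by best-offset Pearson correlation
(labels below r = 0.85 are excluded; a candidate label is substituted when
it correlates better than the best reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "MotifModel",
    "BreakpointWindow",
    "RAG_HEPTAMER",
    "RAG_NONAMER",
    "AID_CORE_MOTIFS",
    "revcomp",
    "extract_windows",
    "scan_motif",
    "count_aid_repeats",
    "dinucleotide_shuffle",
    "motif_enrichment",
    "pwm_correlation",
    "annotate_motif",
    "aid_threshold_from_ig",
]

#: canonical recombination-signal sequences (config-driven defaults)
RAG_HEPTAMER = "CACAGTG"
RAG_NONAMER = "ACAAAAACC"
#: default AID core recognition motifs, scanned on the forward strand only
#: (the list already contains both orientations)
AID_CORE_MOTIFS = ("WRCY", "RGYW")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named motif: IUPAC consensus and/or position weight matrix."""

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (4, width), columns sum to 1
    source: str = "reference"

    def __post_init__(self):
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC characters in consensus: {bad}")
        if self.pwm is not None:
            pwm = np.asarray(self.pwm, dtype=float)
            if pwm.shape[0] != 4 or not np.allclose(pwm.sum(axis=0), 1, atol=1e-9):
                raise ValueError("PWM must be 4 x width with columns summing to 1")
            self.pwm = pwm


@dataclass
class BreakpointWindow:
    sv_id: str
    breakend: str  # 'A' or 'B'
    sequence: str
    clipped: bool = False


def extract_windows(
    svs: pd.DataFrame,
    reference: Mapping[str, str],
    *,
    flank: int = 50,
    ig_regions: Mapping[str, IntervalTree] | None = None,
) -> list[BreakpointWindow]:
    """Extract the +/-``flank`` bp sequence window around each SV breakend.

    Each retained SV contributes exactly two windows ([pos-flank, pos+flank)
    around each breakend, 1-based positions). SVs with BOTH breakends in
    immunoglobulin regions are skipped entirely (the rule is conjunctive);
    windows truncated at contig edges are clipped and flagged. A breakend
    off its contig raises an error.

    ``svs`` columns: sv_id, chrom1, pos1, chrom2, pos2.
    """

    def in_ig(chrom, pos):
        if not ig_regions:
            return False
        tree = ig_regions.get(chrom)
        return bool(tree is not None and tree.overlap(int(pos) - 1, int(pos)))

    windows = []
    for row in svs.itertuples(index=False):
        ends = [(row.chrom1, int(row.pos1)), (row.chrom2, int(row.pos2))]
        if all(in_ig(c, p) for c, p in ends):
            continue
        for label, (chrom, pos) in zip("AB", ends):
            if chrom not in reference:
                raise KeyError(f"contig {chrom!r} not in reference")
            seq = str(reference[chrom])
            if pos < 1 or pos > len(seq):
                raise ValueError(f"breakend {chrom}:{pos} off contig")
            s = max(0, pos - 1 - flank)
            e = min(len(seq), pos - 1 + flank)
            windows.append(
                BreakpointWindow(
                    sv_id=str(row.sv_id),
                    breakend=label,
                    sequence=seq[s:e].upper(),
                    clipped=(e - s) < 2 * flank,
                )
            )
    return windows


def _match_at(seq: str, motif: str, i: int) -> bool:
    return all(seq[i + j] in IUPAC[m] for j, m in enumerate(motif))


def scan_motif(
    sequence: str,
    motif: str,
    *,
    both_strands: bool = True,
) -> tuple[int, list[tuple[int, str]]]:
    """Count overlapping IUPAC motif matches on one or both strands.

    Returns (count, positions) where positions are 0-based offsets on the
    given sequence, each tagged with the matching strand ('+' or '-'; the
    reverse strand is scanned by matching the motif's reverse complement on
    the forward sequence).
    """
    seq = sequence.upper()
    motif = motif.upper()
    w = len(motif)
    hits: list[tuple[int, str]] = []
    if w == 0 or len(seq) < w:
        return 0, hits
    queries = [(motif, "+")]
    if both_strands:
        rc = revcomp(motif)
        if rc != motif:
            queries.append((rc, "-"))
    for query, strand in queries:
        for i in range(len(seq) - w + 1):
            if "N" not in seq[i : i + w] and _match_at(seq, query, i):
                hits.append((i, strand))
    hits.sort()
    return len(hits), hits


def count_aid_repeats(
    windows: Sequence[str],
    core_motifs: Sequence[str] = AID_CORE_MOTIFS,
    *,
    threshold: int = 10,
) -> tuple[int, bool]:
    """Total AID core-motif repeat count over an SV's breakpoint windows.

    Counts overlapping occurrences of each core motif on the forward strand
    of every window (the default motif list carries both orientations, so no
    extra strand pass is made). The SV is AID-positive iff the count is
    strictly greater than ``threshold`` (> 10 repeats).
    """
    total = 0
    for seq in windows:
        for motif in core_motifs:
            total += scan_motif(seq, motif, both_strands=False)[0]
    return total, total > threshold


def aid_threshold_from_ig(ig_counts: Sequence[int], quantile: float = 0.5) -> float:
    """Optional calibration helper: a quantile of repeat counts observed at
    immunoglobulin-region SVs (known AID targets). The package default
    threshold (10) is used unless the caller re-derives one here."""
    return float(np.quantile(np.asarray(ig_counts, dtype=float), quantile))


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul-Erickson style: random Eulerian walk over the dinucleotide
    transition multigraph, guaranteeing the exact dinucleotide counts of the
    input (same first and last base).
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    terminal = seq[-1]

    def last_edges_ok(lasts: dict[str, str]) -> bool:
        # following last edges from every vertex must reach the terminal
        for v in edges:
            if v == terminal:
                continue
            u, hops = v, 0
            while u != terminal:
                if u not in lasts or hops > len(edges):
                    return False
                u = lasts[u]
                hops += 1
        return True

    for _ in range(1000):
        lasts = {
            v: outs[rng.integers(len(outs))]
            for v, outs in edges.items()
            if v != terminal
        }
        if last_edges_ok(lasts):
            break
    else:  # pragma: no cover - pathological composition, leave unshuffled
        return seq

    walk_lists: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in lasts:
            rest.remove(lasts[v])
        rng.shuffle(rest)
        if v in lasts:
            rest.append(lasts[v])
        walk_lists[v] = rest
    out = [seq[0]]
    idx = {v: 0 for v in walk_lists}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_lists[v][idx[v]]
        idx[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def motif_enrichment(
    breakpoint_windows: Sequence[str],
    background_windows: Sequence[str],
    motif: str,
    *,
    both_strands: bool = True,
) -> tuple[float, float]:
    """One-sided Fisher exact test for motif enrichment at breakpoints.

    2x2 table of (window contains >= 1 match) x (breakpoint vs background);
    alternative: breakpoint windows are enriched. Returns (p, odds_ratio);
    the odds ratio is inf for a degenerate table.
    """
    if len(background_windows) == 0:
        raise ValueError("background windows required")
    a = sum(scan_motif(s, motif, both_strands=both_strands)[0] > 0
            for s in breakpoint_windows)
    b = len(breakpoint_windows) - a
    c = sum(scan_motif(s, motif, both_strands=both_strands)[0] > 0
            for s in background_windows)
    d = len(background_windows) - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return float(res.pvalue), float(odds)


def pwm_correlation(pwm_a: np.ndarray, pwm_b: np.ndarray) -> float:
    """Best-offset Pearson correlation between two PWMs.

    The shorter matrix is padded with uniform (0.25) background columns; all
    offsets of the shorter within the longer width are tried and the best r
    over the flattened aligned matrices is returned. NaN when either matrix
    has zero variance after padding.
    """
    a = np.asarray(pwm_a, dtype=float)
    b = np.asarray(pwm_b, dtype=float)
    if a.shape[1] < b.shape[1]:
        a, b = b, a
    wa, wb = a.shape[1], b.shape[1]
    best = np.nan
    for off in range(wa - wb + 1):
        padded = np.full((4, wa), 0.25)
        padded[:, off : off + wb] = b
        x, y = a.ravel(), padded.ravel()
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if np.isnan(best) or r > best:
            best = r
    return best


def annotate_motif(
    discovered: np.ndarray,
    reference_set: Mapping[str, np.ndarray],
    candidate_set: Mapping[str, np.ndarray],
    *,
    min_r: float = 0.85,
) -> tuple[str | None, float, str]:
    """Annotate a discovered PWM against reference and candidate motif sets.

    The best-correlated reference label is replaced by a candidate label
    when the candidate correlates better; motifs whose best correlation is
    below ``min_r`` are excluded (label None).

    Returns (label, r, source) with source in {'candidate', 'reference',
    'excluded'}.
    """
    best_ref, r_ref = None, -np.inf
    for name, pwm in reference_set.items():
        r = pwm_correlation(discovered, pwm)
        if not np.isnan(r) and r > r_ref:
            best_ref, r_ref = name, r
    best_cand, r_cand = None, -np.inf
    for name, pwm in candidate_set.items():
        r = pwm_correlation(discovered, pwm)
        if not np.isnan(r) and r > r_cand:
            best_cand, r_cand = name, r
    if r_cand > r_ref:
        label, r = best_cand, r_cand
        source = "candidate"
    else:
        label, r = best_ref, r_ref
        source = "reference"
    if label is None or r < min_r:
        return None, float(r) if np.isfinite(r) else np.nan, "excluded"
    return label, float(r), source
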