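"""Fully synthetic ALL-like cohort generator with known ground truth.

The real cohorts this toolkit targets are access-restricted, so every
downstream statistic is exercised against a generated cohort whose ground
truth is recorded alongside. The generator emulates the features the
analyses consume -- per-tumour mutation counts, covariate-dependent mutation
placement over regulatory regions, planted driver regions with elevated
recurrence, positional clustering and an expression effect, copy-number
profiles realising the ALL karyotype classes, SV breakpoints with planted
RAG/AID motifs, and nested CCF cluster structures -- on a deliberately
compressed genome (23 contigs of a few Mb) so whole-cohort runs finish in
minutes. Distributional choices are artifact design, recorded in the
config, not claims about any real cohort; see docs/methods.md.

Mutation placement matches the inference model family: for tumour t and
region r the region-mutated indicator is Bernoulli with probability
logistic(a_t + beta . x_r), where x_r are the standardized region
covariates (GC, replication timing, coverage, log-length) and a_t is a
tumour-specific intercept. Parameter recovery by the background model is
therefore well-posed.

All randomness flows from one seeded numpy Generator; identical config and
seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContigSpec",
    "PlantedDriver",
    "ClonalArchitecture",
    "CohortConfig",
    "SyntheticCohort",
    "default_genome",
    "generate_cohort",
    "simulate_reference",
    "simulate_karyotype",
    "simulate_breakpoint_sequences",
    "simulate_ccf_clusters",
]

#: chromosome-count target ranges per karyotype subtype
KARYOTYPE_RANGES = {
    "hyperdiploid": (51, 67),
    "hypodiploid": (39, 44),
    "near-haploid": (24, 30),
    "diploid-range": (46, 46),
}

#: log2 ratio emitted for each integer copy state (noise stays within the
#: default copy-state map's band for the state)
_STATE_LOG2 = {0: -2.0, 1: -0.7, 2: 0.0, 3: 0.5, 4: 0.85}


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int
    gc: float = 0.41

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigurationError(f"contig {self.name}: length must be > 0")


@dataclass(frozen=True)
class PlantedDriver:
    """A region with elevated recurrence, clustering and expression effect.

    recurrence_multiplier scales the per-tumour mutation probability (>= 1);
    cluster_width concentrates the planted mutations into a window of that
    many bp (0 = uniform over the region); expression_effect multiplies the
    target gene's TPM in mutated tumours.
    """

    region_id: str
    recurrence_multiplier: float = 1.0
    cluster_width: int = 0
    expression_effect: float = 1.0

    def __post_init__(self):
        if self.recurrence_multiplier < 1:
            raise ConfigurationError("recurrence multiplier must be >= 1")
        if self.cluster_width < 0:
            raise ConfigurationError("cluster_width must be >= 0")


@dataclass(frozen=True)
class ClonalArchitecture:
    """Per-sample clone-count distribution and CCF ranges.

    ``subclone_counts`` maps number of subclones -> probability (tumours
    most commonly carry two). The clonal cluster CCF is drawn from
    ``clonal_ccf_range`` (inside the (0.9, 1.1) window); subclone CCFs are
    strictly decreasing draws from ``subclone_ccf_range``.
    """

    subclone_counts: tuple[tuple[int, float], ...] = ((1, 0.3), (2, 0.45), (3, 0.25))
    clonal_ccf_range: tuple[float, float] = (0.95, 1.05)
    subclone_ccf_range: tuple[float, float] = (0.15, 0.85)
    variants_per_cluster: tuple[int, int] = (20, 200)

    def __post_init__(self):
        total = sum(p for _, p in self.subclone_counts)
        if abs(total - 1) > 1e-9:
            raise ConfigurationError("subclone count probabilities must sum to 1")
        lo, hi = self.subclone_ccf_range
        if hi >= 1.1:
            raise ConfigurationError(
                "subclone CCF >= 1.1 requires an explicit QC-fail mode"
            )


def default_genome(n_contigs: int = 23, *, min_mb: float = 1.0, max_mb: float = 5.0,
                   seed: int = 7) -> list[ContigSpec]:
    """A compressed 23-contig genome (one contig per chromosome pair)."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(int(min_mb * 1e6), int(max_mb * 1e6), size=n_contigs)
    gcs = rng.uniform(0.35, 0.50, size=n_contigs)
    return [
        ContigSpec(f"chr{i + 1}", int(l), float(round(g, 3)))
        for i, (l, g) in enumerate(zip(lengths, gcs))
    ]


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    background_rate is in mutations per bp per tumour; the per-region
    baseline probability is background_rate * region_length put through the
    tumour/covariate logistic model. covariate_effects are the true
    coefficients on the standardized (GC, replication timing, coverage,
    log-length) covariates.
    """

    n_samples: int = 300
    genome: list[ContigSpec] = field(default_factory=default_genome)
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "hyperdiploid": 0.30,
            "hypodiploid": 0.08,
            "near-haploid": 0.04,
            "diploid-range": 0.58,
        }
    )
    n_regions: int = 2000
    region_length_mean: int = 1000
    background_rate: float = 1e-4
    covariate_effects: tuple[float, float, float, float] = (1.0, 0.5, 0.3, 0.5)
    tumour_effect_sd: float = 0.3
    planted_drivers: list[PlantedDriver] = field(default_factory=list)
    sv_rate: float = 8.0
    expression_baseline_log_mean: float = 2.0
    expression_noise_sd: float = 0.5
    architecture: ClonalArchitecture = field(default_factory=ClonalArchitecture)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.subtype_mix.values())
        if abs(total - 1) > 1e-9:
            raise ConfigurationError("subtype fractions must sum to 1")
        unknown = set(self.subtype_mix) - set(KARYOTYPE_RANGES)
        if unknown:
            raise ConfigurationError(f"unknown subtypes: {sorted(unknown)}")
        if self.background_rate < 0 or self.sv_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.n_samples <= 0 or self.n_regions <= 0:
            raise ConfigurationError("n_samples and n_regions must be > 0")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    samples: pd.DataFrame
    regions: pd.DataFrame
    variants: pd.DataFrame
    segments: pd.DataFrame
    svs: pd.DataFrame
    expression: pd.DataFrame
    ccf_clusters: pd.DataFrame
    truth: dict

    def to_json_truth(self) -> str:
        return json.dumps(self.truth, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# karyotypes


def simulate_karyotype(
    subtype: str,
    genome: Sequence[ContigSpec],
    rng: np.random.Generator,
    *,
    log2_noise_sd: float = 0.04,
) -> pd.DataFrame:
    """Whole-contig copy-number segments realising a karyotype subtype.

    Picks a target chromosome count uniformly from the subtype's defining
    range and assigns integer states per contig (each contig models one
    chromosome pair) whose sum equals the target. Emitted log2 ratios sit at
    the state's band centre plus small noise, so the default copy-state map
    recovers the states exactly.
    """
    if subtype not in KARYOTYPE_RANGES:
        raise ConfigurationError(f"unknown subtype: {subtype!r}")
    lo, hi = KARYOTYPE_RANGES[subtype]
    target = int(rng.integers(lo, hi + 1))
    n = len(genome)
    if subtype == "near-haploid":
        states = np.ones(n, dtype=int)
    elif subtype == "hypodiploid":
        states = np.full(n, 2, dtype=int)
    else:
        states = np.full(n, 2, dtype=int)
    # adjust states until the sum hits the target
    order = rng.permutation(n)
    i = 0
    while states.sum() != target:
        idx = order[i % n]
        if states.sum() < target and states[idx] < 4:
            states[idx] += 1
        elif states.sum() > target and states[idx] > 0:
            states[idx] -= 1
        i += 1
    rows = []
    for contig, state in zip(genome, states):
        base = _STATE_LOG2[int(state)]
        rows.append(
            {
                "contig": contig.name,
                "start": 1,
                "end": contig.length,
                "log2": float(base + rng.normal(0, log2_noise_sd)),
                "state": int(state),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference sequence


def simulate_reference(
    genome: Sequence[ContigSpec], rng: np.random.Generator
) -> dict[str, str]:
    """Random reference sequence per contig honouring its GC fraction."""
    bases = np.array(list("ACGT"))
    out = {}
    for contig in genome:
        p_gc = contig.gc / 2
        p_at = (1 - contig.gc) / 2
        probs = np.array([p_at, p_gc, p_gc, p_at])
        idx = rng.choice(4, size=contig.length, p=probs)
        out[contig.name] = "".join(bases[idx])
    return out


# ---------------------------------------------------------------------------
# breakpoint sequences


def simulate_breakpoint_sequences(
    svs: pd.DataFrame,
    motif_plan: Mapping[str, tuple[str, float]],
    rng: np.random.Generator,
    *,
    reference: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    flank: int = 50,
    gc: float = 0.41,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Breakend flank sequences (2 x 100 bp per SV) with planted motifs.

    ``motif_plan`` maps motif name -> (IUPAC-free motif sequence, planting
    probability). Each emitted window independently receives each planted
    motif with its probability, on a random strand at a random offset.
    Windows are sliced from ``reference`` when given, otherwise drawn
    randomly at the configured GC. Flanks extending beyond contig bounds
    (``contig_lengths`` or reference lengths) are clipped and flagged.

    Returns (windows, truth): windows has one row per breakend with columns
    sv_id, breakend, sequence, clipped; truth records the motifs planted in
    each window.
    """
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lengths: Mapping[str, int] | None
    if contig_lengths is not None:
        lengths = contig_lengths
    elif reference is not None:
        lengths = {c: len(s) for c, s in reference.items()}
    else:
        lengths = None

    win_rows = []
    truth_rows = []
    for row in svs.itertuples(index=False):
        for label, (chrom, pos) in zip(
            "AB", ((row.chrom1, int(row.pos1)), (row.chrom2, int(row.pos2)))
        ):
            s = pos - 1 - flank
            e = pos - 1 + flank
            clipped = False
            if lengths is not None and chrom in lengths:
                if s < 0:
                    s, clipped = 0, True
                if e > lengths[chrom]:
                    e, clipped = lengths[chrom], True
            if reference is not None and chrom in reference:
                seq = list(str(reference[chrom])[s:e].upper())
            else:
                seq = list(bases[rng.choice(4, size=e - s, p=probs)])
            planted = []
            for name, (motif, prob) in motif_plan.items():
                if rng.random() < prob and len(motif) <= len(seq):
                    m = motif.upper()
                    if rng.random() < 0.5:
                        m = _revcomp(m)
                    off = int(rng.integers(0, len(seq) - len(m) + 1))
                    seq[off : off + len(m)] = list(m)
                    planted.append(name)
            win_rows.append(
                {
                    "sv_id": str(row.sv_id),
                    "breakend": label,
                    "sequence": "".join(seq),
                    "clipped": clipped,
                }
            )
            truth_rows.append(
                {
                    "sv_id": str(row.sv_id),
                    "breakend": label,
                    "planted": ";".join(planted),
                }
            )
    return pd.DataFrame(win_rows), pd.DataFrame(truth_rows)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# CCF clusters


def simulate_ccf_clusters(
    n_samples: int,
    architecture: ClonalArchitecture,
    rng: np.random.Generator,
    *,
    sample_ids: Sequence[str] | None = None,
    qc_fail_modes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Nested CCF cluster assignments per sample with truth labels.

    Every sample receives one clonal cluster with CCF inside (0.9, 1.1) and
    a strictly decreasing set of subclone CCFs, unless ``qc_fail_modes``
    assigns it a failure mode: 'superclonal' adds a cluster with CCF > 1.1,
    'no_clonal' lowers the maximal CCF below 0.9, 'vaf_mismatch' and
    'homdel' keep normal clusters but set the corresponding truth flag
    (consumed as auxiliary QC input downstream).
    """
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    counts, weights = zip(*architecture.subclone_counts)
    rows = []
    for sample in sample_ids:
        mode = (qc_fail_modes or {}).get(sample, "")
        n_sub = int(rng.choice(counts, p=weights))
        clonal_ccf = float(rng.uniform(*architecture.clonal_ccf_range))
        ccfs = [clonal_ccf]
        lo, hi = architecture.subclone_ccf_range
        subs = np.sort(rng.uniform(lo, hi, size=n_sub))[::-1]
        # enforce strict nesting: child < parent
        prev = clonal_ccf
        for c in subs:
            c = min(float(c), prev - 1e-3)
            ccfs.append(max(c, 1e-3))
            prev = ccfs[-1]
        if mode == "superclonal":
            ccfs.insert(0, float(rng.uniform(1.15, 1.35)))
        elif mode == "no_clonal":
            ccfs = [min(c, 0.85) for c in ccfs]
            ccfs[0] = float(rng.uniform(0.6, 0.89))
        vlo, vhi = architecture.variants_per_cluster
        for k, ccf in enumerate(sorted(ccfs, reverse=True)):
            if mode == "superclonal" and ccf > 1.1:
                label = "invalid"
            elif k == 0 and 0.9 < ccf < 1.1:
                label = "clonal"
            else:
                label = "subclonal"
            rows.append(
                {
                    "sample_id": sample,
                    "cluster_id": f"{sample}_c{k}",
                    "ccf": float(ccf),
                    "n_variants": int(rng.integers(vlo, vhi + 1)),
                    "truth_label": label,
                    "qc_fail_mode": mode,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole cohort


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort with truth tables.

    Deterministic: identical config and seed give a byte-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_t, n_r = config.n_samples, config.n_regions
    sample_ids = [f"S{i:04d}" for i in range(n_t)]

    # subtypes
    names = sorted(config.subtype_mix)
    mix = np.array([config.subtype_mix[s] for s in names])
    subtype = [names[i] for i in rng.choice(len(names), size=n_t, p=mix)]
    samples = pd.DataFrame({"sample_id": sample_ids, "subtype": subtype})

    # regions with covariates, laid out sequentially over the genome
    lengths = np.maximum(
        100,
        rng.lognormal(np.log(config.region_length_mean), 0.3, size=n_r),
    ).astype(int)
    contigs = []
    starts = []
    gap = 2000
    ci, cursor = 0, 10_000
    for length in lengths:
        if ci >= len(config.genome):
            raise ConfigurationError("genome too small for the requested regions")
        contig = config.genome[ci]
        if cursor + length + gap > contig.length:
            ci += 1
            cursor = 10_000
            if ci >= len(config.genome):
                raise ConfigurationError("genome too small for the requested regions")
            contig = config.genome[ci]
        contigs.append(contig.name)
        starts.append(cursor)
        cursor += length + gap
    starts = np.asarray(starts)
    gc = rng.uniform(0.30, 0.70, size=n_r)
    rep_timing = rng.normal(50, 15, size=n_r)
    coverage = rng.normal(60, 8, size=n_r)
    regions = pd.DataFrame(
        {
            "region_id": [f"R{i:05d}" for i in range(n_r)],
            "contig": contigs,
            "start": starts,
            "end": starts + lengths,
            "gene": [f"G{i:05d}" for i in range(n_r)],
            "gc": gc,
            "rep_timing": rep_timing,
            "coverage": coverage,
            "length": lengths,
            "log_length": np.log(lengths),
        }
    )

    # true mutation probabilities: logistic(a_t + beta . x_r)
    x = np.column_stack([gc, rep_timing, coverage, np.log(lengths)])
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1)
    beta = np.asarray(config.covariate_effects, dtype=float)
    p0 = np.clip(config.background_rate * config.region_length_mean, 1e-12, 0.5)
    intercept = np.log(p0 / (1 - p0))
    tumour_effect = rng.normal(0, config.tumour_effect_sd, size=n_t)
    logit = intercept + tumour_effect[:, None] + (xs @ beta)[None, :]
    prob = _logistic(logit)

    drivers = {d.region_id: d for d in config.planted_drivers}
    region_index = {r: i for i, r in enumerate(regions["region_id"])}
    for rid, d in drivers.items():
        if rid not in region_index:
            raise ConfigurationError(f"planted driver region {rid!r} not in regions")
        j = region_index[rid]
        prob[:, j] = np.clip(prob[:, j] * d.recurrence_multiplier, 0, 0.99)

    mutated = rng.random((n_t, n_r)) < prob
    if config.background_rate == 0 and not config.planted_drivers:
        mutated[:] = False

    # driver cluster windows (fixed per region so tumours share the hotspot)
    cluster_window = {}
    for rid, d in drivers.items():
        j = region_index[rid]
        length = int(lengths[j])
        width = min(d.cluster_width, length)
        if width > 0:
            off = int(rng.integers(0, length - width + 1))
            cluster_window[rid] = (off, off + width)

    # variant records: one mutation per mutated (tumour, region)
    bases = "ACGT"
    var_rows = []
    t_idx, r_idx = np.nonzero(mutated)
    offsets = rng.random(t_idx.size)
    vafs = np.clip(rng.beta(8, 12, size=t_idx.size), 0.05, 0.95)
    for n, (t, r) in enumerate(zip(t_idx, r_idx)):
        rid = regions.at[r, "region_id"]
        length = int(lengths[r])
        if rid in cluster_window:
            lo, hi = cluster_window[rid]
            pos_in = lo + int(offsets[n] * (hi - lo))
        else:
            pos_in = int(offsets[n] * length)
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        var_rows.append(
            {
                "sample_id": sample_ids[t],
                "contig": regions.at[r, "contig"],
                "pos": int(regions.at[r, "start"]) + pos_in + 1,
                "ref": ref,
                "alt": alt,
                "filter": "PASS",
                "vaf": float(vafs[n]),
                "popmax_af": np.nan,
                "region_id": rid,
            }
        )
    variants = pd.DataFrame(
        var_rows,
        columns=[
            "sample_id", "contig", "pos", "ref", "alt", "filter", "vaf",
            "popmax_af", "region_id",
        ],
    )

    # karyotypes
    seg_frames = []
    chrom_counts = {}
    for sample, st in zip(sample_ids, subtype):
        seg = simulate_karyotype(st, config.genome, rng)
        seg.insert(0, "sample_id", sample)
        chrom_counts[sample] = int(seg["state"].sum())
        seg_frames.append(seg)
    segments = pd.concat(seg_frames, ignore_index=True)

    # SVs: random intra-contig deletions/duplications/inversions
    sv_rows = []
    contig_arr = [c.name for c in config.genome]
    contig_len = {c.name: c.length for c in config.genome}
    for sample in sample_ids:
        n_sv = int(rng.poisson(config.sv_rate))
        for k in range(n_sv):
            chrom = contig_arr[int(rng.integers(len(contig_arr)))]
            size = int(rng.lognormal(np.log(50_000), 1.0))
            pos1 = int(rng.integers(1, max(2, contig_len[chrom] - size - 1)))
            pos2 = min(pos1 + size, contig_len[chrom])
            svtype = ("DEL", "DUP", "INV")[int(rng.integers(3))]
            sv_rows.append(
                {
                    "sv_id": f"{sample}_sv{k}",
                    "sample_id": sample,
                    "chrom1": chrom,
                    "pos1": pos1,
                    "strand1": "+",
                    "chrom2": chrom,
                    "pos2": pos2,
                    "strand2": "-" if svtype == "DEL" else "+",
                    "svtype": svtype,
                    "vaf": float(np.clip(rng.beta(8, 12), 0.01, 0.99)),
                    "ccf": float(np.clip(rng.beta(10, 3), 0.01, 1.0)),
                    "callers": "manta,delly",
                    "complex": bool(rng.random() < 0.1),
                }
            )
    svs = pd.DataFrame(
        sv_rows,
        columns=[
            "sv_id", "sample_id", "chrom1", "pos1", "strand1", "chrom2",
            "pos2", "strand2", "svtype", "vaf", "ccf", "callers", "complex",
        ],
    )

    # expression: log-normal baseline per gene, multiplicative driver effect
    base = rng.lognormal(config.expression_baseline_log_mean, 0.8, size=n_r)
    noise = rng.lognormal(0.0, config.expression_noise_sd, size=(n_r, n_t))
    expr = base[:, None] * noise
    for rid, d in drivers.items():
        if d.expression_effect != 1.0:
            j = region_index[rid]
            expr[j, mutated[:, j]] *= d.expression_effect
    expression = pd.DataFrame(
        expr, index=regions["gene"].to_numpy(), columns=sample_ids
    )

    ccf_clusters = simulate_ccf_clusters(
        n_t, config.architecture, rng, sample_ids=sample_ids
    )

    truth = {
        "seed": config.seed,
        "per_sample_draws": {
            s: int(c) for s, c in zip(sample_ids, mutated.sum(axis=1))
        },
        "planted_drivers": [dataclasses.asdict(d) for d in config.planted_drivers],
        "cluster_windows": {k: list(v) for k, v in cluster_window.items()},
        "true_probabilities": prob,
        "mutated_matrix": mutated,
        "covariate_effects": list(config.covariate_effects),
        "chromosome_counts": chrom_counts,
        "subclones": {
            s: int((ccf_clusters["sample_id"] == s).sum()) - 1 for s in sample_ids
        },
    }

    return SyntheticCohort(
        config=config,
        samples=samples,
        regions=regions,
        variants=variants,
        segments=segments,
        svs=svs,
        expression=expression,
        ccf_clusters=ccf_clusters,
        truth=truth,
    )
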