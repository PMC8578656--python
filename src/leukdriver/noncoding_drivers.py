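"""Covariate-aware recurrence and clustering test for non-coding regions.

The central statistic of the toolkit. For every cis-regulatory element (CRE),
promoter, UTR or ncRNA region we ask whether more tumours carry a mutation in
it than a per-tumour background model predicts, and whether the mutations
pile up positionally. The background is a per-tumour logistic regression of
the region-mutated indicator on region covariates (GC content, replication
timing, coverage, log-length); the per-tumour mutation rate is absorbed by
the tumour-specific intercept. Observed recurrence across tumours is then
scored against the Poisson-binomial distribution of the fitted per-tumour
probabilities. Regions with more than five mutations cohort-wide are
additionally tested for positional clustering by permutation under a uniform
placement null, the two P values are combined with Fisher's method, BH
adjusted, and significant regions are validated against expression of the
linked target gene (rank-sum test on TPM, mutated vs non-mutated tumours,
excluding tumours with copy-number changes at the region or gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "BackgroundModel",
    "RegionTestResult",
    "build_promoter_regions",
    "fit_background",
    "poisson_binomial_pmf",
    "poisson_binomial_tail",
    "poisson_binomial_tail_batch",
    "clustering_permutation_test",
    "fisher_combine",
    "expression_association",
    "assign_regions",
    "run_region_pipeline",
]

#: largest n for which the exact dynamic-programming convolution is used;
#: above this a refined normal approximation (second-order, skewness
#: corrected) takes over.
EXACT_POIBIN_LIMIT = 5000


# ---------------------------------------------------------------------------
# promoters


def build_promoter_regions(
    transcripts: pd.DataFrame,
    coding_intervals: pd.DataFrame | None = None,
    *,
    window: int = 2000,
) -> pd.DataFrame:
    """Build strand-aware promoter regions: 2 kb upstream of each TSS.

    Multi-TSS genes contribute the union of their windows and are evaluated
    jointly as one region set. Any base overlapping a coding (CDS) or UTR
    interval is removed; genes whose promoter is entirely removed are
    excluded.

    Parameters
    ----------
    transcripts : DataFrame
        Columns ``gene``, ``contig``, ``tss`` (0-based position of the
        transcription start base) and ``strand`` ('+'/'-').
    coding_intervals : DataFrame, optional
        Columns ``contig``, ``start``, ``end`` (0-based half-open) of CDS and
        UTR sequence to mask out, from any gene.
    window : int
        Upstream window size in bp (default 2000).

    Returns
    -------
    DataFrame with columns ``region_id``, ``gene``, ``contig``, ``start``,
    ``end`` (0-based half-open), one row per disjoint promoter interval.
    """
    masks: dict[str, IntervalTree] = {}
    if coding_intervals is not None:
        for contig, grp in coding_intervals.groupby("contig"):
            tree = IntervalTree()
            for s, e in zip(grp["start"], grp["end"]):
                if e > s:
                    tree.addi(int(s), int(e))
            masks[str(contig)] = tree

    rows = []
    for (gene, contig), grp in transcripts.groupby(["gene", "contig"]):
        windows = []
        for tss, strand in zip(grp["tss"], grp["strand"]):
            tss = int(tss)
            if strand == "+":
                windows.append((max(0, tss - window), tss))
            else:
                windows.append((tss + 1, tss + 1 + window))
        # union of windows
        windows.sort()
        merged: list[list[int]] = []
        for s, e in windows:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        # subtract coding/UTR overlap
        tree = masks.get(str(contig))
        idx = 0
        for s, e in merged:
            pieces = [(s, e)]
            if tree is not None:
                for hit in sorted(tree.overlap(s, e)):
                    nxt = []
                    for ps, pe in pieces:
                        if hit.end <= ps or hit.begin >= pe:
                            nxt.append((ps, pe))
                            continue
                        if ps < hit.begin:
                            nxt.append((ps, hit.begin))
                        if hit.end < pe:
                            nxt.append((hit.end, pe))
                    pieces = nxt
            for ps, pe in pieces:
                if pe > ps:
                    rows.append(
                        {
                            "region_id": f"promoter:{gene}:{idx}",
                            "gene": gene,
                            "contig": contig,
                            "start": ps,
                            "end": pe,
                        }
                    )
                    idx += 1
    return pd.DataFrame(rows, columns=["region_id", "gene", "contig", "start", "end"])


# ---------------------------------------------------------------------------
# background model


@dataclass
class BackgroundModel:
    """Per-tumour logistic background model of region mutation probability.

    Attributes
    ----------
    coefficients : ndarray, shape (n_tumours, n_covariates + 1)
        Intercept followed by coefficients on the standardized covariates.
    probabilities : ndarray, shape (n_tumours, n_regions)
        Fitted per-tumour per-region mutation probabilities, in (0, 1).
    converged : ndarray of bool, shape (n_tumours,)
        False where the IRLS fit failed and the intercept-only fallback was
        used.
    covariate_names : list of str
    covariate_mean, covariate_sd : ndarray
        Standardization applied to the covariates before fitting.
    """

    coefficients: np.ndarray
    probabilities: np.ndarray
    converged: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    covariate_mean: np.ndarray | None = None
    covariate_sd: np.ndarray | None = None


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd, mean, sd


def fit_background(
    mutated: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    *,
    covariate_names: Sequence[str] | None = None,
    prob_floor: float | None = None,
) -> BackgroundModel:
    """Fit one logistic regression per tumour (IRLS via statsmodels GLM).

    Parameters
    ----------
    mutated : ndarray of bool/int, shape (n_tumours, n_regions)
        Region-mutated indicators (a tumour counts once per region however
        many mutations it carries there).
    covariates : DataFrame or ndarray, shape (n_regions, n_covariates)
        Region covariates (GC fraction, replication timing, coverage,
        log-length). Standardized internally.
    prob_floor : float, optional
        Lower bound on fitted probabilities; defaults to 1/(2 * n_regions),
        the empirical-rate floor used for tumours with no mutated region.

    Notes
    -----
    Tumours whose fit does not converge (or with an all-zero/all-one
    response) fall back to an intercept-only model at the empirical rate,
    floored at ``prob_floor``, and are flagged in ``converged``.
    """
    y = np.asarray(mutated, dtype=float)
    if y.ndim != 2:
        raise ValueError("mutated must be a (n_tumours, n_regions) matrix")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        names = list(covariate_names) if covariate_names else [
            f"x{i}" for i in range(x.shape[1])
        ]
    n_tumours, n_regions = y.shape
    if x.shape[0] != n_regions:
        raise ValueError("covariate rows must match number of regions")
    if n_regions < 50:
        raise ValueError("need at least 50 regions per tumour to fit a background")
    if prob_floor is None:
        prob_floor = 1.0 / (2.0 * n_regions)

    xs, mean, sd = _standardize(x)
    design = sm.add_constant(xs, has_constant="add")
    k = design.shape[1]
    coefs = np.zeros((n_tumours, k))
    probs = np.zeros((n_tumours, n_regions))
    converged = np.ones(n_tumours, dtype=bool)

    for t in range(n_tumours):
        yt = y[t]
        s = yt.sum()
        if s == 0 or s == n_regions:
            converged[t] = False
            rate = max(s / n_regions, prob_floor)
            rate = min(rate, 1 - prob_floor)
            coefs[t, 0] = math.log(rate / (1 - rate))
            probs[t] = rate
            continue
        try:
            fit = sm.GLM(yt, design, family=sm.families.Binomial()).fit(maxiter=50)
            ok = getattr(fit, "converged", True) and np.all(np.isfinite(fit.params))
        except Exception:
            ok = False
        if not ok:
            converged[t] = False
            rate = float(np.clip(s / n_regions, prob_floor, 1 - prob_floor))
            coefs[t, 0] = math.log(rate / (1 - rate))
            probs[t] = rate
            continue
        coefs[t] = fit.params
        probs[t] = np.clip(fit.fittedvalues, prob_floor, 1 - prob_floor)

    return BackgroundModel(
        coefficients=coefs,
        probabilities=probs,
        converged=converged,
        covariate_names=names,
        covariate_mean=mean,
        covariate_sd=sd,
    )


# ---------------------------------------------------------------------------
# Poisson binomial


def poisson_binomial_pmf(probabilities: Sequence[float]) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_i) by DP convolution.

    Returns an array of length n+1; entry k is P(K = k).
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def _refined_normal_tail(p: np.ndarray, k: int) -> float:
    """Second-order (skewness-corrected) normal tail approximation."""
    mu = p.sum()
    var = np.sum(p * (1 - p))
    if var == 0:
        return 1.0 if k <= mu else 0.0
    sigma = math.sqrt(var)
    gamma = np.sum(p * (1 - p) * (1 - 2 * p)) / sigma**3
    x = (k - 0.5 - mu) / sigma
    cdf = stats.norm.cdf(x) + gamma * (1 - x * x) * stats.norm.pdf(x) / 6.0
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def poisson_binomial_tail(
    probabilities: Sequence[float],
    k: int,
    *,
    exact_limit: int = EXACT_POIBIN_LIMIT,
) -> tuple[float, str]:
    """Upper tail P(K >= k) of the Poisson-binomial distribution.

    Exact dynamic-programming convolution for n <= ``exact_limit``; a refined
    normal approximation with continuity and skewness corrections above.

    Returns
    -------
    (p, method) : tuple of float and {"exact", "refined-normal"}
        ``p`` is P(K >= k). k > n returns 0.0; k <= 0 returns 1.0.
    """
    p = np.asarray(probabilities, dtype=float)
    n = p.size
    if k <= 0:
        return 1.0, "exact"
    if k > n:
        return 0.0, "exact"
    if n <= exact_limit:
        pmf = poisson_binomial_pmf(p)
        return float(np.clip(pmf[k:].sum(), 0.0, 1.0)), "exact"
    return _refined_normal_tail(p, k), "refined-normal"


def poisson_binomial_tail_batch(
    probabilities: np.ndarray, k_observed: np.ndarray
) -> np.ndarray:
    """Vectorized exact upper tails for many regions at once.

    Parameters
    ----------
    probabilities : ndarray, shape (n_tumours, n_regions)
        Column r holds the per-tumour success probabilities for region r.
    k_observed : ndarray of int, shape (n_regions,)

    Returns
    -------
    ndarray of P(K_r >= k_r), one per region.

    Notes
    -----
    Runs the DP convolution across all regions simultaneously (one
    (n_regions, n_tumours+1) PMF matrix updated per tumour), which makes
    whole-cohort scans cheap.
    """
    p = np.asarray(probabilities, dtype=float)
    n_tumours, n_regions = p.shape
    k = np.asarray(k_observed, dtype=int)
    pmf = np.zeros((n_regions, n_tumours + 1))
    pmf[:, 0] = 1.0
    for t in range(n_tumours):
        pt = p[t][:, None]
        pmf[:, 1 : t + 2] = pmf[:, 1 : t + 2] * (1 - pt) + pmf[:, : t + 1] * pt
        pmf[:, 0] *= (1 - p[t])
    # tail sums
    rev_cum = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    kk = np.clip(k, 0, n_tumours)
    out = rev_cum[np.arange(n_regions), kk]
    out[k <= 0] = 1.0
    out[k > n_tumours] = 0.0
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# clustering


def _min_half_window(sorted_pos: np.ndarray) -> float:
    """Smallest window width containing ceil(m/2) of the m positions."""
    m = sorted_pos.shape[-1]
    w = (m + 1) // 2
    return np.min(
        sorted_pos[..., w - 1 :] - sorted_pos[..., : m - w + 1], axis=-1
    )


def clustering_permutation_test(
    positions: Sequence[float],
    region_length: float,
    *,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    min_mutations: int = 6,
) -> float | None:
    """Permutation test for positional clustering of mutations in a region.

    Statistic: S = width of the smallest window containing at least half
    (ceil(m/2)) of the m mutation positions. The null places m positions
    uniformly over the region; P = (#{S_perm <= S_obs} + 1) / (n_perm + 1).

    Run only for regions with more than five mutations (``min_mutations``
    defaults to 6); returns None below that.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    m = pos.size
    if m < min_mutations:
        return None
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if rng is None:
        rng = np.random.default_rng()
    s_obs = _min_half_window(pos) / region_length
    perm = np.sort(rng.random((n_perm, m)), axis=1)
    s_perm = _min_half_window(perm)
    return float((np.sum(s_perm <= s_obs) + 1) / (n_perm + 1))


class _ClusterNullCache:
    """Shared permutation nulls keyed by mutation count.

    The unit-interval null distribution of the clustering statistic depends
    only on m, so regions with equal mutation counts can share one
    permutation sample. Used by the pipeline for whole-cohort scans.
    """

    def __init__(self, n_perm: int, rng: np.random.Generator):
        self.n_perm = n_perm
        self.rng = rng
        self._cache: dict[int, np.ndarray] = {}

    def pvalue(self, positions: np.ndarray, region_length: float) -> float:
        m = positions.size
        if m not in self._cache:
            perm = np.sort(self.rng.random((self.n_perm, m)), axis=1)
            self._cache[m] = np.sort(_min_half_window(perm))
        s_obs = _min_half_window(np.sort(positions.astype(float))) / region_length
        r = np.searchsorted(self._cache[m], s_obs, side="right")
        return float((r + 1) / (self.n_perm + 1))


def fisher_combine(p_burden: float, p_cluster: float) -> float:
    """Fisher's method for two P values: chi-square with 4 df.

    X = -2 (ln p1 + ln p2); the combined P is the upper tail of chi2_4 at X.
    Zero inputs are clamped to the smallest positive float.
    """
    tiny = np.finfo(float).tiny
    p1 = max(float(p_burden), tiny)
    p2 = max(float(p_cluster), tiny)
    if p1 > 1 or p2 > 1:
        raise ValueError("P values must lie in (0, 1]")
    x = -2.0 * (math.log(p1) + math.log(p2))
    return float(stats.chi2.sf(x, df=4))


# ---------------------------------------------------------------------------
# expression validation


def expression_association(
    expression: pd.DataFrame,
    tested: pd.DataFrame,
    mutated_samples: Mapping[str, set],
    cnv_excluded_samples: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Rank-sum expression validation for significant regions.

    For each tested region, compares the target gene's TPM between mutated
    and non-mutated tumours with a two-sided Wilcoxon rank-sum test, after
    excluding tumours with a CNV at the region or its target gene; BH across
    tested regions.

    Parameters
    ----------
    expression : DataFrame, genes x samples (TPM).
    tested : DataFrame with columns ``region_id`` and ``gene``.
    mutated_samples : mapping region_id -> set of sample ids.
    cnv_excluded_samples : mapping region_id -> set of sample ids to drop.

    Returns
    -------
    DataFrame with columns ``region_id``, ``gene``, ``p_expr``, ``q_expr``,
    ``n_mutated``, ``n_unmutated``, ``reason`` (why missing, if missing).
    """
    rows = []
    all_samples = list(expression.columns)
    for _, row in tested.iterrows():
        rid, gene = row["region_id"], row["gene"]
        reason = ""
        p = np.nan
        nm = nu = 0
        if gene not in expression.index:
            reason = "gene_not_expressed"
        else:
            excl = set() if cnv_excluded_samples is None else set(
                cnv_excluded_samples.get(rid, set())
            )
            mut = {s for s in mutated_samples.get(rid, set()) if s not in excl}
            unmut = [s for s in all_samples if s not in mut and s not in excl]
            mut = [s for s in all_samples if s in mut]
            nm, nu = len(mut), len(unmut)
            if nm < 2 or nu < 2:
                reason = "too_few_samples"
            else:
                vals_m = expression.loc[gene, mut].to_numpy(dtype=float)
                vals_u = expression.loc[gene, unmut].to_numpy(dtype=float)
                if np.all(vals_m == vals_m[0]) and np.all(vals_u == vals_m[0]):
                    p = 1.0
                else:
                    p = float(
                        stats.mannwhitneyu(vals_m, vals_u, alternative="two-sided").pvalue
                    )
        rows.append(
            {
                "region_id": rid,
                "gene": gene,
                "p_expr": p,
                "n_mutated": nm,
                "n_unmutated": nu,
                "reason": reason,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_expr"] = bh_adjust_local(out["p_expr"].to_numpy())
    else:
        out["q_expr"] = []
    return out


# thin alias so this module does not import from coding_consensus at top level
def bh_adjust_local(p):
    from .coding_consensus import bh_adjust

    return bh_adjust(p)


# ---------------------------------------------------------------------------
# orchestration


def assign_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Annotate variants with the region (if any) containing them.

    Regions are 0-based half-open; variant positions are 1-based. A variant
    at 1-based position p lies in region [start, end) iff start < p <= end.
    Returns a copy of ``variants`` with a ``region_id`` column (NaN when the
    variant falls in no region; first region wins on overlap).
    """
    trees: dict[str, IntervalTree] = {}
    for contig, grp in regions.groupby("contig"):
        tree = IntervalTree()
        for rid, s, e in zip(grp["region_id"], grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s), int(e), rid)
        trees[str(contig)] = tree
    out = variants.copy()
    ids = []
    for contig, pos in zip(out["contig"], out["pos"]):
        tree = trees.get(str(contig))
        hits = tree.overlap(int(pos) - 1, int(pos)) if tree is not None else set()
        ids.append(sorted(h.data for h in hits)[0] if hits else np.nan)
    out["region_id"] = ids
    return out


@dataclass
class RegionTestResult:
    """Container for the full region-test table plus fitted background."""

    table: pd.DataFrame
    background: BackgroundModel


def run_region_pipeline(
    variants: pd.DataFrame,
    regions: pd.DataFrame,
    covariate_columns: Sequence[str],
    sample_ids: Sequence[str],
    *,
    expression: pd.DataFrame | None = None,
    cnv_excluded_samples: Mapping[str, set] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    q_threshold: float = 0.1,
    min_cluster_mutations: int = 6,
) -> RegionTestResult:
    """Run the full region recurrence + clustering + expression pipeline.

    Parameters
    ----------
    variants : DataFrame
        QC-passed variants with columns ``sample_id``, ``contig``, ``pos``;
        a ``region_id`` column is used if present, otherwise variants are
        assigned to regions by coordinate.
    regions : DataFrame
        ``region_id``, ``contig``, ``start``, ``end`` (0-based half-open),
        ``gene`` (target gene; optional), plus the covariate columns.
    covariate_columns : names of the covariate columns in ``regions``.
    sample_ids : full cohort sample list (samples with zero variants count).

    Returns
    -------
    RegionTestResult
        ``table`` has one row per region, sorted by combined q then P:
        (region_id, k, n_mutations, p_burden, p_cluster, p_combined, q,
        p_expr, q_expr, burden_method).
    """
    rng = np.random.default_rng(seed)
    samples = list(sample_ids)
    sample_index = {s: i for i, s in enumerate(samples)}
    region_ids = list(regions["region_id"])
    region_index = {r: i for i, r in enumerate(region_ids)}
    n_t, n_r = len(samples), len(region_ids)

    if "region_id" not in variants.columns:
        variants = assign_regions(variants, regions)
    hits = variants.dropna(subset=["region_id"])

    mutated = np.zeros((n_t, n_r), dtype=bool)
    positions: dict[str, list[float]] = {r: [] for r in region_ids}
    region_start = dict(zip(regions["region_id"], regions["start"]))
    for sample, rid, pos in zip(hits["sample_id"], hits["region_id"], hits["pos"]):
        if rid not in region_index or sample not in sample_index:
            continue
        mutated[sample_index[sample], region_index[rid]] = True
        positions[rid].append(float(pos) - 1 - region_start[rid])

    background = fit_background(mutated, regions[list(covariate_columns)])
    k_obs = mutated.sum(axis=0)
    p_burden = poisson_binomial_tail_batch(background.probabilities, k_obs)
    # the DP tail can be exactly 0 only if k > n; clamp for downstream logs
    p_burden = np.clip(p_burden, np.finfo(float).tiny, 1.0)

    cache = _ClusterNullCache(n_perm, rng)
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    p_cluster = np.full(n_r, np.nan)
    n_mut = np.zeros(n_r, dtype=int)
    for i, rid in enumerate(region_ids):
        pos = np.asarray(positions[rid], dtype=float)
        n_mut[i] = pos.size
        if pos.size >= min_cluster_mutations:
            p_cluster[i] = cache.pvalue(pos, lengths[i])

    p_comb = np.array(
        [
            fisher_combine(pb, pc) if not np.isnan(pc) else pb
            for pb, pc in zip(p_burden, p_cluster)
        ]
    )
    q = bh_adjust_local(p_comb)

    table = pd.DataFrame(
        {
            "region_id": region_ids,
            "gene": regions["gene"].to_numpy() if "gene" in regions else np.nan,
            "k": k_obs,
            "n_mutations": n_mut,
            "p_burden": p_burden,
            "p_cluster": p_cluster,
            "p_combined": p_comb,
            "q": q,
        }
    )

    if expression is not None:
        sig = table[table["q"] < q_threshold]
        mut_sets = {
            rid: {samples[t] for t in np.nonzero(mutated[:, region_index[rid]])[0]}
            for rid in sig["region_id"]
        }
        expr = expression_association(
            expression, sig[["region_id", "gene"]], mut_sets, cnv_excluded_samples
        )
        table = table.merge(
            expr[["region_id", "p_expr", "q_expr"]], on="region_id", how="left"
        )
    else:
        table["p_expr"] = np.nan
        table["q_expr"] = np.nan

    table = table.sort_values(["q", "p_combined"], kind="mergesort").reset_index(
        drop=True
    )
    return RegionTestResult(table=table, background=background)
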