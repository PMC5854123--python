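"""Randomization tests and correlation procedures for colony analyses.

All Monte-Carlo p-values use the unbiased estimator ``p = (n + 1)/(m + 1)``
where ``n`` counts null replicates as extreme or more extreme (>=) than the
observed statistic and ``m`` is the number of replicates; this keeps the
estimator strictly positive and its type-I error at the nominal level.
Every randomization consumes an explicit seed and is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, ParameterError, UndefinedResultError


def mc_pvalue(n_extreme: int, reps: int) -> float:
    """Unbiased Monte-Carlo p-value ``(n + 1)/(m + 1)``; always in (0, 1]."""
    if n_extreme < 0 or reps < 0:
        raise ParameterError("counts must be non-negative")
    if n_extreme > reps:
        raise ParameterError("n_extreme cannot exceed reps")
    return (n_extreme + 1) / (reps + 1)


@dataclass
class McResult:
    """Outcome of one Monte-Carlo randomization test."""

    observed: float
    n_extreme: int
    reps: int
    p: float
    null: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"observed": self.observed, "n_extreme": self.n_extreme,
             "reps": self.reps, "p": self.p}
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# Correlation procedures
# ---------------------------------------------------------------------------


def merge_rank_correlate(
    table: pd.DataFrame, x: str, y: str, n_bins: int = 23
) -> dict:
    """Rank-merge correlation between two per-window quantities.

    Windows are ranked by ``x`` and partitioned, neighbouring *in the
    ranking*, into ``n_bins`` near-equal groups (sizes differ by at most one);
    the Pearson correlation and regression p-value are computed on the bin
    means.  The raw per-window Spearman correlation is reported alongside,
    since binning changes the meaning of the p-value.
    """
    if not (21 <= n_bins <= 25):
        warnings.warn(f"n_bins={n_bins} outside the conventional 21-25 range",
                      stacklevel=2)
    sub = table[[x, y]].dropna()
    if len(sub) < n_bins:
        raise InputError(f"need at least {n_bins} windows with both columns")
    sub = sub.sort_values(x, kind="mergesort")
    groups = np.array_split(np.arange(len(sub)), n_bins)
    bx = np.array([sub[x].to_numpy()[g].mean() for g in groups])
    by = np.array([sub[y].to_numpy()[g].mean() for g in groups])
    r, _ = sps.pearsonr(bx, by)
    reg = sps.linregress(bx, by)
    rho, rho_p = sps.spearmanr(sub[x], sub[y])
    return {
        "r": float(r), "p": float(reg.pvalue),
        "slope": float(reg.slope), "intercept": float(reg.intercept),
        "bin_means": pd.DataFrame({x: bx, y: by}),
        "bin_sizes": [len(g) for g in groups],
        "spearman_r": float(rho), "spearman_p": float(rho_p),
    }


def partial_spearman(x, y, *covariates) -> float:
    """Spearman partial correlation of x and y controlling the covariates.

    All series are rank-transformed, and the partial correlation is read off
    the inverse of the rank correlation matrix — equivalent to the recursive
    formula and to correlating rank residuals.
    """
    arrays = [np.asarray(a, dtype=float) for a in (x, y, *covariates)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise InputError("all series must have equal length")
    if n < 4:
        raise InputError("need at least 4 observations")
    for a in arrays:
        if np.ptp(a) == 0:
            raise UndefinedResultError("constant input column")
    ranks = np.column_stack([sps.rankdata(a) for a in arrays])
    corr = np.corrcoef(ranks, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise UndefinedResultError(
            "rank correlation matrix is singular (collinear inputs)") from None
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if not np.isfinite(denom) or denom == 0:
        raise UndefinedResultError("degenerate control structure")
    return float(-prec[0, 1] / denom)


# ---------------------------------------------------------------------------
# Monte-Carlo tests
# ---------------------------------------------------------------------------


def dispersion_test(
    counts,
    reps: int = 10_000,
    seed: int | None = None,
    weights=None,
) -> McResult:
    """Poisson-dispersion Monte Carlo on per-drone mutation counts.

    The observed statistic is the unbiased (n-1) sample variance of per-drone
    counts.  The null allocates the total count over drones by an
    equal-probability multinomial (optionally weighted, e.g. by per-drone
    callable sites) and asks how often the null variance is as great or
    greater than observed — the over-dispersion direction.
    """
    counts = np.asarray(counts, dtype=int)
    if len(counts) < 2:
        raise InputError("need at least 2 drones")
    n = len(counts)
    total = int(counts.sum())
    observed = float(np.var(counts, ddof=1))
    if weights is None:
        probs = np.full(n, 1.0 / n)
    else:
        probs = np.asarray(weights, dtype=float)
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    null = rng.multinomial(total, probs, size=reps).var(axis=1, ddof=1)
    n_extreme = int((null >= observed).sum())
    return McResult(
        observed=observed, n_extreme=n_extreme, reps=reps,
        p=mc_pvalue(n_extreme, reps), null=null,
        extra={"null_mean_variance": float(null.mean()),
               "null_ci": (float(np.quantile(null, 0.025)),
                           float(np.quantile(null, 0.975))),
               "mean": total / n},
    )


def colony_heterogeneity(counts, group_sizes) -> dict:
    """Chi-square test of mutation counts against colony-size expectations.

    Expected counts are the total split by group share (drone counts by
    default; pass callable-site totals to weight by callability instead).
    Pearson chi-square without continuity correction, df = groups - 1.
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if len(counts) != len(sizes) or len(counts) < 2:
        raise InputError("need matching counts and sizes for >= 2 groups")
    total = counts.sum()
    if total == 0:
        raise UndefinedResultError("zero total count")
    expected = total * sizes / sizes.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    return {"expected": expected, "chi2": chi2, "df": df,
            "p": float(sps.chi2.sf(chi2, df))}


def _min_distance_to_events(positions: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Distance from each position to the nearest breakpoint edge (0 inside
    an interval is handled by passing both edges)."""
    if len(edges) == 0:
        return np.full(len(positions), np.inf)
    idx = np.searchsorted(edges, positions)
    left = np.where(idx > 0, positions - edges[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < len(edges), edges[np.minimum(idx, len(edges) - 1)] - positions,
                     np.inf)
    return np.minimum(np.abs(left), np.abs(right))


def proximity_test(
    mutations: pd.DataFrame,
    events: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000,
    reps: int = 10_000,
    seed: int | None = None,
    pooled: bool = False,
) -> McResult:
    """Mutation-to-recombination-breakpoint proximity randomization.

    The observed statistic counts mutations within ``window_bp`` of a kept
    crossover breakpoint of the *same drone's* events (set ``pooled`` to
    compare against all drones' breakpoints).  The null redraws the same
    number of sites uniformly over the genome, drone labels preserved, and
    asks how often at least as many null sites are proximal.
    """
    if reps < 100:
        raise ParameterError("reps must be >= 100")
    kept = events[(events["kind"] == "CO") & (~events["excluded"])] \
        if not events.empty else events
    if kept.empty:
        raise UndefinedResultError("no crossover events to compare against")

    # breakpoint edge arrays per (drone, chrom) or per chrom when pooled
    edges: dict[tuple, np.ndarray] = {}
    group_cols = ["chrom"] if pooled else ["drone", "chrom"]
    for key, grp in kept.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        e = np.sort(np.concatenate([grp["left"].to_numpy(float),
                                    grp["right"].to_numpy(float)]))
        edges[key] = e

    def edge_key(drone, chrom):
        return (chrom,) if pooled else (drone, chrom)

    def count_proximal(mut_rows) -> int:
        total = 0
        for (drone, chrom), grp in mut_rows.groupby(["drone", "chrom"], sort=False):
            e = edges.get(edge_key(drone, chrom))
            if e is None:
                continue
            d = _min_distance_to_events(grp["pos"].to_numpy(float), e)
            total += int((d <= window_bp).sum())
        return total

    observed = count_proximal(mutations)

    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lens / lens.sum()
    n_mut = len(mutations)
    drone_labels = mutations["drone"].to_numpy()
    null = np.zeros(reps, dtype=int)
    # vectorized over replicates: each mutation keeps its drone label and
    # draws (chromosome, position) independently per replicate
    for k in range(n_mut):
        ci = rng.choice(len(chroms), size=reps, p=chrom_p)
        pos = (rng.random(reps) * lens[ci]).astype(np.int64)
        for c_idx, chrom in enumerate(chroms):
            sel = ci == c_idx
            if not sel.any():
                continue
            e = edges.get(edge_key(drone_labels[k], chrom))
            if e is None:
                continue
            d = _min_distance_to_events(pos[sel].astype(float), e)
            null[sel] += (d <= window_bp).astype(int)
    n_extreme = int((null >= observed).sum())
    return McResult(observed=float(observed), n_extreme=n_extreme, reps=reps,
                    p=mc_pvalue(n_extreme, reps), null=null,
                    extra={"window_bp": window_bp, "pooled": pooled})


def conversion_bias_test(
    conversions: pd.DataFrame,
    reps: int = 10_000,
    seed: int | None = None,
) -> McResult:
    """GC-bias randomization on gene-conversion direction.

    ``conversions`` needs ``from_allele`` and ``to_allele`` columns.
    Informative sites are those converting between the A/T and G/C classes;
    the observed statistic is the count converting toward G/C.  The null
    flips a fair coin per informative site; the exact two-sided binomial
    p-value is reported alongside the one-sided Monte-Carlo one.
    """
    gc = {"G", "C"}
    frm = conversions["from_allele"].astype(str)
    to = conversions["to_allele"].astype(str)
    informative = frm.isin(gc) != to.isin(gc)
    n_inf = int(informative.sum())
    if n_inf == 0:
        return McResult(observed=float("nan"), n_extreme=0, reps=0,
                        p=float("nan"), extra={"n_informative": 0,
                                               "declined": True})
    toward_gc = int((informative & to.isin(gc)).sum())
    rng = np.random.default_rng(seed)
    null = rng.binomial(n_inf, 0.5, size=reps)
    n_extreme = int((null >= toward_gc).sum())
    binom = sps.binomtest(toward_gc, n_inf, 0.5)
    return McResult(
        observed=float(toward_gc), n_extreme=n_extreme, reps=reps,
        p=mc_pvalue(n_extreme, reps), null=null,
        extra={"n_informative": n_inf, "toward_gc": toward_gc,
               "toward_at": n_inf - toward_gc,
               "binomial_p_two_sided": float(binom.pvalue),
               "binomial_p_one_sided": float(sps.binom.sf(toward_gc - 1, n_inf, 0.5)),
               "declined": False},
    )


def rate_difference_permutation(
    rates_a, rates_b,
    reps: int = 10_000,
    seed: int | None = None,
) -> McResult:
    """Permutation test for a difference in mean per-individual rates.

    The observed statistic is ``|mean(a) - mean(b)|``; the null re-partitions
    the pooled per-individual rates into the original group sizes.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = len(a)
    perms = rng.permuted(np.tile(pooled, (reps, 1)), axis=1)
    delta = np.abs(perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1))
    n_extreme = int((delta >= observed).sum())
    return McResult(observed=float(observed), n_extreme=n_extreme, reps=reps,
                    p=mc_pvalue(n_extreme, reps), null=delta)


# ---------------------------------------------------------------------------
# Window table construction
# ---------------------------------------------------------------------------


def build_window_table(
    reference: dict[str, np.ndarray],
    het_positions: dict[str, np.ndarray],
    events: pd.DataFrame,
    n_drones: int,
    window_bp: int = 100_000,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tile the genome into nonoverlapping windows and tabulate correlates.

    Columns per window: ``gc`` (G+C fraction of non-N bases), ``het``
    (heterozygous sites per bp), ``cm_per_mb`` (kept crossovers assigned by
    breakpoint midpoint), and with ``genes`` (chrom/start/end intervals)
    ``gene_count`` and ``coding_fraction``.
    """
    from .recombination import window_rates  # local import, avoids a cycle

    chrom_lengths = {c: len(seq) for c, seq in reference.items()}
    wr = window_rates(events, chrom_lengths, n_drones, window_bp=window_bp)
    gc_col, het_col, gene_count, coding_frac = [], [], [], []
    for _, row in wr.iterrows():
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        seg = reference[chrom][start:end]
        known = seg != 4
        n_known = int(known.sum())
        gc_col.append(float(((seg == 1) | (seg == 2)).sum() / n_known)
                      if n_known else np.nan)
        pos = het_positions.get(chrom, np.empty(0, dtype=np.int64))
        lo, hi = np.searchsorted(pos, [start, end])
        het_col.append((hi - lo) / (end - start))
        if genes is not None:
            sub = genes[(genes["chrom"] == chrom)
                        & (genes["start"] < end) & (genes["end"] > start)]
            gene_count.append(len(sub))
            covered = int(np.sum(np.minimum(sub["end"], end)
                                 - np.maximum(sub["start"], start))) if len(sub) else 0
            coding_frac.append(min(covered / (end - start), 1.0))
    wr["gc"] = gc_col
    wr["het"] = het_col
    if genes is not None:
        wr["gene_count"] = gene_count
        wr["coding_fraction"] = coding_frac
    return wr
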