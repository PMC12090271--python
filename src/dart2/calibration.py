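"""Group-size calibration and the nonparametric comparison workflow.

The calibration sweep answers a design question for the assay: how many
flies per tube give a reproducible, well-separated readout?  For each
candidate group size it simulates replicate tubes under an aversive
drift and matched solvent controls (zero drift), window-averages each
tube's CoM trace, and summarizes (a) the replicate-to-replicate variance
of the mean CoM and (b) the standardized effect size (Cohen's d) between
odor and control arms.  Variance falls with group size until the
tube-level component dominates; the effect size rises and plateaus,
and at 32-64 flies crowding pushes part of the group back toward the
odorant, lowering the mean — together these reproduce the rationale for
running 8-16 flies per tube.

The comparison workflow is rank-based throughout: Mann-Whitney U for two
groups, Kruskal-Wallis followed by Dunn's z-tests (Bonferroni adjusted)
for more than two, and the paired Wilcoxon signed-rank test for paired
designs.  Exact small-sample branches are used where they exist without
ties; otherwise midrank/tie-corrected normal approximations apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AssaySimConfig, simulate_com_series
from .timeseries import CoMSeries, OdorWindow, downsample, window_average


@dataclass(frozen=True)
class ReplicateSet:
    """Window-averaged CoM values, one per replicate tube, for one condition."""

    condition: str
    group_size: int
    replicate_means: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.replicate_means, dtype=np.float64)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("replicate_means must be a non-empty 1-D array")
        if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
            raise ValueError("replicate means must lie in [0, 1]")
        object.__setattr__(self, "replicate_means", vals)

    @property
    def n(self) -> int:
        return int(self.replicate_means.size)


@dataclass(frozen=True)
class CalibrationResult:
    """Per-group-size summaries of the calibration sweep."""

    group_sizes: np.ndarray
    variances: np.ndarray
    effect_sizes: np.ndarray
    mean_coms: np.ndarray
    control_mean_coms: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_size": self.group_sizes,
                "variance": self.variances,
                "effect_size": self.effect_sizes,
                "mean_com": self.mean_coms,
                "control_mean_com": self.control_mean_coms,
            }
        )


def variance_of_means(reps: ReplicateSet) -> float:
    """Unbiased (n-1) sample variance of the replicate means."""
    if reps.n < 2:
        raise ValueError("variance requires at least 2 replicates")
    return float(np.var(reps.replicate_means, ddof=1))


def temporal_variance(series: CoMSeries, window: OdorWindow) -> float:
    """Within-replicate variance of the CoM over the window (secondary
    diagnostic; the calibration itself uses across-replicate variance)."""
    lo, hi = window.start_min * 60.0, window.end_min * 60.0
    sel = (series.times >= lo) & (series.times <= hi)
    vals = series.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 in-window samples")
    return float(np.var(vals, ddof=1))


def effect_size(treated: ReplicateSet, control: ReplicateSet) -> float:
    """Cohen's d between two replicate sets, pooled SD with (n-1) weights.

    Returns NaN (flagged as undefined) when the pooled SD is zero.
    """
    if treated.n < 2 or control.n < 2:
        raise ValueError("effect size requires at least 2 replicates per arm")
    a, b = treated.replicate_means, control.replicate_means
    pooled_var = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def _window_means(config: AssaySimConfig, n_reps: int, window: OdorWindow, analysis_interval_s: float) -> np.ndarray:
    times, com = simulate_com_series(config, n_replicates=n_reps)
    out = np.empty(n_reps)
    for i in range(n_reps):
        series = CoMSeries(times=times, values=com[i], cadence_s=1.0 / config.fps)
        series = downsample(series, analysis_interval_s)
        out[i] = window_average(series, window)
    return out


def calibrate_group_size(
    sim_config_base: AssaySimConfig,
    group_sizes: Sequence[int] = (1, 2, 4, 8, 16, 32, 64),
    n_reps: int = 50,
    window: Optional[OdorWindow] = None,
    analysis_interval_s: float = 10.0,
) -> CalibrationResult:
    """Run the calibration sweep over flies-per-tube.

    For each size the base configuration is simulated ``n_reps`` times
    in an odor arm (the base drift) and a matched solvent-control arm
    (drift 0); each replicate trace is decimated to the analysis cadence
    and window-averaged.  Replicate variance is computed on the odor
    arm, Cohen's d between the arms.  Seeds for every (size, arm) cell
    derive deterministically from the base seed, so a fixed base
    configuration reproduces the result bit for bit.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    window = window or OdorWindow("benzaldehyde", 20, 60)
    sizes = [int(s) for s in group_sizes]
    ss = np.random.SeedSequence(sim_config_base.seed).spawn(2 * len(sizes))
    variances, effects, means, ctl_means = [], [], [], []
    for j, size in enumerate(sizes):
        seed_odor = int(ss[2 * j].generate_state(1)[0] % (2**31))
        seed_ctl = int(ss[2 * j + 1].generate_state(1)[0] % (2**31))
        cfg_odor = replace(sim_config_base, n_flies=size, seed=seed_odor)
        cfg_ctl = replace(sim_config_base, n_flies=size, drift_mm_s=0.0, seed=seed_ctl)
        odor = ReplicateSet("odor", size, _window_means(cfg_odor, n_reps, window, analysis_interval_s))
        ctl = ReplicateSet("control", size, _window_means(cfg_ctl, n_reps, window, analysis_interval_s))
        variances.append(variance_of_means(odor))
        effects.append(effect_size(odor, ctl))
        means.append(float(odor.replicate_means.mean()))
        ctl_means.append(float(ctl.replicate_means.mean()))
    return CalibrationResult(
        group_sizes=np.array(sizes),
        variances=np.array(variances),
        effect_sizes=np.array(effects),
        mean_coms=np.array(means),
        control_mean_coms=np.array(ctl_means),
    )


# ---------------------------------------------------------------------------
# Rank-based tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the smaller sample has at most 8 values
    and the pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(np.concatenate([a, b]))
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), method=method)


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on ``a - b``.

    Exact for at most 15 nonzero differences, computed by full
    enumeration of the 2^n sign assignments over midranks of |d| (which
    stays correct under tied differences, where shift-algorithm exact
    p-values do not); the tie-corrected normal approximation is used for
    larger samples.  Zero differences are dropped; all-zero differences
    leave the statistic undefined and are rejected.  The reported
    statistic is min(W+, W-), the smaller signed-rank sum.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 1:
        raise ValueError("samples must be non-empty")
    d = a - b
    d_nz = d[d != 0]
    if d_nz.size == 0:
        raise ValueError("all paired differences are zero; the signed-rank statistic is undefined")
    n = d_nz.size
    if n <= 15:
        ranks = stats.rankdata(np.abs(d_nz))
        tot = float(ranks.sum())
        w_pos = float(ranks[d_nz > 0].sum())
        w_small = min(w_pos, tot - w_pos)
        if _has_ties(np.abs(d_nz)):
            # midranks: enumerate all 2^n sign assignments
            patterns = np.arange(2**n, dtype=np.int64)
            sel = (patterns[:, None] >> np.arange(n)) & 1
            ws = sel @ ranks
            p = float(np.mean(np.minimum(ws, tot - ws) <= w_small + 1e-12))
        else:
            # integer ranks: classical counting recursion over W+,
            # equivalent to (and much cheaper than) full enumeration
            counts = np.zeros(int(tot) + 1)
            counts[0] = 1.0
            for k in range(1, n + 1):
                counts[k:] += counts[:-k].copy()
            probs = counts / counts.sum()
            w_int = int(round(w_small))
            p = float(probs[: w_int + 1].sum() + probs[int(tot) - w_int :].sum())
        return TestResult(statistic=w_small, pvalue=min(1.0, p), method="exact")
    res = stats.wilcoxon(a, b, alternative="two-sided", method="approx", zero_method="wilcox")
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), method="approx")


@dataclass(frozen=True)
class DunnResult:
    """Kruskal-Wallis omnibus plus Dunn's pairwise z-tests."""

    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    p_adjust: str = "bonferroni",
) -> DunnResult:
    """Kruskal-Wallis omnibus followed by Dunn's multiple comparisons.

    Dunn's z statistic for groups i, j uses the pooled midranks:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))``
    with tie correction ``T = sum(t^3 - t) / (12 (N - 1))``.  Raw
    two-sided normal p-values are Bonferroni-adjusted over the tested
    pairs (the conventional, conservative choice).  With exactly two
    groups the omnibus reduces to the two-group Kruskal-Wallis test.
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in arrs):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match the number of groups")
    h, p_omni = stats.kruskal(*arrs)

    pooled = np.concatenate(arrs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrs))]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_tot - 1))) if n_tot > 1 else 0.0
    var_factor = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs = list(combinations(range(len(arrs)), 2))
    rows = []
    for i, j in pairs:
        se = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else math.nan
        p_raw = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else math.nan
        if p_adjust == "bonferroni":
            p_adj = min(1.0, p_raw * len(pairs))
        elif p_adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown p_adjust {p_adjust!r}")
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
            }
        )
    return DunnResult(h_statistic=float(h), p_omnibus=float(p_omni), pairwise=pd.DataFrame(rows))
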