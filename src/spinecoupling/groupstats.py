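"""Between-group and correlation statistics for spine populations.

Implements the statistical toolbox used to compare control and potentiated
spine populations: Mann–Whitney and pooled-variance t tests, Spearman
correlation, ordinary least squares on log10–log10 axes with ANCOVA
comparison of slopes and elevations, Kruskal–Wallis with Dunn's post-hoc,
ratio and relative-change metrics, volume histograms, and descriptive
summaries (mean ± SEM and median ± IQR with a normality check so callers
can pick the appropriate display).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import SpineRecord


# --- two-sample tests ----------------------------------------------------


class MannWhitneyResult(NamedTuple):
    U: float  # statistic of the first sample
    U_other: float  # complementary statistic (n1*n2 - U)
    p: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and the data are tie-free, and the tie-corrected normal
    approximation otherwise. Both U and its complement are reported since
    conventions differ on which is printed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    return MannWhitneyResult(
        U=u, U_other=float(a.size * b.size - u), p=float(res.pvalue), method=method
    )


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def t_test_unpaired(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided unpaired t test with pooled variance; df = n1 + n2 − 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t_test_unpaired requires >= 2 observations per group")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


# --- regression and ANCOVA ----------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit on log10-transformed values."""

    slope: float
    intercept: float
    residual_ss: float
    n: int


def loglog_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of log10(y) on log10(x).

    All values must be strictly positive; the first offending index is
    named in the error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    for name, arr in (("x", x), ("y", y)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(
                f"non-positive value in {name} at index {bad[0]}: {arr[bad[0]]}"
            )
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_ss=float(resid @ resid),
        n=int(x.size),
    )


class AncovaResult(NamedTuple):
    F_slope: float
    df_slope: tuple[int, int]
    p_slope: float
    F_elev: float
    df_elev: tuple[int, int]
    p_elev: float
    slopes_homogeneous: bool  # elevation test is meaningful only if True


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coef
    return float(r @ r)


def ancova_compare(
    x1: Sequence[float],
    y1: Sequence[float],
    x2: Sequence[float],
    y2: Sequence[float],
    log10: bool = True,
) -> AncovaResult:
    """ANCOVA comparison of two regression lines.

    Tests slope homogeneity by comparing the separate-slopes model against
    the common-slope model, F with df (1, n1 + n2 − 4); then tests
    elevation (intercept difference) under the common slope, F with df
    (1, n1 + n2 − 3). Values are log10-transformed by default, matching
    allometric (power-law) comparisons; set ``log10=False`` for raw-scale
    lines. The elevation test is flagged as not meaningful when the slopes
    differ (p_slope < 0.05).
    """
    arrays = [np.asarray(v, dtype=float) for v in (x1, y1, x2, y2)]
    if log10:
        for arr in arrays:
            if not (arr > 0).all():
                raise ValueError("log10 ANCOVA requires strictly positive values")
        arrays = [np.log10(arr) for arr in arrays]
    lx1, ly1, lx2, ly2 = arrays
    n1, n2 = lx1.size, lx2.size
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs n >= 3")
    if np.var(lx1) == 0 or np.var(lx2) == 0:
        raise ValueError("degenerate x-variance in a group")
    x = np.concatenate([lx1, lx2])
    y = np.concatenate([ly1, ly2])
    g = np.concatenate([np.zeros(n1), np.ones(n2)])
    ones = np.ones_like(x)
    # separate slopes and intercepts
    rss_sep = _rss(np.column_stack([ones, g, x, g * x]), y)
    # common slope, separate intercepts
    rss_slope = _rss(np.column_stack([ones, g, x]), y)
    # single line
    rss_single = _rss(np.column_stack([ones, x]), y)

    df2_slope = n1 + n2 - 4
    F_slope = (rss_slope - rss_sep) / (rss_sep / df2_slope)
    p_slope = float(stats.f.sf(F_slope, 1, df2_slope))
    df2_elev = n1 + n2 - 3
    F_elev = (rss_single - rss_slope) / (rss_slope / df2_elev)
    p_elev = float(stats.f.sf(F_elev, 1, df2_elev))
    return AncovaResult(
        F_slope=float(max(F_slope, 0.0)),
        df_slope=(1, df2_slope),
        p_slope=p_slope,
        F_elev=float(max(F_elev, 0.0)),
        df_elev=(1, df2_elev),
        p_elev=p_elev,
        slopes_homogeneous=p_slope >= 0.05,
    )


def spearman_global(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) with two-sided p.

    For tie-free samples of n ≤ 8 the p value is exact, from the full
    permutation null of the rank pairing; larger or tied samples use the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= 8 and tie_free:
        ry = stats.rankdata(y)
        base = np.arange(1.0, n + 1.0)
        perms = np.array(list(itertools.permutations(ry)))
        # tie-free Spearman via the sum-of-squared-rank-differences identity
        d2 = ((perms - base) ** 2).sum(axis=1)
        rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), float(p)


# --- k-sample tests ------------------------------------------------------


class DunnComparison(NamedTuple):
    i: int
    j: int
    z: float
    p_raw: float
    p_adjusted: float


class KruskalDunnResult(NamedTuple):
    H: float
    p: float
    comparisons: list[DunnComparison]


def kruskal_dunn(groups: Sequence[Sequence[float]]) -> KruskalDunnResult:
    """Tie-corrected Kruskal–Wallis H with Dunn's pairwise post-hoc.

    Dunn z for groups i, j uses pooled average ranks:
    ``z = (R̄i − R̄j) / sqrt((N(N+1)/12 − T)(1/ni + 1/nj))`` with the tie
    term ``T = Σ(t³ − t) / (12(N − 1))``; pairwise p values are
    Bonferroni-adjusted over the k(k−1)/2 comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn requires >= 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if any(g.size == 1 for g in groups):
        warnings.warn("singleton group in kruskal_dunn", stacklevel=2)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[k] : bounds[k + 1]].mean() for k in range(len(groups))
    ]
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    comparisons = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        comparisons.append(
            DunnComparison(
                i=i, j=j, z=float(z), p_raw=float(p_raw),
                p_adjusted=float(min(1.0, p_raw * n_pairs)),
            )
        )
    return KruskalDunnResult(H=float(H), p=float(p), comparisons=comparisons)


# --- spine-level derived metrics ----------------------------------------


def ratio_metrics(records: Iterable[SpineRecord]) -> pd.DataFrame:
    """Per-spine PSD-to-volume ratios.

    Returns a frame with columns spine_id, condition, area_ratio_per_um
    (PSD area / spine volume, μm⁻¹) and core_ratio (PSD-core volume /
    spine volume, dimensionless).
    """
    rows = [
        {
            "spine_id": r.id,
            "condition": r.condition,
            "area_ratio_per_um": r.psd_area / r.volume,
            "core_ratio": r.psd_core_volume / r.volume,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows)


class RelativeChangeResult(NamedTuple):
    per_spine: pd.DataFrame  # cLTP spines: spine_id, stratum, relative_value
    U: float
    p: float


def relative_change(
    cltp_records: Sequence[SpineRecord],
    control_records: Sequence[SpineRecord],
    attribute: str = "volume",
) -> RelativeChangeResult:
    """Relative change of a parameter under potentiation, by SER stratum.

    Since the populations are cross-sectional (no per-spine baseline),
    each potentiated spine's value is divided by the *median* of the
    control spines in its SER stratum; the two strata of relative values
    are then compared with a Mann–Whitney test.
    """
    strata: dict[bool, float] = {}
    for flag in (False, True):
        ctrl_vals = [
            getattr(r, attribute) for r in control_records if r.has_ser == flag
        ]
        cltp_vals = [r for r in cltp_records if r.has_ser == flag]
        if not ctrl_vals or not cltp_vals:
            raise ValueError(
                f"empty {'SER' if flag else 'no-SER'} stratum in one condition"
            )
        strata[flag] = float(np.median(ctrl_vals))
    rows = [
        {
            "spine_id": r.id,
            "stratum": "ser" if r.has_ser else "no_ser",
            "relative_value": getattr(r, attribute) / strata[r.has_ser],
        }
        for r in cltp_records
    ]
    frame = pd.DataFrame(rows)
    ser_vals = frame.loc[frame["stratum"] == "ser", "relative_value"]
    noser_vals = frame.loc[frame["stratum"] == "no_ser", "relative_value"]
    mw = mann_whitney(ser_vals, noser_vals)
    return RelativeChangeResult(per_spine=frame, U=mw.U, p=mw.p)


def volume_histogram(
    records: Iterable[SpineRecord], bin_width: float = 0.05
) -> pd.DataFrame:
    """Frequency (%) of spines in fixed-width volume bins from zero.

    Bins are left-closed, right-open; frequencies sum to 100%.
    """
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    volumes = np.array([r.volume for r in records], dtype=float)
    if volumes.size == 0:
        raise ValueError("no records")
    idx = np.floor(volumes / bin_width).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin_lo_um3": np.arange(n_bins) * bin_width,
            "bin_hi_um3": (np.arange(n_bins) + 1) * bin_width,
            "count": counts,
            "frequency_pct": 100.0 * counts / volumes.size,
        }
    )


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary: both parametric and nonparametric displays."""

    n: int
    mean: float
    sem: float
    median: float
    iqr: float
    normality_p: float  # Shapiro–Wilk; NaN when n < 3


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean ± SEM, median ± IQR and a Shapiro–Wilk normality p.

    Both displays are computed so callers can report mean ± SEM for
    normally distributed samples and median ± IQR otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires n >= 1")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    if v.size >= 3 and np.unique(v).size > 1:
        normality_p = float(stats.shapiro(v).pvalue)
    else:
        normality_p = float("nan")
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sem=sem,
        median=float(np.median(v)),
        iqr=float(stats.iqr(v)),
        normality_p=normality_p,
    )
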