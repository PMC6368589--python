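"""Local Spearman correlation profiling across spine volumes.

The population-wide rank correlation between spine volume and PSD size can
hide volume ranges where the two decouple. To detect them, a set of sliding
windows of adjacent spines (in volume order) is centred on each spine; the
pairs in every window are repeatedly subsampled without replacement, a
Spearman coefficient and its p value are computed for each subsample, and
the coefficients and p values are averaged over all subsamples and window
sizes for that spine. Spines whose mean p value fails the significance
threshold mark volume ranges where spine volume is a poor predictor of PSD
size; maximal contiguous runs of such spines form the *decoupled bands*,
and decoupled-spine counts are compared between groups with a chi-square
test.

Spearman p values per subsample use the t-distribution approximation
``t = ρ·√((m−2)/(1−ρ²))`` with ``m − 2`` degrees of freedom, adequate for
the subset sizes (≥ 10) used by default. Subsamples in which either
variable is constant have no defined coefficient; by default they
contribute ρ = 0, p = 1 (option: skip them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import SpineRecord

PARAMETER_PAIRS = {
    # name -> (x attribute, y attribute); windows slide along x
    "psd_area": ("volume", "psd_area"),
    "psd_core_volume": ("volume", "psd_core_volume"),
    "psd_area_vs_core": ("psd_area", "psd_core_volume"),
}


@dataclass(frozen=True)
class LocalCorrParams:
    """Parameters of the sliding-window bootstrap procedure.

    Defaults follow the published procedure: window sizes 14–24 spines,
    2500 resamples without replacement per window, each resample 4 pairs
    smaller than its window (subset sizes 10–20), significance at 0.05.
    """

    window_sizes: tuple[int, ...] = tuple(range(14, 25))
    n_boot: int = 2500
    subset_deficit: int = 4
    alpha: float = 0.05
    seed: int = 0
    constant_policy: str = "zero"  # "zero" | "skip"

    def __post_init__(self) -> None:
        if not self.window_sizes:
            raise ValueError("window_sizes must be non-empty")
        if min(self.window_sizes) <= self.subset_deficit + 2:
            raise ValueError(
                f"min window size {min(self.window_sizes)} must exceed "
                f"subset_deficit + 2 = {self.subset_deficit + 2}"
            )
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.constant_policy not in ("zero", "skip"):
            raise ValueError(f"unknown constant_policy {self.constant_policy!r}")


class RankedPairs(NamedTuple):
    """Rank vectors in x-sorted order, plus the sort permutation."""

    x_ranks: np.ndarray
    y_ranks: np.ndarray
    order: np.ndarray


def rank_by_index(x: Sequence[float], y: Sequence[float]) -> RankedPairs:
    """Sort pairs by ``x`` and replace both variables by average ranks.

    ``x`` is the index vector: the output is in ascending-x order (ties kept
    in input order), and both columns are global average ranks, so any
    strictly increasing transform of either variable leaves the result
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D, got {x.shape}, {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    order = np.argsort(x, kind="stable")
    xr = stats.rankdata(x, method="average")
    yr = stats.rankdata(y, method="average")
    return RankedPairs(x_ranks=xr[order], y_ranks=yr[order], order=order)


class BootstrapResult(NamedTuple):
    mean_rho: float
    mean_p: float
    n_constant: int


def _spearman_rows(
    xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided t-approximation p.

    Returns (rho, p, constant_mask); rows where either variable is constant
    get rho = 0, p = 1 and are flagged.
    """
    m = xs.shape[1]
    rx = stats.rankdata(xs, method="average", axis=1)
    ry = stats.rankdata(ys, method="average", axis=1)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean(axis=1, keepdims=True)
    sx = np.einsum("ij,ij->i", rxc, rxc)
    sy = np.einsum("ij,ij->i", ryc, ryc)
    den = np.sqrt(sx * sy)
    constant = den == 0.0
    num = np.einsum("ij,ij->i", rxc, ryc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(constant, 0.0, num / np.where(constant, 1.0, den))
    rho = np.clip(rho, -1.0, 1.0)
    one_minus = 1.0 - rho**2
    perfect = one_minus <= 0.0
    with np.errstate(divide="ignore"):
        t = np.abs(rho) * np.sqrt((m - 2) / np.where(perfect, 1.0, one_minus))
    p = 2.0 * stats.t.sf(t, df=m - 2)
    p = np.where(perfect, 0.0, p)
    p = np.where(constant, 1.0, p)
    return rho, p, constant


def bootstrap_spearman(
    window_pairs: np.ndarray,
    subset_size: int,
    n_boot: int = 2500,
    seed: int | None = 0,
    constant_policy: str = "zero",
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Mean Spearman rho and p over subsamples of one window.

    ``window_pairs`` is a (w, 2) array of paired values (raw values or
    ranks — subsamples are re-ranked internally, so it makes no
    difference). Each of the ``n_boot`` subsamples draws ``subset_size``
    distinct pairs without replacement; the Spearman coefficient and its
    two-sided p are averaged arithmetically over subsamples.
    """
    pairs = np.asarray(window_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError(f"window_pairs must be (w, 2), got {pairs.shape}")
    w = pairs.shape[0]
    if w < 4:
        raise ValueError(f"window size must be >= 4, got {w}")
    if not 3 <= subset_size < w:
        raise ValueError(f"subset_size must be in [3, {w}), got {subset_size}")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_boot, w)), axis=1)[:, :subset_size]
    x = pairs[:, 0]
    y = pairs[:, 1]
    # tie-free fast path: with x strictly increasing, sorting the subset
    # indices makes the within-subset x-ranks exactly 1..m, and tie-free y
    # ranks follow from one argsort (inverse permutation)
    if (np.diff(x) > 0).all() and np.unique(y).size == w:
        m = subset_size
        idx = np.sort(idx, axis=1)
        ys = y[idx]
        order = np.argsort(ys, axis=1)
        ry = np.empty_like(ys)
        np.put_along_axis(ry, order, np.arange(1.0, m + 1.0), axis=1)
        j = np.arange(1.0, m + 1.0)
        num = ry @ j - m * ((m + 1.0) / 2.0) ** 2
        rho = np.clip(num / (m * (m * m - 1.0) / 12.0), -1.0, 1.0)
        one_minus = 1.0 - rho**2
        perfect = one_minus <= 0.0
        with np.errstate(divide="ignore"):
            t = np.abs(rho) * np.sqrt((m - 2) / np.where(perfect, 1.0, one_minus))
        p = np.where(perfect, 0.0, 2.0 * stats.t.sf(t, df=m - 2))
        constant = np.zeros(n_boot, dtype=bool)
    else:
        rho, p, constant = _spearman_rows(x[idx], y[idx])
    n_const = int(constant.sum())
    if constant_policy == "skip" and n_const:
        keep = ~constant
        if not keep.any():
            return BootstrapResult(mean_rho=0.0, mean_p=1.0, n_constant=n_const)
        rho, p = rho[keep], p[keep]
    return BootstrapResult(
        mean_rho=float(rho.mean()), mean_p=float(p.mean()), n_constant=n_const
    )


@dataclass
class LocalCorrProfile:
    """Per-spine local correlation profile for one parameter pair.

    ``table`` has one row per input spine, in ascending order of the index
    variable, with columns: spine_id, volume_um3, center_value, mean_rho,
    mean_p, n_windows_used, significant.
    """

    parameter: str
    alpha: float
    table: pd.DataFrame

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_decoupled(self) -> int:
        return int((~self.table["significant"]).sum())


def local_profile(
    records: Sequence[SpineRecord],
    parameter: str = "psd_area",
    params: LocalCorrParams | None = None,
) -> LocalCorrProfile:
    """Sliding-window bootstrap Spearman profile over a spine population.

    For each spine, one window of every size in ``params.window_sizes`` is
    centred on the spine's rank along the index variable (windows are
    shifted inward at the edges so every spine receives all sizes);
    ``bootstrap_spearman`` is applied to each window and the coefficients
    and p values are averaged jointly over all windows and subsamples.
    A spine is *significant* when its mean p is below ``params.alpha``.
    """
    if params is None:
        params = LocalCorrParams()
    if parameter not in PARAMETER_PAIRS:
        raise ValueError(
            f"parameter must be one of {sorted(PARAMETER_PAIRS)}, got {parameter!r}"
        )
    records = list(records)
    n = len(records)
    w_max = max(params.window_sizes)
    if n < w_max:
        raise ValueError(
            f"need at least max(window_sizes) = {w_max} records, got {n}"
        )
    x_attr, y_attr = PARAMETER_PAIRS[parameter]
    x = np.array([getattr(r, x_attr) for r in records], dtype=float)
    y = np.array([getattr(r, y_attr) for r in records], dtype=float)
    ranked = rank_by_index(x, y)
    order = ranked.order
    pairs = np.column_stack([ranked.x_ranks, ranked.y_ranks])

    rng = np.random.default_rng(params.seed)
    mean_rho = np.zeros(n)
    mean_p = np.zeros(n)
    n_windows = len(params.window_sizes)
    for i in range(n):
        acc_rho = 0.0
        acc_p = 0.0
        for w in params.window_sizes:
            lo = min(max(i - w // 2, 0), n - w)
            res = bootstrap_spearman(
                pairs[lo : lo + w],
                subset_size=w - params.subset_deficit,
                n_boot=params.n_boot,
                constant_policy=params.constant_policy,
                rng=rng,
            )
            acc_rho += res.mean_rho
            acc_p += res.mean_p
        mean_rho[i] = acc_rho / n_windows
        mean_p[i] = acc_p / n_windows

    table = pd.DataFrame(
        {
            "spine_id": [records[j].id for j in order],
            "volume_um3": [records[j].volume for j in order],
            "center_value": x[order],
            "mean_rho": mean_rho,
            "mean_p": mean_p,
            "n_windows_used": n_windows,
            "significant": mean_p < params.alpha,
        }
    )
    return LocalCorrProfile(parameter=parameter, alpha=params.alpha, table=table)


@dataclass
class DecoupledBands:
    """Maximal contiguous runs of non-significant spines."""

    bands: list[dict]  # each: {"lo", "hi", "n_spines"} in center_value units
    n_decoupled: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_decoupled / self.n_total if self.n_total else 0.0


def nonsignificant_regions(
    profile: LocalCorrProfile, alpha: float | None = None
) -> DecoupledBands:
    """Extract decoupled bands from a profile.

    A band is a maximal run, in index-variable order, of spines whose mean
    p is at or above ``alpha``; its bounds are the index-variable values of
    the run's first and last spines.
    """
    tab = profile.table
    if tab.empty:
        raise ValueError("profile is empty")
    if alpha is None:
        alpha = profile.alpha
    nonsig = (tab["mean_p"].to_numpy() >= alpha)
    values = tab["center_value"].to_numpy()
    bands: list[dict] = []
    start = None
    for i, flag in enumerate(nonsig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            bands.append(
                {"lo": float(values[start]), "hi": float(values[i - 1]),
                 "n_spines": int(i - start)}
            )
            start = None
    if start is not None:
        bands.append(
            {"lo": float(values[start]), "hi": float(values[len(nonsig) - 1]),
             "n_spines": int(len(nonsig) - start)}
        )
    return DecoupledBands(
        bands=bands, n_decoupled=int(nonsig.sum()), n_total=int(len(nonsig))
    )


class Chi2Result(NamedTuple):
    statistic: float
    p: float
    table: np.ndarray  # rows: groups; cols: (significant, non-significant)


def compare_decoupled_counts(
    profile_a: LocalCorrProfile, profile_b: LocalCorrProfile
) -> Chi2Result:
    """Pearson chi-square on significant vs non-significant spine counts.

    Builds the 2×2 table (group × significance) from the two profiles and
    applies the chi-square test without continuity correction.
    """
    table = np.array(
        [
            [profile_a.n_significant, profile_a.n_decoupled],
            [profile_b.n_significant, profile_b.n_decoupled],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate contingency table (zero marginal): {table}")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(stat), p=float(p), table=table)
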