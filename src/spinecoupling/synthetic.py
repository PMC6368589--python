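"""Synthetic spine populations, contour stacks and brick scenes.

No public 3D-EM spine dataset accompanies the analysis this package
implements, so every downstream stage is exercised against a generator that
reproduces the statistical structure the analysis assumes:

* spine volumes are log-normal (log10 μm³ Gaussian);
* PSD surface area follows a power law in spine volume — linear in
  log10–log10 — with Gaussian residuals whose spread is inflated inside a
  configurable mid-volume *decoupling band*, the mechanism that produces
  locally non-significant rank correlation while preserving the strong
  global correlation;
* PSD-core volume is generated from PSD area with a tight log-scale
  coupling (the two differ mainly by an effective PSD thickness), so the
  area–core pair serves as an internal positive control;
* the probability that a spine contains smooth endoplasmic reticulum (SER)
  increases with volume through a logistic model;
* chemical LTP multiplies PSD area and PSD-core volume in every spine, but
  grows the spine itself only when SER is present, and narrows the
  decoupling band — so that potentiated populations show the increased
  PSD-to-volume ratios and the tightened coupling the analysis is designed
  to detect.

Residual spread outside the band is kept small so that, at the sample sizes
used here, sliding windows of adjacent spines outside the band are clearly
significant: the generator's job is to inject a *known* decoupling band,
not to mimic the full biological scatter of real populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .census import BrickSpec
from .morphometry import Trace, TraceStack
from .records import SpineRecord

N_SAMPLES_PER_GROUP = 4  # slices per condition; spines are assigned uniformly


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of the synthetic spine-population generator.

    Volumes are μm³, areas μm²; all log-scale parameters are in log10 units.

    Parameters
    ----------
    n_control, n_cltp : int
        Spines per condition. Defaults are the segmented group sizes of the
        study design being emulated (119 control, 138 potentiated).
    logV_mean, logV_sd : float
        Mean and sd of log10 spine volume. Defaults centre the population
        near 0.08 μm³ with a ~3-decade overall range.
    slope_a, intercept_b : float
        Power-law coupling log10(A) = slope_a·log10(V) + intercept_b.
    noise_sd_base, noise_sd_band : float
        Residual sd of log10(A) outside / inside the decoupling band.
    band_lo, band_hi : float
        Decoupling band (μm³) for control spines.
    cltp_band_lo, cltp_band_hi : float
        Decoupling band (μm³) for potentiated spines; narrower by default,
        emulating the tightened coupling after potentiation.
    core_area_ratio : float
        Effective PSD thickness (μm): core volume ≈ ratio × area.
    core_noise_sd : float
        Residual sd (log10) of core volume around the area coupling.
    ser_logit_b0, ser_logit_b1 : float
        P(SER) = logistic(b0 + b1·log10 V).
    cltp_psd_factor : float
        Multiplicative growth of PSD area and core volume under cLTP.
    cltp_spine_factor_ser : float
        Multiplicative spine-volume growth under cLTP, applied only to
        SER-containing spines.
    perf_prob_ser, perf_prob_noser : float
        PSD-perforation probability for spines with / without SER.
    seed : int
        Seed of the generator's own random stream.
    """

    n_control: int = 119
    n_cltp: int = 138
    logV_mean: float = -1.1
    logV_sd: float = 0.45
    slope_a: float = 1.0
    intercept_b: float = -0.15
    noise_sd_base: float = 0.015
    noise_sd_band: float = 0.25
    band_lo: float = 0.04
    band_hi: float = 0.10
    cltp_band_lo: float = 0.048
    cltp_band_hi: float = 0.073
    core_area_ratio: float = 0.03
    core_noise_sd: float = 0.01
    ser_logit_b0: float = 3.0
    ser_logit_b1: float = 3.2
    cltp_psd_factor: float = 2.2
    cltp_spine_factor_ser: float = 1.8
    perf_prob_ser: float = 0.15
    perf_prob_noser: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_cltp <= 0:
            raise ValueError(
                f"group sizes must be positive, got n_control={self.n_control}, "
                f"n_cltp={self.n_cltp}"
            )
        for name in ("logV_sd", "noise_sd_base", "noise_sd_band", "core_noise_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for lo, hi in (
            (self.band_lo, self.band_hi),
            (self.cltp_band_lo, self.cltp_band_hi),
        ):
            if not 0 < lo < hi:
                raise ValueError(f"invalid decoupling band [{lo}, {hi}]")
        for name in ("cltp_psd_factor", "cltp_spine_factor_ser", "core_area_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("perf_prob_ser", "perf_prob_noser"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return asdict(self)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_population(config: SynthConfig) -> list[SpineRecord]:
    """Draw a synthetic spine population under ``config``.

    Control and potentiated spines are generated with the same baseline
    model; potentiation then (i) multiplies SER-containing spines' volume
    by ``cltp_spine_factor_ser`` *before* the PSD coupling is evaluated, so
    the decoupling band is defined on the measured volume, and (ii)
    multiplies PSD area and core volume of every spine by
    ``cltp_psd_factor``. Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    records: list[SpineRecord] = []
    for condition, n, prefix in (
        ("control", config.n_control, "ctrl"),
        ("cltp", config.n_cltp, "cltp"),
    ):
        log_v = rng.normal(config.logV_mean, config.logV_sd, size=n)
        has_ser = rng.random(n) < _logistic(
            config.ser_logit_b0 + config.ser_logit_b1 * log_v
        )
        if condition == "cltp":
            log_v = log_v + np.where(
                has_ser, math.log10(config.cltp_spine_factor_ser), 0.0
            )
            band_lo, band_hi = config.cltp_band_lo, config.cltp_band_hi
        else:
            band_lo, band_hi = config.band_lo, config.band_hi
        volume = 10.0**log_v
        in_band = (volume >= band_lo) & (volume <= band_hi)
        noise_sd = np.where(in_band, config.noise_sd_band, config.noise_sd_base)
        log_a = (
            config.slope_a * log_v
            + config.intercept_b
            + rng.normal(0.0, 1.0, size=n) * noise_sd
        )
        log_vp = (
            log_a
            + math.log10(config.core_area_ratio)
            + rng.normal(0.0, config.core_noise_sd, size=n)
        )
        if condition == "cltp":
            log_a = log_a + math.log10(config.cltp_psd_factor)
            log_vp = log_vp + math.log10(config.cltp_psd_factor)
        # spine apparatus = stacked SER; present in a subset of SER spines,
        # preferentially the larger ones
        has_sa = has_ser & (
            rng.random(n) < _logistic(1.0 + 2.0 * (log_v - config.logV_mean))
        )
        perf_p = np.where(has_ser, config.perf_prob_ser, config.perf_prob_noser)
        perforated = rng.random(n) < perf_p
        sample = rng.integers(1, N_SAMPLES_PER_GROUP + 1, size=n)
        for i in range(n):
            records.append(
                SpineRecord(
                    id=f"{prefix}-{i:04d}",
                    sample_id=f"{condition}-s{sample[i]}",
                    condition=condition,
                    volume=float(volume[i]),
                    psd_area=float(10.0 ** log_a[i]),
                    psd_core_volume=float(10.0 ** log_vp[i]),
                    has_ser=bool(has_ser[i]),
                    has_spine_apparatus=bool(has_sa[i]),
                    perforated=bool(perforated[i]),
                    n_synapses=1,
                )
            )
    return records


def generate_contour_stacks(
    record: SpineRecord, thickness: float, seed: int = 0
) -> TraceStack:
    """Serial-section trace fixture for one spine.

    The spine body is modelled as a sphere of the record's volume, sliced
    into 64-gon cross-sections at the section spacing; contour radii are
    normalised so the Cavalieri sum (area × thickness) reproduces the
    record's volume. The PSD is laid down as open line traces on the top
    sections whose summed length × thickness reproduces the record's PSD
    area. Deterministic for a fixed seed.
    """
    if not thickness > 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    rng = np.random.default_rng(seed)
    v, a = record.volume, record.psd_area
    r = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
    n_sec = max(1, int(math.floor(2.0 * r / thickness)))
    # sphere cross-section radii at section mid-planes (symmetric about centre)
    z = (np.arange(n_sec) - (n_sec - 1) / 2.0) * thickness
    radii = np.sqrt(np.maximum(r**2 - z**2, (0.05 * r) ** 2))
    cx, cy = rng.uniform(-1.0, 1.0, size=2)

    k = 64
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    theta = theta0 + np.linspace(0.0, 2.0 * math.pi, k, endpoint=False)
    # polygon area of the inscribed 64-gon, then normalise to hit the target
    poly_area_unit = 0.5 * k * math.sin(2.0 * math.pi / k)  # area for radius 1
    measured = float(np.sum(poly_area_unit * radii**2) * thickness)
    radii *= math.sqrt(v / measured)

    traces = []
    for i, rad in enumerate(radii):
        verts = tuple(
            (cx + rad * math.cos(t), cy + rad * math.sin(t)) for t in theta
        )
        traces.append(
            Trace(section_index=i, kind="closed_polygon", label="spine", vertices=verts)
        )

    n_psd = max(1, n_sec // 3)
    seg_len = a / (n_psd * thickness)
    phi = rng.uniform(0.0, math.pi)
    dx, dy = math.cos(phi) * seg_len / 2.0, math.sin(phi) * seg_len / 2.0
    for j in range(n_psd):
        idx = n_sec - 1 - j
        traces.append(
            Trace(
                section_index=idx,
                kind="open_polyline",
                label="psd_core",
                vertices=((cx - dx, cy - dy), (cx + dx, cy + dy)),
            )
        )
    return TraceStack(
        object_id=record.id, section_thickness=thickness, traces=traces
    )


def generate_brick_scene(
    intensity: float, box: BrickSpec, seed: int = 0
) -> np.ndarray:
    """Homogeneous Poisson point scene of synapse reference locations.

    Returns an (n, 3) array of points uniform in ``box`` with
    n ~ Poisson(intensity × |box|). ``intensity`` is in count·μm⁻³;
    an intensity of exactly zero yields an empty scene.
    """
    if intensity < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * box.volume))
    lo = np.asarray(box.origin, dtype=float)
    dims = np.asarray(box.dims, dtype=float)
    return lo + rng.random((n, 3)) * dims
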