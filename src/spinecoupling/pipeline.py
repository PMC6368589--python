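"""End-to-end orchestration: generation → morphometry → census →
local correlation → group statistics → report.

The pipeline consumes exactly one input source — a synthetic-population
config, a spine-record CSV, or a directory of serial-section trace stacks
with an annotation table — and emits a deterministic report bundle: the
per-spine table, a density table, local-correlation profiles for the three
parameter pairs (PSD area vs volume, PSD-core volume vs volume, PSD area
vs PSD-core volume) in each condition, decoupled-band summaries with a
between-group chi-square, SER-stratified statistics, the perforation×SER
cross-tabulation, and a JSON report validated against a committed schema.

All randomness derives from a single global seed, recorded in every
output; fixed-seed runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import groupstats as gs
from .census import BrickSpec, brick_count, spine_density
from .io import dump_json, load_config_mapping, read_records, write_records
from .localcorr import (
    PARAMETER_PAIRS,
    LocalCorrParams,
    compare_decoupled_counts,
    local_profile,
    nonsignificant_regions,
)
from .morphometry import TraceStack, measure_psd_area, measure_volume
from .records import SpineRecord, split_by_condition
from .schema import validate_report
from .synthetic import (
    N_SAMPLES_PER_GROUP,
    SynthConfig,
    generate_brick_scene,
    generate_population,
)

DEFAULT_BRICK = BrickSpec(origin=(0.0, 0.0, 0.0), dims=(10.0, 10.0, 1.5))


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``synth``, ``records_path`` or ``traces_dir`` (with
    ``annotations_path``) must be given. ``seed`` governs every random
    stage and is recorded in the report.
    """

    synth: SynthConfig | None = None
    records_path: str | None = None
    traces_dir: str | None = None
    annotations_path: str | None = None
    localcorr: LocalCorrParams = field(default_factory=LocalCorrParams)
    brick: BrickSpec = DEFAULT_BRICK
    n_bricks_per_sample: int = 4
    density_intensity: float = 0.6  # μm⁻³, synthetic census scenes
    section_thickness: float = 0.06  # μm, traces source
    seed: int = 0
    out_dir: str = "spinecoupling_out"

    def __post_init__(self) -> None:
        sources = [
            self.synth is not None,
            self.records_path is not None,
            self.traces_dir is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: synth | records_path | traces_dir"
            )
        if self.traces_dir is not None and self.annotations_path is None:
            raise ValueError("traces_dir requires annotations_path")

    @classmethod
    def from_mapping(cls, mapping: dict, **overrides) -> "PipelineConfig":
        """Build from a parsed YAML/JSON mapping (CLI entry point)."""
        kwargs = dict(mapping)
        kwargs.update(overrides)
        if isinstance(kwargs.get("synth"), dict):
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if isinstance(kwargs.get("localcorr"), dict):
            lc = dict(kwargs["localcorr"])
            if "window_sizes" in lc:
                lc["window_sizes"] = tuple(lc["window_sizes"])
            kwargs["localcorr"] = LocalCorrParams(**lc)
        if isinstance(kwargs.get("brick"), dict):
            b = kwargs["brick"]
            kwargs["brick"] = BrickSpec(
                origin=tuple(b.get("origin", (0.0, 0.0, 0.0))),
                dims=tuple(b["dims"]),
            )
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        return cls.from_mapping(load_config_mapping(path), **overrides)

    def describe(self) -> dict:
        d: dict = {
            "source": (
                "synthetic"
                if self.synth is not None
                else ("records" if self.records_path is not None else "traces")
            ),
            "seed": self.seed,
            "localcorr": {
                "window_sizes": list(self.localcorr.window_sizes),
                "n_boot": self.localcorr.n_boot,
                "subset_deficit": self.localcorr.subset_deficit,
                "alpha": self.localcorr.alpha,
            },
            "brick": {"origin": list(self.brick.origin), "dims": list(self.brick.dims)},
        }
        if self.synth is not None:
            d["synth"] = self.synth.to_dict()
        if self.records_path is not None:
            d["records_path"] = str(self.records_path)
        if self.traces_dir is not None:
            d["traces_dir"] = str(self.traces_dir)
            d["annotations_path"] = str(self.annotations_path)
        return d


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def records_from_traces(
    traces_dir: str | Path, annotations_path: str | Path, thickness: float
) -> list[SpineRecord]:
    """Measure spine records from trace-stack JSON files.

    ``annotations_path`` is a CSV with columns id, sample_id, condition,
    has_ser, has_spine_apparatus, perforated, n_synapses; each row's id
    must match a ``<id>.json`` trace stack in ``traces_dir``. Spine volume
    and PSD area are measured from the traces; PSD-core volume from the
    closed psd_core contours.
    """
    import pandas as pd

    from .io import _parse_bool

    anno = pd.read_csv(Path(annotations_path), dtype=str)
    needed = ["id", "sample_id", "condition", "has_ser", "has_spine_apparatus",
              "perforated"]
    missing = [c for c in needed if c not in anno.columns]
    if missing:
        raise ValueError(f"{annotations_path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(anno.itertuples(index=False), start=1):
        d = dict(zip(anno.columns, row))
        stack_path = Path(traces_dir) / f"{d['id']}.json"
        if not stack_path.exists():
            raise ValueError(f"row {i}: no trace stack {stack_path}")
        stack = TraceStack.from_json(stack_path)
        if stack.section_thickness <= 0:
            stack.section_thickness = thickness
        records.append(
            SpineRecord(
                id=str(d["id"]),
                sample_id=str(d["sample_id"]),
                condition=str(d["condition"]),
                volume=measure_volume(stack, label="spine"),
                psd_area=measure_psd_area(stack),
                psd_core_volume=measure_volume(stack, label="psd_core"),
                has_ser=_parse_bool(d["has_ser"], i, "has_ser"),
                has_spine_apparatus=_parse_bool(
                    d["has_spine_apparatus"], i, "has_spine_apparatus"
                ),
                perforated=_parse_bool(d["perforated"], i, "perforated"),
                n_synapses=int(d.get("n_synapses", 1) or 1),
            )
        )
    return records


def _density_stage(config: PipelineConfig) -> dict:
    """Synthetic unbiased-brick census: 4 bricks per sample, both groups."""
    per_sample = []
    densities = {"control": [], "cltp": []}
    for ci, condition in enumerate(("control", "cltp")):
        for s in range(1, N_SAMPLES_PER_GROUP + 1):
            counts = []
            for b in range(config.n_bricks_per_sample):
                scene_seed = (
                    config.seed + 100_000 + ci * 10_000 + s * 100 + b
                ) % (2**31)
                scene = generate_brick_scene(
                    config.density_intensity, config.brick, seed=scene_seed
                )
                counts.append(brick_count(scene, config.brick))
            dens = spine_density(counts, config.brick.volume)
            densities[condition].append(dens)
            per_sample.append(
                {
                    "sample_id": f"{condition}-s{s}",
                    "condition": condition,
                    "density_per_um3": dens,
                }
            )
    tt = gs.t_test_unpaired(densities["control"], densities["cltp"])
    return {
        "brick_volume_um3": config.brick.volume,
        "per_sample": per_sample,
        "t_test": {"t": tt.t, "df": tt.df, "p": tt.p},
    }


def _mw_dict(a, b) -> dict:
    mw = gs.mann_whitney(a, b)
    return {"U": mw.U, "U_other": mw.U_other, "p": mw.p, "method": mw.method}


def _summary_dict(values) -> dict:
    s = gs.summarize(values)
    return {
        "n": s.n, "mean": s.mean, "sem": s.sem, "median": s.median,
        "iqr": s.iqr, "normality_p": _nan_to_none(s.normality_p),
    }


def _nan_to_none(x: float):
    return None if (x != x) else float(x)


def _attr(records: Sequence[SpineRecord], name: str) -> np.ndarray:
    return np.array([getattr(r, name) for r in records], dtype=float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the report dict; files are written under ``config.out_dir``.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}"]

    # --- input stage ----------------------------------------------------
    try:
        if config.synth is not None:
            synth = SynthConfig(**{**config.synth.to_dict(), "seed": config.seed})
            records = generate_population(synth)
            log_lines.append(f"generated {len(records)} synthetic records")
        elif config.records_path is not None:
            records = read_records(config.records_path)
            log_lines.append(f"read {len(records)} records from {config.records_path}")
        else:
            records = records_from_traces(
                config.traces_dir, config.annotations_path, config.section_thickness
            )
            log_lines.append(f"measured {len(records)} records from traces")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("input", exc) from exc
    write_records(records, out / "records.csv")
    control, cltp = split_by_condition(records)
    if not control or not cltp:
        raise PipelineError(
            "input", ValueError("both conditions must be represented")
        )

    report: dict = {
        "seed": config.seed,
        "config": config.describe(),
        "n_spines": {
            "control": len(control),
            "cltp": len(cltp),
            "total": len(records),
        },
    }

    # --- census stage (synthetic scenes only) ---------------------------
    try:
        report["density"] = (
            _density_stage(config) if config.synth is not None else None
        )
    except Exception as exc:
        raise PipelineError("census", exc) from exc

    # --- group comparisons ----------------------------------------------
    try:
        ratios = gs.ratio_metrics(records)
        rc, rl = (
            ratios[ratios["condition"] == "control"],
            ratios[ratios["condition"] == "cltp"],
        )
        comparisons = {}
        for name, a, b in [
            ("volume_um3", _attr(control, "volume"), _attr(cltp, "volume")),
            ("psd_area_um2", _attr(control, "psd_area"), _attr(cltp, "psd_area")),
            (
                "psd_core_volume_um3",
                _attr(control, "psd_core_volume"),
                _attr(cltp, "psd_core_volume"),
            ),
            (
                "area_to_volume_ratio_per_um",
                rc["area_ratio_per_um"].to_numpy(),
                rl["area_ratio_per_um"].to_numpy(),
            ),
            (
                "core_to_volume_ratio",
                rc["core_ratio"].to_numpy(),
                rl["core_ratio"].to_numpy(),
            ),
        ]:
            comparisons[name] = {
                "mann_whitney": _mw_dict(a, b),
                "control": _summary_dict(a),
                "cltp": _summary_dict(b),
            }
        report["group_comparisons"] = comparisons
    except Exception as exc:
        raise PipelineError("group_comparisons", exc) from exc

    # --- regression / ANCOVA / global Spearman --------------------------
    try:
        regression = {}
        for param, (x_attr, y_attr) in PARAMETER_PAIRS.items():
            entry = {}
            for label, grp in (("control", control), ("cltp", cltp)):
                fit = gs.loglog_fit(_attr(grp, x_attr), _attr(grp, y_attr))
                rho, p = gs.spearman_global(_attr(grp, x_attr), _attr(grp, y_attr))
                entry[label] = {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "residual_ss": fit.residual_ss,
                    "n": fit.n,
                    "spearman_rho": rho,
                    "spearman_p": p,
                }
            anc = gs.ancova_compare(
                _attr(control, x_attr), _attr(control, y_attr),
                _attr(cltp, x_attr), _attr(cltp, y_attr),
            )
            entry["ancova"] = {
                "F_slope": anc.F_slope,
                "df_slope": list(anc.df_slope),
                "p_slope": anc.p_slope,
                "F_elev": anc.F_elev,
                "df_elev": list(anc.df_elev),
                "p_elev": anc.p_elev,
                "slopes_homogeneous": anc.slopes_homogeneous,
            }
            regression[param] = entry
        report["regression"] = regression
    except Exception as exc:
        raise PipelineError("regression", exc) from exc

    # --- local correlation profiles -------------------------------------
    try:
        localcorr = {}
        for pi, param in enumerate(PARAMETER_PAIRS):
            entry = {}
            profiles = {}
            for ci, (label, grp) in enumerate((("control", control), ("cltp", cltp))):
                params = LocalCorrParams(
                    window_sizes=config.localcorr.window_sizes,
                    n_boot=config.localcorr.n_boot,
                    subset_deficit=config.localcorr.subset_deficit,
                    alpha=config.localcorr.alpha,
                    seed=(config.seed + 1000 + pi * 10 + ci) % (2**31),
                    constant_policy=config.localcorr.constant_policy,
                )
                profile = local_profile(grp, parameter=param, params=params)
                profiles[label] = profile
                profile.table.to_csv(
                    out / f"profile_{param}_{label}.csv", index=False
                )
                bands = nonsignificant_regions(profile)
                entry[label] = {
                    "n_decoupled": bands.n_decoupled,
                    "n_total": bands.n_total,
                    "fraction": bands.fraction,
                    "bands": bands.bands,
                }
            try:
                chi = compare_decoupled_counts(profiles["control"], profiles["cltp"])
                entry["chi2"] = {
                    "statistic": chi.statistic,
                    "p": chi.p,
                    "table": chi.table.astype(int).tolist(),
                }
            except ValueError:
                # all spines on one side of the threshold in both groups
                # (e.g. the tightly coupled area-core internal control)
                entry["chi2"] = None
            localcorr[param] = entry
            log_lines.append(
                f"localcorr {param}: control decoupled "
                f"{entry['control']['n_decoupled']}/{entry['control']['n_total']}, "
                f"cltp {entry['cltp']['n_decoupled']}/{entry['cltp']['n_total']}"
            )
        report["local_correlation"] = localcorr
        hist = gs.volume_histogram(records)
        hist.to_csv(out / "volume_histogram.csv", index=False)
    except Exception as exc:
        raise PipelineError("local_correlation", exc) from exc

    # --- SER-stratified statistics --------------------------------------
    try:
        strata = {
            "control_no_ser": [r for r in control if not r.has_ser],
            "control_ser": [r for r in control if r.has_ser],
            "cltp_no_ser": [r for r in cltp if not r.has_ser],
            "cltp_ser": [r for r in cltp if r.has_ser],
        }
        ser_report: dict = {
            "n": {k: len(v) for k, v in strata.items()},
            "kruskal_dunn": {},
            "relative_change": {},
        }
        group_names = list(strata)
        for attr_name in ("volume", "psd_area", "psd_core_volume"):
            kd = gs.kruskal_dunn([_attr(v, attr_name) for v in strata.values()])
            ser_report["kruskal_dunn"][attr_name] = {
                "H": kd.H,
                "p": kd.p,
                "groups": group_names,
                "dunn": [
                    {
                        "pair": [group_names[c.i], group_names[c.j]],
                        "z": c.z,
                        "p_adjusted": c.p_adjusted,
                    }
                    for c in kd.comparisons
                ],
            }
            rel = gs.relative_change(cltp, control, attribute=attr_name)
            med = rel.per_spine.groupby("stratum")["relative_value"].median()
            ser_report["relative_change"][attr_name] = {
                "U": rel.U,
                "p": rel.p,
                "median_ser": float(med.get("ser", float("nan"))),
                "median_no_ser": float(med.get("no_ser", float("nan"))),
            }
        report["ser"] = ser_report
    except Exception as exc:
        raise PipelineError("ser", exc) from exc

    # --- perforation × SER ----------------------------------------------
    try:
        perf_table = {}
        perf_wo_ser = {}
        for label, grp in (("control", control), ("cltp", cltp)):
            perf_table[label] = {
                "ser_perforated": sum(r.has_ser and r.perforated for r in grp),
                "ser_intact": sum(r.has_ser and not r.perforated for r in grp),
                "no_ser_perforated": sum(
                    (not r.has_ser) and r.perforated for r in grp
                ),
                "no_ser_intact": sum(
                    (not r.has_ser) and not r.perforated for r in grp
                ),
            }
            perf_wo_ser[label] = perf_table[label]["no_ser_perforated"]
        report["perforation"] = {
            "table": perf_table,
            "perforated_without_ser": perf_wo_ser,
        }
    except Exception as exc:
        raise PipelineError("perforation", exc) from exc

    validate_report(report)
    dump_json(report, out / "report.json")
    band_summary = {
        param: {
            label: report["local_correlation"][param][label]
            for label in ("control", "cltp")
        }
        for param in PARAMETER_PAIRS
    }
    dump_json({"seed": config.seed, "bands": band_summary}, out / "bands.json")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
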