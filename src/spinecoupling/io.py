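"""Reading and writing the pipeline's table and config formats.

Spine records travel as a CSV with an explicit unit-bearing header; trace
stacks use the JSON layout defined in :mod:`spinecoupling.morphometry`;
pipeline configuration is a YAML/JSON mapping.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .records import CONDITIONS, SpineRecord

RECORD_COLUMNS = [
    "id",
    "sample_id",
    "condition",
    "volume_um3",
    "psd_area_um2",
    "psd_core_volume_um3",
    "has_ser",
    "has_spine_apparatus",
    "perforated",
    "n_synapses",
]

_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {column}={value!r}")


def read_records(path: str | Path) -> list[SpineRecord]:
    """Load and validate a spine-record table.

    The CSV must carry the full header (columns with units); every record
    invariant is enforced with the offending row number in the error.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        d = dict(zip(frame.columns, row))
        if d["condition"] not in CONDITIONS:
            raise ValueError(
                f"row {i}: unknown condition {d['condition']!r} "
                f"(expected one of {CONDITIONS})"
            )
        try:
            rec = SpineRecord(
                id=str(d["id"]),
                sample_id=str(d["sample_id"]),
                condition=d["condition"],
                volume=float(d["volume_um3"]),
                psd_area=float(d["psd_area_um2"]),
                psd_core_volume=float(d["psd_core_volume_um3"]),
                has_ser=_parse_bool(d["has_ser"], i, "has_ser"),
                has_spine_apparatus=_parse_bool(
                    d["has_spine_apparatus"], i, "has_spine_apparatus"
                ),
                perforated=_parse_bool(d["perforated"], i, "perforated"),
                n_synapses=int(d["n_synapses"]),
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_records(records: Iterable[SpineRecord], path: str | Path) -> None:
    """Write records as the canonical CSV (round-trips with read_records)."""
    rows = [
        {
            "id": r.id,
            "sample_id": r.sample_id,
            "condition": r.condition,
            "volume_um3": repr(r.volume),
            "psd_area_um2": repr(r.psd_area),
            "psd_core_volume_um3": repr(r.psd_core_volume),
            "has_ser": r.has_ser,
            "has_spine_apparatus": r.has_spine_apparatus,
            "perforated": r.perforated,
            "n_synapses": r.n_synapses,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_scene_csv(path: str | Path):
    """Load synapse reference points (columns x_um, y_um, z_um) as (n, 3)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("x_um", "y_um", "z_um") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def load_config_mapping(path: str | Path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, stable float repr)."""
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
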