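"""Serial-section contour morphometry.

Objects traced on aligned serial EM sections are represented as a
:class:`TraceStack`: closed polygons (spine or PSD-core outlines) and open
polylines (PSD profiles drawn along the active zone) on individual sections,
with a single section thickness per stack.

Measurement semantics follow the classic serial-reconstruction workflow:

* volume is a Cavalieri sum — planar contour area times section thickness,
  summed over sections, with no interpolation between sections;
* PSD surface area combines the two ways a PSD can intersect a section:
  profiles perpendicular to the cutting plane are traced as open lines and
  contribute (length × thickness), PSDs lying parallel to the plane are
  outlined as closed contours and contribute their planar area directly;
* true section thickness is estimated with the cylindrical-diameters method:
  a cylindrical organelle of in-plane diameter ``d`` crossing ``s``
  consecutive sections gives a per-object estimate ``d / s``.

All coordinates are in μm; the section plane is (x, y) and the z position of
section ``i`` is ``i × thickness`` (origin arbitrary per stack).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

TRACE_KINDS = ("closed_polygon", "open_polyline")
TRACE_LABELS = ("spine", "psd_core")


@dataclass(frozen=True)
class Trace:
    """One traced contour on one section."""

    section_index: int
    kind: str  # "closed_polygon" | "open_polyline"
    label: str  # "spine" | "psd_core"
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.section_index < 0:
            raise ValueError(f"section_index must be >= 0, got {self.section_index}")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        if self.label not in TRACE_LABELS:
            raise ValueError(f"label must be one of {TRACE_LABELS}, got {self.label!r}")
        n = len(self.vertices)
        if self.kind == "closed_polygon" and n < 3:
            raise ValueError(f"closed_polygon needs >= 3 vertices, got {n}")
        if self.kind == "open_polyline" and n < 2:
            raise ValueError(f"open_polyline needs >= 2 vertices, got {n}")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )


@dataclass
class TraceStack:
    """All traces of one object across sections, plus the section thickness."""

    object_id: str
    section_thickness: float
    traces: list[Trace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.section_thickness > 0:
            raise ValueError(
                f"section_thickness must be > 0, got {self.section_thickness}"
            )

    # --- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "object_id": self.object_id,
            "section_thickness": self.section_thickness,
            "traces": [
                {
                    "section_index": t.section_index,
                    "kind": t.kind,
                    "label": t.label,
                    "vertices": [[x, y] for x, y in t.vertices],
                }
                for t in self.traces
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraceStack":
        return cls(
            object_id=d["object_id"],
            section_thickness=d["section_thickness"],
            traces=[
                Trace(
                    section_index=t["section_index"],
                    kind=t["kind"],
                    label=t["label"],
                    vertices=tuple((x, y) for x, y in t["vertices"]),
                )
                for t in d["traces"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TraceStack":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CylinderObservation:
    """In-plane diameter of a cylindrical organelle and its section span."""

    diameter: float
    span: int

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.span < 1:
            raise ValueError(f"span must be >= 1, got {self.span}")


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Planar area (μm²) of a closed, non-self-intersecting polygon.

    The result is non-negative and independent of vertex orientation and of
    the starting vertex.

    Raises
    ------
    ValueError
        For fewer than 3 vertices or a self-intersecting outline.
    """
    pts = [(float(x), float(y)) for x, y in vertices]
    if len(pts) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(pts)}")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError(
            f"self-intersecting or degenerate polygon (shapely: "
            f"{poly.is_valid=}, first vertex {pts[0]})"
        )
    return float(poly.area)


def polyline_length(vertices: Sequence[Sequence[float]]) -> float:
    """Length (μm) of an open polyline."""
    pts = [(float(x), float(y)) for x, y in vertices]
    if len(pts) < 2:
        raise ValueError(f"polyline needs >= 2 vertices, got {len(pts)}")
    return float(LineString(pts).length)


def measure_volume(stack: TraceStack, label: str = "spine") -> float:
    """Cavalieri volume (μm³) of the closed contours carrying ``label``.

    Sums, over sections, the total polygon area on that section times the
    section thickness. Multiple polygons on one section are summed (e.g. a
    branched profile). Open polylines under the requested label are ignored
    with a warning — they carry no area.
    """
    closed = [t for t in stack.traces if t.label == label and t.kind == "closed_polygon"]
    open_same_label = [
        t for t in stack.traces if t.label == label and t.kind == "open_polyline"
    ]
    if open_same_label:
        warnings.warn(
            f"{len(open_same_label)} open polyline(s) with label {label!r} "
            "ignored by measure_volume",
            stacklevel=2,
        )
    if not closed:
        raise ValueError(f"no closed_polygon traces with label {label!r} in stack")
    return sum(polygon_area(t.vertices) for t in closed) * stack.section_thickness


def measure_psd_area(stack: TraceStack) -> float:
    """PSD surface area (μm²) from psd_core traces.

    Open polylines (PSD perpendicular to the section) contribute
    ``length × thickness``; closed contours (PSD parallel to the section)
    contribute their planar area. Both kinds may coexist in one stack and
    are summed.
    """
    psd = [t for t in stack.traces if t.label == "psd_core"]
    if not psd:
        raise ValueError("no psd_core traces in stack")
    area = 0.0
    for t in psd:
        if t.kind == "open_polyline":
            area += polyline_length(t.vertices) * stack.section_thickness
        else:
            area += polygon_area(t.vertices)
    return area


def estimate_section_thickness(
    observations: Iterable[CylinderObservation],
) -> tuple[float, np.ndarray]:
    """Mean section thickness (μm) from cylindrical-diameter observations.

    Each observation yields an estimate ``diameter / span``; the arithmetic
    mean is returned together with the per-observation estimates for QC.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("estimate_section_thickness requires >= 1 observation")
    per_obs = np.array([o.diameter / o.span for o in obs], dtype=float)
    return float(per_obs.mean()), per_obs
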