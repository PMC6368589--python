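"""Per-spine morphometry records.

A :class:`SpineRecord` holds the 3D-EM measurements of one dendritic spine —
spine volume, PSD surface area and PSD-core volume — together with its
organelle annotations (smooth endoplasmic reticulum, spine apparatus,
PSD perforation) and the experimental condition of the slice it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

CONDITIONS = ("control", "cltp")


@dataclass(frozen=True)
class SpineRecord:
    """One dendritic spine's morphometry and annotations.

    Parameters
    ----------
    id : str
        Unique spine identifier.
    sample_id : str
        Identifier of the slice/sample the spine belongs to.
    condition : {"control", "cltp"}
        Treatment group of the sample.
    volume : float
        Spine volume in μm³ (> 0).
    psd_area : float
        PSD surface area in μm², summed over synapses of the spine (> 0).
    psd_core_volume : float
        PSD-core volume in μm³, summed over synapses (> 0).
    has_ser : bool
        Smooth endoplasmic reticulum tubule enters the spine neck.
    has_spine_apparatus : bool
        Stacked SER (spine apparatus) present; implies ``has_ser``.
    perforated : bool
        PSD shows a perforation.
    n_synapses : int
        Number of synapses on the spine (≥ 1; > 1 for multisynaptic spines).
    """

    id: str
    sample_id: str
    condition: str
    volume: float
    psd_area: float
    psd_core_volume: float
    has_ser: bool = False
    has_spine_apparatus: bool = False
    perforated: bool = False
    n_synapses: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        for name in ("volume", "psd_area", "psd_core_volume"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.has_spine_apparatus and not self.has_ser:
            raise ValueError(
                "has_spine_apparatus implies has_ser (a spine apparatus is stacked SER)"
            )
        if self.n_synapses < 1:
            raise ValueError(f"n_synapses must be >= 1, got {self.n_synapses}")

    def with_(self, **changes) -> "SpineRecord":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


def merge_multisynaptic(records: Sequence[SpineRecord]) -> SpineRecord:
    """Merge the per-synapse records of one multisynaptic spine.

    PSD areas and PSD-core volumes are summed across synapses, annotation
    flags are OR-combined and ``n_synapses`` is set to the number of merged
    records. All records must agree on the spine itself (id, sample,
    condition, volume).

    Raises
    ------
    ValueError
        If no records are given or the records disagree on spine identity
        or spine volume.
    """
    records = list(records)
    if not records:
        raise ValueError("merge_multisynaptic requires at least one record")
    first = records[0]
    if len(records) == 1:
        return first
    for rec in records[1:]:
        if (rec.id, rec.sample_id, rec.condition) != (
            first.id,
            first.sample_id,
            first.condition,
        ):
            raise ValueError(
                f"records to merge must share spine identity; {rec.id!r} vs {first.id!r}"
            )
        if rec.volume != first.volume:
            raise ValueError(
                f"conflicting spine volumes for spine {first.id!r}: "
                f"{rec.volume} vs {first.volume}"
            )
    return first.with_(
        psd_area=sum(r.psd_area for r in records),
        psd_core_volume=sum(r.psd_core_volume for r in records),
        has_ser=any(r.has_ser for r in records),
        has_spine_apparatus=any(r.has_spine_apparatus for r in records),
        perforated=any(r.perforated for r in records),
        n_synapses=sum(r.n_synapses for r in records),
    )


def split_by_condition(
    records: Iterable[SpineRecord],
) -> tuple[list[SpineRecord], list[SpineRecord]]:
    """Split records into (control, cltp) lists, preserving order."""
    control = [r for r in records if r.condition == "control"]
    cltp = [r for r in records if r.condition == "cltp"]
    return control, cltp
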