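"""Data model and geometry arithmetic for e-cigarette atomizer coils and wicks.

An atomizer pairs a resistive heating coil (a helical wire, possibly two
wires in parallel or two independently wrapped coils) with a porous wick
that supplies e-liquid.  The quantities that feed the emission score are
the total heated wire length L (mm), the total wick outer surface area
SA (mm²) available to absorb heat, and the number of wraps n per coil.
Units are fixed to mm / mm² / W at this boundary; callers convert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "CoilStyle",
    "Orientation",
    "WickKind",
    "Aggregation",
    "WickSpec",
    "CoilSpec",
    "AtomizerDevice",
    "EffectiveGeometry",
    "wick_outer_surface_area",
    "effective_geometry",
    "helix_wire_length",
    "read_devices",
    "write_devices",
    "DEVICE_COLUMNS",
]


class CoilStyle(str, Enum):
    SINGLE = "single"
    PARALLEL = "parallel"
    DUAL = "dual"


class Orientation(str, Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


class WickKind(str, Enum):
    CYLINDER = "cylinder"
    MEASURED = "measured"


class Aggregation(str, Enum):
    """How per-wire measurements combine into the score inputs.

    ``SUM_WIRES`` (default): the recorded wire length is per wire and total
    coil length is ``wire_length_per_wire * wire_count``; wick areas sum over
    physical wicks; wraps stay per-coil.  This makes the model-1 score of a
    dual build equal to the score of one of its identical halves.

    ``PER_COIL``: the recorded wire length is already the total for the
    build and is used as-is.  Covers device tables that tabulate total
    rather than per-wire length.
    """

    SUM_WIRES = "sum_wires"
    PER_COIL = "per_coil"


def _require_positive(name: str, value: float) -> None:
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class WickSpec:
    """Wick geometry: an idealized cylinder or a directly measured area.

    ``outer_surface_area`` is per wick; totals multiply by ``wick_count``
    (a dual build has two physical wicks).  For a cylinder the lateral
    area pi*d*l is used; end caps abut the tank/chimney and are excluded.
    """

    geometry_kind: WickKind
    diameter: Optional[float] = None
    length: Optional[float] = None
    outer_surface_area: Optional[float] = None
    wick_count: int = 1

    def __post_init__(self) -> None:
        kind = WickKind(self.geometry_kind)
        object.__setattr__(self, "geometry_kind", kind)
        if not isinstance(self.wick_count, int) or self.wick_count < 1:
            raise ValueError(f"wick_count must be a positive integer, got {self.wick_count!r}")
        if kind is WickKind.CYLINDER:
            _require_positive("wick diameter", self.diameter)
            _require_positive("wick length", self.length)
        else:
            _require_positive("wick outer_surface_area", self.outer_surface_area)

    @property
    def area_per_wick(self) -> float:
        if self.geometry_kind is WickKind.CYLINDER:
            return math.pi * self.diameter * self.length
        return float(self.outer_surface_area)


@dataclass(frozen=True)
class CoilSpec:
    """Heating-coil build: style, orientation and per-wire wrap geometry."""

    style: CoilStyle
    orientation: Orientation
    wire_length_per_wire: float
    wraps: int
    wire_count: Optional[int] = None
    wire_material: str = ""
    wire_gauge: Optional[float] = None

    def __post_init__(self) -> None:
        style = CoilStyle(self.style)
        object.__setattr__(self, "style", style)
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        _require_positive("wire_length_per_wire", self.wire_length_per_wire)
        if not isinstance(self.wraps, int) or self.wraps < 1:
            raise ValueError(f"wraps must be a positive integer, got {self.wraps!r}")
        expected = 1 if style is CoilStyle.SINGLE else 2
        if self.wire_count is None:
            object.__setattr__(self, "wire_count", expected)
        elif self.wire_count != expected:
            raise ValueError(
                f"{style.value} coil requires wire_count = {expected}, got {self.wire_count}"
            )


@dataclass(frozen=True)
class AtomizerDevice:
    """One atomizer: coil + wick + manufacturer-recommended maximum power."""

    device_id: str
    coil: CoilSpec
    wick: WickSpec
    power: Optional[float] = None
    resistance: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.device_id:
            raise ValueError("device_id must be non-empty")
        if self.power is not None:
            _require_positive("power", self.power)
        if self.coil.style is CoilStyle.DUAL and self.wick.wick_count != self.coil.wire_count:
            raise ValueError(
                "dual coil builds wrap each wire with its own wick: "
                f"wick_count must equal wire_count ({self.coil.wire_count}), "
                f"got {self.wick.wick_count}"
            )


class EffectiveGeometry(NamedTuple):
    total_coil_length: float  # mm
    total_wick_area: float  # mm^2
    wraps: int


def wick_outer_surface_area(wick: WickSpec) -> float:
    """Total wick outer surface area in mm², summed over physical wicks.

    Measured areas are taken per wick; cylinders contribute the lateral
    area pi*d*l each.
    """
    return wick.area_per_wick * wick.wick_count


def effective_geometry(
    device: AtomizerDevice, aggregation: Aggregation = Aggregation.SUM_WIRES
) -> EffectiveGeometry:
    """Aggregate a build into (total coil length mm, total wick area mm², wraps).

    Wraps are per coil, never multiplied by wire count: duplicating an
    identical coil+wick unit doubles L and SA but leaves wraps — and hence
    the model-1 score — unchanged.
    """
    aggregation = Aggregation(aggregation)
    if aggregation is Aggregation.SUM_WIRES:
        length = device.coil.wire_length_per_wire * device.coil.wire_count
    else:
        length = device.coil.wire_length_per_wire
    return EffectiveGeometry(
        total_coil_length=length,
        total_wick_area=wick_outer_surface_area(device.wick),
        wraps=device.coil.wraps,
    )


def helix_wire_length(core_diameter: float, wire_diameter: float, wraps: int) -> float:
    """Wire length of a tight helix of negligible pitch: wraps * pi * (d_core + d_wire).

    Convenience for users who measured the wrap geometry instead of
    unspooling the wire.
    """
    _require_positive("core_diameter", core_diameter)
    _require_positive("wire_diameter", wire_diameter)
    if not isinstance(wraps, int) or wraps < 1:
        raise ValueError(f"wraps must be a positive integer, got {wraps!r}")
    return wraps * math.pi * (core_diameter + wire_diameter)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

DEVICE_COLUMNS = [
    "device_id",
    "coil_style",
    "orientation",
    "wire_length_mm",
    "wire_count",
    "wraps",
    "wick_kind",
    "wick_diameter_mm",
    "wick_length_mm",
    "wick_area_mm2",
    "wick_count",
    "power_w",
    "resistance_ohm",
]


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_devices(path) -> list[AtomizerDevice]:
    """Read a device table (CSV) into validated :class:`AtomizerDevice` records.

    Blank cells are permitted only where the wick geometry kind makes them
    inapplicable; anything else is rejected with the offending row number.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DEVICE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"devices file {path} is missing columns: {missing}")
    devices: list[AtomizerDevice] = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            kind = WickKind(str(row["wick_kind"]))
            wick = WickSpec(
                geometry_kind=kind,
                diameter=_opt(row["wick_diameter_mm"]),
                length=_opt(row["wick_length_mm"]),
                outer_surface_area=_opt(row["wick_area_mm2"]),
                wick_count=int(row["wick_count"]),
            )
            coil = CoilSpec(
                style=CoilStyle(str(row["coil_style"])),
                orientation=Orientation(str(row["orientation"])),
                wire_length_per_wire=float(row["wire_length_mm"]),
                wraps=int(row["wraps"]),
                wire_count=None if pd.isna(row["wire_count"]) else int(row["wire_count"]),
            )
            devices.append(
                AtomizerDevice(
                    device_id=str(row["device_id"]),
                    coil=coil,
                    wick=wick,
                    power=_opt(row["power_w"]),
                    resistance=_opt(row["resistance_ohm"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    ids = [d.device_id for d in devices]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate device_id values in {path}: {sorted(dupes)}")
    return devices


def write_devices(devices: Sequence[AtomizerDevice], path) -> None:
    rows = []
    for d in devices:
        rows.append(
            {
                "device_id": d.device_id,
                "coil_style": d.coil.style.value,
                "orientation": d.coil.orientation.value,
                "wire_length_mm": d.coil.wire_length_per_wire,
                "wire_count": d.coil.wire_count,
                "wraps": d.coil.wraps,
                "wick_kind": d.wick.geometry_kind.value,
                "wick_diameter_mm": d.wick.diameter,
                "wick_length_mm": d.wick.length,
                "wick_area_mm2": d.wick.outer_surface_area,
                "wick_count": d.wick.wick_count,
                "power_w": d.power,
                "resistance_ohm": d.resistance,
            }
        )
    # %.17g round-trips IEEE doubles exactly through text
    pd.DataFrame(rows, columns=DEVICE_COLUMNS).to_csv(path, index=False, float_format="%.17g")
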