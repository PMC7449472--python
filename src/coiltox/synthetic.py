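"""Synthetic atomizer fleets and emission sessions for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:

* a fleet of devices spanning single/parallel/dual coil styles and both
  orientations, with geometry drawn uniformly from configurable ranges;
* per-session total carbonyls following y = a_true * exp(b_true * score)
  micrograms per gram of e-liquid, where score is the geometric predictor
  L/(SA*n) of the device, with multiplicative lognormal noise — so the
  absolute spread of replicates grows with the device mean, as observed
  for high-emitting devices;
* occasional gross high-side outliers (a fixed multiplier), emulating
  burnt coils and faulty builds;
* the session total split across the six carbonyls with fixed proportions
  (formaldehyde/acetaldehyde dominant); the split never affects the
  totals-based analysis downstream.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from coiltox.device_model import (
    Aggregation,
    AtomizerDevice,
    CoilSpec,
    CoilStyle,
    Orientation,
    WickKind,
    WickSpec,
    effective_geometry,
    write_devices,
)
from coiltox.emissions import ANALYTES, SessionRecord, write_sessions
from coiltox.scoring import model1_score

__all__ = [
    "SyntheticConfig",
    "SessionTruth",
    "FleetTruth",
    "ANALYTE_FRACTIONS",
    "generate_fleet",
    "generate_sessions",
    "make_benchmark",
    "read_truth",
]

#: fixed six-analyte split of each session total (formaldehyde and
#: acetaldehyde dominate carbonyl panels from PG/GL degradation)
ANALYTE_FRACTIONS = {
    "formaldehyde": 0.30,
    "acetaldehyde": 0.40,
    "acetone": 0.08,
    "propanal": 0.12,
    "butyraldehyde": 0.05,
    "benzaldehyde": 0.05,
}

_STYLE_KEYS = [
    (style, orientation)
    for style in (CoilStyle.SINGLE, CoilStyle.PARALLEL, CoilStyle.DUAL)
    for orientation in (Orientation.HORIZONTAL, Orientation.VERTICAL)
]


def _default_style_mix() -> dict:
    return {key: 1.0 / len(_STYLE_KEYS) for key in _STYLE_KEYS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic fleet.

    Defaults mirror the experimental design being emulated: 12 devices
    tested in (at least) quadruplicate, emission amplitude a_true = 5 µg/g
    at score zero, rate b_true = 8 per score unit, 20% multiplicative noise
    (log-scale SD 0.2), occasional ×20 high-side outliers, and geometry
    ranges bracketing a real rebuildable dual build (98 mm wire, 8 wraps,
    65 W) plus common commercial values.
    """

    n_devices: int = 12
    replicates_per_device: int = 4
    a_true: float = 5.0  # ug per g e-liquid at score 0
    b_true: float = 8.0  # per score unit (score is mm^-1)
    noise_sigma: float = 0.2  # log-scale SD of multiplicative noise
    outlier_rate: float = 0.05  # probability per session
    outlier_multiplier: float = 20.0
    wire_length_mm: tuple[float, float] = (40.0, 120.0)
    wraps: tuple[int, int] = (4, 10)
    wick_diameter_mm: tuple[float, float] = (2.0, 4.0)
    wick_length_mm: tuple[float, float] = (8.0, 15.0)
    power_w: tuple[float, float] = (10.0, 80.0)
    eliquid_g: tuple[float, float] = (0.5, 1.5)
    style_mix: dict = field(default_factory=_default_style_mix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_devices < 0:
            raise ValueError("n_devices must be >= 0")
        if self.replicates_per_device < 3:
            raise ValueError("replicates_per_device must be >= 3 (triplicate minimum)")
        for name in ("a_true", "b_true", "outlier_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outlier_multiplier <= 1:
            raise ValueError("outlier_multiplier must be > 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be in [0, 1]")
        for name in (
            "wire_length_mm",
            "wraps",
            "wick_diameter_mm",
            "wick_length_mm",
            "power_w",
            "eliquid_g",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"range {name} must satisfy 0 < min <= max, got {lo, hi}")
        mix = {}
        for key, proportion in self.style_mix.items():
            style, orientation = key
            mix[(CoilStyle(style), Orientation(orientation))] = float(proportion)
        if any(p < 0 for p in mix.values()):
            raise ValueError("style_mix proportions must be >= 0")
        total = sum(mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"style_mix proportions must sum to 1, got {total}")
        object.__setattr__(self, "style_mix", mix)


@dataclass(frozen=True)
class SessionTruth:
    """Ground truth for one generated session."""

    device_id: str
    replicate_id: str
    true_score: float
    true_total_per_g: float  # noiseless a*exp(b*score), ug/g
    is_outlier: bool


@dataclass(frozen=True)
class FleetTruth:
    """Ground truth for a generated benchmark."""

    a_true: float
    b_true: float
    device_scores: dict[str, float]
    sessions: tuple[SessionTruth, ...]

    @property
    def outlier_sessions(self) -> list[tuple[str, str]]:
        return [(t.device_id, t.replicate_id) for t in self.sessions if t.is_outlier]


def generate_fleet(config: SyntheticConfig) -> list[AtomizerDevice]:
    """Sample a fleet of devices; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    keys = list(config.style_mix.keys())
    probabilities = np.array([config.style_mix[k] for k in keys])
    devices: list[AtomizerDevice] = []
    for index in range(config.n_devices):
        style, orientation = keys[rng.choice(len(keys), p=probabilities)]
        wire_length = rng.uniform(*config.wire_length_mm)
        wraps = int(rng.integers(config.wraps[0], config.wraps[1] + 1))
        diameter = rng.uniform(*config.wick_diameter_mm)
        length = rng.uniform(*config.wick_length_mm)
        power = rng.uniform(*config.power_w)
        wick_count = 2 if style is CoilStyle.DUAL else 1
        devices.append(
            AtomizerDevice(
                device_id=f"SYN{index + 1:02d}",
                coil=CoilSpec(
                    style=style,
                    orientation=orientation,
                    wire_length_per_wire=wire_length,
                    wraps=wraps,
                ),
                wick=WickSpec(
                    geometry_kind=WickKind.CYLINDER,
                    diameter=diameter,
                    length=length,
                    wick_count=wick_count,
                ),
                power=power,
            )
        )
    return devices


def generate_sessions(
    fleet: Sequence[AtomizerDevice], config: SyntheticConfig
) -> tuple[list[SessionRecord], FleetTruth]:
    """Generate replicate sessions for every device plus the ground truth.

    The random stream draws noise, outlier and e-liquid variates for every
    session regardless of configuration, so runs that differ only in
    noise_sigma or outlier_rate stay draw-for-draw comparable at the same
    seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    sessions: list[SessionRecord] = []
    truths: list[SessionTruth] = []
    device_scores: dict[str, float] = {}
    for device in fleet:
        length, area, wraps = effective_geometry(device, Aggregation.SUM_WIRES)
        score = model1_score(length, area, wraps)
        device_scores[device.device_id] = score
        true_total_per_g = config.a_true * math.exp(config.b_true * score)
        for replicate in range(config.replicates_per_device):
            epsilon = rng.normal(0.0, 1.0) * config.noise_sigma
            outlier_draw = rng.uniform()
            eliquid = rng.uniform(*config.eliquid_g)
            total_per_g = true_total_per_g * math.exp(epsilon)
            is_outlier = outlier_draw < config.outlier_rate
            if is_outlier:
                total_per_g *= config.outlier_multiplier
            total = total_per_g * eliquid
            amounts = {a: total * ANALYTE_FRACTIONS[a] for a in ANALYTES}
            replicate_id = f"r{replicate + 1}"
            sessions.append(
                SessionRecord(
                    device_id=device.device_id,
                    replicate_id=replicate_id,
                    analyte_amounts=amounts,
                    eliquid_consumed=eliquid,
                    unit="ug",
                )
            )
            truths.append(
                SessionTruth(
                    device_id=device.device_id,
                    replicate_id=replicate_id,
                    true_score=score,
                    true_total_per_g=true_total_per_g,
                    is_outlier=is_outlier,
                )
            )
    truth = FleetTruth(
        a_true=config.a_true,
        b_true=config.b_true,
        device_scores=device_scores,
        sessions=tuple(truths),
    )
    return sessions, truth


def make_benchmark(config: SyntheticConfig, outdir) -> tuple[Path, Path, Path]:
    """Write devices.csv, sessions.csv and truth.csv for a synthetic study.

    The truth file records, per session, the generating parameters
    (a_true, b_true), the device's true score and whether a gross outlier
    was injected — everything a test needs to assert recovery.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fleet = generate_fleet(config)
    sessions, truth = generate_sessions(fleet, config)
    devices_path = outdir / "devices.csv"
    sessions_path = outdir / "sessions.csv"
    truth_path = outdir / "truth.csv"
    write_devices(fleet, devices_path)
    write_sessions(sessions, sessions_path)
    pd.DataFrame(
        [
            {
                "device_id": t.device_id,
                "replicate_id": t.replicate_id,
                "a_true": truth.a_true,
                "b_true": truth.b_true,
                "true_score": t.true_score,
                "true_total_per_g": t.true_total_per_g,
                "is_outlier": int(t.is_outlier),
            }
            for t in truth.sessions
        ]
    ).to_csv(truth_path, index=False, float_format="%.17g")
    return devices_path, sessions_path, truth_path


def read_truth(path) -> FleetTruth:
    """Read a truth.csv back into a :class:`FleetTruth`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    sessions = tuple(
        SessionTruth(
            device_id=str(row.device_id),
            replicate_id=str(row.replicate_id),
            true_score=float(row.true_score),
            true_total_per_g=float(row.true_total_per_g),
            is_outlier=bool(row.is_outlier),
        )
        for row in frame.itertuples()
    )
    scores = {t.device_id: t.true_score for t in sessions}
    return FleetTruth(
        a_true=float(frame["a_true"].iloc[0]),
        b_true=float(frame["b_true"].iloc[0]),
        device_scores=scores,
        sessions=sessions,
    )
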