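"""Per-device emission summaries from replicate carbonyl measurements.

A collection session yields the amounts of six carbonyl degradation
products (formaldehyde, acetaldehyde, acetone, propanal, butyraldehyde,
benzaldehyde) trapped over a fixed puffing run, plus the mass of e-liquid
consumed (tank mass before minus after).  The analysis quantity is the
TOTAL of the six carbonyls normalized per gram of e-liquid consumed.
Replicates per device are screened with a sequential two-sided Grubbs
outlier test before taking the mean and standard error; gross high-side
outliers correspond to burnt coils or faulty builds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANALYTES",
    "MOLAR_MASS_G_PER_MOL",
    "SessionRecord",
    "DeviceEmissionSummary",
    "total_carbonyls",
    "normalize_per_eliquid",
    "grubbs_statistic",
    "grubbs_critical_value",
    "screen_outliers",
    "summarize_device",
    "summarize_fleet",
    "read_sessions",
    "write_sessions",
    "SESSION_COLUMNS",
]

ANALYTES = (
    "formaldehyde",
    "acetaldehyde",
    "acetone",
    "propanal",
    "butyraldehyde",
    "benzaldehyde",
)

#: molar masses (g/mol) for nmol <-> ug conversion of the six-carbonyl panel
MOLAR_MASS_G_PER_MOL = {
    "formaldehyde": 30.026,
    "acetaldehyde": 44.053,
    "acetone": 58.080,
    "propanal": 58.080,
    "butyraldehyde": 72.107,
    "benzaldehyde": 106.124,
}

_VALID_UNITS = ("ug", "nmol")


@dataclass(frozen=True)
class SessionRecord:
    """One aerosol collection run for one device.

    ``analyte_amounts`` are collection totals over the session in the unit
    given by ``unit`` ('ug' micrograms or 'nmol' nanomoles);
    ``eliquid_consumed`` is grams of e-liquid aerosolized.
    """

    device_id: str
    replicate_id: str
    analyte_amounts: Mapping[str, float]
    eliquid_consumed: float
    unit: str = "ug"

    def __post_init__(self) -> None:
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")
        for analyte in ANALYTES:
            if analyte not in self.analyte_amounts or self.analyte_amounts[analyte] is None:
                raise ValueError(
                    f"session {self.device_id}/{self.replicate_id}: missing analyte "
                    f"'{analyte}' (a missing measurement is an error, not zero)"
                )
            value = self.analyte_amounts[analyte]
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"session {self.device_id}/{self.replicate_id}: analyte '{analyte}' "
                    f"amount must be finite and >= 0, got {value!r}"
                )
        if not np.isfinite(self.eliquid_consumed) or self.eliquid_consumed <= 0:
            raise ValueError(
                f"session {self.device_id}/{self.replicate_id}: eliquid_consumed must "
                f"be > 0 g, got {self.eliquid_consumed!r}"
            )


@dataclass(frozen=True)
class DeviceEmissionSummary:
    """Mean normalized total carbonyls (µg per g e-liquid) for one device."""

    device_id: str
    mean_emission: float
    standard_error: float
    n_used: int
    n_outliers_removed: int
    screening_stopped: bool = False  # True if screening hit the n >= 2 floor
    removed_replicates: tuple = ()  # replicate_ids screened out


def total_carbonyls(session: SessionRecord) -> float:
    """Sum of the six carbonyl amounts, in micrograms.

    Amounts declared in nmol are converted with the fixed molar-mass table.
    """
    if session.unit == "ug":
        return float(sum(session.analyte_amounts[a] for a in ANALYTES))
    return float(
        sum(session.analyte_amounts[a] * MOLAR_MASS_G_PER_MOL[a] / 1000.0 for a in ANALYTES)
    )


def normalize_per_eliquid(session: SessionRecord) -> float:
    """Total carbonyls (µg) per gram of e-liquid consumed."""
    return total_carbonyls(session) / session.eliquid_consumed


def grubbs_statistic(values: Sequence[float]) -> tuple[float, int]:
    """Grubbs statistic G = max_i |y_i - mean| / s and the extreme index.

    ``s`` is the sample standard deviation (n-1 denominator).  Zero-variance
    samples return G = 0 by convention.  When two values tie in absolute
    deviation the larger one is reported (gross failures are high-side).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"Grubbs test requires at least 3 values, got {arr.size}")
    s = arr.std(ddof=1)
    # spread at rounding-noise level counts as zero variance
    if s <= 1e-12 * max(1.0, float(np.abs(arr).max())):
        return 0.0, 0
    deviations = np.abs(arr - arr.mean())
    max_dev = deviations.max()
    candidates = np.flatnonzero(deviations == max_dev)
    index = int(candidates[np.argmax(arr[candidates])])
    return float(max_dev / s), index


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs test requires n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def screen_outliers(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[int], bool]:
    """Sequential Grubbs screening; returns removed indices and a stop flag.

    Repeatedly tests the current sample and removes the single most extreme
    value while G exceeds the critical value.  The test needs n >= 3 and the
    retained sample never drops below 2 values; the flag is True when a
    still-significant G could not be acted on because of that floor.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"screening requires at least 3 values, got {arr.size}")
    remaining = list(range(arr.size))
    removed: list[int] = []
    while len(remaining) >= 3:
        sub = arr[remaining]
        g, local_idx = grubbs_statistic(sub)
        if g <= grubbs_critical_value(len(remaining), alpha):
            return removed, False
        removed.append(remaining.pop(local_idx))
    # n = 2 left: the test is undefined, so a further outlier cannot be acted on
    return removed, True


def summarize_device(
    sessions: Sequence[SessionRecord], alpha: float = 0.05
) -> DeviceEmissionSummary:
    """Screen replicates of one device and return mean ± SE of the survivors.

    The Grubbs screen runs on the per-session normalized totals (µg/g); the
    standard error is s/sqrt(n_used) over the retained replicates.
    """
    if len(sessions) < 3:
        raise ValueError(
            f"device needs >= 3 sessions to screen and summarize, got {len(sessions)}"
        )
    device_ids = {s.device_id for s in sessions}
    if len(device_ids) != 1:
        raise ValueError(f"sessions span multiple devices: {sorted(device_ids)}")
    # Sort for permutation invariance of the screening order.
    order = sorted(range(len(sessions)), key=lambda i: (sessions[i].replicate_id, i))
    values = np.array([normalize_per_eliquid(sessions[i]) for i in order])
    removed, stopped = screen_outliers(values, alpha)
    kept = np.delete(values, removed)
    mean = float(kept.mean())
    se = float(kept.std(ddof=1) / np.sqrt(kept.size)) if kept.size > 1 else 0.0
    return DeviceEmissionSummary(
        device_id=next(iter(device_ids)),
        mean_emission=mean,
        standard_error=se,
        n_used=int(kept.size),
        n_outliers_removed=len(removed),
        screening_stopped=stopped,
        removed_replicates=tuple(sessions[order[i]].replicate_id for i in removed),
    )


def summarize_fleet(
    sessions: Sequence[SessionRecord], alpha: float = 0.05
) -> dict[str, DeviceEmissionSummary]:
    """Group sessions by device and summarize each; keyed by device_id."""
    by_device: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        by_device.setdefault(s.device_id, []).append(s)
    return {
        device_id: summarize_device(group, alpha) for device_id, group in by_device.items()
    }


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "device_id",
    "replicate_id",
    *ANALYTES,
    "unit",
    "eliquid_g",
]


def read_sessions(path) -> list[SessionRecord]:
    """Read a sessions table (CSV) into validated :class:`SessionRecord` rows.

    Blank analyte or e-liquid cells are rejected with the row number; a
    missing measurement is never silently coerced to zero.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"sessions file {path} is missing columns: {missing}")
    records: list[SessionRecord] = []
    for i, row in frame.iterrows():
        line = i + 2
        try:
            amounts = {}
            for analyte in ANALYTES:
                if pd.isna(row[analyte]):
                    raise ValueError(f"missing analyte '{analyte}'")
                amounts[analyte] = float(row[analyte])
            if pd.isna(row["eliquid_g"]):
                raise ValueError("missing eliquid_g")
            records.append(
                SessionRecord(
                    device_id=str(row["device_id"]),
                    replicate_id=str(row["replicate_id"]),
                    analyte_amounts=amounts,
                    eliquid_consumed=float(row["eliquid_g"]),
                    unit=str(row["unit"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return records


def write_sessions(sessions: Sequence[SessionRecord], path) -> None:
    rows = []
    for s in sessions:
        row = {"device_id": s.device_id, "replicate_id": s.replicate_id}
        row.update({a: s.analyte_amounts[a] for a in ANALYTES})
        row["unit"] = s.unit
        row["eliquid_g"] = s.eliquid_consumed
        rows.append(row)
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False, float_format="%.17g")
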