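"""Chlorophyll-fluorescence endpoints and leaf-level quality control.

Pulse-amplitude-modulation (PAM) fluorometry yields two photosystem-II
efficiency endpoints per leaf:

* effective quantum yield ``dF/Fm' = (Fm' - F) / Fm'`` measured on
  illuminated leaves, the primary phytotoxicity endpoint, and
* maximum quantum yield ``Fv/Fm = (Fm - F0) / Fm`` measured after dark
  adaptation, used to screen leaves before an assay and to verify that
  solvent controls stay healthy over the exposure.

Inhibition of either yield is expressed relative to the mean solvent-control
yield of the same batch and timepoint:
``inhibition (%) = 100 * (Y_control - Y_sample) / Y_control``.
Negative inhibition (stimulation above the control mean) is preserved; it
carries real information for curve fitting and truncating it would bias the
lower asymptote of the logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRecord",
    "YieldValue",
    "InvalidMeasurementError",
    "ControlQCError",
    "effective_quantum_yield",
    "maximum_quantum_yield",
    "percent_inhibition",
    "screen_leaves",
    "control_drift_qc",
    "DriftVerdict",
    "ScreenResult",
    "plate_endpoints",
    "DEFAULT_SCREEN_THRESHOLD",
    "DEFAULT_MAX_CONTROL_DROP",
    "TIMEPOINT_TOLERANCE_H",
]

#: leaves must exceed this dark-adapted Fv/Fm to enter an assay (strict >)
DEFAULT_SCREEN_THRESHOLD = 0.65

#: solvent-control mean Fv/Fm may decline by less than this many percent
#: from the 0 h baseline at every later timepoint
DEFAULT_MAX_CONTROL_DROP = 8.5

#: readings within this many hours of a nominal timepoint are binned to it
TIMEPOINT_TOLERANCE_H = 1.0


class InvalidMeasurementError(ValueError):
    """A fluorescence reading violates physical constraints (e.g. F > Fm')."""


class ControlQCError(ValueError):
    """Solvent controls are unusable (zero yield or missing baseline)."""


@dataclass(frozen=True)
class WellRecord:
    """One leaf in one well at one timepoint.

    ``F``/``Fm_prime`` are the light-adapted minimum/maximum fluorescence;
    ``F0``/``Fm`` the dark-adapted pair (optional: only needed for screening
    and control-drift QC). Arbitrary instrument units; only ratios are used.
    """

    plate_id: str
    well_id: str
    leaf_id: str
    treatment_id: str
    timepoint_h: float
    F: float
    Fm_prime: float
    F0: float | None = None
    Fm: float | None = None
    is_solvent_control: bool = False

    def __post_init__(self) -> None:
        if not (self.Fm_prime > 0):
            raise InvalidMeasurementError(
                f"well {self.well_id!r} (leaf {self.leaf_id!r}): Fm' must be > 0, got {self.Fm_prime}"
            )
        if self.F < 0 or self.F > self.Fm_prime:
            raise InvalidMeasurementError(
                f"well {self.well_id!r} (leaf {self.leaf_id!r}): need 0 <= F <= Fm', "
                f"got F={self.F}, Fm'={self.Fm_prime}"
            )
        if (self.F0 is None) != (self.Fm is None):
            raise InvalidMeasurementError(
                f"well {self.well_id!r}: F0 and Fm must be given together"
            )
        if self.Fm is not None:
            if not (self.Fm > 0):
                raise InvalidMeasurementError(
                    f"well {self.well_id!r}: Fm must be > 0, got {self.Fm}"
                )
            if self.F0 < 0 or self.F0 > self.Fm:
                raise InvalidMeasurementError(
                    f"well {self.well_id!r}: need 0 <= F0 <= Fm, got F0={self.F0}, Fm={self.Fm}"
                )

    @property
    def has_dark_adapted(self) -> bool:
        return self.F0 is not None and self.Fm is not None


@dataclass(frozen=True)
class YieldValue:
    """A dimensionless PSII quantum yield in [0, 1]."""

    value: float
    kind: Literal["effective", "maximum"]

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise InvalidMeasurementError(
                f"quantum yield must lie in [0, 1], got {self.value}"
            )


def effective_quantum_yield(
    F: float, Fm_prime: float, *, well: str | None = None
) -> YieldValue:
    """Effective quantum yield of PSII under illumination, (Fm' - F)/Fm'."""
    where = f" in well {well!r}" if well else ""
    if not (Fm_prime > 0):
        raise InvalidMeasurementError(f"Fm' must be > 0{where}, got {Fm_prime}")
    if F < 0 or F > Fm_prime:
        raise InvalidMeasurementError(
            f"need 0 <= F <= Fm'{where}, got F={F}, Fm'={Fm_prime}"
        )
    return YieldValue((Fm_prime - F) / Fm_prime, "effective")


def maximum_quantum_yield(
    F0: float, Fm: float, *, well: str | None = None
) -> YieldValue:
    """Maximum (dark-adapted) quantum yield of PSII, (Fm - F0)/Fm."""
    where = f" in well {well!r}" if well else ""
    if not (Fm > 0):
        raise InvalidMeasurementError(f"Fm must be > 0{where}, got {Fm}")
    if F0 < 0 or F0 > Fm:
        raise InvalidMeasurementError(
            f"need 0 <= F0 <= Fm{where}, got F0={F0}, Fm={Fm}"
        )
    return YieldValue((Fm - F0) / Fm, "maximum")


def percent_inhibition(y_sample: YieldValue, y_control: YieldValue) -> float:
    """Percent inhibition of a yield relative to the control yield.

    Returns ``100 * (Yc - Ys) / Yc``. Negative values (stimulation above the
    control) are preserved.
    """
    if y_sample.kind != y_control.kind:
        raise ValueError(
            f"cannot compare yields of different kinds: {y_sample.kind} vs {y_control.kind}"
        )
    if y_control.value <= 0:
        raise ControlQCError("control yield is zero; control batch unusable")
    return 100.0 * (y_control.value - y_sample.value) / y_control.value


@dataclass
class ScreenResult:
    """Partition of leaves into assay-ready and rejected, with reasons."""

    accepted: list[WellRecord] = field(default_factory=list)
    rejected: list[WellRecord] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)  # leaf_id -> reason


def screen_leaves(
    records: Iterable[WellRecord],
    threshold: float = DEFAULT_SCREEN_THRESHOLD,
) -> ScreenResult:
    """Accept only leaves whose dark-adapted Fv/Fm strictly exceeds ``threshold``.

    Leaves at exactly the threshold are rejected; leaves without dark-adapted
    readings cannot be screened and are rejected with reason ``"unscreened"``.
    """
    out = ScreenResult()
    for rec in records:
        if not rec.has_dark_adapted:
            out.rejected.append(rec)
            out.reasons[rec.leaf_id] = "unscreened"
            continue
        fvfm = maximum_quantum_yield(rec.F0, rec.Fm, well=rec.well_id).value
        if fvfm > threshold:
            out.accepted.append(rec)
        else:
            out.rejected.append(rec)
            out.reasons[rec.leaf_id] = f"Fv/Fm={fvfm:.3f} <= {threshold}"
    return out


@dataclass(frozen=True)
class DriftVerdict:
    """Control-drift QC outcome: percent decline of mean Fv/Fm per timepoint."""

    passed: bool
    declines_pct: dict[float, float]  # timepoint_h -> decline from baseline (%)
    max_drop: float


def control_drift_qc(
    control_records: Iterable[WellRecord],
    max_drop: float = DEFAULT_MAX_CONTROL_DROP,
) -> DriftVerdict:
    """Check that mean control Fv/Fm declines less than ``max_drop`` percent.

    The mean dark-adapted yield at each later timepoint is compared with the
    0 h baseline; the verdict passes only if every decline is strictly below
    the bound. Readings within ±1 h of a nominal timepoint are binned to it.
    """
    by_time: dict[float, list[float]] = {}
    for rec in control_records:
        if not rec.has_dark_adapted:
            continue
        t = _bin_timepoint(rec.timepoint_h)
        fvfm = maximum_quantum_yield(rec.F0, rec.Fm, well=rec.well_id).value
        by_time.setdefault(t, []).append(fvfm)
    if 0.0 not in by_time:
        raise ControlQCError("missing 0 h baseline controls for drift QC")
    baseline = float(np.mean(by_time[0.0]))
    if baseline <= 0:
        raise ControlQCError("baseline control Fv/Fm is zero")
    declines = {
        t: 100.0 * (baseline - float(np.mean(vals))) / baseline
        for t, vals in sorted(by_time.items())
        if t > 0
    }
    passed = all(d < max_drop for d in declines.values())
    return DriftVerdict(passed=passed, declines_pct=declines, max_drop=max_drop)


def _bin_timepoint(
    t: float,
    nominal: Sequence[float] = (0.0, 24.0, 48.0),
    tol: float = TIMEPOINT_TOLERANCE_H,
) -> float:
    for nom in nominal:
        if abs(t - nom) <= tol:
            return nom
    return t


def plate_endpoints(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Tidy per-leaf endpoint table from raw well records.

    Computes dF/Fm' (and Fv/Fm where dark-adapted readings exist) per well and
    percent inhibition of dF/Fm' against the mean solvent-control yield of the
    same timepoint within the supplied batch. Columns: ``leaf_id``,
    ``treatment_id``, ``timepoint_h``, ``dY``, ``FvFm``, ``inhibition_pct``,
    ``is_control``.
    """
    rows = []
    for rec in records:
        dY = effective_quantum_yield(rec.F, rec.Fm_prime, well=rec.well_id).value
        fvfm = (
            maximum_quantum_yield(rec.F0, rec.Fm, well=rec.well_id).value
            if rec.has_dark_adapted
            else np.nan
        )
        rows.append(
            {
                "plate_id": rec.plate_id,
                "leaf_id": rec.leaf_id,
                "treatment_id": rec.treatment_id,
                "timepoint_h": _bin_timepoint(rec.timepoint_h),
                "dY": dY,
                "FvFm": fvfm,
                "is_control": rec.is_solvent_control,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(inhibition_pct=pd.Series(dtype=float))

    ctrl = df[df["is_control"]]
    if ctrl.empty:
        raise ControlQCError("no solvent controls in batch; cannot normalize")
    ctrl_mean = ctrl.groupby("timepoint_h")["dY"].mean()
    if (ctrl_mean <= 0).any():
        bad = ctrl_mean[ctrl_mean <= 0].index.tolist()
        raise ControlQCError(f"mean control yield is zero at timepoint(s) {bad}")

    def _inhib(row: pd.Series) -> float:
        t = row["timepoint_h"]
        if t not in ctrl_mean.index:
            raise ControlQCError(f"no solvent controls at timepoint {t} h")
        yc = ctrl_mean.loc[t]
        return 100.0 * (yc - row["dY"]) / yc

    df["inhibition_pct"] = df.apply(_inhib, axis=1)
    return df[
        [
            "plate_id",
            "leaf_id",
            "treatment_id",
            "timepoint_h",
            "dY",
            "FvFm",
            "inhibition_pct",
            "is_control",
        ]
    ]
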