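"""Synthetic bioassay generator mirroring the leaf-assay study design.

The emulated design: 12-well plates, nine replicate leaves per concentration,
solvent controls defining 0 % inhibition, a geometric concentration series
spanning two orders of magnitude around the true IC50 for single compounds,
and the fixed TU dilution series (0, 0.25, 0.5, 0.75, 1, 1.5, 2, 4) for
mixtures. Responses are drawn from a true 4PL curve plus independent Gaussian
noise on the percent-inhibition scale (homoscedastic, sd = ``noise_sd``
points); an alternative yield-scale noise mode is available through
``simulate_raw_plate``, which produces raw fluorescence wells and therefore
heteroscedastic inhibition after normalisation.

Everything is reproducible from a single integer seed. ``deviation_factor``
lets mixture simulations depart from exact Concentration Addition: with
factor k, each nominal TU acts as k TU (k = 1 is the CA null, k > 1 synergy,
k < 1 antagonism).
"""

from __future__ import annotations

import zlib

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fluorometry import WellRecord
from .mixtures import DEFAULT_TU_LEVELS, MixtureSpec, ToxicUnitTable

__all__ = [
    "Truth4PL",
    "AssayScenario",
    "PlateSimResult",
    "default_scenario",
    "geometric_dose_series",
    "simulate_single_assay",
    "simulate_raw_plate",
    "simulate_mixture_assay",
]


@dataclass(frozen=True)
class Truth4PL:
    """True concentration-response parameters used by the generator."""

    bottom: float
    top: float
    hill: float
    ic50: float
    duration_h: float = 24.0

    def inhibition(self, dose: np.ndarray | float) -> np.ndarray | float:
        """Mean inhibition at ``dose``; dose 0 is a control (mean 0 by scale)."""
        x = np.asarray(dose, dtype=float)
        safe = np.where(x > 0, x, 1.0)
        val = self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ic50 / safe) ** self.hill
        )
        out = np.where(x > 0, val, 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AssayScenario:
    """Study conditions for the synthetic generator.

    ``noise_sd`` is in percent-inhibition points; ``control_yield`` is the
    healthy-leaf effective quantum yield that anchors the raw-fluorescence
    conversion; ``screen_fvfm`` the dark-adapted yield written into simulated
    wells (0.70 passes the 0.65 screening floor).
    """

    truths: dict[str, Truth4PL]
    dose_series: dict[str, tuple[float, ...]] = field(default_factory=dict)
    n_replicates: int = 9
    noise_sd: float = 5.0
    yield_noise_sd: float = 0.03
    control_yield: float = 0.70
    screen_fvfm: float = 0.70
    seed: int = 0
    deviation_factor: float = 1.0
    tu_levels: tuple[float, ...] = DEFAULT_TU_LEVELS

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd <= 0 or self.yield_noise_sd <= 0:
            raise ValueError("noise sds must be > 0")
        if not (0 < self.control_yield <= 1):
            raise ValueError("control_yield must be in (0, 1]")
        if self.deviation_factor <= 0:
            raise ValueError("deviation_factor must be > 0")

    def with_seed(self, seed: int) -> "AssayScenario":
        return replace(self, seed=seed)

    def doses_for(self, herbicide: str) -> tuple[float, ...]:
        if herbicide in self.dose_series:
            return self.dose_series[herbicide]
        return geometric_dose_series(self.truths[herbicide].ic50)


def geometric_dose_series(
    ic50: float, span: float = 30.0, n: int = 7
) -> tuple[float, ...]:
    """Geometric ladder of ``n`` doses from ic50/span to ic50*span."""
    return tuple(np.geomspace(ic50 / span, ic50 * span, n))


def default_scenario(seed: int = 0, **overrides) -> AssayScenario:
    """Scenario with the shipped single-compound endpoint table as truths.

    True IC50s are the published 24 h (and, where measured, 48 h) values;
    curves default to a full 0-100 % span with Hill slope 1, the canonical
    shape for single-site PSII binding.
    """
    from .datasets import inhibition_endpoints

    ep = inhibition_endpoints()
    truths: dict[str, Truth4PL] = {}
    for _, row in ep.iterrows():
        key = (
            row["herbicide"]
            if row["duration_h"] == 24.0
            else f"{row['herbicide']}_48h"
        )
        truths[key] = Truth4PL(
            bottom=0.0,
            top=100.0,
            hill=1.0,
            ic50=float(row["ic50"]),
            duration_h=float(row["duration_h"]),
        )
    return AssayScenario(truths=truths, seed=seed, **overrides)


def _stable_stream(name: str, offset: int) -> int:
    """Process-independent stream id for a treatment name (crc32, not hash())."""
    return (zlib.crc32(name.encode("utf-8")) + offset) % (2**31)


def _rng(scenario: AssayScenario, stream: int) -> np.random.Generator:
    """Independent per-stage stream fanned out from the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, stream]))


def simulate_single_assay(
    scenario: AssayScenario,
    herbicide: str,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulated inhibition observations for one compound's dilution series.

    Returns the tidy observation table (``treatment_id``, ``dose``,
    ``replicate``, ``duration_h``, ``inhibition``, ``dose_scale``) with
    ``n_replicates`` leaves per dose, controls at dose 0 included with mean
    inhibition 0.
    """
    truth = scenario.truths[herbicide]
    if rng is None:
        rng = _rng(scenario, stream=_stable_stream(herbicide, 0))
    doses = (0.0,) + tuple(scenario.doses_for(herbicide))
    rows = []
    for dose in doses:
        mean = truth.inhibition(dose)
        noise = rng.normal(0.0, scenario.noise_sd, scenario.n_replicates)
        for rep, eps in enumerate(noise):
            rows.append(
                {
                    "treatment_id": herbicide,
                    "dose": dose,
                    "replicate": rep,
                    "duration_h": truth.duration_h,
                    "inhibition": mean + eps,
                    "dose_scale": "concentration",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PlateSimResult:
    """Raw simulated wells plus bookkeeping from the yield conversion."""

    records: list[WellRecord]
    n_clipped: int


def simulate_raw_plate(
    scenario: AssayScenario,
    herbicide: str,
    *,
    rng: np.random.Generator | None = None,
    fvfm: float | None = None,
    fm_prime_scale: float = 0.5,
    fm_scale: float = 0.6,
    timepoint_h: float | None = None,
) -> PlateSimResult:
    """Raw fluorescence wells realising a single-compound assay.

    Inhibition draws are converted to effective yields
    ``y = control_yield * (1 - I/100)``, clipped to [0, 1] (clip events
    counted), then to a (F, Fm') pair at an arbitrary positive instrument
    scale; dark-adapted (F0, Fm) pairs encode ``fvfm`` (default the
    scenario's ``screen_fvfm``). Wells are laid out 12 to a plate.
    """
    truth = scenario.truths[herbicide]
    if rng is None:
        rng = _rng(scenario, stream=_stable_stream(herbicide, 1))
    if fvfm is None:
        fvfm = scenario.screen_fvfm
    t = truth.duration_h if timepoint_h is None else timepoint_h

    doses = (0.0,) + tuple(scenario.doses_for(herbicide))
    records: list[WellRecord] = []
    n_clipped = 0
    idx = 0
    for dose in doses:
        mean = truth.inhibition(dose)
        for rep in range(scenario.n_replicates):
            inhib = mean + rng.normal(0.0, scenario.noise_sd)
            y = scenario.control_yield * (1.0 - inhib / 100.0)
            if y < 0.0 or y > 1.0:
                n_clipped += 1
                y = min(max(y, 0.0), 1.0)
            plate = idx // 12
            well = idx % 12
            records.append(
                WellRecord(
                    plate_id=f"{herbicide}_P{plate:02d}",
                    well_id=f"{herbicide}_P{plate:02d}_W{well:02d}",
                    leaf_id=f"{herbicide}_L{idx:03d}",
                    treatment_id=f"{herbicide}@{dose:g}" if dose > 0 else "solvent_control",
                    timepoint_h=t,
                    F=fm_prime_scale * (1.0 - y),
                    Fm_prime=fm_prime_scale,
                    F0=fm_scale * (1.0 - fvfm),
                    Fm=fm_scale,
                    is_solvent_control=dose == 0.0,
                )
            )
            idx += 1
    return PlateSimResult(records=records, n_clipped=n_clipped)


def simulate_mixture_assay(
    scenario: AssayScenario,
    spec: MixtureSpec,
    table: ToxicUnitTable,
    *,
    reference: Truth4PL | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulated mixture observations along the TU dilution series.

    The response mean at nominal TU_sum level L is the reference TU-scale
    truth curve evaluated at the *effective* dose ``deviation_factor * L``;
    factor 1 is exact Concentration Addition. The reference truth defaults to
    a 0-100 % curve with Hill slope 1 and IC50 = 1 TU. Doses in the returned
    table are nominal TU_sum values (``dose_scale`` = "TU").
    """
    if spec.duration_h != table.duration_h:
        raise ValueError("mixture spec and Toxic-Unit table use different durations")
    for name, _ in spec.components:
        table.ic50(name)  # raises on missing component
    if reference is None:
        reference = Truth4PL(
            bottom=0.0, top=100.0, hill=1.0, ic50=1.0, duration_h=spec.duration_h
        )
    if rng is None:
        rng = _rng(scenario, stream=_stable_stream(spec.mixture_id, 2))

    rows = []
    for level in scenario.tu_levels:
        mean = reference.inhibition(scenario.deviation_factor * level)
        noise = rng.normal(0.0, scenario.noise_sd, scenario.n_replicates)
        for rep, eps in enumerate(noise):
            rows.append(
                {
                    "treatment_id": spec.mixture_id,
                    "dose": level,
                    "replicate": rep,
                    "duration_h": spec.duration_h,
                    "inhibition": mean + eps,
                    "dose_scale": "TU",
                }
            )
    return pd.DataFrame(rows)
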