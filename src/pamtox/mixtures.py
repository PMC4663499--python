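"""Toxic-Unit arithmetic and Concentration-Addition mixture analysis.

Concentration Addition (CA) is the joint-action model for toxicants sharing a
mode of action: each component's concentration is rescaled by its own potency
into Toxic Units, ``TU_i = C_i / IC50_i`` (so 1 TU is the component's IC50),
and the mixture dose is the sum

    TU_sum = sum_i C_i / IC50_i.

Under exact CA a mixture behaves like a single compound with IC50 = 1 on the
TU scale, whatever the component proportions. Mixture assays are therefore
run along a TU-space dilution series, fitted with the same 4PL machinery as
single compounds, and classified:

* **additive** — mixture IC50 (TU_sum) not significantly different from the
  sham reference mixtures' (a compound "mixed" with itself, whose TU-scale
  response must equal the single compound by construction);
* **synergistic** — significantly different and IC50 < 1 TU;
* **antagonistic** — significantly different and IC50 > 1 TU.

The significance test against reference mixtures takes precedence over the
point estimate's direction: an IC50 of 0.90 TU that matches the shams is
additive, not synergistic. Without references the fallback is the cruder
"95 % CI contains 1 TU" rule, flagged as such in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .doseresponse import (
    ICEstimate,
    ICxNotReachedError,
    LogisticFit,
    compare_ic50_ftest,
    fit_4pl,
    invert_icx,
)

__all__ = [
    "DEFAULT_TU_LEVELS",
    "ToxicUnitTable",
    "MixtureSpec",
    "AdditivityResult",
    "toxic_units",
    "tu_sum",
    "design_mixture_series",
    "ca_expected_curve",
    "classify_additivity",
    "percent_lower",
]

#: the TU-space dilution series used for every mixture assay
DEFAULT_TU_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0)


@dataclass(frozen=True)
class ToxicUnitTable:
    """Per-herbicide IC50s defining 1 TU, all on one exposure-duration basis."""

    entries: dict[str, float]  # herbicide -> IC50 (µg/l)
    duration_h: float = 24.0
    basis_note: str = "1 TU = single-compound IC50 at the stated duration"

    def __post_init__(self) -> None:
        for name, ic50 in self.entries.items():
            if not ic50 > 0:
                raise ValueError(f"IC50 for {name!r} must be > 0, got {ic50}")

    def ic50(self, herbicide: str) -> float:
        try:
            return self.entries[herbicide]
        except KeyError:
            raise KeyError(
                f"herbicide {herbicide!r} not in Toxic-Unit table "
                f"(have: {sorted(self.entries)})"
            ) from None


def toxic_units(concentration: float, ic50: float) -> float:
    """Concentration expressed in Toxic Units: TU = C / IC50."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be > 0, got {ic50}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / ic50


def tu_sum(
    components: Iterable[tuple[str, float]],
    table: ToxicUnitTable,
) -> float:
    """TU_sum of a mixture: sum over components of C_i / IC50_i."""
    return float(
        sum(toxic_units(conc, table.ic50(name)) for name, conc in components)
    )


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture design: component TU proportions and the TU dilution series.

    Proportions are shares of the Toxic-Unit contribution (not of mass): an
    equal binary mixture contributes 0.5 TU of each component per TU_sum.
    """

    mixture_id: str
    components: tuple[tuple[str, float], ...]
    tu_levels: tuple[float, ...] = DEFAULT_TU_LEVELS
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        props = [p for _, p in self.components]
        if any(p <= 0 for p in props):
            raise ValueError("component proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(props)}")
        lv = list(self.tu_levels)
        if any(l < 0 for l in lv):
            raise ValueError("TU levels must be non-negative")
        pos = [l for l in lv if l > 0]
        if sorted(pos) != pos or len(set(pos)) != len(pos):
            raise ValueError("positive TU levels must be strictly increasing")

    @classmethod
    def equal_proportions(
        cls,
        mixture_id: str,
        herbicides: Sequence[str],
        tu_levels: Sequence[float] = DEFAULT_TU_LEVELS,
        duration_h: float = 24.0,
    ) -> "MixtureSpec":
        p = 1.0 / len(herbicides)
        return cls(
            mixture_id=mixture_id,
            components=tuple((h, p) for h in herbicides),
            tu_levels=tuple(tu_levels),
            duration_h=duration_h,
        )


def design_mixture_series(
    spec: MixtureSpec, table: ToxicUnitTable
) -> pd.DataFrame:
    """Per-component dosing table realising the TU dilution series.

    At TU level L, component i receives ``C_i = L * p_i * IC50_i`` so that
    ``tu_sum`` of the row equals L exactly. Columns: ``mixture_id``,
    ``tu_level``, ``component``, ``concentration_ugL``, ``tu_component``.
    """
    if spec.duration_h != table.duration_h:
        raise ValueError(
            f"mixture designed on a {spec.duration_h} h basis but the "
            f"Toxic-Unit table is {table.duration_h} h; bases must match"
        )
    rows = []
    for level in spec.tu_levels:
        for name, prop in spec.components:
            ic50 = table.ic50(name)
            rows.append(
                {
                    "mixture_id": spec.mixture_id,
                    "tu_level": level,
                    "component": name,
                    "concentration_ugL": level * prop * ic50,
                    "tu_component": level * prop,
                }
            )
    return pd.DataFrame(rows)


def ca_expected_curve(reference_fit: LogisticFit):
    """Expected mixture inhibition as a function of TU_sum under CA.

    Returns a callable ``f(tu) -> percent inhibition`` that simply evaluates
    the reference TU-scale curve: under Concentration Addition a mixture's
    response depends on TU_sum alone. At TU_sum = 1 the expectation is 50 %
    when the reference spans 0→100; otherwise it is the reference curve's own
    value at 1 TU.
    """
    if reference_fit.dose_scale != "TU":
        raise ValueError(
            "reference fit must be on the TU dose scale "
            f"(got {reference_fit.dose_scale!r})"
        )
    return reference_fit.predict


@dataclass
class AdditivityResult:
    """Joint-action classification of a mixture on the TU_sum scale.

    ``ic50_tu`` is the dose (in TU_sum) at 50 % absolute inhibition from the
    fitted curve — the quantity the additivity rule is stated in — not the
    raw 4PL midpoint parameter (the two differ when the asymptotes are free).
    """

    mixture_id: str
    ic50_tu: float
    ci: tuple[float, float]
    ic10_tu: float | None
    ic10_ci: tuple[float, float] | None
    classification: str  # additive | synergistic | antagonistic
    rule: str  # reference_ftest | ci_contains_1
    reference_comparisons: pd.DataFrame | None = None
    fit: LogisticFit | None = None


def classify_additivity(
    mixture_obs: pd.DataFrame,
    reference_obs: Sequence[pd.DataFrame] | None = None,
    *,
    alpha: float = 0.05,
    mixture_id: str = "",
    reference_ids: Sequence[str] | None = None,
) -> AdditivityResult:
    """Fit a mixture's TU-scale curve and classify its joint action.

    ``mixture_obs`` (and each reference) is an observation table whose
    ``dose`` column is TU_sum. References are sham self-mixtures (or any
    user-chosen control mixtures); the mixture is called non-additive only
    when its IC50 differs significantly (pairwise extra-SS F tests at
    ``alpha``) from *every* reference — a difference from one sham but not
    the other reflects the shams' own spread, not a departure from
    Concentration Addition. Non-additive mixtures are synergistic or
    antagonistic by whether the IC50 falls below or above 1 TU. With no
    references the decision falls back to whether the IC50's 95 % CI contains
    1 TU, flagged via ``rule``.
    """
    fit = fit_4pl(mixture_obs, dose_scale="TU", treatment_id=mixture_id)
    ic50_est = invert_icx(fit, 50.0)
    try:
        ic10_est: ICEstimate | None = invert_icx(fit, 10.0)
    except ICxNotReachedError:
        ic10_est = None

    if reference_obs:
        rows = []
        sig_flags = []
        ids = list(reference_ids or [f"reference_{i}" for i in range(len(reference_obs))])
        for rid, ref in zip(ids, reference_obs):
            res = compare_ic50_ftest([mixture_obs, ref], posthoc=False)
            sig = res.p_value < alpha
            sig_flags.append(sig)
            rows.append(
                {
                    "reference": rid,
                    "F": res.f_stat,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p_value,
                    "significant": sig,
                }
            )
        comparisons = pd.DataFrame(rows)
        if not all(sig_flags):
            classification = "additive"
        elif ic50_est.value < 1.0:
            classification = "synergistic"
        else:
            classification = "antagonistic"
        rule = "reference_ftest"
    else:
        comparisons = None
        # tiny relative slack so a numerically degenerate CI at exactly 1 TU
        # (zero-residual fit) still counts as containing 1
        if ic50_est.ci_low * (1 - 1e-9) <= 1.0 <= ic50_est.ci_high * (1 + 1e-9):
            classification = "additive"
        elif ic50_est.value < 1.0:
            classification = "synergistic"
        else:
            classification = "antagonistic"
        rule = "ci_contains_1"

    return AdditivityResult(
        mixture_id=mixture_id,
        ic50_tu=ic50_est.value,
        ci=(ic50_est.ci_low, ic50_est.ci_high),
        ic10_tu=None if ic10_est is None else ic10_est.value,
        ic10_ci=None if ic10_est is None else (ic10_est.ci_low, ic10_est.ci_high),
        classification=classification,
        rule=rule,
        reference_comparisons=comparisons,
        fit=fit,
    )


def percent_lower(value: float, reference: float) -> float:
    """How many percent ``value`` lies below ``reference``: 100*(ref - v)/ref."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference
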