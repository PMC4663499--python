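"""Simulation studies validating the estimation machinery end to end.

The single-compound raw well data behind the published endpoint tables were
never deposited, so the fitted IC50s themselves cannot be recomputed from
data. What can be checked — and what these studies check — is that the whole
estimation pipeline is trustworthy under the study's own design:

* ``oracle_equivalence_study`` — on noiseless 4PL curves, the
  Levenberg-Marquardt fitter lands on the same SS minimum as the independent
  grid+bisection minimiser (:mod:`pamtox.validation`);
* ``recovery_study`` — for each published endpoint used as generator truth,
  repeated simulated assays (9 replicates, default noise) recover the true
  IC50 with small median log-error and near-nominal 95 % CI coverage;
* ``ca_null_study`` — mixtures simulated under exact Concentration Addition
  fit to IC50 near 1 TU_sum, and pairwise extra-SS F tests between them
  reject at close to the nominal rate (type-I control);
* ``synergy_power_study`` — a twofold potency deviation is reliably
  classified synergistic against sham references.

Each study is deterministic given its base seed; per-iteration scenario
seeds are ``base_seed * 1000 + k`` (kept below 2**31 by the callers), and
each simulated treatment draws from its own named substream, so the studies
are mutually independent within a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import FitError, compare_ic50_ftest, fit_4pl, invert_icx
from .mixtures import MixtureSpec, classify_additivity
from .simulate import Truth4PL, default_scenario, geometric_dose_series, simulate_mixture_assay, simulate_single_assay
from .validation import grid_fit_4pl

__all__ = [
    "oracle_equivalence_study",
    "recovery_study",
    "ca_null_study",
    "synergy_power_study",
]

#: the four mixtures of the published design: two shams, the binary test
#: mixture and the all-compound complex mixture
STUDY_MIXTURES = ("diuron+diuron", "atrazine+atrazine", "diuron+atrazine", "10-herbicide-mix")


def _study_specs(scenario) -> dict[str, MixtureSpec]:
    ten = sorted(h for h in scenario.truths if not h.endswith("_48h"))
    return {
        "diuron+diuron": MixtureSpec.equal_proportions("diuron+diuron", ["diuron", "diuron"]),
        "atrazine+atrazine": MixtureSpec.equal_proportions(
            "atrazine+atrazine", ["atrazine", "atrazine"]
        ),
        "diuron+atrazine": MixtureSpec.equal_proportions(
            "diuron+atrazine", ["diuron", "atrazine"]
        ),
        "10-herbicide-mix": MixtureSpec.equal_proportions("10-herbicide-mix", ten),
    }


def oracle_equivalence_study(
    hills=(0.6, 1.0, 2.5), ic50s=(0.5, 10.0, 250.0)
) -> float:
    """Worst-case relative IC50 disagreement between LM fit and grid oracle.

    Evaluated on noiseless 4PL curves over a grid of Hill slopes and IC50s.
    """
    worst = 0.0
    for h in hills:
        for ic50 in ic50s:
            truth = Truth4PL(5.0, 95.0, h, ic50)
            doses = geometric_dose_series(ic50)
            data = np.array(
                [[d, truth.inhibition(d)] for d in doses for _ in range(3)]
            )
            fit = fit_4pl(data)
            oracle = grid_fit_4pl(data[:, 0], data[:, 1])
            worst = max(worst, abs(fit.ic50 - oracle.ic50) / oracle.ic50)
    return worst


def recovery_study(base_seed: int = 0, n_seeds: int = 200) -> pd.DataFrame:
    """Parameter recovery per published truth: log-error and CI coverage.

    For each (herbicide, duration) truth, ``n_seeds`` assays are simulated
    (9 replicates, default noise) and refit. Returns one row per truth with
    ``median_abs_log10_error`` of the IC50 and ``coverage`` of the true IC50
    by the fit's 95 % CI.
    """
    scenario0 = default_scenario(seed=base_seed)
    rows = []
    for name, truth in scenario0.truths.items():
        errs, covered, n_ok = [], 0, 0
        for k in range(n_seeds):
            sc = scenario0.with_seed(base_seed * 1000 + k)
            try:
                fit = fit_4pl(simulate_single_assay(sc, name))
                est = invert_icx(fit, 50.0)
            except FitError:
                continue
            n_ok += 1
            errs.append(abs(np.log10(est.value / truth.ic50)))
            covered += est.ci_low <= truth.ic50 <= est.ci_high
        rows.append(
            {
                "herbicide": name,
                "true_ic50": truth.ic50,
                "n_fits": n_ok,
                "median_abs_log10_error": float(np.median(errs)),
                "coverage": covered / n_ok,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CANullResult:
    mean_ic50_tu: float  # grand mean of fitted mixture IC50s over seeds
    mean_by_mixture: dict[str, float]
    rejection_rate: float  # pairwise F-test type-I rate at alpha
    n_tests: int


def ca_null_study(
    base_seed: int = 0, n_seeds: int = 200, alpha: float = 0.05
) -> CANullResult:
    """Four mixtures under exact CA: IC50 near 1 TU, F-test type-I near alpha."""
    scenario0 = default_scenario(seed=base_seed)
    table = _tu_table_from(scenario0)
    specs = _study_specs(scenario0)
    ic50s: dict[str, list[float]] = {m: [] for m in STUDY_MIXTURES}
    n_reject = 0
    n_tests = 0
    for k in range(n_seeds):
        sc = scenario0.with_seed(base_seed * 1000 + k)
        obs = {m: simulate_mixture_assay(sc, specs[m], table) for m in STUDY_MIXTURES}
        for m, df in obs.items():
            ic50s[m].append(invert_icx(fit_4pl(df), 50.0).value)
        res = compare_ic50_ftest(list(obs.values()))
        n_reject += int((res.pairwise["p"] < alpha).sum())
        n_tests += len(res.pairwise)
    mean_by = {m: float(np.mean(v)) for m, v in ic50s.items()}
    return CANullResult(
        mean_ic50_tu=float(np.mean([v for vs in ic50s.values() for v in vs])),
        mean_by_mixture=mean_by,
        rejection_rate=n_reject / n_tests,
        n_tests=n_tests,
    )


def synergy_power_study(
    base_seed: int = 0, n_seeds: int = 200, deviation_factor: float = 2.0
) -> float:
    """Fraction of seeds in which a true synergist is classified synergistic.

    The test mixture is simulated with ``deviation_factor`` (each nominal TU
    acts as that many TU); the sham references stay at exact CA.
    """
    scenario0 = default_scenario(seed=base_seed)
    table = _tu_table_from(scenario0)
    specs = _study_specs(scenario0)
    hits = 0
    for k in range(n_seeds):
        sc = scenario0.with_seed(base_seed * 1000 + k)
        hot = dataclasses.replace(sc, deviation_factor=deviation_factor)
        mix = simulate_mixture_assay(hot, specs["diuron+atrazine"], table)
        refs = [
            simulate_mixture_assay(sc, specs[m], table)
            for m in ("diuron+diuron", "atrazine+atrazine")
        ]
        res = classify_additivity(mix, refs, mixture_id="diuron+atrazine")
        hits += res.classification == "synergistic"
    return hits / n_seeds


def _tu_table_from(scenario):
    from .mixtures import ToxicUnitTable

    return ToxicUnitTable(
        entries={
            name: t.ic50
            for name, t in scenario.truths.items()
            if not name.endswith("_48h")
        },
        duration_h=24.0,
    )
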