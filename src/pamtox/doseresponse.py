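"""Four-parameter logistic (4PL) concentration-response analysis.

The inhibition of a photosynthetic endpoint as a function of dose ``x`` is
modelled as

    I(x) = B + (T - B) / (1 + (IC50 / x)^h)

with lower asymptote ``B`` (bottom), upper asymptote ``T`` (top), Hill slope
``h`` and midpoint ``IC50``. Internally the model is parameterised in
``m = log10(IC50)`` and fitted against ``z = log10(dose)``: this makes the
optimiser well-conditioned and delta-method confidence intervals symmetric on
the log scale, the standard convention for concentration-response work.
Controls (dose 0) are excluded from the nonlinear fit — they define the 0 %
inhibition scale, so including them would double-count the normalisation.

ICx inversion is *absolute* by default: IC10 is the dose where the curve
crosses 10 % inhibition, which is what threshold-protection comparisons need.
A *relative* mode (10 % of the B→T span) is available for cross-package
comparison.

Curves are compared with the extra-sum-of-squares F test: the reduced model
shares one IC50 across datasets, the full model gives each its own, and (by
default) B, T and h are shared globally in both models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "LN10",
    "logistic4",
    "FitError",
    "ICxNotReachedError",
    "LogisticFit",
    "ICEstimate",
    "RelativePotency",
    "FTestResult",
    "fit_4pl",
    "bootstrap_icx",
    "invert_icx",
    "relative_potency",
    "relative_potency_table",
    "compare_ic50_ftest",
    "goodness_of_fit",
]

LN10 = np.log(10.0)


class FitError(RuntimeError):
    """The 4PL fit failed (degenerate data or no start converged)."""


class ICxNotReachedError(ValueError):
    """The requested inhibition level lies outside the fitted (B, T) span.

    In tabular outputs this is reported as "> max dose tested".
    """


def logistic4(
    x: np.ndarray | float,
    bottom: float,
    top: float,
    hill: float,
    ic50: float,
) -> np.ndarray | float:
    """Evaluate the 4PL curve at dose ``x`` (same units as ``ic50``)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.log10(x)
    out = _model(z, bottom, top, hill, np.log10(ic50))
    return float(out) if out.ndim == 0 else out


def _model(z, B, T, h, m):
    """4PL on the log10-dose scale; numerically stable via the logistic sigmoid."""
    s = special.expit(-LN10 * h * (np.asarray(m) - np.asarray(z)))
    return B + (T - B) * s


def _jacobian(z, B, T, h, m):
    """Analytic Jacobian of the model w.r.t. (B, T, h, m); rows = observations."""
    s = special.expit(-LN10 * h * (m - z))
    w = (T - B) * s * (1.0 - s) * LN10
    J = np.empty((z.size, 4))
    J[:, 0] = 1.0 - s
    J[:, 1] = s
    J[:, 2] = -w * (m - z)
    J[:, 3] = -w * h
    return J


@dataclass
class LogisticFit:
    """A fitted 4PL curve with covariance and diagnostics.

    ``covariance`` is the 4x4 parameter covariance in the order
    (bottom, top, hill, log10 IC50); for the constrained fit (B, T fixed) the
    bottom/top rows and columns are zero.
    """

    bottom: float
    top: float
    hill: float
    ic50: float
    log_ic50_se: float
    covariance: np.ndarray
    r2: float
    ss_resid: float
    df: int
    n_obs: int
    dose_scale: Literal["concentration", "TU"] = "concentration"
    treatment_id: str = ""
    duration_h: float | None = None
    constrained: bool = False
    converged: bool = True

    @property
    def log_ic50(self) -> float:
        return float(np.log10(self.ic50))

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return logistic4(x, self.bottom, self.top, self.hill, self.ic50)


@dataclass(frozen=True)
class ICEstimate:
    """Dose inhibiting the endpoint by ``level`` percent, with 95 % CI."""

    level: float
    value: float
    ci_low: float
    ci_high: float
    mode: Literal["absolute", "relative"] = "absolute"


@dataclass(frozen=True)
class RelativePotency:
    """Potency relative to the reference compound: IC50_ref / IC50_test."""

    herbicide: str
    duration_h: float | None
    rep: float


def _prepare(observations) -> tuple[np.ndarray, np.ndarray, dict]:
    """Extract positive-dose (dose, inhibition) arrays plus metadata."""
    meta: dict = {}
    if isinstance(observations, pd.DataFrame):
        df = observations
        dose = df["dose"].to_numpy(dtype=float)
        y = df["inhibition"].to_numpy(dtype=float)
        for col, key in [
            ("treatment_id", "treatment_id"),
            ("duration_h", "duration_h"),
            ("dose_scale", "dose_scale"),
        ]:
            if col in df.columns and df[col].nunique() == 1:
                meta[key] = df[col].iloc[0]
    else:
        arr = np.asarray(observations, dtype=float)
        dose, y = arr[:, 0], arr[:, 1]
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    keep = dose > 0
    return dose[keep], y[keep], meta


def _start_list(z: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: midpoint ±1 decade x Hill {0.5, 1, 2}."""
    m0 = float(np.mean(z))
    b0 = float(np.min(y))
    t0 = float(np.max(y))
    if t0 - b0 < 1e-9:
        t0 = b0 + 1.0
    return [
        np.array([b0, t0, h, m0 + dm])
        for h in (0.5, 1.0, 2.0)
        for dm in (-1.0, 0.0, 1.0)
    ]


def fit_4pl(
    observations,
    *,
    constrain: bool = False,
    dose_scale: str | None = None,
    treatment_id: str | None = None,
    min_doses: int = 5,
) -> LogisticFit:
    """Least-squares 4PL fit of percent-inhibition vs dose.

    Parameters
    ----------
    observations
        DataFrame with ``dose`` and ``inhibition`` columns (optionally
        ``treatment_id``, ``duration_h``, ``dose_scale``), or an (n, 2) array
        of (dose, inhibition). Controls (dose 0) are dropped before fitting.
    constrain
        If True, fix bottom = 0 and top = 100 and fit only (hill, log IC50).
    min_doses
        Minimum number of distinct positive doses required.

    The fit is run from a deterministic list of starting points (log IC50 at
    the dose grid midpoint and ±1 decade, Hill slope in {0.5, 1, 2}); the
    solution with the lowest residual sum of squares wins, ties broken by the
    smallest |log IC50 - grid midpoint|. The returned curve is canonicalised
    to a positive Hill slope (the 4PL is invariant under (B,T,h) -> (T,B,-h)).
    """
    dose, y, meta = _prepare(observations)
    n_doses = np.unique(dose).size
    if n_doses < min_doses:
        raise FitError(
            f"need >= {min_doses} distinct positive doses, got {n_doses}"
        )
    if np.ptp(y) < 1e-12:
        raise FitError("all responses identical: no dose-response to fit")
    z = np.log10(dose)
    n = y.size
    m_mid = float(np.mean(z))

    span = np.ptp([np.mean(y[dose == d]) for d in np.unique(dose)])
    if span < 0.5 * np.ptp(y) and n_doses >= 5:
        warnings.warn(
            "dose means span little of the response range; the doses may not "
            "cover the curve from near-bottom to near-top",
            stacklevel=2,
        )

    if constrain:
        best = _fit_constrained(z, y, m_mid)
    else:
        best = _fit_free(z, y, m_mid)
    if best is None:
        raise FitError("4PL fit did not converge from any start")

    B, T, h, m = best
    if h < 0:  # canonical form: positive Hill slope
        B, T, h = T, B, -h
    if T < B:
        warnings.warn(
            "fitted top < bottom: response is non-increasing with dose",
            stacklevel=2,
        )

    resid = _model(z, B, T, h, m) - y
    ss = float(resid @ resid)
    p_free = 2 if constrain else 4
    df = n - p_free
    if df <= 0:
        raise FitError("not enough observations for the number of parameters")
    sigma2 = ss / df

    J = _jacobian(z, B, T, h, m)
    if constrain:
        J = J[:, 2:]
    JTJ = J.T @ J
    try:
        cov_free = sigma2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov_free = sigma2 * np.linalg.pinv(JTJ)
    cov = np.zeros((4, 4))
    if constrain:
        cov[2:, 2:] = cov_free
    else:
        cov = cov_free

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss / ss_tot if ss_tot > 0 else np.nan

    return LogisticFit(
        bottom=float(B),
        top=float(T),
        hill=float(h),
        ic50=float(10.0 ** m),
        log_ic50_se=float(np.sqrt(max(cov[3, 3], 0.0))),
        covariance=cov,
        r2=r2,
        ss_resid=ss,
        df=df,
        n_obs=n,
        dose_scale=dose_scale or meta.get("dose_scale", "concentration"),
        treatment_id=treatment_id or str(meta.get("treatment_id", "")),
        duration_h=meta.get("duration_h"),
        constrained=constrain,
    )


def _free_bounds(z, y):
    """Data-driven box constraints that exclude the 4PL's degenerate ridges.

    Without bounds the unconstrained 4PL can drift to B -> -inf with a
    compensating h -> 0 on draws that happen to look log-linear. Asymptotes
    are allowed one full response span beyond the data, Hill slopes a
    physiological range, and log IC50 two decades beyond the dose grid.
    """
    span = max(np.ptp(y), 1.0)
    lo = [y.min() - span, y.min() - span, 0.05, z.min() - 2.0]
    hi = [y.max() + span, y.max() + span, 20.0, z.max() + 2.0]
    return np.array(lo), np.array(hi)


def _fit_free(z, y, m_mid):
    lo, hi = _free_bounds(z, y)
    best, best_key = None, None
    for p0 in _start_list(z, y):
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                lambda p: _model(z, *p) - y,
                p0,
                jac=lambda p: _jacobian(z, *p),
                method="trf",
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not res.success:
            continue
        ss = 2.0 * res.cost
        key = (round(ss, 10), abs(res.x[3] - m_mid))
        if best_key is None or key < best_key:
            best, best_key = res.x, key
    return best


def _fit_constrained(z, y, m_mid):
    best, best_key = None, None
    for h0 in (0.5, 1.0, 2.0):
        for dm in (-1.0, 0.0, 1.0):
            p0 = np.array([h0, m_mid + dm])
            try:
                res = optimize.least_squares(
                    lambda p: _model(z, 0.0, 100.0, p[0], p[1]) - y,
                    p0,
                    jac=lambda p: _jacobian(z, 0.0, 100.0, p[0], p[1])[:, 2:],
                    method="trf",
                    bounds=([0.05, z.min() - 2.0], [20.0, z.max() + 2.0]),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not res.success:
                continue
            ss = 2.0 * res.cost
            key = (round(ss, 10), abs(res.x[1] - m_mid))
            if best_key is None or key < best_key:
                best, best_key = res.x, key
    if best is None:
        return None
    return np.array([0.0, 100.0, best[0], best[1]])


def invert_icx(
    fit: LogisticFit,
    level: float,
    *,
    mode: Literal["absolute", "relative"] = "absolute",
    confidence: float = 0.95,
) -> ICEstimate:
    """Dose at which the fitted curve reaches ``level`` percent inhibition.

    Absolute mode (default) solves ``I(x) = level``:
    ``x = IC50 * ((level - B) / (T - level)) ** (1/h)``. Relative mode treats
    ``level`` as a fraction of the B→T span: ``x = IC50 * (f/(100-f))**(1/h)``.
    The confidence interval is a delta-method interval on log10(x) using the
    fit covariance and a t quantile with the fit's residual df.
    """
    B, T, h, m = fit.bottom, fit.top, fit.hill, fit.log_ic50
    if mode == "absolute":
        if not (B < level < T):
            raise ICxNotReachedError(
                f"inhibition level {level}% outside fitted span "
                f"({B:.1f}, {T:.1f}); report as > max dose tested"
            )
        ratio = (level - B) / (T - level)
        # d(log10 x)/d(B, T, h, m)
        grad = np.array(
            [
                -1.0 / (h * LN10 * (level - B)),
                -1.0 / (h * LN10 * (T - level)),
                -np.log10(ratio) / h**2,
                1.0,
            ]
        )
    elif mode == "relative":
        if not (0.0 < level < 100.0):
            raise ICxNotReachedError(f"relative level must be in (0, 100), got {level}")
        ratio = level / (100.0 - level)
        grad = np.array([0.0, 0.0, -np.log10(ratio) / h**2, 1.0])
    else:
        raise ValueError(f"unknown ICx mode {mode!r}")

    log_x = m + np.log10(ratio) / h
    var = float(grad @ fit.covariance @ grad)
    se = np.sqrt(max(var, 0.0))
    tq = stats.t.ppf(0.5 + confidence / 2.0, fit.df)
    lo, hi = 10.0 ** (log_x - tq * se), 10.0 ** (log_x + tq * se)
    return ICEstimate(
        level=float(level),
        value=float(10.0 ** log_x),
        ci_low=float(lo),
        ci_high=float(hi),
        mode=mode,
    )


def relative_potency(
    ic50_reference: float,
    ic50_herbicide: float,
    *,
    herbicide: str = "",
    duration_h: float | None = None,
) -> RelativePotency:
    """Relative potency ReP = IC50(reference) / IC50(test compound).

    ReP > 1 means the test compound is more potent than the reference.
    """
    if ic50_reference <= 0 or ic50_herbicide <= 0:
        raise ValueError("IC50 values must be positive")
    return RelativePotency(
        herbicide=herbicide,
        duration_h=duration_h,
        rep=ic50_reference / ic50_herbicide,
    )


def relative_potency_table(
    endpoints: pd.DataFrame,
    reference: str = "diuron",
    reference_duration_h: float = 24.0,
) -> pd.DataFrame:
    """ReP for every (herbicide, duration) row of an endpoint table.

    The reference IC50 is the reference compound's value at
    ``reference_duration_h`` (24 h by convention) for *all* rows, including
    longer-exposure rows: potencies are expressed on a single common basis.
    Expects columns ``herbicide``, ``duration_h``, ``ic50``.
    """
    ref_rows = endpoints[
        (endpoints["herbicide"] == reference)
        & (endpoints["duration_h"] == reference_duration_h)
    ]
    if ref_rows.empty:
        raise ValueError(
            f"reference {reference!r} at {reference_duration_h} h not in table"
        )
    ref_ic50 = float(ref_rows["ic50"].iloc[0])
    out = endpoints[["herbicide", "duration_h", "ic50"]].copy()
    out["rep"] = ref_ic50 / out["ic50"]
    return out


def bootstrap_icx(
    observations,
    level: float,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    constrain: bool = False,
    mode: Literal["absolute", "relative"] = "absolute",
    confidence: float = 0.95,
) -> ICEstimate:
    """Nonparametric bootstrap CI for an ICx: resample replicates within dose.

    The point estimate comes from the full-data fit; the interval is the
    percentile interval of the ICx over ``n_boot`` seeded resamples (each
    refit started from the full-data solution). Resamples whose refit fails
    or whose curve does not reach ``level`` are skipped.
    """
    dose, y, _ = _prepare(observations)
    full = fit_4pl(np.column_stack([dose, y]), constrain=constrain)
    point = invert_icx(full, level, mode=mode, confidence=confidence)

    rng = np.random.default_rng(seed)
    z = np.log10(dose)
    p_full = np.array([full.bottom, full.top, full.hill, full.log_ic50])
    groups = {d: np.flatnonzero(dose == d) for d in np.unique(dose)}
    draws = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(g, size=g.size, replace=True) for g in groups.values()]
        )
        zb, yb = z[idx], y[idx]
        try:
            lo, hi = _free_bounds(zb, yb)
            res = optimize.least_squares(
                lambda p: _model(zb, *p) - yb,
                np.clip(p_full, lo + 1e-9, hi - 1e-9),
                jac=lambda p: _jacobian(zb, *p),
                method="trf",
                bounds=(lo, hi),
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=400,
            )
            if not res.success:
                continue
            B, T, h, m = res.x
            if h < 0:
                B, T, h = T, B, -h
            if mode == "absolute":
                if not (B < level < T):
                    continue
                ratio = (level - B) / (T - level)
            else:
                ratio = level / (100.0 - level)
            draws.append(m + np.log10(ratio) / h)
        except Exception:
            continue
    if len(draws) < max(20, n_boot // 10):
        raise FitError("too few successful bootstrap resamples for a CI")
    q = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(draws, [q, 1.0 - q])
    return ICEstimate(
        level=float(level),
        value=point.value,
        ci_low=float(10.0 ** lo),
        ci_high=float(10.0 ** hi),
        mode=mode,
    )


@dataclass
class FTestResult:
    """Extra-sum-of-squares F test of a shared IC50 across curves."""

    f_stat: float
    df1: int
    df2: int
    p_value: float
    ss_full: float
    ss_reduced: float
    ic50s: list[float]
    sharing: str
    pairwise: pd.DataFrame | None = None


def _stack(datasets: Sequence) -> tuple[list[np.ndarray], list[np.ndarray]]:
    zs, ys = [], []
    for d in datasets:
        dose, y, _ = _prepare(d)
        if dose.size == 0:
            raise ValueError("a dataset has no positive doses")
        zs.append(np.log10(dose))
        ys.append(y)
    return zs, ys


def _fit_shared(zs, ys, n_ic50: int, p0: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit B, T, h shared + ``n_ic50`` log-IC50 parameters by stacked LS."""
    groups = np.concatenate(
        [np.full(z.size, i if n_ic50 > 1 else 0) for i, z in enumerate(zs)]
    )
    z_all = np.concatenate(zs)
    y_all = np.concatenate(ys)

    def resid(p):
        B, T, h = p[0], p[1], p[2]
        m = p[3 + groups]
        return _model(z_all, B, T, h, m) - y_all

    def jac(p):
        B, T, h = p[0], p[1], p[2]
        m = p[3 + groups]
        J4 = _jacobian(z_all, B, T, h, m)
        J = np.zeros((z_all.size, 3 + n_ic50))
        J[:, :3] = J4[:, :3]
        for i in range(n_ic50):
            mask = groups == i
            J[mask, 3 + i] = J4[mask, 3]
        return J

    lo_b, hi_b = _free_bounds(z_all, y_all)
    lo = np.concatenate([lo_b[:3], np.full(n_ic50, lo_b[3])])
    hi = np.concatenate([hi_b[:3], np.full(n_ic50, hi_b[3])])
    res = optimize.least_squares(
        resid,
        np.clip(p0, lo + 1e-9, hi - 1e-9),
        jac=jac,
        method="trf",
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    if not res.success:
        raise FitError("shared-parameter fit did not converge")
    return res.x, 2.0 * res.cost


def compare_ic50_ftest(
    datasets: Sequence,
    *,
    sharing: Literal["shared_bth", "separate_all"] = "shared_bth",
    alpha: float = 0.05,
    posthoc: bool = True,
) -> FTestResult:
    """Extra-sum-of-squares F test of whether curves share one IC50.

    Reduced model: a single IC50 for all datasets. Full model: one IC50 per
    dataset. Under ``shared_bth`` (default) bottom, top and Hill slope are
    common to all curves in both models; under ``separate_all`` each curve
    keeps its own B, T, h and only the IC50 is shared in the reduced model.
    Post-hoc output is the table of uncorrected pairwise two-curve F tests
    (with a Holm-adjusted column alongside).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to compare")
    zs, ys = _stack(datasets)
    k = len(datasets)
    n = sum(y.size for y in ys)

    indiv = [fit_4pl(d) for d in datasets]

    if sharing == "shared_bth":
        b0 = float(np.mean([f.bottom for f in indiv]))
        t0 = float(np.mean([f.top for f in indiv]))
        h0 = float(np.mean([f.hill for f in indiv]))
        p0_full = np.concatenate([[b0, t0, h0], [f.log_ic50 for f in indiv]])
        p_full, ss_full = _fit_shared(zs, ys, k, p0_full)
        p0_red = np.array([b0, t0, h0, float(np.mean([f.log_ic50 for f in indiv]))])
        _, ss_red = _fit_shared(zs, ys, 1, p0_red)
        df_full = n - (3 + k)
        df_red = n - 4
        ic50s = [float(10.0 ** m) for m in p_full[3:]]
    elif sharing == "separate_all":
        ss_full = sum(f.ss_resid for f in indiv)
        df_full = n - 4 * k
        _, ss_red = _fit_separate_bth_shared_m(zs, ys, indiv)
        df_red = n - (3 * k + 1)
        ic50s = [f.ic50 for f in indiv]
    else:
        raise ValueError(f"unknown sharing scheme {sharing!r}")

    df1 = df_red - df_full
    df2 = df_full
    if df2 <= 0:
        raise FitError("no residual degrees of freedom in the full model")
    extra = max(ss_red - ss_full, 0.0)
    if ss_full <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (extra / df1) / (ss_full / df2)
        p = float(stats.f.sf(f_stat, df1, df2))

    pairwise = None
    if posthoc and k > 2:
        rows = []
        for i, j in itertools.combinations(range(k), 2):
            sub = compare_ic50_ftest(
                [datasets[i], datasets[j]], sharing=sharing, posthoc=False
            )
            rows.append(
                {
                    "curve_a": i,
                    "curve_b": j,
                    "F": sub.f_stat,
                    "df1": sub.df1,
                    "df2": sub.df2,
                    "p": sub.p_value,
                }
            )
        pairwise = pd.DataFrame(rows)
        pairwise["p_holm"] = _holm(pairwise["p"].to_numpy())
        pairwise["significant"] = pairwise["p"] < alpha

    return FTestResult(
        f_stat=float(f_stat),
        df1=int(df1),
        df2=int(df2),
        p_value=float(p),
        ss_full=float(ss_full),
        ss_reduced=float(ss_red),
        ic50s=ic50s,
        sharing=sharing,
        pairwise=pairwise,
    )


def _fit_separate_bth_shared_m(zs, ys, indiv):
    """Reduced model for the separate_all scheme: per-curve B, T, h, one m."""
    k = len(zs)
    sizes = [z.size for z in zs]
    z_all = np.concatenate(zs)
    y_all = np.concatenate(ys)
    bounds_idx = np.cumsum([0] + sizes)

    def unpack(p):
        bth = p[: 3 * k].reshape(k, 3)
        return bth, p[3 * k]

    def resid(p):
        bth, m = unpack(p)
        out = np.empty(z_all.size)
        for i in range(k):
            lo, hi = bounds_idx[i], bounds_idx[i + 1]
            out[lo:hi] = _model(zs[i], bth[i, 0], bth[i, 1], bth[i, 2], m) - ys[i]
        return out

    def jac(p):
        bth, m = unpack(p)
        J = np.zeros((z_all.size, 3 * k + 1))
        for i in range(k):
            lo, hi = bounds_idx[i], bounds_idx[i + 1]
            J4 = _jacobian(zs[i], bth[i, 0], bth[i, 1], bth[i, 2], m)
            J[lo:hi, 3 * i : 3 * i + 3] = J4[:, :3]
            J[lo:hi, 3 * k] = J4[:, 3]
        return J

    p0 = np.concatenate(
        [np.array([f.bottom, f.top, f.hill]) for f in indiv]
        + [[float(np.mean([f.log_ic50 for f in indiv]))]]
    )
    lo_b, hi_b = _free_bounds(z_all, y_all)
    lo = np.concatenate([np.tile(lo_b[:3], k), [lo_b[3]]])
    hi = np.concatenate([np.tile(hi_b[:3], k), [hi_b[3]]])
    res = optimize.least_squares(
        resid,
        np.clip(p0, lo + 1e-9, hi - 1e-9),
        jac=jac,
        method="trf",
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2400,
    )
    if not res.success:
        raise FitError("reduced (shared IC50) fit did not converge")
    return res.x, 2.0 * res.cost


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    order = np.argsort(p)
    k = p.size
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def goodness_of_fit(fit: LogisticFit) -> float:
    """Coefficient of determination R² = 1 - SS_resid / SS_total.

    NaN (not applicable) when the fitted observations had zero total
    variance.
    """
    return fit.r2
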