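"""Independent brute-force 4PL minimiser for cross-checking fits.

``grid_fit_4pl`` minimises the residual sum of squares over
(bottom, top, hill, log10 IC50) by a zooming grid search: for each candidate
(hill, log IC50) pair the bottom and top enter the model linearly, so they
are profiled out exactly with a closed-form 2x2 linear least-squares solve;
the outer (hill, log IC50) grid is then repeatedly refined (bisected) around
the incumbent optimum. The implementation shares no code path with the
Levenberg-Marquardt fitter and serves as its oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["GridFit", "grid_fit_4pl"]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class GridFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    ss: float


def _profile_ss(z: np.ndarray, y: np.ndarray, h: float, m: np.ndarray):
    """For each m, profile out (B, T) by linear LS; return SS, B, T arrays."""
    # s has shape (len(m), len(z))
    s = special.expit(-_LN10 * h * (m[:, None] - z[None, :]))
    a = 1.0 - s  # coefficient of B
    b = s  # coefficient of T
    aa = (a * a).sum(axis=1)
    ab = (a * b).sum(axis=1)
    bb = (b * b).sum(axis=1)
    ay = a @ y
    by = b @ y
    det = aa * bb - ab * ab
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    B = (ay * bb - by * ab) / det
    T = (aa * by - ab * ay) / det
    pred = B[:, None] * a + T[:, None] * b
    ss = ((pred - y[None, :]) ** 2).sum(axis=1)
    ss = np.where(np.isnan(ss), np.inf, ss)
    return ss, B, T


def grid_fit_4pl(
    dose: np.ndarray,
    inhibition: np.ndarray,
    *,
    hill_range: tuple[float, float] = (0.1, 8.0),
    n_grid: int = 21,
    n_zoom: int = 40,
) -> GridFit:
    """Brute-force 4PL fit by zooming grid search with profiled asymptotes.

    ``dose`` must be positive (controls excluded beforehand). ``n_zoom``
    rounds shrinking the (log hill, log IC50) box by 2/n_grid per round give
    roughly machine-level localisation of the optimum for smooth problems.
    """
    dose = np.asarray(dose, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    keep = dose > 0
    dose, y = dose[keep], y[keep]
    z = np.log10(dose)

    lo_lh, hi_lh = np.log10(hill_range[0]), np.log10(hill_range[1])
    lo_m, hi_m = z.min() - 1.5, z.max() + 1.5

    best = (np.inf, np.nan, np.nan, np.nan, np.nan)  # ss, B, T, h, m
    for _ in range(n_zoom):
        lhs = np.linspace(lo_lh, hi_lh, n_grid)
        ms = np.linspace(lo_m, hi_m, n_grid)
        for lh in lhs:
            h = 10.0 ** lh
            ss, B, T = _profile_ss(z, y, h, ms)
            i = int(np.argmin(ss))
            if ss[i] < best[0]:
                best = (float(ss[i]), float(B[i]), float(T[i]), h, float(ms[i]))
        # shrink the box around the incumbent
        _, _, _, h_best, m_best = best
        span_lh = (hi_lh - lo_lh) * (2.0 / (n_grid - 1))
        span_m = (hi_m - lo_m) * (2.0 / (n_grid - 1))
        c_lh = np.log10(h_best)
        lo_lh, hi_lh = c_lh - span_lh, c_lh + span_lh
        lo_m, hi_m = m_best - span_m, m_best + span_m

    ss, B, T, h, m = best
    return GridFit(bottom=B, top=T, hill=h, ic50=10.0 ** m, ss=ss)
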