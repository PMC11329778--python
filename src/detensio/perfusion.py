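"""Vascular parameters from macromolecular-contrast enhancement curves.

After i.v. injection of a macromolecular contrast agent, the normalized
tissue enhancement y(t) = C_t / C_blood rises approximately linearly over
the first minutes.  Ordinary least squares of y against t over the early
window yields two parameters: the intercept fBV (fractional blood volume,
fBV = C_0 / C_blood, a proxy for vessel density) and the slope PS
(permeability surface-area product, 1/min, the rate of contrast
extravasation, PS = (C_t - C_0) / (C_blood * t) along the fitted line).
The default window is the first 15 minutes after administration; the
pre-injection baseline (t <= 0) is excluded from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnhancementSeries",
    "PerfusionParams",
    "normalize_enhancement",
    "fit_fbv_ps",
    "mean_perfusion",
]


@dataclass(frozen=True)
class EnhancementSeries:
    """Contrast enhancement time course for one region of interest.

    ``c_blood`` is either a scalar (blood concentration already extrapolated
    to t = 0) or a per-time-point series, in which case the t = 0 value is
    obtained by ordinary linear extrapolation.
    """

    t_min: np.ndarray
    c_t: np.ndarray
    c_blood: float | np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=np.float64)
        c = np.asarray(self.c_t, dtype=np.float64)
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "c_t", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("t_min and c_t must be 1D and the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_min must be strictly increasing")
        if np.count_nonzero(t > 0) < 3:
            raise ValueError("need at least 3 time points with t > 0")
        if np.isscalar(self.c_blood) or np.ndim(self.c_blood) == 0:
            if not float(self.c_blood) > 0:
                raise ValueError("C_blood must be positive")
        else:
            cb = np.asarray(self.c_blood, dtype=np.float64)
            object.__setattr__(self, "c_blood", cb)
            if cb.shape != t.shape:
                raise ValueError("C_blood series must match t_min length")


@dataclass(frozen=True)
class PerfusionParams:
    """Fitted (fBV, PS) with goodness-of-fit and physicality flag.

    Negative estimates are reported as-is (clipping would bias group
    means); ``nonphysical`` flags them for downstream QC.
    """

    fBV: float
    PS_per_min: float
    r2: float
    window_min: float
    nonphysical: bool


def extrapolated_blood_concentration(series: EnhancementSeries) -> float:
    """Blood concentration at t = 0, by OLS extrapolation if a series."""
    if np.ndim(series.c_blood) == 0:
        return float(series.c_blood)
    cb = np.asarray(series.c_blood, dtype=np.float64)
    slope, intercept = np.polyfit(series.t_min, cb, 1)
    c0 = float(intercept)
    if c0 <= 0:
        raise ValueError("extrapolated C_blood(0) is non-positive")
    return c0


def normalize_enhancement(
    series: EnhancementSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (t, y) with y = C_t / C_blood (dimensionless enhancement)."""
    cb0 = extrapolated_blood_concentration(series)
    return series.t_min.copy(), series.c_t / cb0


def fit_fbv_ps(
    series: EnhancementSeries, window_min: float = 15.0
) -> PerfusionParams:
    """OLS fit of C_t/C_blood against t over the window (0, window_min].

    Intercept is fBV, slope is PS (1/min).  Requires >= 3 in-window points.
    """
    t, y = normalize_enhancement(series)
    sel = (t > 0) & (t <= window_min)
    if np.count_nonzero(sel) < 3:
        raise ValueError(
            f"need at least 3 points with 0 < t <= {window_min} min"
        )
    tw, yw = t[sel], y[sel]
    if np.all(tw == tw[0]):
        raise ValueError("all in-window times identical (singular design)")
    res = stats.linregress(tw, yw)
    fbv = float(res.intercept)
    ps = float(res.slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return PerfusionParams(
        fBV=fbv,
        PS_per_min=ps,
        r2=r2,
        window_min=float(window_min),
        nonphysical=bool(fbv < 0 or ps < 0),
    )


def mean_perfusion(fits: list[PerfusionParams]) -> dict:
    """Mean fBV and PS over per-site fits (one value per implantation site)."""
    if not fits:
        raise ValueError("no fits to aggregate")
    fbv = np.array([f.fBV for f in fits])
    ps = np.array([f.PS_per_min for f in fits])
    return {
        "n_sites": len(fits),
        "fBV_mean": float(fbv.mean()),
        "fBV_sem": float(fbv.std(ddof=1) / np.sqrt(len(fits))) if len(fits) > 1 else float("nan"),
        "PS_mean": float(ps.mean()),
        "PS_sem": float(ps.std(ddof=1) / np.sqrt(len(fits))) if len(fits) > 1 else float("nan"),
        "n_nonphysical": int(sum(f.nonphysical for f in fits)),
    }
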