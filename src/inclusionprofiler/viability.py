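"""Live-cell survival curves and crystal-violet dose-response fitting.

GFP-positive cell counts per well are normalized to their own starting count
and then to a matched control series at every timepoint (relative survival);
treatment effects are compared by the trapezoid area under that curve.
Plate-reader absorbance dose series are fit with the four-parameter logistic
("log(inhibitor) vs normalized response, variable slope"):

    y(c) = bottom + (top − bottom) / (1 + 10^((log10 IC50 − log10 c) · hill))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["SurvivalSeries", "DoseResponseFit", "relative_survival", "auc",
           "fit_dose_response"]

#: zero-dose points enter the log axis at (min nonzero dose) / this factor
ZERO_DOSE_FACTOR = 100.0


@dataclass
class SurvivalSeries:
    """Relative-survival curve of one arm against its matched control."""

    timepoints: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    relative: np.ndarray
    arm: str = ""
    control_arm: str = ""

    def __post_init__(self) -> None:
        assert self.relative[0] == 1.0
        assert np.all(np.diff(self.timepoints) > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.timepoints, "count": self.counts,
            "normalized": self.normalized, "relative": self.relative,
        })


def relative_survival(
    counts,
    control_counts,
    timepoints,
    arm: str = "",
    control_arm: str = "control",
) -> SurvivalSeries:
    """Normalize counts to t0 and then to the matched control at each timepoint.

    Both series must share timepoints and have positive starting counts.
    relative[t] = (counts[t]/counts[0]) / (control[t]/control[0]), so
    relative[t0] = 1 exactly and a series measured against itself is
    identically 1.
    """
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if c.shape != t.shape or ctrl.shape != t.shape:
        raise ValueError("counts, control counts and timepoints must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if c[0] <= 0 or ctrl[0] <= 0:
        raise ValueError("starting count must be > 0 for both series")
    if np.any(ctrl <= 0):
        raise ValueError("control counts must stay > 0 (division per timepoint)")
    normalized = c / c[0]
    relative = normalized / (ctrl / ctrl[0])
    return SurvivalSeries(timepoints=t, counts=c, normalized=normalized,
                          relative=relative, arm=arm, control_arm=control_arm)


def auc(series: SurvivalSeries) -> float:
    """Trapezoid area under the relative-survival curve, in survival x hours."""
    if len(series.timepoints) < 2:
        raise ValueError("need >= 2 timepoints for an area under the curve")
    return float(np.trapezoid(series.relative, series.timepoints))


def _four_pl(logc: np.ndarray, bottom: float, top: float,
             log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10 ** ((log_ic50 - logc) * hill))


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit result."""

    log10_ic50: float
    hill: float
    top: float
    bottom: float
    residual_sd: float
    converged: bool
    extrapolated: bool
    n_points: int

    @property
    def ic50(self) -> float:
        return float(10 ** self.log10_ic50)

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        logc = np.log10(np.where(conc > 0, conc, np.nan))
        return _four_pl(logc, self.bottom, self.top, self.log10_ic50, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "-----------------------------------------",
            f"IC50          {self.ic50:.4g} µM" + ("  (extrapolated)" if self.extrapolated else ""),
            f"log10 IC50    {self.log10_ic50:.4f}",
            f"hill slope    {self.hill:.4f}",
            f"top           {self.top:.4f}",
            f"bottom        {self.bottom:.4f}",
            f"residual sd   {self.residual_sd:.4g}",
            f"n points      {self.n_points}",
            f"converged     {self.converged}",
        ]
        return "\n".join(lines)


def fit_dose_response(concs, response) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    Zero-dose points are placed on the log axis at (min nonzero dose)/100.
    Starting values come from data quantiles; the hill-slope sign follows the
    observed direction of response, so monotone-increasing data fit with a
    flipped slope.  Non-convergence is flagged, with quantile-seeded
    parameters returned alongside a warning rather than raising.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concs and response must align")
    if len(np.unique(c)) < 5:
        raise ValueError("need >= 5 distinct concentrations for a 4PL fit")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    nonzero = c[c > 0]
    floor = nonzero.min() / ZERO_DOSE_FACTOR
    logc = np.log10(np.where(c > 0, c, floor))

    top0, bottom0 = float(np.max(y)), float(np.min(y))
    # midpoint guess: log-dose at which response crosses halfway
    half = (top0 + bottom0) / 2.0
    order = np.argsort(logc)
    log_ic50_0 = float(np.interp(half, np.sort(y)[::1], logc[order][np.argsort(y[order])])
                       if np.ptp(y) > 0 else np.median(logc))
    declining = y[np.argmin(c)] >= y[np.argmax(c)]
    hill0 = 1.0 if declining else -1.0
    p0 = (bottom0, top0, log_ic50_0, hill0)
    try:
        popt, _ = curve_fit(_four_pl, logc, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        import warnings
        warnings.warn("4PL fit did not converge; returning quantile-seeded parameters",
                      stacklevel=2)
        popt, converged = p0, False
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    resid = y - _four_pl(logc, bottom, top, log_ic50, hill)
    extrapolated = not (np.log10(nonzero.min()) <= log_ic50 <= np.log10(nonzero.max()))
    return DoseResponseFit(
        log10_ic50=log_ic50, hill=hill, top=top, bottom=bottom,
        residual_sd=float(resid.std()), converged=converged,
        extrapolated=extrapolated, n_points=len(y),
    )
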