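"""IS-normalized response and 1/x^2-weighted linear calibration.

The response of a sample is the ratio of the analyte signal to the
internal-standard signal, which cancels preparation and ionization
variability.  Calibration fits the linear model

    y_i = a + b * x_i,    minimizing  sum_i w_i (y_i - a - b x_i)^2,
    w_i = 1 / x_i^2,

on the replicate responses of the non-zero calibration standards
(zero-concentration samples never enter the fit: their weight is
undefined).  The 1/x^2 weighting equalizes the *relative* error across a
calibration range spanning three orders of magnitude, the standard
bioanalytical convention.  Concentrations are back-calculated by inverse
prediction, x_hat = (y - a) / b, and each calibration level is accepted
when its mean back-calculated bias is within +/-15% (+/-20% at the
LLOQ); the curve is accepted when at least 75% of the standards and a
minimum number of levels pass.  The determination coefficient is
computed on the weighted model and reported against a configurable
floor (default 0.988); guidelines gate on bias, not r^2, so it does not
by itself reject a curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Response",
    "CalibrationModel",
    "CalibrationResult",
    "CalibrationAcceptance",
    "compute_response",
    "fit_weighted_linear",
    "back_calculate",
    "evaluate_calibration",
]


@dataclass
class Response:
    """IS-normalized response of one sample (analyte area / IS area)."""

    y: float
    valid: bool = True
    extraction_method: str = "MobA"
    sample_id: str | None = None


def compute_response(
    analyte_area: float,
    is_area: float,
    extraction_method: str = "MobA",
    sample_id: str | None = None,
) -> Response:
    """y = analyte_area / is_area; a zero IS area flags the response invalid."""
    if analyte_area < 0 or is_area < 0:
        raise ValueError("areas must be >= 0")
    if is_area == 0:
        return Response(y=np.nan, valid=False, extraction_method=extraction_method,
                        sample_id=sample_id)
    return Response(y=analyte_area / is_area, valid=True,
                    extraction_method=extraction_method, sample_id=sample_id)


class CalibrationModel:
    """Weighted linear calibration model on (nominal concentration, response).

    Parameters
    ----------
    x, y : array-like
        Nominal concentrations (ng/mL) and IS-normalized responses of the
        calibration standards.  Zero-concentration points are excluded
        (recorded in ``n_excluded``); at least two distinct positive
        concentrations are required.
    weighting : {"1/x^2", "1/x", "none"}
        Weight scheme; the assay's convention is ``1/x^2``.
    use_level_means : bool
        Fit on per-level mean responses instead of individual replicates.
        Regression on replicates is the default (standard EMA practice).
    """

    def __init__(self, x, y, weighting: str = "1/x^2", use_level_means: bool = False):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        keep = np.isfinite(x) & np.isfinite(y) & (x > 0)
        self.n_excluded = int(len(x) - keep.sum())
        x, y = x[keep], y[keep]
        if use_level_means:
            levels = np.unique(x)
            y = np.array([y[x == lvl].mean() for lvl in levels])
            x = levels
        if len(np.unique(x)) < 2:
            raise ValueError("calibration requires >= 2 distinct positive concentrations")
        if weighting not in ("1/x^2", "1/x", "none"):
            raise ValueError(f"unknown weighting: {weighting!r}")
        self.x, self.y, self.weighting = x, y, weighting
        self.use_level_means = use_level_means

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_col: str = "nominal_conc_ng_per_mL",
        y_col: str = "response",
        **kwargs,
    ) -> "CalibrationModel":
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy(), **kwargs)

    @property
    def weights(self) -> np.ndarray:
        if self.weighting == "1/x^2":
            return 1.0 / self.x**2
        if self.weighting == "1/x":
            return 1.0 / self.x
        return np.ones_like(self.x)

    def fit(self) -> "CalibrationResult":
        """Weighted least squares via statsmodels WLS; deterministic."""
        exog = sm.add_constant(self.x)
        res = sm.WLS(self.y, exog, weights=self.weights).fit()
        intercept, slope = res.params
        se_a, se_b = res.bse
        return CalibrationResult(
            intercept=float(intercept),
            slope=float(slope),
            intercept_se=float(se_a),
            slope_se=float(se_b),
            r2=float(res.rsquared),
            n=int(len(self.x)),
            weighting=self.weighting,
            x=self.x.copy(),
            y=self.y.copy(),
        )


@dataclass
class CalibrationResult:
    """Fitted calibration line with diagnostics and inverse prediction."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r2: float
    n: int
    weighting: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def back_calculate(self, y):
        """Inverse prediction x_hat = (y - a) / b.

        Values below zero are reported as-is (honest blank and carry-over
        statistics need them); callers may flag them.
        """
        if self.slope <= 0:
            raise ValueError("back-calculation requires a positive slope")
        out = (np.asarray(y, dtype=float) - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out

    def evaluate(
        self,
        lloq_conc: float | None = None,
        bias_limit_pct: float = 15.0,
        lloq_bias_limit_pct: float = 20.0,
        min_fraction: float = 0.75,
        min_levels: int = 6,
        r2_threshold: float = 0.988,
    ) -> "CalibrationAcceptance":
        """Per-level back-calculation bias and the curve acceptance verdict."""
        levels = np.unique(self.x)
        lloq = lloq_conc if lloq_conc is not None else float(levels.min())
        back = self.back_calculate(self.y)
        rows = []
        for lvl in levels:
            m = self.x == lvl
            mean_back = float(np.mean(back[m]))
            bias = 100.0 * (mean_back - lvl) / lvl
            limit = lloq_bias_limit_pct if lvl == lloq else bias_limit_pct
            rows.append(
                {
                    "level": float(lvl),
                    "n": int(m.sum()),
                    "mean_back_calc": mean_back,
                    "bias_pct": float(bias),
                    "accepted": bool(abs(bias) <= limit),
                }
            )
        n_ok = sum(r["accepted"] for r in rows)
        fraction = n_ok / len(rows)
        verdict = bool(fraction >= min_fraction and n_ok >= min_levels and self.slope > 0)
        return CalibrationAcceptance(
            per_level=rows,
            accepted_levels=n_ok,
            n_levels=len(rows),
            fraction_accepted=float(fraction),
            r2=self.r2,
            r2_ok=bool(self.r2 >= r2_threshold),
            verdict=verdict,
        )

    def summary(self) -> str:
        lines = [
            "Weighted linear calibration",
            "---------------------------",
            f"n points        {self.n:>10d}   (weighting {self.weighting})",
            f"slope b         {self.slope:>12.6g} +/- {self.slope_se:.3g} per ng/mL",
            f"intercept a     {self.intercept:>12.6g} +/- {self.intercept_se:.3g}",
            f"weighted r^2    {self.r2:>12.6f}",
        ]
        acc = self.evaluate()
        lines.append(f"levels accepted {acc.accepted_levels:>6d}/{acc.n_levels}   verdict: "
                     + ("accepted" if acc.verdict else "rejected"))
        lines.append("level (ng/mL)    n   back-calc    bias%   ok")
        for r in acc.per_level:
            lines.append(
                f"{r['level']:>12.4g} {r['n']:>4d} {r['mean_back_calc']:>11.4g} "
                f"{r['bias_pct']:>8.2f}   {'y' if r['accepted'] else 'N'}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Calibration points and fitted line (log-x), matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.x, self.y, s=14, color="k", label="standards")
        grid = np.geomspace(self.x.min(), self.x.max(), 200)
        ax.plot(grid, self.predict(grid), color="tab:blue",
                label=f"y = {self.intercept:.3g} + {self.slope:.3g} x")
        ax.set_xscale("log")
        ax.set_xlabel("nominal concentration (ng/mL)")
        ax.set_ylabel("response (analyte / IS)")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "r2": self.r2,
            "n": self.n,
            "weighting": self.weighting,
        }


@dataclass
class CalibrationAcceptance:
    per_level: list[dict]
    accepted_levels: int
    n_levels: int
    fraction_accepted: float
    r2: float
    r2_ok: bool
    verdict: bool

    def to_dict(self) -> dict:
        return {
            "per_level": self.per_level,
            "accepted_levels": self.accepted_levels,
            "n_levels": self.n_levels,
            "fraction_accepted": self.fraction_accepted,
            "r2": self.r2,
            "r2_ok": self.r2_ok,
            "verdict": self.verdict,
        }


def fit_weighted_linear(points: Sequence[tuple[float, float]], **kwargs) -> CalibrationResult:
    """Fit the weighted calibration line on (x, y) pairs."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    return CalibrationModel(arr[:, 0], arr[:, 1], **kwargs).fit()


def back_calculate(fit: CalibrationResult, y):
    return fit.back_calculate(y)


def evaluate_calibration(fit: CalibrationResult, **kwargs) -> CalibrationAcceptance:
    return fit.evaluate(**kwargs)
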