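"""Surrogate-analyte calibration linearity assessment.

Three unweighted fits of PAR against nominal concentration are supported,
matching standard bioanalytical practice when longitudinal fold changes
(rather than external calibration) will be compared:

* ``linear``        PAR = a + b*conc           (ordinary least squares)
* ``through_zero``  PAR = b*conc               (b = sum(x*y)/sum(x^2))
* ``power``         log PAR = log a + b*log conc  (OLS in log-log space)

No weighting is applied anywhere. Each fit reports R^2 in its own fitted
space (uncentered total sum of squares for the no-intercept model) and
per-level back-calculated recovery, i.e. 100 * back_calculated / nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

MODEL_KINDS = ("linear", "through_zero", "power")


@dataclass
class FitResult:
    """A fitted calibration model with per-level recovery diagnostics.

    ``params`` is (intercept a, slope b) for the linear models and
    (coefficient a, exponent b) for the power model. ``recoveries`` maps
    nominal concentration -> mean recovery % over replicates at that level;
    ``recovery_table`` keeps every replicate.
    """

    model_kind: str
    params: tuple[float, float]
    r_squared: float
    recoveries: dict[float, float] = field(default_factory=dict)
    recovery_table: pd.DataFrame | None = None

    @property
    def slope(self) -> float:
        return self.params[1]


def _as_xy(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.DataFrame):
        x = series["nominal_conc"].to_numpy(dtype=float)
        y = series["par"].to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def fit_calibration(series, model_kind: str = "through_zero") -> FitResult:
    """Fit one calibration model to (concentration, PAR) data.

    ``series`` is a DataFrame with columns ``nominal_conc, par`` or a
    sequence of (conc, PAR) pairs. At least three distinct concentrations
    are required; the power model additionally requires strictly positive
    PAR.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected one of {MODEL_KINDS}")
    x, y = _as_xy(series)
    if len(np.unique(x)) < 3:
        raise ValueError("calibration requires at least 3 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")

    if model_kind == "linear":
        b, a = np.polyfit(x, y, 1)
        pred = a + b * x
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        params = (float(a), float(b))
    elif model_kind == "through_zero":
        b = float(np.sum(x * y) / np.sum(x * x))
        pred = b * x
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum(y**2))  # uncentered: standard for no-intercept models
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        params = (0.0, b)
    else:  # power
        if np.any(y <= 0):
            raise ValueError("power model requires strictly positive PAR values")
        lx, ly = np.log(x), np.log(y)
        b, la = np.polyfit(lx, ly, 1)
        pred = la + b * lx
        ss_res = float(np.sum((ly - pred) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        params = (float(np.exp(la)), float(b))

    fit = FitResult(model_kind=model_kind, params=params, r_squared=float(r2))
    rows = []
    for xi, yi in zip(x, y):
        try:
            bc = back_calculate(fit, yi)
        except ValueError:
            bc = np.nan
        rows.append({"nominal_conc": xi, "par": yi, "back_calculated": bc,
                     "recovery_pct": 100.0 * bc / xi})
    tbl = pd.DataFrame(rows)
    fit.recovery_table = tbl
    fit.recoveries = (
        tbl.groupby("nominal_conc")["recovery_pct"].mean().to_dict()
    )
    return fit


def back_calculate(fit: FitResult, par: float) -> float:
    """Invert a fitted model at one observed PAR, returning nM."""
    a, b = fit.params
    if b == 0:
        raise ValueError(f"{fit.model_kind} fit has zero slope; not invertible")
    if fit.model_kind == "linear":
        return (par - a) / b
    if fit.model_kind == "through_zero":
        return par / b
    if par <= 0:
        raise ValueError("power model cannot back-calculate a non-positive PAR")
    return float((par / a) ** (1.0 / b))


@dataclass
class LinearRangeResult:
    """Outcome of the linear-dynamic-range decision."""

    accepted_range: tuple[float, float] | None
    accepted_levels: list[float]
    per_level: pd.DataFrame  # nominal_conc, recovery_pct, passed
    tolerance_pct: float


def assess_linear_range(fit: FitResult, tolerance_pct: float = 30.0) -> LinearRangeResult:
    """Find the widest contiguous concentration span with acceptable recovery.

    A level passes when its mean back-calculated recovery is within
    ``tolerance_pct`` of 100%. The accepted range is the longest contiguous
    run of passing levels (ties broken toward the wider concentration
    span); with the default 30% tolerance this reproduces the +-30%
    accuracy rule used to declare the assay's linear dynamic range.
    """
    if not fit.recoveries:
        raise ValueError("fit has no recovery data")
    levels = sorted(fit.recoveries)
    passed = [abs(fit.recoveries[lv] - 100.0) <= tolerance_pct for lv in levels]
    per_level = pd.DataFrame(
        {"nominal_conc": levels,
         "recovery_pct": [fit.recoveries[lv] for lv in levels],
         "passed": passed}
    )
    best: list[float] = []
    run: list[float] = []
    for lv, ok in zip(levels, passed):
        if ok:
            run.append(lv)
        else:
            run = []
        if len(run) > len(best) or (
            run and len(run) == len(best) and run[-1] / run[0] > best[-1] / best[0]
        ):
            best = list(run)
    rng = (best[0], best[-1]) if best else None
    return LinearRangeResult(
        accepted_range=rng, accepted_levels=best, per_level=per_level,
        tolerance_pct=tolerance_pct,
    )
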