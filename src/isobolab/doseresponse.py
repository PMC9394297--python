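"""Log-dose least-squares regression and EDx estimation.

The dose–response curve (DRC) is modelled as a straight line in
(log10 dose, effect) space — the standard behavioural-pharmacology
construction for doses spanning one to two orders of magnitude — fit by
ordinary least squares to group mean effects, one point per dose. The
dose producing an x% effect (EDx; here ED30, chosen because the partial
agonist caps below 50%) is the inverse of the fitted line, with its
standard error from the delta method:

    g = (x - b0) / b1,     dose = 10**g
    Var(g) = (Var(b0) + g^2 Var(b1) + 2 g Cov(b0, b1)) / b1^2
    Var(dose) = (ln 10 * dose)^2 * Var(g)

A linear-dose scale is also available (``scale="linear_dose"``), in which
case dose = g and se(dose) = se(g).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import statsmodels.api as sm

from .errors import ComputationError, ValidationError

LN10 = log(10.0)


class DoseScale(str, enum.Enum):
    LOG10_DOSE = "log10_dose"
    LINEAR_DOSE = "linear_dose"


class ExtrapolationWarning(UserWarning):
    """EDx requested outside the observed effect range."""


@dataclass(frozen=True)
class DRCFit:
    """An OLS dose–response line with its coefficient covariance."""

    doses: tuple[float, ...]
    effects: tuple[float, ...]
    scale: DoseScale
    b0: float  # intercept
    b1: float  # slope per log10(dose) (or per dose unit on linear scale)
    resid_var: float
    cov: np.ndarray  # 2x2 covariance of (b0, b1)
    n_points: int

    @property
    def df(self) -> int:
        return self.n_points - 2

    def transform(self, dose: float) -> float:
        if self.scale is DoseScale.LOG10_DOSE:
            if dose <= 0:
                raise ValidationError(f"dose must be > 0 on the log scale: {dose}")
            return float(np.log10(dose))
        return float(dose)


@dataclass(frozen=True)
class EDxEstimate:
    """The dose producing an x% effect, with its delta-method SE."""

    x: float
    dose: float
    se: float
    df: int

    def __post_init__(self):
        if not self.dose > 0:
            raise ComputationError(f"EDx dose must be positive, got {self.dose}")
        if self.se < 0:
            raise ComputationError("EDx se must be non-negative")


def fit_drc(
    doses, effects, scale: DoseScale | str = DoseScale.LOG10_DOSE
) -> DRCFit:
    """Fit effect on (transformed) dose by ordinary least squares."""
    scale = DoseScale(scale)
    doses = np.asarray(doses, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if doses.shape != effects.shape or doses.ndim != 1:
        raise ValidationError("doses and effects must be 1-D arrays of equal length")
    if len(np.unique(doses)) < 2:
        raise ValidationError("need >= 2 distinct doses to fit a line")
    if scale is DoseScale.LOG10_DOSE and np.any(doses <= 0):
        raise ValidationError("all doses must be > 0 under the log10 scale")
    x = np.log10(doses) if scale is DoseScale.LOG10_DOSE else doses
    model = sm.OLS(effects, sm.add_constant(x))
    res = model.fit()
    b0, b1 = res.params
    # with df_resid == 0 (two points) the line is exact: zero residual variance
    resid_var = float(res.mse_resid) if res.df_resid > 0 else 0.0
    cov = (
        np.asarray(res.cov_params())
        if res.df_resid > 0
        else np.zeros((2, 2))
    )
    return DRCFit(
        doses=tuple(doses),
        effects=tuple(effects),
        scale=scale,
        b0=float(b0),
        b1=float(b1),
        resid_var=resid_var,
        cov=cov,
        n_points=len(doses),
    )


def predict_effect(fit: DRCFit, dose: float) -> float:
    """Fitted effect (%) at a dose."""
    return fit.b0 + fit.b1 * fit.transform(dose)


def edx(fit: DRCFit, x: float) -> EDxEstimate:
    """Invert the fitted line to the dose giving an x% effect.

    Warns (:class:`ExtrapolationWarning`) when x lies outside the observed
    effect range — a shallow-topped curve makes this a realistic situation
    worth flagging rather than forbidding.
    """
    if abs(fit.b1) < 1e-12:
        raise ComputationError("cannot invert a flat dose-response line (b1 = 0)")
    lo, hi = min(fit.effects), max(fit.effects)
    if not (lo <= x <= hi):
        warnings.warn(
            f"ED{x:g} lies outside the observed effect range [{lo:.3g}, {hi:.3g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    g = (x - fit.b0) / fit.b1
    var_g = (
        fit.cov[0, 0] + g * g * fit.cov[1, 1] + 2.0 * g * fit.cov[0, 1]
    ) / (fit.b1 * fit.b1)
    var_g = max(var_g, 0.0)
    if fit.scale is DoseScale.LOG10_DOSE:
        dose = 10.0 ** g
        se = LN10 * dose * sqrt(var_g)
    else:
        dose = g
        se = sqrt(var_g)
    if not np.isfinite(dose) or dose <= 0:
        raise ComputationError(f"ED{x:g} inversion gave a non-positive dose: {dose}")
    return EDxEstimate(x=x, dose=float(dose), se=float(se), df=fit.df)


def fit_report(fit: DRCFit, ed: EDxEstimate | None = None) -> dict:
    """JSON-ready summary of a fit (coefficients, covariance, optional EDx)."""
    report = {
        "scale": fit.scale.value,
        "n_points": fit.n_points,
        "b0": fit.b0,
        "b1": fit.b1,
        "resid_var": fit.resid_var,
        "cov": [list(map(float, row)) for row in fit.cov],
        "df": fit.df,
    }
    if ed is not None:
        report["edx"] = {"x": ed.x, "dose": ed.dose, "se": ed.se, "df": ed.df}
    return report
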