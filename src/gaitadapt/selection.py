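"""Model selection between single and double exponential fits.

Goodness of fit is compared with the least-squares Akaike information
criterion

    AIC = n ln(RSS / n) + 2 (p + 1),

counting the error variance as a fitted parameter; the model with the
lower AIC (closer to negative infinity) is preferred, with ties resolved
toward the single model by parsimony.  Residuals of each model are checked
for normality with the Shapiro-Wilk test and exported as QQ point sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .events import AsymmetrySeries
from .fitting import ExponentialModelFit, eval_model

__all__ = [
    "aic",
    "aicc",
    "ModelComparison",
    "compare_models",
    "residual_diagnostics",
]


def aic(rss: float, n: int, p: int) -> float:
    """Least-squares AIC with the error variance counted as a parameter.

    Only AIC differences between models fitted to the same series are
    meaningful.  A zero RSS (perfect fit) leaves the criterion undefined.
    """
    if rss < 0:
        raise ValidationError("rss must be non-negative")
    if rss == 0:
        raise DegenerateStatisticError(
            "AIC undefined for a perfect fit (rss = 0)")
    if n <= p + 2:
        raise ValidationError("need n > p + 2 observations")
    return n * np.log(rss / n) + 2 * (p + 1)


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample corrected AIC; optional, per-stage stride counts are
    usually in the hundreds so the correction is negligible."""
    k = p + 1
    base = aic(rss, n, p)
    if n - k - 1 <= 0:
        raise ValidationError("AICc undefined: n too small for p")
    return base + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelComparison:
    """AIC comparison of a single vs a double fit on one series."""

    aic_single: float
    aic_double: float
    chosen: str                    # "single" | "double"
    delta_aic: float               # aic_single - aic_double
    shapiro_single: tuple[float, float]   # (W, p)
    shapiro_double: tuple[float, float]


def _shapiro(residuals: np.ndarray) -> tuple[float, float]:
    if np.ptp(residuals) == 0:
        raise DegenerateStatisticError(
            "Shapiro-Wilk undefined for constant residuals")
    w, p = stats.shapiro(residuals)
    return float(w), float(p)


def compare_models(fit_single: ExponentialModelFit,
                   fit_double: ExponentialModelFit,
                   corrected: bool = False) -> ModelComparison:
    """Select between the two fits by AIC (lower wins, ties go to single).

    Both fits must be over the same series (equal ``n``).  ``corrected``
    switches to AICc.
    """
    if fit_single.kind != "single" or fit_double.kind != "double":
        raise ValidationError("pass (single fit, double fit) in that order")
    if fit_single.n != fit_double.n:
        raise ValidationError(
            f"fits are over different series (n={fit_single.n} vs "
            f"{fit_double.n})")
    criterion = aicc if corrected else aic
    a_s = criterion(fit_single.rss, fit_single.n, fit_single.n_parameters)
    a_d = criterion(fit_double.rss, fit_double.n, fit_double.n_parameters)
    chosen = "double" if a_d < a_s else "single"
    return ModelComparison(
        aic_single=float(a_s),
        aic_double=float(a_d),
        chosen=chosen,
        delta_aic=float(a_s - a_d),
        shapiro_single=_shapiro(fit_single.residuals),
        shapiro_double=_shapiro(fit_double.residuals),
    )


def residual_diagnostics(fit: ExponentialModelFit,
                         series: AsymmetrySeries):
    """Shapiro-Wilk normality check plus QQ points for the fit residuals.

    Returns ``(W, p, qq)`` where ``qq`` is an (n, 2) array of
    (theoretical standard-normal quantile, ordered residual) pairs.
    """
    if len(series) < 3:
        raise ValidationError("need at least 3 strides for diagnostics")
    residuals = series.asymmetry - eval_model(fit.parameters, series.t,
                                              fit.kind)
    w, p = _shapiro(residuals)
    n = len(residuals)
    # Blom plotting positions for the theoretical quantiles
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq = np.column_stack([theoretical, np.sort(residuals)])
    return w, p, qq
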