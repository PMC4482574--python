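"""Abundance-distance curve estimation, selection and projection.

Local abundance y (burrows/km^2) is modelled as a decreasing function of
the Mahalanobis distance d to the niche centroid. Nine classic
curve-estimation families are fitted, each by ordinary least squares in
its linearizing space (the convention of SPSS-style curve estimation):

    linear        y = b0 + b1 d
    logarithmic   y = b0 + b1 ln d
    inverse       y = b0 + b1 / d
    quadratic     y = b0 + b1 d + b2 d^2
    cubic         y = b0 + b1 d + b2 d^2 + b3 d^3
    power         y = b0 d^b1            (fit: ln y ~ ln d)
    growth        y = exp(b0 + b1 d)     (fit: ln y ~ d)
    exponential   y = b0 exp(b1 d)       (fit: ln y ~ d)
    logistic      1/y = b0 b1^d          (fit: ln(1/y) ~ d; no upper bound)

R^2, adjusted R^2 and the overall-F p-value are reported in the fitting
space, which makes growth, exponential and logistic exact
reparameterizations of one OLS problem (identical R^2 by construction).
The best family is the one with maximal adjusted R^2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .errors import ContractError, FitDomainError, InsufficientDataError
from .io_geo import GridSpec
from .niche import DistanceSurface, DistributionMask

logger = logging.getLogger(__name__)

#: fixed family order; also the final tie-break in model selection
FAMILIES = (
    "linear",
    "logarithmic",
    "inverse",
    "quadratic",
    "cubic",
    "power",
    "growth",
    "exponential",
    "logistic",
)

_N_PREDICTORS = {
    "linear": 1, "logarithmic": 1, "inverse": 1,
    "quadratic": 2, "cubic": 3,
    "power": 1, "growth": 1, "exponential": 1, "logistic": 1,
}
_LOG_RESPONSE = frozenset({"power", "growth", "exponential", "logistic"})
_NEEDS_POSITIVE_D = frozenset({"logarithmic", "inverse", "power"})

#: relative distance floor used when evaluating singular forms near d=0
DISTANCE_FLOOR_FACTOR = 1e-6


@dataclass
class CurveFit:
    """One fitted abundance-distance functional form."""

    family: str
    coefficients: tuple[float, ...]  # (b0, b1[, b2[, b3]])
    r2: float
    adj_r2: float
    p_value: float
    n: int
    p_predictors: int
    fit_space: str  # "raw" or "log-response"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": list(self.coefficients),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
            "n": self.n,
            "p_predictors": self.p_predictors,
            "fit_space": self.fit_space,
        }


@dataclass
class AbundanceSurface:
    """Predicted per-pixel density (burrows/km^2) over the distribution mask."""

    spec: GridSpec
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.spec.shape:
            raise ContractError("surface shape must match the GridSpec")


def adjusted_r2(r2: float, n: int, p_predictors: int) -> float:
    """Penalize R^2 for predictor count: 1 - (1-R^2)(n-1)/(n-p-1)."""
    if n <= p_predictors + 1:
        raise ContractError("n must exceed p_predictors + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_predictors - 1)


def _distance_floor(d: np.ndarray) -> float:
    pos = d[d > 0]
    if pos.size == 0:
        return np.finfo(float).tiny
    return DISTANCE_FLOOR_FACTOR * float(np.median(pos))


def _design_and_response(d, y, family, floor=None):
    """Transform (d, y) into the family's linearizing space."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if floor is not None and family in _NEEDS_POSITIVE_D:
        d = np.maximum(d, floor)
    if family in _NEEDS_POSITIVE_D:
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            raise FitDomainError(
                f"{family} family requires d > 0; offending records: "
                f"{bad.tolist()}", offending=bad)
    if family in _LOG_RESPONSE:
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise FitDomainError(
                f"{family} family requires y > 0; offending records: "
                f"{bad.tolist()}", offending=bad)
    if family == "linear":
        X, resp = d[:, None], y
    elif family == "logarithmic":
        X, resp = np.log(d)[:, None], y
    elif family == "inverse":
        X, resp = (1.0 / d)[:, None], y
    elif family == "quadratic":
        X, resp = np.column_stack([d, d**2]), y
    elif family == "cubic":
        X, resp = np.column_stack([d, d**2, d**3]), y
    elif family == "power":
        X, resp = np.log(d)[:, None], np.log(y)
    elif family in ("growth", "exponential"):
        X, resp = d[:, None], np.log(y)
    elif family == "logistic":
        X, resp = d[:, None], np.log(1.0 / y)
    else:
        raise ContractError(f"unknown family {family!r}; choose from {FAMILIES}")
    return X, resp


def _coefficients_from_params(family, params) -> tuple[float, ...]:
    """Back-transform OLS parameters to the family's reported (b0, b1, ...)."""
    intercept, *slopes = (float(v) for v in params)
    if family == "power":
        return (float(np.exp(intercept)), slopes[0])
    if family == "exponential":
        return (float(np.exp(intercept)), slopes[0])
    if family == "growth":
        return (intercept, slopes[0])
    if family == "logistic":
        # ln(1/y) = ln b0 + d ln b1  ->  1/y = b0 * b1^d
        return (float(np.exp(intercept)), float(np.exp(slopes[0])))
    return (intercept, *slopes)


def fit_family(d, y, family: str, on_zero: str = "error") -> CurveFit:
    """Fit one curve family by OLS in its linearizing space.

    ``on_zero`` controls log-response families facing y = 0: "error"
    (default) raises :class:`FitDomainError` listing the offending
    records; "drop" excludes and reports them.
    """
    if family not in FAMILIES:
        raise ContractError(f"unknown family {family!r}; choose from {FAMILIES}")
    d = np.asarray(d, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if d.shape != y.shape:
        raise ContractError("d and y must have the same length")
    if np.any(y < 0):
        raise ContractError("abundance y must be nonnegative")
    if on_zero == "drop" and family in _LOG_RESPONSE:
        zeros = np.flatnonzero(y == 0)
        if zeros.size:
            logger.warning("%s fit: dropping %d zero-count record(s) at %s",
                           family, zeros.size, zeros.tolist())
            keep = y > 0
            d, y = d[keep], y[keep]
    p = _N_PREDICTORS[family]
    n = d.size
    if n < p + 2:
        raise InsufficientDataError(
            f"{family} needs at least {p + 2} records, got {n}")
    X, resp = _design_and_response(d, y, family)
    res = sm.OLS(resp, sm.add_constant(X)).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
        f_pvalue = float(res.f_pvalue)
    if not np.isfinite(f_pvalue):  # perfect fit: zero residual variance
        f_pvalue = np.finfo(float).tiny if r2 > 0.999999 else 1.0
    return CurveFit(
        family=family,
        coefficients=_coefficients_from_params(family, res.params),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        p_value=f_pvalue,
        n=n,
        p_predictors=p,
        fit_space="log-response" if family in _LOG_RESPONSE else "raw",
    )


def fit_all(d, y, families=FAMILIES, on_zero: str = "error") -> list[CurveFit]:
    """Fit every applicable family; returns fits sorted by adj R^2 descending.

    Families whose domain constraints fail on these data are skipped with
    a logged reason rather than aborting the whole suite.
    """
    fits, skipped = [], []
    for family in families:
        try:
            fits.append(fit_family(d, y, family, on_zero=on_zero))
        except (FitDomainError, InsufficientDataError) as exc:
            skipped.append((family, str(exc)))
    for family, reason in skipped:
        logger.warning("family %s skipped: %s", family, reason)
    if not fits:
        raise FitDomainError(
            "no curve family is applicable to these data: "
            + "; ".join(f"{f}: {r}" for f, r in skipped))
    fits.sort(key=lambda f: -f.adj_r2)
    return fits


def select_best(fits: list[CurveFit]) -> CurveFit:
    """Pick the fit with maximal adjusted R^2.

    Ties break toward fewer predictors, then toward the fixed family
    order, so selection is fully deterministic.
    """
    if not fits:
        raise ContractError("select_best needs a nonempty fit list")
    return min(fits, key=lambda f: (-f.adj_r2, f.p_predictors,
                                    FAMILIES.index(f.family)))


def predict(fit: CurveFit, d) -> np.ndarray:
    """Evaluate the fitted functional form at distances d >= 0.

    For the singular forms (inverse, logarithmic, power) distances below
    a floor of 1e-6 x the median positive distance are raised to the
    floor, so the centroid pixel gets a finite, maximal prediction.
    Log-response families back-transform by exponentiation. Negative
    predictions are returned as-is; clamping to zero happens only when a
    map surface is produced.
    """
    d = np.asarray(d, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d).astype(float)
    if np.any(d < 0):
        raise ContractError("distances must be nonnegative")
    b = fit.coefficients
    if fit.family in _NEEDS_POSITIVE_D:
        d = np.maximum(d, _distance_floor(d))
    if fit.family == "linear":
        out = b[0] + b[1] * d
    elif fit.family == "logarithmic":
        out = b[0] + b[1] * np.log(d)
    elif fit.family == "inverse":
        out = b[0] + b[1] / d
    elif fit.family == "quadratic":
        out = b[0] + b[1] * d + b[2] * d**2
    elif fit.family == "cubic":
        out = b[0] + b[1] * d + b[2] * d**2 + b[3] * d**3
    elif fit.family == "power":
        out = b[0] * d ** b[1]
    elif fit.family == "growth":
        out = np.exp(b[0] + b[1] * d)
    elif fit.family == "exponential":
        out = b[0] * np.exp(b[1] * d)
    elif fit.family == "logistic":
        out = 1.0 / (b[0] * b[1] ** d)
    else:  # pragma: no cover - guarded in fit_family
        raise ContractError(f"unknown family {fit.family!r}")
    return float(out[0]) if scalar else out


def abundance_surface(fit: CurveFit, surface: DistanceSurface,
                      mask: DistributionMask) -> AbundanceSurface:
    """Project the fitted curve over the potential distribution.

    Predictions are made per valid masked pixel, negatives clamped to 0;
    pixels outside the mask carry NaN.
    """
    if not surface.spec.same_geometry(mask.spec):
        raise ContractError("distance surface and mask must share geometry")
    use = mask.values & surface.valid_mask
    out = np.full(surface.spec.shape, np.nan)
    d = surface.values[use]
    out[use] = np.maximum(predict(fit, d), 0.0)
    return AbundanceSurface(spec=surface.spec, values=out, valid_mask=use)


def fits_to_json(fits: list[CurveFit], path=None) -> str:
    """Serialize a list of fits (Table-2-style record per family)."""
    text = json.dumps([f.to_dict() for f in fits], indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def fits_report(fits: list[CurveFit]) -> str:
    """Plain-text goodness-of-fit table: family, R^2, adjusted R^2, p."""
    lines = [f"{'Model':<12} {'R2':>7} {'adj R2':>7} {'P-value':>9}"]
    for f in fits:
        p = "< 0.001" if f.p_value < 0.001 else f"{f.p_value:.3f}"
        lines.append(f"{f.family:<12} {f.r2:>7.3f} {f.adj_r2:>7.3f} {p:>9}")
    return "\n".join(lines)
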