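"""Mahalanobis-distance ecological niche model.

The niche centroid is the multivariate mean of the environmental
conditions observed at the species' occurrence sites; the covariance of
those conditions defines the metric. The distance of any pixel's
environment v to the centroid mu is

    d(v) = sqrt((v - mu)^T  Sigma^-1  (v - mu))

and the potential distribution is the environmental envelope of radius
d_max, the distance to the farthest occurrence: every pixel with
d <= d_max is inside. Because bioclimatic layers are strongly collinear,
the covariance is ridge-regularized when near-singular rather than
inverted blindly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractError, InsufficientDataError
from .io_geo import EnvStack, GridSpec

logger = logging.getLogger(__name__)

#: covariance condition number above which ridge regularization kicks in
CONDITION_LIMIT = 1e10
#: initial ridge strength, as a fraction of the mean covariance diagonal
RIDGE_EPS = 1e-8


@dataclass
class NicheModel:
    """Fitted niche centroid, covariance metric and envelope radius."""

    variable_names: list[str]
    centroid: np.ndarray
    covariance: np.ndarray
    precision: np.ndarray
    n_occurrences: int
    regularization_used: bool = False
    d_max: float | None = None
    squared: bool = False  # report squared distances instead of the root form

    @property
    def n_variables(self) -> int:
        return len(self.centroid)

    def to_json(self, path=None) -> str:
        doc = {
            "variable_names": list(self.variable_names),
            "centroid": self.centroid.tolist(),
            "covariance": self.covariance.tolist(),
            "d_max": self.d_max,
            "n_occurrences": self.n_occurrences,
            "regularization_used": self.regularization_used,
            "squared": self.squared,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "NicheModel":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        cov = np.asarray(doc["covariance"], dtype=float)
        precision, used = _invert_covariance(cov)
        return cls(
            variable_names=list(doc["variable_names"]),
            centroid=np.asarray(doc["centroid"], dtype=float),
            covariance=cov,
            precision=precision,
            n_occurrences=int(doc["n_occurrences"]),
            regularization_used=bool(doc["regularization_used"]) or used,
            d_max=doc.get("d_max"),
            squared=bool(doc.get("squared", False)),
        )


@dataclass
class DistanceSurface:
    """Per-pixel Mahalanobis distance to the niche centroid (dimensionless)."""

    spec: GridSpec
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.valid_mask.shape != self.spec.shape:
            raise ContractError("surface arrays must match the GridSpec shape")


@dataclass
class DistributionMask:
    """Boolean potential-distribution mask (True = inside the envelope)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.spec.shape:
            raise ContractError("mask must match the GridSpec shape")

    @property
    def n_inside(self) -> int:
        return int(self.values.sum())


def _invert_covariance(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert, ridge-regularizing near-singular covariance matrices.

    When cond(Sigma) > CONDITION_LIMIT, add eps*mean(diag(Sigma))*I with
    eps starting at RIDGE_EPS and escalating tenfold until the matrix is
    well-conditioned. Returns (precision, regularization_used).
    """
    cov = np.asarray(cov, dtype=float)
    scale = float(np.mean(np.diag(cov)))
    if scale <= 0:
        scale = 1.0
    eps = RIDGE_EPS
    work = cov
    used = False
    while True:
        cond = np.linalg.cond(work)
        if np.isfinite(cond) and cond <= CONDITION_LIMIT:
            break
        used = True
        work = cov + eps * scale * np.eye(cov.shape[0])
        eps *= 10.0
        if eps > 1.0:  # give up escalating; pseudo-inverse as last resort
            logger.warning("covariance irrecoverably singular; using pinv")
            return np.linalg.pinv(cov), True
    precision = np.linalg.inv(work)
    # symmetrize against fp drift
    precision = (precision + precision.T) / 2.0
    return precision, used


def fit_niche(env_matrix: np.ndarray,
              variable_names: list[str] | None = None,
              squared: bool = False) -> NicheModel:
    """Estimate centroid and covariance from n x P occurrence environments.

    The centroid is the per-variable arithmetic mean and the covariance
    the sample covariance (denominator n-1). Zero-variance variables are
    reported and handled through the same ridge path as collinearity.
    n >= P+1 is recommended for a full-rank covariance; n >= 2 is required.
    """
    env = np.asarray(env_matrix, dtype=float)
    if env.ndim != 2:
        raise ContractError("env_matrix must be 2-D (n points x P variables)")
    n, p = env.shape
    if n < 2:
        raise InsufficientDataError(f"need at least 2 occurrences, got {n}")
    names = list(variable_names) if variable_names is not None else [
        f"var_{i}" for i in range(p)
    ]
    if len(names) != p:
        raise ContractError("variable_names length must equal P")
    if n < p + 1:
        logger.warning("only %d occurrences for %d variables; covariance is "
                       "rank-deficient and will be regularized", n, p)
    centroid = env.mean(axis=0)
    cov = np.cov(env, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    zero_var = np.flatnonzero(np.diag(cov) <= 0)
    if zero_var.size:
        logger.warning("zero-variance variable(s): %s; treating as collinearity",
                       [names[i] for i in zero_var])
    precision, used = _invert_covariance(cov)
    return NicheModel(
        variable_names=names,
        centroid=centroid,
        covariance=cov,
        precision=precision,
        n_occurrences=n,
        regularization_used=used or zero_var.size > 0,
        squared=squared,
    )


def mahalanobis(model: NicheModel, v: np.ndarray) -> float:
    """Distance from one P-vector to the niche centroid.

    Returns the root form sqrt((v-mu)^T P (v-mu)); the squared form when
    the model was built with ``squared=True``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (model.n_variables,):
        raise ContractError(
            f"expected a vector of length {model.n_variables}, got shape {v.shape}"
        )
    diff = v - model.centroid
    q = float(diff @ model.precision @ diff)
    q = max(q, 0.0)  # clamp fp negatives near the centroid
    return q if model.squared else float(np.sqrt(q))


def distance_surface(model: NicheModel, stack: EnvStack) -> DistanceSurface:
    """Mahalanobis distance for every valid pixel of the stack.

    The stack's layer names and order must match the model's variables;
    invalid cells carry NaN.
    """
    if list(stack.layer_names) != list(model.variable_names):
        raise ContractError(
            f"stack layers {stack.layer_names} do not match model variables "
            f"{model.variable_names}"
        )
    p, nr, nc = stack.values.shape
    flat = stack.values.reshape(p, -1).T  # (npix, P)
    diff = flat - model.centroid
    q = np.einsum("ij,jk,ik->i", diff, model.precision, diff)
    np.maximum(q, 0.0, out=q)
    d = q if model.squared else np.sqrt(q)
    d = d.reshape(nr, nc)
    out = np.where(stack.valid_mask, d, np.nan)
    return DistanceSurface(spec=stack.spec, values=out,
                           valid_mask=stack.valid_mask.copy())


def envelope_radius(model: NicheModel, occ_matrix: np.ndarray) -> NicheModel:
    """Set d_max to the distance of the farthest occurrence (in place).

    The environmental envelope radius equals the maximal centroid-to-
    occurrence distance, so every fitting occurrence lies inside the
    resulting potential distribution by construction.
    """
    occ = np.asarray(occ_matrix, dtype=float)
    if occ.ndim != 2 or occ.shape[0] == 0:
        raise InsufficientDataError("occ_matrix must be a nonempty n x P matrix")
    dists = [mahalanobis(model, row) for row in occ]
    model.d_max = float(np.max(dists))
    return model


def potential_distribution(surface: DistanceSurface, d_max: float
                           ) -> DistributionMask:
    """Threshold the distance surface at the envelope radius (inclusive).

    A pixel is inside the potential distribution when it is valid and its
    distance is <= d_max.
    """
    if d_max is None or d_max < 0:
        raise ContractError(f"d_max must be a nonnegative real, got {d_max}")
    with np.errstate(invalid="ignore"):
        inside = surface.valid_mask & (surface.values <= d_max)
    return DistributionMask(spec=surface.spec, values=inside)


def apply_slope_filter(mask: DistributionMask, slope_layer: np.ndarray,
                       cutoff: float) -> DistributionMask:
    """Remove cells steeper than ``cutoff`` from the distribution mask.

    The species is absent from steep terrain, so pixels whose slope
    exceeds the cutoff are excluded; all other cells are unchanged. No
    default cutoff exists — the caller must choose one deliberately.
    """
    slope = np.asarray(slope_layer, dtype=float)
    if slope.shape != mask.spec.shape:
        raise ContractError("slope layer geometry does not match the mask")
    if not cutoff > 0:
        raise ContractError(f"slope cutoff must be > 0, got {cutoff}")
    keep = mask.values & ~(slope > cutoff)
    return DistributionMask(spec=mask.spec, values=keep)
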