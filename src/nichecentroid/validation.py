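"""Split validation, bootstrap uncertainty surfaces and decline statistics.

Predictive capacity of the selected abundance-distance model is
quantified two ways, both by repeated random train/test partitions of the
plot data (subsets drawn without replacement, following the split-based
resampling design rather than classical with-replacement bootstrap):

* **split_validate** — a 70/30 split repeated 10 times: refit the chosen
  family on the training fraction, predict the held-out plots, and
  regress observed on predicted abundance; the R^2 of that second
  regression measures predictive power.
* **bootstrap_uncertainty** — a 65/35 split repeated 1000 times: each
  refit predicts the whole pixel grid, yielding per-pixel standard
  deviation and 95% percentile bands (2.5th/97.5th of the per-pixel
  prediction distribution) for the uncertainty map. Coverage of held-out
  observations is scored, per iteration, against the 95% OLS prediction
  interval of the refitted regression (``ci_method="prediction"``, the
  default, which has nominal 95% coverage under a well-specified model)
  or against the per-plot percentile band (``ci_method="percentile"``).

The same family — selected once on the full data — is used in every
trial and iteration; selection is not repeated per split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import abundance as ab
from .errors import ContractError, FitDomainError, InsufficientDataError
from .niche import DistanceSurface, DistributionMask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Split validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-trial observed-vs-predicted regression statistics + summaries."""

    trials: pd.DataFrame  # columns: trial_id, r, r2, p_value, flagged
    train_fraction: float
    n_trials: int
    seed: int | None

    def _ok(self) -> pd.DataFrame:
        return self.trials[~self.trials["flagged"]]

    @property
    def summary(self) -> pd.DataFrame:
        ok = self._ok()[["r", "r2", "p_value"]]
        return pd.DataFrame(
            {
                "mean": ok.mean(),
                "sd": ok.std(ddof=1),
                "min": ok.min(),
                "max": ok.max(),
            }
        )

    @property
    def mean_r2(self) -> float:
        return float(self._ok()["r2"].mean())

    @property
    def sd_r2(self) -> float:
        return float(self._ok()["r2"].std(ddof=1))

    def to_csv(self, path) -> None:
        """Trial rows followed by Mean/SD/Min/Max summary rows."""
        body = self.trials[["trial_id", "r", "r2", "p_value"]].copy()
        s = self.summary
        rows = []
        for label, key in [("Mean", "mean"), ("Standard deviation", "sd"),
                           ("Minimum", "min"), ("Maximum", "max")]:
            rows.append({"trial_id": label, "r": s.loc["r", key],
                         "r2": s.loc["r2", key], "p_value": s.loc["p_value", key]})
        pd.concat([body, pd.DataFrame(rows)], ignore_index=True).to_csv(
            path, index=False)


def _split_sizes(n: int, train_fraction: float, p_predictors: int
                 ) -> tuple[int, int]:
    """Training size = round(f*n), forced to leave >= p+2 records per side."""
    lo = p_predictors + 2
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, lo), n - lo)
    if n_train < lo or n - n_train < lo:
        raise InsufficientDataError(
            f"n={n} cannot be split {train_fraction:.0%} leaving {lo} per side")
    return n_train, n - n_train


def split_validate(d, y, family: str, train_fraction: float = 0.70,
                   n_trials: int = 10, seed: int | None = None
                   ) -> ValidationReport:
    """Repeated random split validation of one curve family.

    Per trial: partition the plots, refit the family on the training
    part, predict the held-out part, then regress observed on predicted
    abundance and record (r, r2, p). Trials whose predictions are
    degenerate (constant) are flagged and excluded from the summaries.
    """
    d = np.asarray(d, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if d.shape != y.shape:
        raise ContractError("d and y must have the same length")
    n = d.size
    p = ab._N_PREDICTORS[family]
    n_train, _ = _split_sizes(n, train_fraction, p)
    rng = np.random.default_rng(seed)
    records = []
    for trial in range(1, n_trials + 1):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        fit = ab.fit_family(d[tr], y[tr], family)
        pred = ab.predict(fit, d[te])
        flagged = bool(np.ptp(pred) < 1e-12 or not np.all(np.isfinite(pred)))
        if flagged:
            logger.warning("trial %d: degenerate predictions; excluded", trial)
            r = r2 = pval = np.nan
        else:
            lr = scipy.stats.linregress(pred, y[te])
            r = float(lr.rvalue)
            r2 = r * r
            pval = float(lr.pvalue)
        records.append({"trial_id": trial, "r": r, "r2": r2,
                        "p_value": pval, "flagged": flagged})
    return ValidationReport(trials=pd.DataFrame(records),
                            train_fraction=train_fraction,
                            n_trials=n_trials, seed=seed)


# ---------------------------------------------------------------------------
# Bootstrap uncertainty
# ---------------------------------------------------------------------------


@dataclass
class UncertaintyResult:
    """Per-pixel bootstrap spread and held-out coverage."""

    sd_surface: np.ndarray | None
    ci_low_surface: np.ndarray | None
    ci_high_surface: np.ndarray | None
    coverage_pct: float
    n_iterations: int
    train_fraction: float
    seed: int | None
    ci_method: str
    n_redrawn: int = 0
    spec: object | None = None

    def manifest(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "ci_method": self.ci_method,
            "coverage_pct": self.coverage_pct,
            "n_redrawn": self.n_redrawn,
        }


def _prediction_interval_hits(d_train, y_train, d_test, y_test, family,
                              alpha=0.05):
    """Count held-out observations inside the refit's 95% prediction interval.

    The interval is built in the family's fitting (linearized) space and
    back-transformed for log-response families, where it maps
    monotonically onto the observation scale. Held-out zero counts cannot
    be scored in log space and are excluded from the tally for
    log-response families.
    """
    X_tr, resp_tr = ab._design_and_response(d_train, y_train, family)
    res = sm.OLS(resp_tr, sm.add_constant(X_tr)).fit()
    floor = ab._distance_floor(np.asarray(d_train, dtype=float))
    d_test = np.asarray(d_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if family in ab._LOG_RESPONSE:
        keep = y_test > 0
        d_test, y_test = d_test[keep], y_test[keep]
        if d_test.size == 0:
            return 0, 0
    X_te, resp_te = ab._design_and_response(d_test, y_test, family, floor=floor)
    frame = res.get_prediction(sm.add_constant(X_te, has_constant="add")
                               ).summary_frame(alpha=alpha)
    lo = frame["obs_ci_lower"].to_numpy()
    hi = frame["obs_ci_upper"].to_numpy()
    # fp tolerance so a noiseless fit (zero-width interval) still covers
    tol = 1e-8 * (1.0 + np.abs(resp_te))
    hits = int(np.sum((resp_te >= lo - tol) & (resp_te <= hi + tol)))
    return hits, len(resp_te)


def bootstrap_uncertainty(d, y, family: str,
                          distance_surface: DistanceSurface | None = None,
                          mask: DistributionMask | None = None,
                          n_iterations: int = 1000,
                          train_fraction: float = 0.65,
                          seed: int | None = None,
                          ci_method: str = "prediction",
                          max_redraws: int = 100) -> UncertaintyResult:
    """Split-based resampling of the abundance model.

    Each iteration draws a random 65/35 partition, refits the family on
    the training part and predicts the full pixel grid (when a distance
    surface is supplied) and the held-out plots. Per-pixel SD and
    percentile 95% bands summarize the prediction distribution;
    coverage_pct is the percentage of held-out observations inside their
    interval (see module docstring for the two ci_method choices).
    Iterations whose refit hits a domain violation are redrawn (count
    logged and reported).
    """
    if ci_method not in ("prediction", "percentile"):
        raise ContractError("ci_method must be 'prediction' or 'percentile'")
    d = np.asarray(d, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = d.size
    p = ab._N_PREDICTORS[family]
    n_train, _ = _split_sizes(n, train_fraction, p)
    rng = np.random.default_rng(seed)

    grid = None
    if distance_surface is not None:
        if mask is None:
            raise ContractError("a mask must accompany the distance surface")
        if not distance_surface.spec.same_geometry(mask.spec):
            raise ContractError("distance surface and mask must share geometry")
        use = mask.values & distance_surface.valid_mask
        d_grid = distance_surface.values[use]
        grid = np.empty((n_iterations, d_grid.size), dtype=np.float32)

    plot_preds = np.full((n_iterations, n), np.nan)  # held-out predictions
    held_out = np.zeros((n_iterations, n), dtype=bool)
    hits = total = 0
    n_redrawn = 0
    it = 0
    while it < n_iterations:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        try:
            fit = ab.fit_family(d[tr], y[tr], family)
            if ci_method == "prediction":
                h, t = _prediction_interval_hits(d[tr], y[tr], d[te], y[te],
                                                 family)
                hits += h
                total += t
        except (FitDomainError, InsufficientDataError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise
            continue
        if grid is not None:
            grid[it] = np.maximum(ab.predict(fit, d_grid), 0.0)
        plot_preds[it, te] = ab.predict(fit, d[te])
        held_out[it, te] = True
        it += 1
    if n_redrawn:
        logger.warning("%d iteration(s) redrawn after failed refits", n_redrawn)

    sd_s = lo_s = hi_s = None
    spec = None
    if grid is not None:
        spec = distance_surface.spec
        sd_flat = grid.std(axis=0, ddof=1)
        lo_flat = np.percentile(grid, 2.5, axis=0)
        hi_flat = np.percentile(grid, 97.5, axis=0)
        sd_s = np.full(spec.shape, np.nan)
        lo_s = np.full(spec.shape, np.nan)
        hi_s = np.full(spec.shape, np.nan)
        sd_s[use], lo_s[use], hi_s[use] = sd_flat, lo_flat, hi_flat

    if ci_method == "percentile":
        # per-plot band from the iterations in which the plot was held out
        for j in range(n):
            preds = plot_preds[held_out[:, j], j]
            if preds.size == 0:
                continue
            lo, hi = np.percentile(preds, [2.5, 97.5])
            inside = lo <= y[j] <= hi
            m = int(held_out[:, j].sum())
            hits += m if inside else 0
            total += m
    coverage = 100.0 * hits / total if total else float("nan")
    return UncertaintyResult(
        sd_surface=sd_s, ci_low_surface=lo_s, ci_high_surface=hi_s,
        coverage_pct=coverage, n_iterations=n_iterations,
        train_fraction=train_fraction, seed=seed, ci_method=ci_method,
        n_redrawn=n_redrawn, spec=spec)


# ---------------------------------------------------------------------------
# Decline arithmetic
# ---------------------------------------------------------------------------


class Decline(NamedTuple):
    """Percent decline between two census counts."""

    exact: float   # 100 * (past - present) / past
    percent: int   # rounded to the nearest integer percent


def percent_decline(past_count: int, present_count: int) -> Decline:
    """Percentage decline from a historical count to a present count.

    Returns both the exact value and its nearest-integer rounding, e.g.
    88 -> 8 individuals is a 90.909...% ~ 91% decline.
    """
    if past_count <= 0:
        raise ContractError(f"past_count must be positive, got {past_count}")
    if present_count < 0:
        raise ContractError("present_count must be nonnegative")
    exact = 100.0 * (past_count - present_count) / past_count
    return Decline(exact=exact, percent=int(round(exact)))
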