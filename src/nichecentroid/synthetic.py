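"""Seeded virtual species: landscapes, occurrences and abundance plots.

The generator produces the data-generating process the
distance-to-niche-centroid analysis assumes, with every knob explicit:

* P spatially autocorrelated environmental layers (Gaussian white noise
  smoothed with a kernel of width ``autocorrelation_length``, then
  affinely mixed so the pixel distribution has mean ``true_centroid``
  and covariance approximately ``true_covariance``);
* a true Mahalanobis distance surface computed from the *true*
  parameters, never from estimates;
* a true expected-density surface following the inverse law
  ``lambda(d) = max(0, b0 + b1 / max(d, eps))`` in burrows/km^2;
* occurrence points drawn without replacement with probability
  proportional to ``exp(-occurrence_decay * d)``, giving the
  center-weighted occurrence cloud a Mahalanobis niche fit assumes;
* abundance plots on distinct uniformly-drawn cells with Poisson (or
  rounded-Gaussian) counts around the true density.

Everything is bit-reproducible from (config, seed); each sampling role
uses its own child seed so results do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .io_geo import EnvStack, GridSpec, PointTable
from .niche import DistanceSurface, NicheModel, _invert_covariance, distance_surface

# child-seed roles so each artifact is reproducible independently
_ROLE_LANDSCAPE, _ROLE_OCCURRENCES, _ROLE_PLOTS = 11, 23, 37


@dataclass
class SyntheticConfig:
    """Full parameterization of a virtual landscape and its sampling.

    Defaults describe a paper-scale study system: a 200x200 ~1 km grid,
    four correlated environmental layers, 241 occurrences concentrated
    near the niche centroid, and 22 ~1 km^2 abundance plots with Poisson
    burrow counts in the 1-20 burrows/km^2 range.
    """

    n_rows: int = 200
    n_cols: int = 200
    n_layers: int = 4
    autocorrelation_length: float = 5.0
    true_centroid: np.ndarray | None = None      # default: zeros(P)
    true_covariance: np.ndarray | None = None    # default: 1 on diag, 0.3 off
    abundance_b0: float = 1.0
    abundance_b1: float = 25.0
    distance_floor: float = 0.5
    n_occurrences: int = 241
    n_plots: int = 22
    count_noise: str = "poisson"                 # or "gaussian"
    gaussian_sigma: float = 1.0
    occurrence_decay: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_rows, self.n_cols, self.n_layers,
               self.n_occurrences, self.n_plots) <= 0:
            raise ConfigError("all sizes must be positive")
        if not self.distance_floor > 0:
            raise ConfigError("distance_floor must be > 0")
        if self.count_noise not in ("poisson", "gaussian"):
            raise ConfigError("count_noise must be 'poisson' or 'gaussian'")
        if self.occurrence_decay < 0:
            raise ConfigError("occurrence_decay must be >= 0")
        p = self.n_layers
        if self.true_centroid is None:
            self.true_centroid = np.zeros(p)
        self.true_centroid = np.asarray(self.true_centroid, dtype=float)
        if self.true_centroid.shape != (p,):
            raise ConfigError("true_centroid must have length n_layers")
        if self.true_covariance is None:
            self.true_covariance = np.full((p, p), 0.3) + 0.7 * np.eye(p)
        self.true_covariance = np.asarray(self.true_covariance, dtype=float)
        if self.true_covariance.shape != (p, p):
            raise ConfigError("true_covariance must be n_layers x n_layers")
        if not np.allclose(self.true_covariance, self.true_covariance.T):
            raise ConfigError("true_covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.true_covariance)
        if np.min(eigvals) <= 0:
            raise ConfigError("true_covariance must be positive definite")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed,
                       true_centroid=self.true_centroid.copy(),
                       true_covariance=self.true_covariance.copy())

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "n_layers": self.n_layers,
            "autocorrelation_length": self.autocorrelation_length,
            "true_centroid": self.true_centroid.tolist(),
            "true_covariance": self.true_covariance.tolist(),
            "abundance_b0": self.abundance_b0,
            "abundance_b1": self.abundance_b1,
            "distance_floor": self.distance_floor,
            "n_occurrences": self.n_occurrences, "n_plots": self.n_plots,
            "count_noise": self.count_noise,
            "gaussian_sigma": self.gaussian_sigma,
            "occurrence_decay": self.occurrence_decay, "seed": self.seed,
        }


@dataclass
class TruthBundle:
    """The virtual landscape plus its known truth surfaces and samples."""

    config: SyntheticConfig
    stack: EnvStack
    true_distance: DistanceSurface
    true_lambda: np.ndarray
    occurrences: PointTable | None = None
    plots: PointTable | None = None


def _rng(config: SyntheticConfig, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, role]))


def true_niche_model(config: SyntheticConfig) -> NicheModel:
    """The generating niche model (true centroid and covariance)."""
    precision, _ = _invert_covariance(config.true_covariance)
    return NicheModel(
        variable_names=[f"env_{i:02d}" for i in range(config.n_layers)],
        centroid=config.true_centroid.copy(),
        covariance=config.true_covariance.copy(),
        precision=precision,
        n_occurrences=0,
    )


def gen_landscape(config: SyntheticConfig) -> EnvStack:
    """Generate the P-layer autocorrelated environmental stack.

    Independent white-noise fields are smoothed with a Gaussian kernel of
    sigma ``autocorrelation_length`` cells, standardized per layer, then
    linearly mixed through the Cholesky factor of ``true_covariance`` so
    the marginal pixel distribution matches the requested moments.
    """
    rng = _rng(config, _ROLE_LANDSCAPE)
    p, nr, nc = config.n_layers, config.n_rows, config.n_cols
    fields = rng.standard_normal((p, nr, nc))
    if config.autocorrelation_length > 0:
        fields = np.stack([
            ndimage.gaussian_filter(f, sigma=config.autocorrelation_length,
                                    mode="reflect")
            for f in fields
        ])
    # re-standardize: smoothing shrinks the marginal variance
    flat = fields.reshape(p, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1,
                                                                keepdims=True)
    chol = np.linalg.cholesky(config.true_covariance)
    mixed = (chol @ flat) + config.true_centroid[:, None]
    spec = GridSpec(n_rows=nr, n_cols=nc, x_origin=0.0, y_origin=float(nr),
                    cell_size=1.0, crs_id="synthetic-local")
    return EnvStack(
        spec=spec,
        layer_names=[f"env_{i:02d}" for i in range(p)],
        values=mixed.reshape(p, nr, nc),
        valid_mask=np.ones((nr, nc), dtype=bool),
    )


def gen_truth(config: SyntheticConfig, stack: EnvStack | None = None
              ) -> TruthBundle:
    """Compute the true distance and expected-density surfaces.

    Distances come from the *true* centroid/covariance; the expected
    density is ``max(0, b0 + b1 / max(d, distance_floor))``.
    """
    if stack is None:
        stack = gen_landscape(config)
    surf = distance_surface(true_niche_model(config), stack)
    lam = true_lambda_of(config, surf.values)
    return TruthBundle(config=config, stack=stack, true_distance=surf,
                       true_lambda=lam)


def true_lambda_of(config: SyntheticConfig, d) -> np.ndarray:
    """The generating inverse abundance law evaluated at distances d."""
    d = np.asarray(d, dtype=float)
    return np.maximum(
        0.0, config.abundance_b0
        + config.abundance_b1 / np.maximum(d, config.distance_floor))


def _cell_table(spec: GridSpec, rows, cols, prefix: str,
                counts=None) -> PointTable:
    xs, ys = [], []
    for r, c in zip(rows, cols):
        x, y = spec.cell_center(int(r), int(c))
        xs.append(x)
        ys.append(y)
    frame = pd.DataFrame({
        "id": [f"{prefix}_{i:04d}" for i in range(len(xs))],
        "x": xs, "y": ys,
    })
    if counts is not None:
        frame["count"] = np.asarray(counts, dtype=int)
    return PointTable(frame)


def sample_occurrences(bundle: TruthBundle,
                       config: SyntheticConfig | None = None) -> PointTable:
    """Draw occurrence cells without replacement, center-weighted.

    Cell probability is proportional to exp(-occurrence_decay * d); with
    decay 0 the draw is uniform over valid cells. Points sit at cell
    centers.
    """
    config = config or bundle.config
    rng = _rng(config, _ROLE_OCCURRENCES)
    mask = bundle.true_distance.valid_mask
    d = bundle.true_distance.values[mask]
    n_valid = d.size
    if config.n_occurrences > n_valid:
        raise ConfigError(
            f"n_occurrences={config.n_occurrences} exceeds {n_valid} valid cells")
    logw = -config.occurrence_decay * d
    w = np.exp(logw - logw.max())
    prob = w / w.sum()
    idx = rng.choice(n_valid, size=config.n_occurrences, replace=False, p=prob)
    rows, cols = np.nonzero(mask)
    return _cell_table(bundle.stack.spec, rows[idx], cols[idx], "occ")


def sample_plots(bundle: TruthBundle, config: SyntheticConfig | None = None,
                 stratify_distance: bool = False) -> PointTable:
    """Draw distinct plot cells and noisy burrow counts.

    Cells are uniform over the valid region (optionally stratified across
    distance quartiles so large distances are represented); counts are
    Poisson(lambda) or rounded Gaussian(lambda, sigma), clipped at 0.
    """
    config = config or bundle.config
    rng = _rng(config, _ROLE_PLOTS)
    mask = bundle.true_distance.valid_mask
    rows, cols = np.nonzero(mask)
    n_valid = rows.size
    if config.n_plots > n_valid:
        raise ConfigError(
            f"n_plots={config.n_plots} exceeds {n_valid} valid cells")
    if stratify_distance:
        d = bundle.true_distance.values[mask]
        strata = np.searchsorted(np.quantile(d, [0.25, 0.5, 0.75]), d)
        idx = []
        per = [config.n_plots // 4] * 4
        for k in range(config.n_plots % 4):
            per[k] += 1
        for s in range(4):
            pool = np.flatnonzero(strata == s)
            take = min(per[s], pool.size)
            idx.extend(rng.choice(pool, size=take, replace=False))
        idx = np.asarray(idx)
        if idx.size < config.n_plots:  # top up from the remainder
            rest = np.setdiff1d(np.arange(n_valid), idx)
            idx = np.concatenate([idx, rng.choice(
                rest, size=config.n_plots - idx.size, replace=False)])
    else:
        idx = rng.choice(n_valid, size=config.n_plots, replace=False)
    lam = bundle.true_lambda[rows[idx], cols[idx]]
    if config.count_noise == "poisson":
        counts = rng.poisson(lam)
    else:
        counts = np.maximum(
            0, np.round(rng.normal(lam, config.gaussian_sigma))).astype(int)
    return _cell_table(bundle.stack.spec, rows[idx], cols[idx], "plot",
                       counts=counts)


def simulate(config: SyntheticConfig) -> TruthBundle:
    """Full virtual-species draw: landscape, truth surfaces and samples."""
    bundle = gen_truth(config)
    bundle.occurrences = sample_occurrences(bundle)
    bundle.plots = sample_plots(bundle)
    return bundle


def paper_scale_config(seed: int = 0) -> SyntheticConfig:
    """A virtual species calibrated to the field study's statistical regime.

    22 plots, counts of roughly 1-20 burrows/km^2, and Poisson noise
    sized so a full-data inverse fit typically lands near adjusted
    R^2 ~ 0.68 — the regime in which split validation was reported.
    """
    return SyntheticConfig(seed=seed)


def recovery_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """A high-abundance virtual species for parameter-recovery benchmarks.

    With Poisson noise, relative count noise scales as 1/sqrt(lambda), so
    recovering an intercept to within 10% demands densities well above
    field scale; this config raises (b0, b1) until both coefficients are
    identifiable from 200 plots while keeping the same inverse law shape.
    The near-zero distance floor keeps the generating law exactly inverse
    over the sampled range.
    """
    return SyntheticConfig(seed=seed, abundance_b0=100.0, abundance_b1=150.0,
                           distance_floor=0.05, n_plots=200)
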