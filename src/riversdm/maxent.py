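"""L1-regularized maximum-entropy presence-background model.

The model estimates a Gibbs distribution over background cells,

    q(x) = exp(Σ_j λ_j f_j(x)) / Z,

chosen to maximize the penalized presence log-likelihood

    L(λ) = Σ_j λ_j f̄_j − ln Z(λ) − Σ_j β_j |λ_j|,

where f̄_j is the empirical mean of feature j over presence cells and Z
normalizes over the background.  At the optimum the KKT conditions give
the familiar relaxed mean-matching certificate

    |f̄_j − E_q f_j| ≤ β_j,   with equality whenever λ_j ≠ 0.

Features are expansions of the raw predictor layers — linear, quadratic,
pairwise products, hinge and threshold pieces at empirical quantile
knots, and indicator features for categorical codes — each min–max
scaled to [0, 1] on the background sample.  The per-feature penalties
default to β_j = β_multiplier · s_j · c(class) / √m with s_j the
feature's background standard deviation, m the presence count, and
c(class) a per-class constant (0.5 for hinge, 1.0 otherwise).

The logistic output p = q·e^H / (1 + q·e^H), with H the entropy of the
fitted q, maps the raw Gibbs density to an occurrence-probability-like
index in (0, 1) with default prevalence τ = 0.5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid import GridGeometry, Raster
from .stack import CATEGORICAL, CONTINUOUS, EnvStack, extract

__all__ = [
    "Feature", "FeatureSet", "MaxentModel", "SuitabilityMap",
    "build_features", "sample_background", "fit", "predict",
    "MaxentConvergenceError", "DEFAULT_CLASSES",
]

log = logging.getLogger(__name__)

DEFAULT_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold")

#: per-class regularization constants
_CLASS_CONSTANT = {"linear": 1.0, "quadratic": 1.0, "product": 1.0,
                   "hinge": 0.5, "threshold": 1.0, "category": 1.0}


class MaxentConvergenceError(RuntimeError):
    """Raised when the optimizer cannot certify the KKT conditions."""


@dataclass(frozen=True)
class Feature:
    """One feature: a transform of one or two raw predictor layers.

    ``kind`` is linear | quadratic | product | hinge | threshold |
    category.  ``knot`` is the hinge/threshold location; ``forward``
    distinguishes the two hinge orientations; ``code`` is the indicator
    code for categorical features; ``lo``/``hi`` are the layer's
    background range used by hinge normalization.
    """

    kind: str
    layer: str
    layer2: str | None = None
    knot: float | None = None
    forward: bool = True
    code: int | None = None
    lo: float | None = None
    hi: float | None = None

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.layer
        if self.kind == "quadratic":
            return f"{self.layer}^2"
        if self.kind == "product":
            return f"{self.layer}*{self.layer2}"
        if self.kind == "hinge":
            tag = "'" if self.forward else "`"
            return f"{tag}{self.layer}@{self.knot:.6g}"
        if self.kind == "threshold":
            return f"({self.layer}>{self.knot:.6g})"
        return f"{self.layer}=={self.code}"

    def raw(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.layer].to_numpy(dtype=float)
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x * x
        if self.kind == "product":
            return x * df[self.layer2].to_numpy(dtype=float)
        if self.kind == "hinge":
            if self.forward:
                span = self.hi - self.knot
                v = (x - self.knot) / span if span > 0 else np.zeros_like(x)
            else:
                span = self.knot - self.lo
                v = (self.knot - x) / span if span > 0 else np.zeros_like(x)
            return np.clip(v, 0.0, 1.0)
        if self.kind == "threshold":
            return (x > self.knot).astype(float)
        if self.kind == "category":
            return (x == self.code).astype(float)
        raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureSet:
    """Feature definitions plus background-fitted scaling and penalties."""

    features: list[Feature]
    scale_lo: np.ndarray          # per-feature min on background (raw scale)
    scale_hi: np.ndarray          # per-feature max on background
    beta: np.ndarray              # per-feature penalty β_j ≥ 0
    layer_names: list[str]        # raw layers the features consume

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def design_matrix(self, df: pd.DataFrame, clamp_log: bool = False) -> np.ndarray:
        """Scaled feature matrix in [0, 1], one row per point."""
        cols = []
        n_clamped = 0
        for j, feat in enumerate(self.features):
            v = feat.raw(df)
            lo, hi = self.scale_lo[j], self.scale_hi[j]
            if hi > lo:
                s = (v - lo) / (hi - lo)
            else:
                s = np.zeros_like(v)
            n_clamped += int(np.sum((s < 0) | (s > 1)))
            cols.append(np.clip(s, 0.0, 1.0))
        if clamp_log and n_clamped:
            log.info("clamped %d feature values outside the training range",
                     n_clamped)
        return np.column_stack(cols)


def _quantile_knots(values: np.ndarray, count: int) -> np.ndarray:
    """Interior equally-spaced empirical quantiles, deduplicated."""
    qs = np.linspace(0, 1, count + 2)[1:-1]
    return np.unique(np.quantile(values, qs))


def build_features(stack: EnvStack, presences: np.ndarray,
                   background: np.ndarray,
                   classes: tuple[str, ...] = DEFAULT_CLASSES,
                   hinge_knots: int = 50,
                   beta_multiplier: float = 1.0) -> FeatureSet:
    """Expand the stack's layers into a scaled, penalized feature set.

    Scaling and knots are fitted on the background sample; β penalties
    use the presence count m.  Constant layers (zero background range)
    contribute no features and are warned about.
    """
    bg = extract(stack, background)
    m = max(len(presences), 1)
    cont = [n for n in stack.names if stack.kinds[n] == CONTINUOUS]
    cat = [n for n in stack.names if stack.kinds[n] == CATEGORICAL]

    usable: list[str] = []
    for name in cont:
        v = bg[name].to_numpy(dtype=float)
        if np.nanmax(v) > np.nanmin(v):
            usable.append(name)
        else:
            warnings.warn(f"layer {name!r} is constant on the background; "
                          "its features are dropped")
    feats: list[Feature] = []
    for name in usable:
        v = bg[name].to_numpy(dtype=float)
        lo, hi = float(np.min(v)), float(np.max(v))
        if "linear" in classes:
            feats.append(Feature("linear", name))
        if "quadratic" in classes:
            feats.append(Feature("quadratic", name))
        if "hinge" in classes:
            for k in _quantile_knots(v, hinge_knots):
                if k < hi:
                    feats.append(Feature("hinge", name, knot=float(k),
                                         forward=True, lo=lo, hi=hi))
                if k > lo:
                    feats.append(Feature("hinge", name, knot=float(k),
                                         forward=False, lo=lo, hi=hi))
        if "threshold" in classes:
            for k in _quantile_knots(v, hinge_knots):
                if lo < k < hi:
                    feats.append(Feature("threshold", name, knot=float(k)))
    if "product" in classes:
        for i, a in enumerate(usable):
            for b in usable[i + 1:]:
                feats.append(Feature("product", a, layer2=b))
    for name in cat:
        codes = np.unique(bg[name].to_numpy())
        for code in codes:
            feats.append(Feature("category", name, code=int(code)))
    if not feats:
        raise ValueError("no usable features (all layers constant?)")

    raw = np.column_stack([f.raw(bg) for f in feats])
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    # hinge/threshold/category values are already in [0,1] by construction;
    # pin their scaling to the identity so knots keep their meaning
    for j, f in enumerate(feats):
        if f.kind in ("hinge", "threshold", "category"):
            lo[j], hi[j] = 0.0, 1.0
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (raw - lo) / span
    sd = scaled.std(axis=0)
    const = np.array([_CLASS_CONSTANT[f.kind] for f in feats])
    beta = beta_multiplier * sd * const / np.sqrt(m)
    layer_names = sorted({f.layer for f in feats}
                         | {f.layer2 for f in feats if f.layer2})
    return FeatureSet(feats, lo, hi, beta, layer_names)


def sample_background(stack: EnvStack, n: int, seed: int) -> np.ndarray:
    """Uniform sample of n valid cells without replacement.

    Presence cells are eligible.  If n is at least the number of valid
    cells, all valid cells are returned (deterministically, in row-major
    order).
    """
    cells = stack.valid_cells()
    if len(cells) == 0:
        raise ValueError("validity mask is empty")
    if n >= len(cells):
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return cells[np.sort(idx)]


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    Holds the feature set, the weight vector λ, the background cells and
    the fitted Gibbs distribution q over them, the log-partition ln Z,
    the entropy H of q, and the logistic prevalence τ.
    """

    features: FeatureSet
    lam: np.ndarray
    background: np.ndarray
    q_background: np.ndarray
    log_z: float
    entropy: float
    tau: float = 0.5
    kkt_gap: np.ndarray | None = None

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.features.design_matrix(df, clamp_log=True) @ self.lam

    def logistic(self, df: pd.DataFrame) -> np.ndarray:
        """p = q e^H / (1 + q e^H) with q normalized by the training Z."""
        log_qeh = self.linear_predictor(df) - self.log_z + self.entropy
        return 1.0 / (1.0 + np.exp(-log_qeh))

    def to_json(self) -> str:
        doc = {
            "lambda": self.lam.tolist(),
            "beta": self.features.beta.tolist(),
            "scale_lo": self.features.scale_lo.tolist(),
            "scale_hi": self.features.scale_hi.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "tau": self.tau,
            "features": [vars(f) | {"name": f.name} for f in self.features.features],
        }
        return json.dumps(doc, indent=2)

    def write_lambdas(self, path: str | Path) -> None:
        """Plain-text per-feature export: name, λ, scaling range, β."""
        with open(path, "w") as fh:
            for j, f in enumerate(self.features.features):
                fh.write(f"{f.name}, {self.lam[j]:.10g}, "
                         f"{self.features.scale_lo[j]:.10g}, "
                         f"{self.features.scale_hi[j]:.10g}, "
                         f"{self.features.beta[j]:.10g}\n")
            fh.write(f"logZ, {self.log_z:.10g}\n")
            fh.write(f"entropy, {self.entropy:.10g}\n")
            fh.write(f"tau, {self.tau:.10g}\n")


@dataclass
class SuitabilityMap:
    """Per-cell logistic suitability p ∈ (0, 1) on the analysis grid."""

    raster: Raster
    replicate: int | None = None

    @property
    def data(self) -> np.ndarray:
        return self.raster.data

    @property
    def geometry(self) -> GridGeometry:
        return self.raster.geometry


def fit(features: FeatureSet, presences: np.ndarray, background: np.ndarray,
        stack: EnvStack, beta_multiplier: float | None = None,
        tol: float = 1e-5, max_iter: int = 500) -> MaxentModel:
    """Maximize the L1-penalized presence log-likelihood.

    The non-smooth objective is solved by L-BFGS-B on the standard split
    λ = u − v with u, v ≥ 0, which turns the |λ| penalty into a linear
    term.  Convergence is certified by the KKT mean-matching conditions:
    |f̄_j − E_q f_j| ≤ β_j + tol for every feature.

    ``beta_multiplier`` rescales the feature set's β vector (None keeps
    it); presence cells must be at least 2 and lie on valid cells.
    """
    presences = np.asarray(presences, dtype=int)
    if len(presences) < 2:
        raise ValueError("need at least 2 presence cells")
    X_bg = features.design_matrix(extract(stack, background))
    X_pr = features.design_matrix(extract(stack, presences))
    emp = X_pr.mean(axis=0)
    beta = features.beta.copy()
    if beta_multiplier is not None:
        scale = beta_multiplier
        beta = beta * scale
    nJ = X_bg.shape[1]

    def objective(w: np.ndarray):
        u, v = w[:nJ], w[nJ:]
        lam = u - v
        eta = X_bg @ lam
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        mean_bg = q @ X_bg
        f = -(emp @ lam) + lz + beta @ (u + v)
        grad = np.concatenate([-emp + mean_bg + beta, emp - mean_bg + beta])
        return f, grad

    w0 = np.zeros(2 * nJ)
    # restarting L-BFGS-B from its own solution resets the Hessian memory
    # and polishes runs that stall just short of the KKT certificate
    for attempt in range(4):
        res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * nJ),
                       options={"maxiter": max(2000, max_iter),
                                "maxfun": 10 * max(2000, max_iter),
                                "ftol": 1e-15, "gtol": 1e-10})
        lam = res.x[:nJ] - res.x[nJ:]
        lam[np.abs(lam) < 1e-12] = 0.0
        eta = X_bg @ lam
        log_z = float(logsumexp(eta))
        q = np.exp(eta - log_z)
        mean_bg = q @ X_bg
        gap = np.abs(emp - mean_bg)
        viol = gap - beta
        if np.max(viol) <= max(10 * tol, 1e-4) / 2:
            break
        w0 = res.x
    if np.max(viol) > max(10 * tol, 1e-4):
        raise MaxentConvergenceError(
            f"KKT violation {np.max(viol):.3g} exceeds tolerance "
            f"(feature {features.names[int(np.argmax(viol))]!r})")
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxentModel(features, lam, np.asarray(background, dtype=int),
                       q, log_z, entropy, kkt_gap=gap)


def predict(model: MaxentModel, stack: EnvStack,
            output: str = "logistic", replicate: int | None = None
            ) -> SuitabilityMap:
    """Apply a fitted model to every valid cell of a stack.

    ``output="raw"`` gives the Gibbs density renormalized over the
    prediction region (sums to 1 there); ``output="logistic"`` gives
    p = q·e^H/(1+q·e^H) with q normalized by the *training* partition
    function, so predicting on the training background reproduces the
    training q exactly and a uniform (all-zero-weight) model yields
    p = τ = 0.5 everywhere.  Feature values outside the training range
    are clamped to [0, 1] after scaling (logged).
    """
    missing = [n for n in model.features.layer_names if n not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks layers required by the model: {missing}")
    cells = stack.valid_cells()
    if len(cells) == 0:
        raise ValueError("no valid cells to predict on")
    df = extract(stack, cells)
    grid = np.full(stack.geometry.shape, np.nan)
    if output == "raw":
        eta = model.linear_predictor(df)
        lz = logsumexp(eta)
        grid[cells[:, 0], cells[:, 1]] = np.exp(eta - lz)
    elif output == "logistic":
        grid[cells[:, 0], cells[:, 1]] = model.logistic(df)
    else:
        raise ValueError(f"unknown output {output!r}")
    return SuitabilityMap(Raster(grid, stack.geometry), replicate=replicate)
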