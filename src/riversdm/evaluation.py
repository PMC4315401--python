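"""Model evaluation: replicate AUC, jackknife, permutation importance.

Evaluation follows the usual presence-background protocol: occurrence
cells are split into training and test fractions (background shared
across replicates), a model is fitted per replicate, and discrimination
is scored by the rank-based AUC — the probability that a random
presence outranks a random background point, ties counting ½.

Variable importance comes in two flavours:

* jackknife — refit with each variable alone and with it withheld,
  reporting test AUC of each against the full model;
* permutation — shuffle one raw layer's values across the evaluation
  points, re-extract features, and measure the AUC drop; drops are
  floored at zero and normalized to sum to 100%.

Variables whose permutation importance falls below a threshold
(default 1%) can be pruned, and the model refitted on the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .grid import Raster
from .maxent import (FeatureSet, MaxentModel, SuitabilityMap, build_features,
                     fit, predict, DEFAULT_CLASSES)
from .stack import CATEGORICAL, EnvStack, extract

__all__ = [
    "EvaluationReport", "auc", "replicate_evaluation", "jackknife_auc",
    "permutation_importance", "prune_and_refit", "response_curve",
]

log = logging.getLogger(__name__)


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann–Whitney AUC of presences vs background pseudo-absences."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score groups must be non-empty")
    y = np.concatenate([np.ones(pres.size), np.zeros(bg.size)])
    s = np.concatenate([pres, bg])
    if np.all(s == s[0]):          # roc_auc_score is fine with ties but not
        return 0.5                 # with a single unique score level
    return float(roc_auc_score(y, s))


@dataclass
class EvaluationReport:
    """Replicate AUCs, their summary, and the averaged suitability map."""

    replicates: pd.DataFrame                 # columns: replicate, seed, train_auc, test_auc
    mean_train_auc: float
    sd_train_auc: float | None               # None when replicates == 1
    mean_test_auc: float
    sd_test_auc: float | None
    mean_map: SuitabilityMap
    models: list[MaxentModel] = field(default_factory=list, repr=False)

    def summary(self) -> str:
        sd_tr = f"{self.sd_train_auc:.4f}" if self.sd_train_auc is not None else "—"
        sd_te = f"{self.sd_test_auc:.4f}" if self.sd_test_auc is not None else "—"
        return (f"replicates: {len(self.replicates)}\n"
                f"training AUC: {self.mean_train_auc:.4f} (SD {sd_tr})\n"
                f"test AUC:     {self.mean_test_auc:.4f} (SD {sd_te})")

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def _model_scores(model: MaxentModel, stack: EnvStack,
                  cells: np.ndarray) -> np.ndarray:
    return model.logistic(extract(stack, cells))


def _fit_once(stack: EnvStack, presences: np.ndarray, background: np.ndarray,
              classes, hinge_knots, beta_multiplier, tol, max_iter
              ) -> MaxentModel:
    feats = build_features(stack, presences, background, classes=classes,
                           hinge_knots=hinge_knots,
                           beta_multiplier=beta_multiplier)
    return fit(feats, presences, background, stack, tol=tol,
               max_iter=max_iter)


def replicate_evaluation(presences: np.ndarray, stack: EnvStack,
                         background: np.ndarray,
                         train_fraction: float = 0.75,
                         replicates: int = 30, seed: int = 0,
                         classes: tuple[str, ...] = DEFAULT_CLASSES,
                         hinge_knots: int = 50,
                         beta_multiplier: float = 1.0,
                         tol: float = 1e-5, max_iter: int = 500,
                         keep_models: bool = True) -> EvaluationReport:
    """Random presence splits, one model per replicate, AUC summaries.

    The background is shared across replicates (splits are presence-only).
    The averaged suitability map — the cell-wise mean of the replicate
    logistic maps — is retained for downstream thresholding.
    """
    presences = np.asarray(presences, dtype=int)
    n = len(presences)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(f"{n} presences cannot support a "
                         f"{train_fraction:.0%} train split")
    rng = np.random.default_rng(seed)
    rows = []
    models: list[MaxentModel] = []
    sum_map = np.zeros(stack.geometry.shape)
    for rep in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        perm = rep_rng.permutation(n)
        train, test = presences[perm[:n_train]], presences[perm[n_train:]]
        try:
            model = _fit_once(stack, train, background, classes, hinge_knots,
                              beta_multiplier, tol, max_iter)
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} (seed {rep_seed}) failed: "
                               f"{exc}") from exc
        bg_scores = _model_scores(model, stack, background)
        train_auc = auc(_model_scores(model, stack, train), bg_scores)
        test_auc = auc(_model_scores(model, stack, test), bg_scores)
        rows.append({"replicate": rep, "seed": rep_seed,
                     "train_auc": train_auc, "test_auc": test_auc})
        smap = predict(model, stack, output="logistic", replicate=rep)
        sum_map += np.nan_to_num(smap.data, nan=0.0)
        if keep_models:
            models.append(model)
    df = pd.DataFrame(rows)
    mean_data = sum_map / replicates
    mean_data[~stack.validity_mask] = np.nan
    mean_map = SuitabilityMap(Raster(mean_data, stack.geometry))
    one = replicates == 1
    return EvaluationReport(
        replicates=df,
        mean_train_auc=float(df["train_auc"].mean()),
        sd_train_auc=None if one else float(df["train_auc"].std(ddof=1)),
        mean_test_auc=float(df["test_auc"].mean()),
        sd_test_auc=None if one else float(df["test_auc"].std(ddof=1)),
        mean_map=mean_map, models=models)


def jackknife_auc(presences: np.ndarray, stack: EnvStack,
                  background: np.ndarray, variables: list[str] | None = None,
                  train_fraction: float = 0.75, seed: int = 0,
                  **fit_kwargs) -> pd.DataFrame:
    """Per-variable 'only' and 'without' test AUC under one fixed split.

    Returns a DataFrame with columns variable, auc_only, auc_without,
    plus a final row ``__full__`` holding the full-model reference AUC.
    """
    variables = list(variables) if variables is not None else stack.names
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    presences = np.asarray(presences, dtype=int)
    n = len(presences)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train, test = presences[perm[:n_train]], presences[perm[n_train:]]

    def test_auc_on(sub: EnvStack) -> float:
        model = _fit_once(sub, train, background,
                          fit_kwargs.get("classes", DEFAULT_CLASSES),
                          fit_kwargs.get("hinge_knots", 50),
                          fit_kwargs.get("beta_multiplier", 1.0),
                          fit_kwargs.get("tol", 1e-5),
                          fit_kwargs.get("max_iter", 500))
        bg_scores = _model_scores(model, sub, background)
        return auc(_model_scores(model, sub, test), bg_scores)

    rows = []
    for v in variables:
        rows.append({"variable": v,
                     "auc_only": test_auc_on(stack.subset([v])),
                     "auc_without": test_auc_on(
                         stack.subset([w for w in variables if w != v]))})
    full = test_auc_on(stack.subset(variables))
    rows.append({"variable": "__full__", "auc_only": full,
                 "auc_without": full})
    return pd.DataFrame(rows)


def permutation_importance(model: MaxentModel, presences: np.ndarray,
                           background: np.ndarray, stack: EnvStack,
                           seed: int = 0) -> pd.DataFrame:
    """AUC drop when one raw layer is shuffled across evaluation points.

    The permutation acts on the layer's values at the combined
    presence + background points; features are re-extracted from the
    permuted values, so importance reflects the variable rather than any
    single feature.  Drops are floored at 0 and normalized to 100%.
    """
    presences = np.asarray(presences, dtype=int)
    background = np.asarray(background, dtype=int)
    pts = np.vstack([presences, background])
    df = extract(stack, pts)
    n_pres = len(presences)
    scores = model.logistic(df)
    base = auc(scores[:n_pres], scores[n_pres:])
    rng = np.random.default_rng(seed)
    drops = {}
    for v in model.features.layer_names:
        perm_df = df.copy()
        perm_df[v] = rng.permutation(perm_df[v].to_numpy())
        s = model.logistic(perm_df)
        drops[v] = max(0.0, base - auc(s[:n_pres], s[n_pres:]))
    total = sum(drops.values())
    rows = [{"variable": v,
             "auc_drop": d,
             "importance_pct": (100.0 * d / total) if total > 0 else 0.0}
            for v, d in drops.items()]
    return pd.DataFrame(rows)


def prune_and_refit(presences: np.ndarray, stack: EnvStack,
                    background: np.ndarray, threshold_pct: float = 1.0,
                    seed: int = 0, classes: tuple[str, ...] = DEFAULT_CLASSES,
                    hinge_knots: int = 50, beta_multiplier: float = 1.0,
                    tol: float = 1e-5, max_iter: int = 500
                    ) -> tuple[EnvStack, MaxentModel, pd.DataFrame]:
    """Drop variables with permutation importance below ``threshold_pct``
    and refit on the remainder.

    Returns (pruned stack, refitted model, importance table with a
    ``pruned`` column).  A threshold of 0 never removes anything; it is
    an error for pruning to remove every variable.
    """
    presences = np.asarray(presences, dtype=int)
    model = _fit_once(stack, presences, background, classes, hinge_knots,
                      beta_multiplier, tol, max_iter)
    imp = permutation_importance(model, presences, background, stack,
                                 seed=seed)
    imp["pruned"] = (imp["importance_pct"] < threshold_pct) & (threshold_pct > 0)
    drop = imp.loc[imp["pruned"], "variable"].tolist()
    if len(drop) == len(imp):
        raise ValueError("pruning would remove every variable; "
                         f"importances:\n{imp}")
    if not drop:
        return stack, model, imp
    pruned = stack.drop(drop)
    log.info("pruned variables below %.2f%%: %s", threshold_pct, drop)
    refit = _fit_once(pruned, presences, background, classes, hinge_knots,
                      beta_multiplier, tol, max_iter)
    return pruned, refit, imp


def response_curve(models: list[MaxentModel] | MaxentModel, variable: str,
                   stack: EnvStack, background: np.ndarray,
                   grid_points: int = 100) -> pd.DataFrame:
    """Partial response of logistic output to one variable.

    The variable sweeps its background range at ``grid_points`` values
    while the other layers sit at their background means (categorical at
    the mode); mean and SD are taken across the replicate models.
    Returns a DataFrame (value, mean_p, sd_p).
    """
    if isinstance(models, MaxentModel):
        models = [models]
    ref = models[0]
    if variable not in ref.features.layer_names:
        raise KeyError(f"variable {variable!r} not in model")
    bg = extract(stack, background)
    base = {}
    for name in ref.features.layer_names:
        col = bg[name]
        if stack.kinds[name] == CATEGORICAL:
            base[name] = float(col.mode().iloc[0])
        else:
            base[name] = float(col.mean())
    lo, hi = float(bg[variable].min()), float(bg[variable].max())
    values = np.linspace(lo, hi, grid_points)
    sweep = pd.DataFrame({name: np.full(grid_points, val)
                          for name, val in base.items()})
    sweep[variable] = values
    preds = np.stack([m.logistic(sweep) for m in models])
    return pd.DataFrame({
        "value": values,
        "mean_p": preds.mean(axis=0),
        "sd_p": preds.std(axis=0, ddof=1) if len(models) > 1
                else np.zeros(grid_points),
    })
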