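"""Feature selection and model fitting for typability indices.

Re-implements the three-stage pipeline used to build the published index,
so it can be refit on any scored corpus:

* **Stage 1** — a random-forest regression over all candidate variables;
  for each text/key attribute with several calculation variants, keep the
  variant with the highest permutation importance (% increase in MSE).
* **Stage 2** — remove exactly collinear (singular) variables and then
  iteratively remove variables with variance inflation factor (VIF) above
  threshold, dropping the least important member of each problematic group.
* **Stage 3** — a fresh random forest over the survivors; keep the top
  variables up to the inflection point ("elbow") of the sorted importance
  curve, fit ordinary least squares, and prune non-significant predictors
  one at a time (least significant first, refitting) until all p < alpha.

Importance is permutation importance expressed as percent increase in the
forest's mean squared error; the elbow rule is the position of the largest
drop between consecutive sorted importances (ties to the smaller count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .scoring import LinearIndexModel

__all__ = [
    "TrainConfig",
    "ImportanceTable",
    "FitSummary",
    "SelectionReport",
    "ValidationResult",
    "rf_importance",
    "best_variant_per_attribute",
    "inflection_count",
    "vif_filter",
    "fit_linear",
    "run_three_stage",
    "validate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Random-forest and selection hyperparameters.

    Defaults: 500 trees with one third of the variables tried per split
    (the regression convention), 5 permutation repeats, VIF threshold 10,
    significance threshold 0.05.
    """

    n_trees: int = 500
    max_features: float = 1 / 3
    n_permutation_repeats: int = 5
    vif_threshold: float = 10.0
    alpha: float = 0.05
    min_items: int = 50
    seed: int = 0


@dataclass
class ImportanceTable:
    """Permutation importance (% increase in MSE) per candidate variable."""

    pct_inc_mse: pd.Series  # variable -> % Inc MSE
    n_trees: int
    seed: int

    def ranked(self) -> pd.Series:
        return self.pct_inc_mse.sort_values(ascending=False, kind="stable")


@dataclass
class FitSummary:
    """OLS fit: per-predictor B, SE, t, p and standardised beta, plus fit stats."""

    predictors: list[str]
    B: pd.Series
    SE: pd.Series
    t: pd.Series
    p: pd.Series
    beta: pd.Series  # standardised coefficients
    intercept: float
    intercept_se: float
    adj_r2: float
    r2: float
    rmse: float
    aic: float
    n: int
    aic_convention: str = "statsmodels Gaussian log-likelihood"


@dataclass
class SelectionReport:
    """Audit trail of the three-stage selection: what was kept/removed and why."""

    events: list[dict] = field(default_factory=list)

    def add(self, stage: str, variable: str, action: str, reason: str, value: float | None = None):
        self.events.append(
            {"stage": stage, "variable": variable, "action": action, "reason": reason, "value": value}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["stage", "variable", "action", "reason", "value"])

    def removed(self, stage: str | None = None) -> list[str]:
        return [
            e["variable"]
            for e in self.events
            if e["action"] == "removed" and (stage is None or e["stage"] == stage)
        ]


@dataclass(frozen=True)
class ValidationResult:
    """Out-of-sample predictive performance and calibration diagnostics."""

    r2: float
    adj_r2: float
    rmse: float
    slope: float
    intercept: float
    n: int


def _check_matrix(features: pd.DataFrame, target: pd.Series | np.ndarray) -> None:
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValueError(f"feature matrix contains missing values in {bad}")
    if np.asarray(target).ndim != 1 or len(target) != len(features):
        raise ValueError("target must be one value per feature row")


def rf_importance(
    features: pd.DataFrame, target: pd.Series | np.ndarray, config: TrainConfig | None = None
) -> ImportanceTable:
    """Out-of-bag permutation importance from a random-forest regression.

    For each tree, each variable is permuted within the tree's out-of-bag
    sample and the increase in that tree's OOB MSE recorded; importance is
    the tree-averaged increase as a percent of the mean OOB MSE (% Inc
    MSE).  Using OOB rather than training predictions keeps pure-noise
    variables near zero even though the forest interpolates its training
    data.  Reproducible given ``config.seed``.
    """
    from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

    config = config or TrainConfig()
    _check_matrix(features, target)
    if len(features) < config.min_items:
        raise ValueError(f"need >= {config.min_items} items, got {len(features)}")
    y = np.asarray(target, dtype=float)
    X = features.values.astype(np.float64)
    n = len(y)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=config.seed,
        bootstrap=True,
        n_jobs=1,
    ).fit(X, y)
    rng = np.random.default_rng(config.seed)
    n_bootstrap = _get_n_samples_bootstrap(n, None, None)
    p = X.shape[1]
    increases = np.zeros(p)
    oob_mses = []
    n_trees_used = 0
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_bootstrap, None)
        if len(oob) < 2:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        oob_mses.append(base)
        n_trees_used += 1
        for j in range(p):
            X_perm = X_oob.copy()
            for _ in range(config.n_permutation_repeats):
                X_perm[:, j] = X_oob[rng.permutation(len(oob)), j]
                perm_mse = float(np.mean((tree.predict(X_perm) - y_oob) ** 2))
                increases[j] += (perm_mse - base) / config.n_permutation_repeats
    if not n_trees_used:
        raise ValueError("no tree had an out-of-bag sample; cannot compute importances")
    denom = float(np.mean(oob_mses)) or 1.0
    pct = pd.Series(increases / n_trees_used / denom * 100.0, index=features.columns)
    return ImportanceTable(pct_inc_mse=pct, n_trees=config.n_trees, seed=config.seed)


def best_variant_per_attribute(
    importances: ImportanceTable, attribute_map: dict[str, str]
) -> list[str]:
    """Keep the most important calculation variant of each attribute.

    ``attribute_map`` maps variable -> attribute; single-variant attributes
    are kept regardless of rank.  Returns variables in importance order.
    """
    unmapped = [v for v in importances.pct_inc_mse.index if v not in attribute_map]
    if unmapped:
        raise ValueError(f"variables missing from attribute_map: {unmapped}")
    ranked = importances.ranked()
    kept: dict[str, str] = {}  # attribute -> best variable
    for variable in ranked.index:
        attr = attribute_map[variable]
        kept.setdefault(attr, variable)
    return [v for v in ranked.index if v in kept.values()]


def inflection_count(importances: ImportanceTable) -> int:
    """Predictor count at the inflection point of the sorted importance curve.

    Sort importances descending and return the position of the largest
    drop between consecutive values; ties break to the smaller count.  A
    flat (no-elbow) curve returns 1 with a warning.
    """
    ranked = importances.ranked()
    if len(ranked) < 3:
        raise ValueError(f"need >= 3 variables to locate an inflection, got {len(ranked)}")
    drops = -np.diff(ranked.values)
    best = int(np.argmax(drops))  # argmax takes the first (smaller count) on ties
    if np.allclose(drops, drops[0]):
        warnings.warn(
            "importance curve has no clear inflection (uniform decay); using the smallest count",
            stacklevel=2,
        )
        return 1
    return best + 1


def _vif_table(X: pd.DataFrame) -> pd.Series:
    design = sm.add_constant(X.values.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vifs = [variance_inflation_factor(design, i + 1) for i in range(X.shape[1])]
    return pd.Series(vifs, index=X.columns)


def _singular_groups(X: pd.DataFrame, tol: float = 1e-10) -> list[str]:
    """Variables involved in exact linear dependencies, via the design-matrix null space."""
    arr = X.values.astype(float)
    arr = np.column_stack([np.ones(len(arr)), arr])
    _, s, vt = np.linalg.svd(arr - arr.mean(axis=0), full_matrices=False)
    null = vt[s < tol * max(s[0], 1.0)]
    involved: list[str] = []
    for row in null:
        for j, col in enumerate(X.columns):
            if abs(row[j + 1]) > 1e-6 and col not in involved:
                involved.append(col)
    return involved


def vif_filter(
    features: pd.DataFrame,
    threshold: float = 10.0,
    importances: ImportanceTable | None = None,
    report: SelectionReport | None = None,
    stage: str = "stage2",
) -> tuple[list[str], pd.Series]:
    """Iteratively remove collinear variables until all VIF <= threshold.

    Exact linear dependencies (singularity) are resolved first; within each
    problematic group the variable with the lowest importance is removed
    (alphabetical last resort when no importances are given).  Returns the
    removed variables and the final VIF table.
    """
    if len(features) <= features.shape[1]:
        raise ValueError("need more items than variables to estimate VIFs")
    X = features.copy()
    removed: list[str] = []

    def least_important(candidates: list[str]) -> str:
        if importances is not None:
            ranked = importances.pct_inc_mse
            return min(candidates, key=lambda v: (ranked.get(v, -np.inf), v))
        return sorted(candidates)[-1]

    # exact singularity first
    while True:
        group = _singular_groups(X)
        if not group:
            break
        victim = least_important(group)
        X = X.drop(columns=victim)
        removed.append(victim)
        if report is not None:
            report.add(stage, victim, "removed", "singular (exact linear dependency)")
        if X.shape[1] == 0:
            raise ValueError("all variables removed as singular; degenerate design")
    # then high VIF
    while True:
        vifs = _vif_table(X)
        over = vifs[vifs > threshold]
        if over.empty:
            break
        victim = least_important(list(over.index))
        X = X.drop(columns=victim)
        removed.append(victim)
        if report is not None:
            report.add(stage, victim, "removed", f"VIF {over[victim]:.2f} > {threshold}", float(over[victim]))
        if X.shape[1] == 0:
            raise ValueError("all variables removed by the VIF filter; degenerate design")
    return removed, _vif_table(X) if X.shape[1] else pd.Series(dtype=float)


def fit_linear(features: pd.DataFrame, target: pd.Series | np.ndarray) -> FitSummary:
    """Ordinary least squares with standardised and unstandardised coefficients.

    Standardised betas come from a second fit on z-scored predictors and
    target (sample SDs), so the identity ``beta = B * SD(x) / SD(y)`` holds
    and can be cross-checked.  RMSE is the root mean squared residual; AIC
    uses the statsmodels Gaussian convention (recorded in the summary).
    """
    _check_matrix(features, target)
    y = np.asarray(target, dtype=float)
    n, p = features.shape
    if n <= p + 1:
        raise ValueError(f"need n > predictors + 1 (n={n}, predictors={p})")
    design = sm.add_constant(features.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        raise ValueError("rank-deficient design matrix; remove collinear variables first")
    model = sm.OLS(y, design).fit()
    B = model.params.drop("const")
    sd_y = float(np.std(y, ddof=1))
    z_x = (features - features.mean()) / features.std(ddof=1)
    z_y = (y - y.mean()) / sd_y
    z_fit = sm.OLS(z_y, sm.add_constant(z_x.astype(float), has_constant="add")).fit()
    beta = z_fit.params.drop("const")
    residuals = y - model.predict(design)
    return FitSummary(
        predictors=list(features.columns),
        B=B,
        SE=model.bse.drop("const"),
        t=model.tvalues.drop("const"),
        p=model.pvalues.drop("const"),
        beta=beta,
        intercept=float(model.params["const"]),
        intercept_se=float(model.bse["const"]),
        adj_r2=float(model.rsquared_adj),
        r2=float(model.rsquared),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        aic=float(model.aic),
        n=n,
    )


def run_three_stage(
    features: pd.DataFrame,
    target: pd.Series | np.ndarray,
    attribute_map: dict[str, str],
    config: TrainConfig | None = None,
    model_name: str = "refit_typability_index",
) -> tuple[LinearIndexModel, SelectionReport]:
    """Full selection pipeline: variant choice, collinearity removal, elbow
    selection, OLS, and stepwise significance pruning.

    Returns the final model (intercept-only, with a warning, if nothing
    survives pruning) and the complete audit trail.
    """
    config = config or TrainConfig()
    report = SelectionReport()
    y = np.asarray(target, dtype=float)

    # Stage 1: most explanatory calculation variant per attribute
    imp1 = rf_importance(features, y, config)
    survivors = best_variant_per_attribute(imp1, attribute_map)
    for v in features.columns:
        if v in survivors:
            report.add("stage1", v, "retained", "best (or only) variant of its attribute", float(imp1.pct_inc_mse[v]))
        else:
            report.add("stage1", v, "removed", "variant-inferior", float(imp1.pct_inc_mse[v]))

    # Stage 2: singularity and multicollinearity removal
    X2 = features[survivors]
    imp2 = rf_importance(X2, y, config)
    elbow2 = inflection_count(imp2)
    report.add("stage2", "(all)", "info", f"inflection point of stage-2 importance curve at {elbow2} predictors", float(elbow2))
    removed2, _ = vif_filter(X2, config.vif_threshold, imp2, report, stage="stage2")
    survivors = [v for v in survivors if v not in removed2]
    for v in survivors:
        report.add("stage2", v, "retained", f"VIF <= {config.vif_threshold}")

    # Stage 3: elbow selection on the survivors, OLS, significance pruning
    X3 = features[survivors]
    imp3 = rf_importance(X3, y, config)
    n_keep = inflection_count(imp3)
    ranked3 = imp3.ranked()
    selected = list(ranked3.index[:n_keep])
    for v in survivors:
        if v in selected:
            report.add("stage3", v, "retained", f"within top {n_keep} at the inflection point", float(ranked3[v]))
        else:
            report.add("stage3", v, "removed", "sub-inflection importance", float(ranked3[v]))
    removed3, _ = vif_filter(X3[selected], config.vif_threshold, imp3, report, stage="stage3") if selected else ([], None)
    selected = [v for v in selected if v not in removed3]

    while selected:
        fit = fit_linear(features[selected], y)
        worst = fit.p.idxmax()
        if fit.p[worst] < config.alpha:
            break
        report.add("stage3", worst, "removed", f"non-significant (p = {fit.p[worst]:.4f} >= {config.alpha})", float(fit.p[worst]))
        selected.remove(worst)

    if not selected:
        warnings.warn("no predictor survived selection; returning an intercept-only model", stacklevel=2)
        model = LinearIndexModel(
            name=model_name,
            intercept=float(np.mean(y)),
            coefficients={},
            standardized_coefficients={},
            notes={"warning": "intercept-only: no significant predictors"},
        )
        return model, report

    fit = fit_linear(features[selected], y)
    model = LinearIndexModel(
        name=model_name,
        intercept=fit.intercept,
        coefficients={v: float(fit.B[v]) for v in selected},
        standardized_coefficients={v: float(fit.beta[v]) for v in selected},
        notes={
            "adj_r2": f"{fit.adj_r2:.6f}",
            "rmse": f"{fit.rmse:.6f}",
            "aic": f"{fit.aic:.4f} ({fit.aic_convention})",
            "n": str(fit.n),
            "rf": f"{config.n_trees} trees, max_features={config.max_features}, seed={config.seed}",
        },
    )
    return model, report


def validate(
    model: LinearIndexModel, features: pd.DataFrame, target: pd.Series | np.ndarray
) -> ValidationResult:
    """Predict-and-compare on held-out data.

    Regresses actual typability on the model's predictions; slope and
    intercept diagnose calibration shifts (slope 1, intercept 0 = perfectly
    calibrated).  RMSE is of raw predictions against the target.
    """
    missing = [v for v in model.coefficients if v not in features.columns]
    if missing:
        raise KeyError(f"validation features are missing {missing}")
    y = np.asarray(target, dtype=float)
    preds = model.intercept + features[list(model.coefficients)].values @ np.array(
        list(model.coefficients.values())
    )
    design = sm.add_constant(preds)
    fit = sm.OLS(y, design).fit()
    return ValidationResult(
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        rmse=float(np.sqrt(np.mean((preds - y) ** 2))),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=len(y),
    )
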