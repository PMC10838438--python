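"""Sex-interaction modelling and WAIC model comparison.

Vocal physiology differs by sex, most visibly in fundamental-frequency and
harmonicity measures, so the classifier is refit with sex-by-feature
interaction terms for the F0 and HNR feature subsets and compared to the
no-interaction model with the Watanabe-Akaike information criterion
(WAIC = -2 * (lppd - p_waic)). Both compared models carry the sex main
effect, so the comparison isolates the interactions. The simpler model is
retained unless the interaction model's WAIC is lower by more than twice
the standard error of the pointwise difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .manifest import FeatureManifest, load_manifest
from .model import (
    ModelConfig,
    PosteriorFit,
    fit_lasso_logistic,
    make_splits,
    select_contrast,
    standardize_features,
)

__all__ = [
    "WaicResult",
    "WaicComparison",
    "build_interaction_design",
    "compute_waic",
    "compare_interaction_models",
]

#: "substantially better" = WAIC lower by more than this many SEs of the
#: pointwise difference
SUBSTANTIALITY_SE_MULTIPLE = 2.0


def encode_sex(sex: pd.Series | np.ndarray) -> np.ndarray:
    """Map sex labels to 0 = female, 1 = male."""
    mapping = {"F": 0, "M": 1, "f": 0, "m": 1, 0: 0, 1: 1, 0.0: 0, 1.0: 1}
    out = []
    for v in np.asarray(sex):
        key = v.item() if hasattr(v, "item") else v
        if key not in mapping:
            raise ValueError(f"unknown sex value {v!r}; expected F/M or 0/1")
        out.append(mapping[key])
    return np.asarray(out, dtype=np.float64)


def build_interaction_design(
    X: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    manifest: FeatureManifest | None = None,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Append the sex main effect and, optionally, sex x feature products.

    ``X`` must be standardized; interaction columns are the elementwise
    product of the sex indicator (0 = female, 1 = male) with the
    standardized F0 and designated HNR columns, named ``sex_x_<feature>``.
    """
    manifest = manifest or load_manifest()
    s = encode_sex(sex)
    if s.size != len(X):
        raise ValueError("sex must be known for every row")
    out = X.copy()
    out["sex"] = s
    if include_interactions:
        for name in manifest.interaction_features():
            if name in X.columns:
                out[f"sex_x_{name}"] = s * X[name].to_numpy()
    return out


@dataclass(frozen=True)
class WaicResult:
    """WAIC decomposition for one fitted model."""

    waic: float                  # -2 * (lppd - p_waic), lower is better
    lppd: float
    p_waic: float
    pointwise_elpd: np.ndarray   # per-observation lppd_i - p_waic_i
    se: float                    # SE of WAIC itself


def compute_waic(fit: PosteriorFit | np.ndarray) -> WaicResult:
    """WAIC from the pointwise log-likelihood matrix (draws x n).

    lppd_i = log mean_s exp(ll_si); p_waic_i = var_s(ll_si); WAIC on the
    deviance scale is -2 * sum_i (lppd_i - p_waic_i).
    """
    ll = fit.log_lik if isinstance(fit, PosteriorFit) else np.asarray(fit)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws x n) log-likelihood matrix with >= 2 draws")
    S, n = ll.shape
    from scipy.special import logsumexp

    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = np.var(ll, axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic = -2.0 * float(np.sum(elpd_i))
    se = 2.0 * float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(waic, float(np.sum(lppd_i)), float(np.sum(p_i)), elpd_i, se)


@dataclass(frozen=True)
class WaicComparison:
    """WAIC comparison of the interaction vs no-interaction model."""

    waic_base: float
    waic_interaction: float
    delta: float                 # waic_base - waic_interaction (>0 favours interaction)
    se_delta: float              # SE of the pointwise difference (deviance scale)
    decision: str                # "retain simpler" | "prefer interaction"

    def to_dict(self) -> dict:
        return {
            "waic_base": round(self.waic_base, 4),
            "waic_inter": round(self.waic_interaction, 4),
            "delta": round(self.delta, 4),
            "se": round(self.se_delta, 4),
            "decision": self.decision,
        }


def compare_waic(base: WaicResult, interaction: WaicResult) -> WaicComparison:
    """Decide between models; ties and small differences keep the simpler one."""
    diff_i = base.pointwise_elpd - interaction.pointwise_elpd
    n = diff_i.size
    se_delta = 2.0 * float(np.sqrt(n * np.var(diff_i, ddof=1))) if n > 1 else 0.0
    delta = base.waic - interaction.waic
    prefer = delta > SUBSTANTIALITY_SE_MULTIPLE * se_delta and delta > 0
    return WaicComparison(
        waic_base=base.waic,
        waic_interaction=interaction.waic,
        delta=delta,
        se_delta=se_delta,
        decision="prefer interaction" if prefer else "retain simpler",
    )


def compare_interaction_models(
    table: pd.DataFrame,
    cfg: ModelConfig | None = None,
    contrast: str = "control_vs_als",
    manifest: FeatureManifest | None = None,
    n_reps: int = 10,
    seed: int = 0,
) -> dict:
    """Fit both models on each training split and compare WAIC per fold.

    Returns per-fold comparisons plus the majority verdict ("retain
    simpler" unless most folds substantially prefer the interaction model).
    """
    cfg = cfg or ModelConfig()
    manifest = manifest or load_manifest()
    sub, y = select_contrast(table, contrast)
    sex = encode_sex(sub["sex"])
    X_all = sub[list(manifest.names)]
    plans = make_splits(y, n_reps=n_reps, seed=seed)

    folds = []
    prefer_count = 0
    for plan in plans:
        train_X, _, scaler = standardize_features(
            X_all.iloc[plan.train_idx], X_all.iloc[plan.test_idx]
        )
        s_train = pd.Series(sex[plan.train_idx], index=train_X.index)
        X_base = build_interaction_design(train_X, s_train, manifest,
                                          include_interactions=False)
        X_inter = build_interaction_design(train_X, s_train, manifest,
                                           include_interactions=True)
        y_train = y[plan.train_idx]
        fit_base = fit_lasso_logistic(X_base, y_train, cfg, seed=plan.seed)
        fit_inter = fit_lasso_logistic(X_inter, y_train, cfg, seed=plan.seed)
        cmp = compare_waic(compute_waic(fit_base), compute_waic(fit_inter))
        folds.append({
            "rep": plan.rep,
            **cmp.to_dict(),
            "converged": bool(fit_base.converged and fit_inter.converged),
        })
        if cmp.decision == "prefer interaction":
            prefer_count += 1
    verdict = (
        "prefer interaction" if prefer_count > len(folds) / 2 else "retain simpler"
    )
    return {"folds": folds, "verdict": verdict,
            "prefer_interaction_folds": prefer_count, "n_folds": len(folds)}
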