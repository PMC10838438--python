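"""Bayesian LASSO logistic classification with repeated-split evaluation.

The classifier is a logistic regression with a standard Normal N(0, 1)
prior on the intercept and a sparsity-inducing Laplace L(0, 0.5) prior on
each of the J feature coefficients (the Bayesian LASSO); labels follow a
Bernoulli likelihood through the logistic link. Evaluation mirrors the
clinical protocol: ten repeated, class-stratified pseudorandom 50/50
train/test splits, features standardized (and missing values imputed by
medians) using training data only, AUROC on each held-out half, and
per-feature posterior-median coefficients aggregated by their median
across splits.

Class 1 is always the less-impaired group (controls against patients,
early-stage against late-stage), so a positive aggregated coefficient
means the less-impaired group has the higher feature value.

Sampling uses Hamiltonian Monte Carlo with a diagonal mass matrix taken
from the curvature at the L1-regularized maximum a-posteriori solution and
a dual-averaged step size; the posterior is log-concave, so HMC mixes
rapidly. Convergence is checked with rank-normalized split-R-hat across
chains.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .manifest import FeatureManifest, load_manifest

__all__ = [
    "ModelConfig",
    "PosteriorFit",
    "SplitPlan",
    "ComparisonResult",
    "CONTRASTS",
    "stratify_cohort",
    "make_splits",
    "standardize_features",
    "fit_lasso_logistic",
    "predict_probability",
    "compute_auroc",
    "run_binary_comparison",
    "aggregate_coefficients",
]

#: contrast name -> (class-0 stratum, class-1 stratum); class 1 = less impaired
CONTRASTS: dict[str, tuple[str, str]] = {
    "control_vs_als": ("ALS", "control"),
    "control_vs_alse": ("ALS-E", "control"),
    "alse_vs_alsl": ("ALS-L", "ALS-E"),
}

FRS_EARLY_CUTOFF = 11.0  # score >= 11 of 12 -> early (less impaired) stratum


@dataclass(frozen=True)
class ModelConfig:
    """Priors and sampler settings for the Bayesian logistic model."""

    coef_prior: str = "laplace"      # "laplace" (LASSO) or "normal"
    laplace_scale: float = 0.5       # b of L(0, b)
    normal_sd: float = 1.0           # sd of N(0, sd^2) alternative prior
    intercept_sd: float = 1.0
    chains: int = 4
    warmup: int = 500                # adaptation iterations, discarded
    draws: int = 500                 # kept iterations per chain
    max_stored_draws: int = 4000
    rhat_threshold: float = 1.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coef_prior not in ("laplace", "normal"):
            raise ValueError("coef_prior must be 'laplace' or 'normal'")
        if min(self.laplace_scale, self.normal_sd, self.intercept_sd) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SplitPlan:
    """One repetition of the 50/50 train/test protocol."""

    rep: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class ScalerRecord:
    """Train-split standardization constants (audit trail included)."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...]
    medians: np.ndarray          # train medians used for imputation
    train_hash: str              # sha256 of the raw train block


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one fitted fold."""

    alpha: np.ndarray            # (S,)
    beta: np.ndarray             # (S, J)
    feature_names: tuple[str, ...]
    log_lik: np.ndarray          # (S, n) pointwise log-likelihood
    max_rhat: float
    converged: bool
    config: ModelConfig

    @property
    def beta_median(self) -> np.ndarray:
        return np.median(self.beta, axis=0)


def stratify_cohort(table: pd.DataFrame) -> pd.Series:
    """Assign each subject to control / ALS-E / ALS-L / ALS-unknown.

    Patients with bulbar score >= 11 of 12 are early-stage (ALS-E), below
    11 late-stage (ALS-L); patients missing the score are retained only for
    the control-vs-all-patients contrast.
    """
    frs = pd.to_numeric(table["frs_bulb"], errors="coerce")
    bad = frs.dropna()
    if ((bad < 0) | (bad > 12)).any():
        raise ValueError("frs_bulb values must lie in [0, 12]")
    out = []
    for grp, score in zip(table["group"], frs):
        if str(grp).lower() == "control":
            out.append("control")
        elif np.isnan(score):
            out.append("ALS-unknown")
        elif score >= FRS_EARLY_CUTOFF:
            out.append("ALS-E")
        else:
            out.append("ALS-L")
    return pd.Series(out, index=table.index, name="stratum")


def make_splits(
    labels: Sequence[int] | np.ndarray,
    n_reps: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> list[SplitPlan]:
    """Class-stratified repeated random 50/50 partitions.

    Every class appears in both halves of every repetition; |train| and
    |test| differ by at most one. Reproducible from the master seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.min(counts) < 2:
        raise ValueError("every class needs >= 2 members to appear in both halves")
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    plans = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        train, test = [], []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            if train_fraction == 0.5:
                # odd classes alternate their extra subject so the overall
                # halves stay within one of each other
                k = idx.size // 2
                if idx.size % 2 == 1 and len(train) <= len(test):
                    k += 1
            else:
                k = int(round(train_fraction * idx.size))
            k = min(max(k, 1), idx.size - 1)
            train.extend(idx[:k])
            test.extend(idx[k:])
        plans.append(SplitPlan(
            rep=rep,
            train_idx=np.sort(np.asarray(train)),
            test_idx=np.sort(np.asarray(test)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return plans


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a, dtype=np.float64).tobytes()).hexdigest()


def standardize_features(
    train_X: pd.DataFrame, test_X: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, ScalerRecord]:
    """Center/scale both blocks with train-split mean and variance.

    Missing entries are imputed with train-column medians first; columns
    with zero train variance (or no observed train values) are dropped from
    both blocks and recorded.
    """
    train_X = train_X.copy()
    test_X = test_X.copy()
    medians = train_X.median(axis=0)
    train_X = train_X.fillna(medians)
    test_X = test_X.fillna(medians)

    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0, ddof=0)
    keep = [c for c in train_X.columns if np.isfinite(sds[c]) and sds[c] > 0]
    dropped = tuple(c for c in train_X.columns if c not in keep)
    record = ScalerRecord(
        columns=tuple(keep),
        means=means[keep].to_numpy(),
        sds=sds[keep].to_numpy(),
        dropped=dropped,
        medians=medians[keep].to_numpy(),
        train_hash=_hash_array(train_X.to_numpy()),
    )
    train_t = (train_X[keep] - means[keep]) / sds[keep]
    test_t = (test_X[keep] - means[keep]) / sds[keep]
    return train_t, test_t, record


def _log_posterior_factory(X: np.ndarray, y: np.ndarray, cfg: ModelConfig):
    """Vectorized log posterior and gradient over chain batches (C, 1 + J)."""
    from scipy.special import expit

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        alpha = theta[:, 0]
        beta = theta[:, 1:]
        z = alpha[None, :] + X @ beta.T                      # (n, C)
        ll = np.sum(y[:, None] * z - np.logaddexp(0.0, z), axis=0)
        lp = -0.5 * (alpha / cfg.intercept_sd) ** 2
        if cfg.coef_prior == "laplace":
            lp = lp - np.sum(np.abs(beta), axis=1) / cfg.laplace_scale
        else:
            lp = lp - 0.5 * np.sum(beta**2, axis=1) / cfg.normal_sd**2
        return ll + lp

    def grad(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        alpha = theta[:, 0]
        beta = theta[:, 1:]
        z = alpha[None, :] + X @ beta.T                      # (n, C)
        resid = y[:, None] - expit(z)                        # (n, C)
        g = np.empty_like(theta)
        g[:, 0] = resid.sum(axis=0) - alpha / cfg.intercept_sd**2
        g[:, 1:] = resid.T @ X
        if cfg.coef_prior == "laplace":
            g[:, 1:] -= np.sign(beta) / cfg.laplace_scale
        else:
            g[:, 1:] -= beta / cfg.normal_sd**2
        return g

    return log_prob, grad


def _map_estimate(X: np.ndarray, y: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """L1/L2-regularized point estimate used to initialize the walkers."""
    from sklearn.linear_model import LogisticRegression

    if cfg.coef_prior == "laplace":
        est = LogisticRegression(penalty="l1", C=cfg.laplace_scale,
                                 solver="liblinear", max_iter=2000,
                                 random_state=0)
    else:
        est = LogisticRegression(penalty="l2", C=cfg.normal_sd**2,
                                 solver="lbfgs", max_iter=2000)
    est.fit(X, y)
    return np.concatenate([est.intercept_, est.coef_.ravel()])


def _split_rhat(chain: np.ndarray) -> float:
    """Max rank-normalized split-R-hat over parameters.

    ``chain`` has shape (iterations, chains, ndim).
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = np.moveaxis(chain, 1, 0)          # (chain, draw, ndim)
        rh = az.rhat(az.convert_to_dataset(data))
        return float(np.nanmax(rh["x"].values))


def _hmc_sample(
    log_prob,
    grad,
    init: np.ndarray,
    mass: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
) -> np.ndarray:
    """Preconditioned HMC over a batch of chains; returns (draws, C, D).

    Leapfrog integration with a diagonal mass matrix and dual-averaging
    step-size adaptation during warmup; trajectory lengths are jittered to
    avoid resonances. All chains advance in lock-step through batched
    matrix products.
    """
    C, D = init.shape
    theta = init.copy()
    logp = log_prob(theta)

    # two warmup windows: the first adapts the step size under the initial
    # (curvature-based) mass, the second re-adapts after the mass is reset
    # to the inverse warmup-draw variances, which repairs directions whose
    # width the initial curvature estimate missed
    w1 = warmup // 2
    phases = [(w1, False), (warmup - w1, False), (draws, True)]
    mass = mass.copy()
    out = np.empty((draws, C, D))
    window: list[np.ndarray] = []
    eps = 0.2

    for phase, (length, sampling) in enumerate(phases):
        inv_mass = 1.0 / mass
        sqrt_mass = np.sqrt(mass)
        mu, h_bar, log_eps_bar = np.log(10.0 * eps), 0.0, np.log(eps)
        gamma, t0, kappa = 0.05, 10.0, 0.75
        for t in range(length):
            p0 = sqrt_mass[None, :] * rng.standard_normal((C, D))
            theta_new, p = theta.copy(), p0.copy()
            n_leap = int(rng.integers(12, 25))
            g = grad(theta_new)
            for _ in range(n_leap):
                p = p + 0.5 * eps * g
                theta_new = theta_new + eps * inv_mass[None, :] * p
                g = grad(theta_new)
                p = p + 0.5 * eps * g
            logp_new = log_prob(theta_new)
            delta_h = (
                logp_new - logp
                - 0.5 * np.sum(inv_mass[None, :] * (p**2 - p0**2), axis=1)
            )
            delta_h = np.where(np.isfinite(delta_h), delta_h, -np.inf)
            accept_prob = np.minimum(1.0, np.exp(np.minimum(delta_h, 0.0)))
            accepted = rng.random(C) < accept_prob
            theta[accepted] = theta_new[accepted]
            logp = np.where(accepted, logp_new, logp)

            if sampling:
                out[t] = theta
            else:
                it = t + 1
                h_bar = (1 - 1 / (it + t0)) * h_bar + (
                    target_accept - float(np.mean(accept_prob))
                ) / (it + t0)
                log_eps = mu - np.sqrt(it) / gamma * h_bar
                w = it ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
                if phase == 0 and t >= length // 2:
                    window.append(theta.copy())
        eps = float(np.exp(log_eps_bar)) if not sampling else eps
        if phase == 0 and window:
            var = np.var(np.concatenate(window, axis=0), axis=0)
            mass = 1.0 / np.maximum(var, 1e-8)
    return out


def fit_lasso_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    cfg: ModelConfig | None = None,
    feature_names: Sequence[str] | None = None,
    seed: int | None = None,
) -> PosteriorFit:
    """Sample the Bayesian (LASSO) logistic posterior.

    ``X`` must already be standardized; ``y`` is binary with class 1 the
    less-impaired group. If the split-R-hat convergence gate fails, the
    sampler is rerun once with doubled warmup and draws; a fit that still
    fails is returned with ``converged=False`` so callers can drop the
    fold.
    """
    cfg = cfg or ModelConfig()
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        feature_names = tuple(feature_names or (f"x{j}" for j in range(X.shape[1])))
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, J = X.shape
    ndim = 1 + J
    run_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)

    log_prob, grad = _log_posterior_factory(X, y, cfg)
    theta0 = _map_estimate(X, y, cfg)

    # diagonal mass = posterior curvature estimate at the MAP: Bernoulli
    # Fisher information plus the prior's (Gaussianized) precision
    from scipy.special import expit

    p_hat = expit(theta0[0] + X @ theta0[1:])
    wts = p_hat * (1.0 - p_hat)
    fisher = np.empty(ndim)
    fisher[0] = np.sum(wts) + 1.0 / cfg.intercept_sd**2
    prior_prec = (
        2.0 / cfg.laplace_scale**2
        if cfg.coef_prior == "laplace"
        else 1.0 / cfg.normal_sd**2
    )
    fisher[1:] = (wts[:, None] * X**2).sum(axis=0) + prior_prec
    scale = 1.0 / np.sqrt(fisher)   # approximate posterior sd per parameter

    def run(warmup: int, draws: int) -> np.ndarray:
        init = theta0[None, :] + scale[None, :] * rng.standard_normal(
            (cfg.chains, ndim)
        )
        return _hmc_sample(log_prob, grad, init, fisher, warmup, draws, rng)

    chain = run(cfg.warmup, cfg.draws)
    max_rhat = _split_rhat(chain)
    converged = max_rhat < cfg.rhat_threshold
    if not converged:  # one retry with a longer run
        chain = run(2 * cfg.warmup, 2 * cfg.draws)
        max_rhat = _split_rhat(chain)
        converged = max_rhat < cfg.rhat_threshold

    flat = chain.reshape(-1, ndim)
    if flat.shape[0] > cfg.max_stored_draws:
        step = flat.shape[0] // cfg.max_stored_draws
        flat = flat[::step][: cfg.max_stored_draws]
    alpha, beta = flat[:, 0], flat[:, 1:]
    z = alpha[:, None] + beta @ X.T                          # (S, n)
    log_lik = y[None, :] * z - np.logaddexp(0.0, z)
    return PosteriorFit(alpha, beta, feature_names, log_lik,
                        max_rhat, converged, cfg)


def predict_probability(fit: PosteriorFit, X_new: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Posterior-mean probability of class 1 for each row."""
    if isinstance(X_new, pd.DataFrame):
        if tuple(X_new.columns) != fit.feature_names:
            raise ValueError("columns of X_new do not match the fitted design")
        X_new = X_new.to_numpy(dtype=np.float64)
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.shape[1] != fit.beta.shape[1]:
        raise ValueError("X_new column count does not match the fitted design")
    z = fit.alpha[None, :] + X_new @ fit.beta.T              # (n, S)
    from scipy.special import expit

    return np.mean(expit(z), axis=1)


def compute_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC (Mann-Whitney formulation, ties at 0.5); NaN if one class."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        return float("nan")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


@dataclass
class ComparisonResult:
    """Repeated-split evaluation of one binary contrast."""

    contrast: str
    fold_aurocs: list[float]
    auroc_mean: float
    auroc_sd: float
    median_coefficients: pd.Series      # per-feature median of fold medians
    fold_coefficients: pd.DataFrame     # features x folds
    fold_records: list[dict]            # split/scaler audit trail
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_subjects": self.n_subjects,
            "fold_aurocs": [round(a, 6) for a in self.fold_aurocs],
            "auroc_mean": round(self.auroc_mean, 6),
            "auroc_sd": round(self.auroc_sd, 6),
            "coefficients": {
                k: (None if not np.isfinite(v) else round(float(v), 6))
                for k, v in self.median_coefficients.items()
            },
        }


def aggregate_coefficients(fold_coefficients: pd.DataFrame) -> pd.Series:
    """Median across folds of each feature's posterior-median coefficient."""
    return fold_coefficients.median(axis=1, skipna=True)


def select_contrast(
    table: pd.DataFrame, contrast: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Rows and 0/1 labels (1 = less impaired) for a named contrast."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {list(CONTRASTS)}")
    strata = stratify_cohort(table)
    neg, pos = CONTRASTS[contrast]
    if contrast == "control_vs_als":
        mask = strata.isin(["control"]) | table["group"].eq("ALS")
        y = strata.eq("control").astype(int).to_numpy()[mask.to_numpy()]
    else:
        mask = strata.isin([neg, pos])
        y = strata[mask].eq(pos).astype(int).to_numpy()
    sub = table.loc[mask.to_numpy()].reset_index(drop=True)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"contrast {contrast!r} needs both classes present")
    return sub, y


def run_binary_comparison(
    table: pd.DataFrame,
    contrast: str,
    cfg: ModelConfig | None = None,
    manifest: FeatureManifest | None = None,
    n_reps: int = 10,
    seed: int = 0,
) -> ComparisonResult:
    """Full repeated-split protocol for one contrast.

    For each of the ten 50/50 splits: impute missing features with train
    medians, standardize with train statistics, sample the posterior, score
    the held-out half and record AUROC plus the fold's posterior-median
    coefficients. Non-converged folds are dropped (and reported).
    """
    cfg = cfg or ModelConfig()
    manifest = manifest or load_manifest()
    sub, y = select_contrast(table, contrast)
    X_all = sub[list(manifest.names)]
    plans = make_splits(y, n_reps=n_reps, seed=seed)

    aurocs: list[float] = []
    fold_coefs = pd.DataFrame(index=list(manifest.names))
    records: list[dict] = []
    for plan in plans:
        train_X, test_X, scaler = standardize_features(
            X_all.iloc[plan.train_idx], X_all.iloc[plan.test_idx]
        )
        fit = fit_lasso_logistic(train_X, y[plan.train_idx], cfg, seed=plan.seed)
        rec = {
            "rep": plan.rep,
            "train_idx": plan.train_idx.tolist(),
            "test_idx": plan.test_idx.tolist(),
            "train_hash": scaler.train_hash,
            "dropped": list(scaler.dropped),
            "max_rhat": fit.max_rhat,
            "converged": fit.converged,
        }
        records.append(rec)
        if not fit.converged:
            continue
        scores = predict_probability(fit, test_X)
        auroc = compute_auroc(scores, y[plan.test_idx])
        aurocs.append(auroc)
        rec["scores"] = scores.tolist()
        rec["labels"] = y[plan.test_idx].tolist()
        coefs = pd.Series(np.nan, index=list(manifest.names))
        coefs[list(scaler.columns)] = fit.beta_median
        fold_coefs[f"fold_{plan.rep}"] = coefs
        rec["auroc"] = auroc

    if not aurocs:
        raise RuntimeError(f"no fold of contrast {contrast!r} converged")
    return ComparisonResult(
        contrast=contrast,
        fold_aurocs=aurocs,
        auroc_mean=float(np.mean(aurocs)),
        auroc_sd=float(np.std(aurocs, ddof=1)) if len(aurocs) > 1 else 0.0,
        median_coefficients=aggregate_coefficients(fold_coefs),
        fold_coefficients=fold_coefs,
        fold_records=records,
        n_subjects=int(y.size),
    )
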