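"""Behavioral decoding from communication-subspace activity.

Features are the aligned and local projections of the top canonical pairs
(default 10 of each, 20 columns).  Binary behaviors (correct/error,
outbound/inbound, left/right) use Bernoulli regression; continuous
behaviors (velocity, acceleration, linearized position, IdPhi) use a
robust Student-t regression (ν = 4) that tolerates outliers.  Fits are
deterministic penalized maximum likelihood via iteratively reweighted
least squares; coefficient intervals come from the asymptotic covariance.

Also here: the behavior-vs-theta mixed model comparison for the top shared
component, per-epoch rhythm-coupling regressions, and high/low-state
density contrasts of the shared axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from . import stats as ncstats
from .cca import SharedLocalSeries
from .windows import WindowSet

TRAIN_BINS_DEFAULT = 50_000
CONTINUOUS_FAMILIES = ("gaussian", "robust_t")


@dataclass
class FeatureMatrix:
    """T × 2k feature matrix: aligned_1..k then local_1..k."""

    values: np.ndarray
    names: list[str]
    times: np.ndarray

    @property
    def aligned_cols(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n.startswith("aligned")]

    @property
    def local_cols(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n.startswith("local")]


@dataclass
class GlmFit:
    """A fitted behavior model with held-out performance."""

    family: str
    coef: np.ndarray  # includes intercept as element 0
    coef_lo: np.ndarray
    coef_hi: np.ndarray
    feature_names: list[str]
    heldout_metric: float  # R² (continuous) or F1 (binary)
    metric_name: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    n_iter: int
    converged: bool


def build_features(sl: SharedLocalSeries, k: int = 10) -> FeatureMatrix:
    """Top-k aligned then top-k local components as decoding features."""
    if sl.k < k:
        raise ValueError(f"only {sl.k} components available, need {k}")
    values = np.hstack([sl.aligned[:, :k], sl.local[:, :k]])
    names = [f"aligned_{i+1}" for i in range(k)] + [f"local_{i+1}" for i in range(k)]
    return FeatureMatrix(values=values, names=names, times=sl.times)


# ---------------------------------------------------------------------------
# IRLS fitting


def _irls_bernoulli(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                    max_iter: int = 100, tol: float = 1e-10):
    beta = np.zeros(X.shape[1])
    for it in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        xtwx = X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1])
        new = np.linalg.solve(xtwx, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            return new, xtwx, it + 1, True
        beta = new
    return beta, xtwx, max_iter, False


def _irls_student_t(X: np.ndarray, y: np.ndarray, nu: float = 4.0,
                    ridge: float = 1e-8, max_iter: int = 200, tol: float = 1e-10):
    """EM/IRLS for linear regression with Student-t errors (fixed ν)."""
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    s2 = max(resid.var(), 1e-12)
    for it in range(max_iter):
        resid = y - X @ beta
        w = (nu + 1.0) / (nu + resid**2 / s2)
        xtwx = X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1])
        new = np.linalg.solve(xtwx, X.T @ (w * y))
        s2_new = max(float(np.mean(w * (y - X @ new) ** 2)), 1e-12)
        if np.max(np.abs(new - beta)) < tol and abs(s2_new - s2) < tol * max(s2, 1.0):
            beta, s2 = new, s2_new
            return beta, xtwx / s2, it + 1, True
        beta, s2 = new, s2_new
    return beta, xtwx / s2, max_iter, False


def _ols(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8):
    xtx = X.T @ X + ridge * np.eye(X.shape[1])
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    return beta, xtx / max(s2, 1e-12), 1, True


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def fit_behavior_glm(
    features: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    family: str = "robust_t",
    feature_names: list[str] | None = None,
    train_bins: int = TRAIN_BINS_DEFAULT,
    seed: int = 0,
    sampler: str = "mle",
) -> GlmFit:
    """Fit one behavior model and score it on held-out bins.

    ``train_bins`` random bins train the model (70% of the data when fewer
    exist); the remainder is held out.  Continuous families report held-out
    R², the Bernoulli family reports F1 at a 0.5 threshold.  Coefficient
    95% intervals come from the asymptotic inverse Fisher information.
    """
    if sampler != "mle":
        raise NotImplementedError(
            "only the deterministic penalized-MLE sampler is implemented"
        )
    if isinstance(features, FeatureMatrix):
        feature_names = features.names
        features = features.values
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i+1}" for i in range(X.shape[1])]
    T = X.shape[0]
    rng = np.random.default_rng(seed)
    n_train = train_bins if T > train_bins else int(round(0.7 * T))
    n_train = max(min(n_train, T - 1), 1)
    perm = rng.permutation(T)
    tr, te = perm[:n_train], perm[n_train:]
    Xd = np.column_stack([np.ones(T), X])

    if family == "bernoulli":
        beta, info, n_iter, conv = _irls_bernoulli(Xd[tr], y[tr])
        eta = np.clip(Xd[te] @ beta, -30, 30)
        pred = (1.0 / (1.0 + np.exp(-eta)) >= 0.5).astype(float)
        metric, metric_name = _f1(y[te], pred), "f1"
    elif family == "robust_t":
        beta, info, n_iter, conv = _irls_student_t(Xd[tr], y[tr])
        pred = Xd[te] @ beta
        sst = float(((y[te] - y[tr].mean()) ** 2).sum())
        metric = 1.0 - float(((y[te] - pred) ** 2).sum()) / sst if sst > 0 else 0.0
        metric_name = "r2"
    elif family == "gaussian":
        beta, info, n_iter, conv = _ols(Xd[tr], y[tr])
        pred = Xd[te] @ beta
        sst = float(((y[te] - y[tr].mean()) ** 2).sum())
        metric = 1.0 - float(((y[te] - pred) ** 2).sum()) / sst if sst > 0 else 0.0
        metric_name = "r2"
    else:
        raise ValueError(f"unknown family {family!r}")

    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(np.linalg.pinv(info)))
    zc = sps.norm.ppf(0.975)
    return GlmFit(
        family=family,
        coef=beta,
        coef_lo=beta - zc * se,
        coef_hi=beta + zc * se,
        feature_names=["intercept"] + list(feature_names),
        heldout_metric=float(metric),
        metric_name=metric_name,
        train_idx=tr,
        test_idx=te,
        n_iter=n_iter,
        converged=conv,
    )


# ---------------------------------------------------------------------------
# Shared vs local dissociation


BEHAVIOR_FAMILIES = {
    "velocity": "robust_t",
    "acceleration": "robust_t",
    "lin_pos": "robust_t",
    "idphi": "robust_t",
    "correct": "bernoulli",
    "outbound": "bernoulli",
    "turn_left": "bernoulli",
}


def evaluate_decoding(
    features: FeatureMatrix,
    behavior: pd.DataFrame,
    behaviors: list[str] | None = None,
    train_bins: int = TRAIN_BINS_DEFAULT,
    seed: int = 0,
    epoch_wise: bool = False,
) -> pd.DataFrame:
    """Contrast aligned-only vs local-only decoding per behavior.

    Behavior samples are matched to feature bins by nearest time.  For each
    behavior: held-out metric of the aligned-only and local-only models and
    the cumulative coefficient-magnitude ratio Σ|β_aligned| / Σ|β_local|
    from the full model.  With ``epoch_wise`` one row is produced per epoch.
    """
    if behaviors is None:
        behaviors = [b for b in BEHAVIOR_FAMILIES if b in behavior.columns]
    beh_t = behavior["time"].to_numpy()
    idx = np.clip(np.searchsorted(beh_t, features.times + 1e-9) - 1, 0, beh_t.size - 1)
    epochs = (
        sorted(behavior["epoch"].unique()) if epoch_wise and "epoch" in behavior else [None]
    )
    al, lo = features.aligned_cols, features.local_cols
    rows = []
    for ep in epochs:
        if ep is None:
            sel = np.ones(features.values.shape[0], dtype=bool)
        else:
            sel = behavior["epoch"].to_numpy()[idx] == ep
        Xall = features.values[sel]
        for var in behaviors:
            yv = behavior[var].to_numpy().astype(float)[idx[sel]]
            fam = BEHAVIOR_FAMILIES.get(var, "robust_t")
            if fam == "bernoulli" and len(np.unique(yv)) < 2:
                continue
            fit_a = fit_behavior_glm(Xall[:, al], yv, fam, train_bins=train_bins, seed=seed)
            fit_l = fit_behavior_glm(Xall[:, lo], yv, fam, train_bins=train_bins, seed=seed)
            fit_full = fit_behavior_glm(Xall, yv, fam, train_bins=train_bins, seed=seed)
            b = fit_full.coef[1:]
            mag_a = float(np.abs(b[: len(al)]).sum())
            mag_l = float(np.abs(b[len(al) :]).sum())
            rows.append(
                {
                    "behavior": var,
                    "epoch": ep,
                    "family": fam,
                    "metric": fit_a.metric_name,
                    "aligned_metric": fit_a.heldout_metric,
                    "local_metric": fit_l.heldout_metric,
                    "full_metric": fit_full.heldout_metric,
                    "coef_ratio": mag_a / mag_l if mag_l > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed behavior × theta models


MIXED_MODEL_SET = {
    "R~B": "response ~ behavior",
    "R~theta": "response ~ theta",
    "R~B+theta": "response ~ behavior + theta",
    "R~B*theta": "response ~ behavior * theta",
    "R~B+theta|group": "response ~ behavior + theta + C(group)",
}


def compare_mixed_models(
    response: np.ndarray,
    behavior_values: np.ndarray,
    theta_power: np.ndarray,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the behavior/theta model family for one data split.

    Models: behavior only, theta only, additive, interaction, and additive
    with per-group intercepts (grouped fallback to additive when a single
    group is present).  Returns R² and AIC per model.
    """
    df = pd.DataFrame(
        {
            "response": np.asarray(response, float),
            "behavior": np.asarray(behavior_values, float),
            "theta": np.asarray(theta_power, float),
            "group": groups if groups is not None else np.zeros(len(response), int),
        }
    )
    rows = []
    for label, formula in MIXED_MODEL_SET.items():
        use = formula
        if "C(group)" in formula and df["group"].nunique() < 2:
            use = MIXED_MODEL_SET["R~B+theta"]
        try:
            fit = smf.ols(use, data=df).fit()
            rows.append(
                {"model": label, "r2": float(fit.rsquared), "aic": float(fit.aic)}
            )
        except Exception as e:  # singular fits: pooled fallback
            warnings.warn(f"model {label} failed ({e}); skipped")
    out = pd.DataFrame(rows)
    if not out.empty:
        out["winner"] = out["aic"] == out["aic"].min()
    return out


def compare_mixed_models_over_splits(
    df: pd.DataFrame,
    response_col: str,
    behavior_cols: list[str],
    theta_col: str,
    split_cols: list[str],
    group_col: str | None = None,
) -> pd.DataFrame:
    """Run the model family per (split × behavior variable) and summarize.

    Splits follow the grouping columns (e.g. animal × epoch); each
    continuous behavior variable defines its own model family instance.
    """
    rows = []
    for keys, sub in df.groupby(split_cols):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for bvar in behavior_cols:
            res = compare_mixed_models(
                sub[response_col].to_numpy(),
                sub[bvar].to_numpy(),
                sub[theta_col].to_numpy(),
                groups=sub[group_col].to_numpy() if group_col else None,
            )
            res["behavior_var"] = bvar
            for c, v in zip(split_cols, keys):
                res[c] = v
            rows.append(res)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# Rhythm coupling over epochs


def rhythm_coupling_over_epochs(
    sl: SharedLocalSeries,
    response: np.ndarray,
    epochs: np.ndarray,
    n_subsets: int = 10,
    subset_frac: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-epoch linear R² of theta power/coherence on the first canonical pair.

    Predictors are the aligned and local series of component 1; per epoch,
    ``n_subsets`` random time subsets are fit and their R² recorded.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(len(response)), sl.aligned[:, 0], sl.local[:, 0]])
    y = np.asarray(response, float)
    rows = []
    for ep in np.unique(epochs):
        sel = np.nonzero(epochs == ep)[0]
        n_take = max(int(round(subset_frac * sel.size)), 3)
        for s in range(n_subsets):
            pick = rng.choice(sel, size=min(n_take, sel.size), replace=False)
            beta = np.linalg.lstsq(X[pick], y[pick], rcond=None)[0]
            resid = y[pick] - X[pick] @ beta
            sst = float(((y[pick] - y[pick].mean()) ** 2).sum())
            r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
            rows.append({"epoch": ep, "subset": s, "r2": r2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# State-density contrast


def state_density_contrast(
    sl: SharedLocalSeries,
    window_sets: dict[str, tuple[WindowSet, WindowSet]],
    component: int = 1,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Shared-axis distribution in high vs low windows, per state variable.

    For each state (theta power, theta coherence, speed): the aligned and
    local component values of all bins inside high vs low windows, the
    difference of means, and a permutation-test p value.
    """
    bin_t = sl.times
    rows = []
    for state, (hi, lo) in window_sets.items():
        if hi.n == 0 or lo.n == 0:
            warnings.warn(f"state {state!r}: empty window set, skipped")
            continue
        def _vals(ws: WindowSet, data: np.ndarray) -> np.ndarray:
            mask = np.zeros(bin_t.size, dtype=bool)
            for s0, s1 in ws.intervals():
                mask |= (bin_t >= s0) & (bin_t < s1)
            return data[mask, component - 1]
        for which, data in (("aligned", sl.aligned), ("local", sl.local)):
            a, b = _vals(hi, data), _vals(lo, data)
            if a.size == 0 or b.size == 0:
                continue
            test = ncstats.permutation_test_means(a, b, n_perm=n_perm, seed=seed)
            rows.append(
                {
                    "state": state,
                    "axis": which,
                    "n_high": a.size,
                    "n_low": b.size,
                    "mean_high": a.mean(),
                    "mean_low": b.mean(),
                    "mean_diff": test.statistic,
                    "p_value": test.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IdPhi for real position data


def compute_idphi(x: np.ndarray, y: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Integrated absolute change of heading over a sliding window.

    Heading φ = atan2(dy, dx); IdPhi(t) = ∫ |dφ/dt| over the window around
    t.  The synthetic generator plants IdPhi directly; this estimator is
    for externally recorded position data.
    """
    dx = np.gradient(np.asarray(x, float))
    dy = np.gradient(np.asarray(y, float))
    phi = np.unwrap(np.arctan2(dy, dx))
    dphi = np.abs(np.gradient(phi)) * fs
    w = max(1, int(round(window_s * fs)))
    kernel = np.ones(w)
    return np.convolve(dphi, kernel, mode="same") / fs
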