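"""Reduced-rank regression (RRR) of one population on another.

The mapping Y = X B + ε is first fit by ordinary least squares,
B_OLS = (XᵀX)⁻¹XᵀY.  Rank-m predictors are obtained by projecting the OLS
predictions onto their top-m principal directions:
B_RRR(m) = B_OLS V_{1:m} V_{1:m}ᵀ, where V holds principal directions of
Ŷ = X B_OLS.  Cross-validated R²(m) curves (folds formed over windows, not
bins, to avoid within-window leakage) yield the optimal dimension m̂ — the
smallest rank whose mean R² lies within one standard error of the
full-rank model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as ncstats

#: condition-number threshold above which OLS falls back to a pseudoinverse
COND_THRESHOLD = 1e10


@dataclass
class RrrFit:
    """OLS coefficients, prediction principal directions, CV performance."""

    b_ols: np.ndarray  # p × q
    v: np.ndarray  # q × m_max, orthonormal columns
    r2_folds: np.ndarray  # folds × m_max, R²(m) per held-out fold
    m_max: int
    optimal_m: int
    sem_full: float

    @property
    def r2_mean(self) -> np.ndarray:
        return self.r2_folds.mean(axis=0)

    def r2_at(self, m: int) -> float:
        return float(self.r2_mean[m - 1])


def ols_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares B = (XᵀX)⁻¹XᵀY with a rank-safe fallback.

    When XᵀX is ill-conditioned (condition number above 1e10) the inverse
    is replaced by a Moore–Penrose pseudoinverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("no samples")
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    xtx = x.T @ x
    xty = x.T @ y
    if np.linalg.cond(xtx) < COND_THRESHOLD:
        return np.linalg.solve(xtx, xty)
    return np.linalg.pinv(xtx) @ xty


def prediction_pcs(b_ols: np.ndarray, x_train: np.ndarray) -> np.ndarray:
    """Principal directions V (q × q) of the training predictions X·B_OLS.

    Columns are eigenvectors of ŶᵀŶ ordered by decreasing eigenvalue.
    """
    yhat = x_train @ b_ols
    # SVD of predictions: right singular vectors = eigenvectors of ŶᵀŶ
    _, _, vt = np.linalg.svd(yhat, full_matrices=False)
    q = b_ols.shape[1]
    v = vt.T
    if v.shape[1] < q:
        raise ValueError("fewer samples than target units; cannot span prediction space")
    return v[:, :q]


def rrr_truncate(b_ols: np.ndarray, x_train: np.ndarray, m: int) -> np.ndarray:
    """Rank-m predictor B_RRR(m) = B_OLS V_{1:m} V_{1:m}ᵀ."""
    q = b_ols.shape[1]
    if not (1 <= m <= q):
        raise ValueError(f"rank m={m} outside [1, {q}]")
    v = prediction_pcs(b_ols, x_train)
    vm = v[:, :m]
    return b_ols @ vm @ vm.T


def _r2(y_true: np.ndarray, y_pred: np.ndarray, center: np.ndarray) -> float:
    """Pooled coefficient of determination over all target units.

    SST is taken around ``center`` (the training mean of Y), so a model
    worse than predicting the training mean scores negative.
    """
    sse = float(((y_true - y_pred) ** 2).sum())
    sst = float(((y_true - center) ** 2).sum())
    if sst == 0:
        return 0.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


def cv_rank_curve(
    x: np.ndarray,
    y: np.ndarray,
    t_w: int = 1,
    folds: int = 5,
    m_max: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated R²(m) for m = 1..m_max; returns a folds × m_max array.

    Rows of ``x``/``y`` are grouped into windows of ``t_w`` consecutive
    bins; folds are formed over windows so that the bins of one window never
    straddle the train/test split.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T, q = y.shape
    if T % t_w != 0:
        raise ValueError("row count must be a multiple of the window length")
    n_win = T // t_w
    if n_win < folds:
        raise ValueError(f"only {n_win} windows for {folds} folds")
    if m_max is None:
        m_max = q
    m_max = min(m_max, q)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_win)
    fold_of = np.empty(n_win, dtype=int)
    fold_of[perm] = np.arange(n_win) % folds
    row_fold = np.repeat(fold_of, t_w)
    out = np.empty((folds, m_max))
    for f in range(folds):
        tr = row_fold != f
        te = ~tr
        b = ols_fit(x[tr], y[tr])
        v = prediction_pcs(b, x[tr])
        center = y[tr].mean(axis=0)
        y_te = y[te]
        x_te = x[te]
        bv = b @ v  # p × q; rank-m prediction = x (B V_{1:m}) V_{1:m}ᵀ
        for m in range(1, m_max + 1):
            y_pred = (x_te @ bv[:, :m]) @ v[:, :m].T
            out[f, m - 1] = _r2(y_te, y_pred, center)
    return out


def optimal_rank(r2_folds: np.ndarray) -> int:
    """Smallest m whose mean R²(m) is within one SEM of the full-rank R²."""
    r2_folds = np.asarray(r2_folds, dtype=float)
    if r2_folds.ndim != 2 or r2_folds.shape[0] < 2:
        raise ValueError("need per-fold curves from at least 2 folds")
    means = r2_folds.mean(axis=0)
    sem_full = r2_folds[:, -1].std(ddof=1) / np.sqrt(r2_folds.shape[0])
    cutoff = means[-1] - sem_full
    qualifying = np.nonzero(means >= cutoff)[0]
    return int(qualifying[0]) + 1


def fit_rrr(
    x: np.ndarray,
    y: np.ndarray,
    t_w: int = 1,
    folds: int = 5,
    m_max: int | None = None,
    seed: int = 0,
) -> RrrFit:
    """Full-data OLS fit plus the cross-validated rank curve and m̂."""
    curves = cv_rank_curve(x, y, t_w=t_w, folds=folds, m_max=m_max, seed=seed)
    b = ols_fit(x, y)
    v = prediction_pcs(b, x)
    m_hat = optimal_rank(curves)
    sem_full = float(curves[:, -1].std(ddof=1) / np.sqrt(curves.shape[0]))
    return RrrFit(
        b_ols=b,
        v=v[:, : curves.shape[1]],
        r2_folds=curves,
        m_max=curves.shape[1],
        optimal_m=m_hat,
        sem_full=sem_full,
    )


# ---------------------------------------------------------------------------
# High/low state contrast over partitions


def state_contrast(results: pd.DataFrame, q_fdr: float = 0.05) -> pd.DataFrame:
    """Summarize paired high−low differences of m̂ and R² per state/target.

    ``results`` must be tidy with columns
    [partition, state, level, target, m_hat, r2]; levels "high"/"low" are
    paired within (partition, state, target).  Two-sample t-tests compare the
    high and low partition samples; decisions are Benjamini–Hochberg
    corrected at ``q_fdr`` across all state × target × measure contrasts.
    """
    required = {"partition", "state", "level", "target", "m_hat", "r2"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    rows = []
    for (state, target), grp in results.groupby(["state", "target"]):
        wide = grp.pivot_table(
            index="partition", columns="level", values=["m_hat", "r2"]
        )
        for measure in ["m_hat", "r2"]:
            if (measure, "high") not in wide.columns or (measure, "low") not in wide.columns:
                continue
            pair = wide[measure].dropna()
            if pair.empty:
                continue
            hi, lo = pair["high"].to_numpy(), pair["low"].to_numpy()
            diff = hi - lo
            test = ncstats.two_sample_t(hi, lo)
            rows.append(
                {
                    "state": state,
                    "target": target,
                    "measure": measure,
                    "n_pairs": len(pair),
                    "mean_high": hi.mean(),
                    "sem_high": hi.std(ddof=1) / np.sqrt(len(hi)) if len(hi) > 1 else np.nan,
                    "mean_low": lo.mean(),
                    "sem_low": lo.std(ddof=1) / np.sqrt(len(lo)) if len(lo) > 1 else np.nan,
                    "mean_diff": diff.mean(),
                    "t_stat": test.statistic,
                    "p_value": test.p_value,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        reject, p_adj = ncstats.benjamini_hochberg(table["p_value"].to_numpy(), q=q_fdr)
        table["p_adjusted"] = p_adj
        table["significant"] = reject
    return table
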