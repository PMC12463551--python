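"""Canonical correlation analysis between two spike-count populations.

CCA finds paired linear combinations (canonical variates U = X·A for CA1
and V = Y·B for PFC) maximizing inter-region correlation; successive pairs
are mutually uncorrelated within each region.  Weights are estimated by
SVD of the whitened cross-covariance, with a small trace-scaled ridge on
each within-region covariance for numerical safety.  Held-out canonical
correlations from five-fold cross-validation guard against overfitting;
the reported variates come from a final full-data fit.

Each canonical pair splits into an aligned ("shared", reciprocated)
component (U+V)/√2 and a local ("unreciprocated") component (U−V)/√2 —
an isometry per component pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REG_SCALE = 1e-8  # ridge as a fraction of mean covariance trace


@dataclass
class CcaFit:
    """Canonical weights and train/held-out correlation spectra."""

    a: np.ndarray  # p × k weights for region X (CA1)
    b: np.ndarray  # q × k weights for region Y (PFC)
    rho_train: np.ndarray  # k, full-data training canonical correlations
    rho_heldout: np.ndarray  # k, mean held-out correlations across folds
    rho_folds: np.ndarray  # folds × k
    k: int
    fold_of: np.ndarray | None = None


@dataclass
class VariateSeries:
    """Canonical variate time courses U (CA1) and V (PFC)."""

    u: np.ndarray  # T × k
    v: np.ndarray  # T × k
    times: np.ndarray  # bin start times (s)

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("U and V must have identical shapes")


@dataclass
class SharedLocalSeries:
    """Aligned (shared) and local (unreciprocated) projections per pair."""

    aligned: np.ndarray  # (U+V)/√2
    local: np.ndarray  # (U−V)/√2
    times: np.ndarray

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def _cca_weights(x: np.ndarray, y: np.ndarray, k: int):
    """Whitened-cross-covariance SVD CCA on centered data.

    Returns (A, B, rho) with variates unit-variance on this data.
    """
    T = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cxx = xc.T @ xc / (T - 1)
    cyy = yc.T @ yc / (T - 1)
    cxy = xc.T @ yc / (T - 1)
    for c in (cxx, cyy):
        tr = np.trace(c) / c.shape[0]
        if tr <= 0:
            tr = 1.0
        c[np.diag_indices_from(c)] += REG_SCALE * tr
    lx = np.linalg.cholesky(cxx)
    ly = np.linalg.cholesky(cyy)
    m = np.linalg.solve(lx, cxy) @ np.linalg.inv(ly).T
    uu, s, vvt = np.linalg.svd(m)
    a = np.linalg.solve(lx.T, uu[:, :k])
    b = np.linalg.solve(ly.T, vvt.T[:, :k])
    return a, b, np.clip(s[:k], 0.0, 1.0)


def _fix_signs(a: np.ndarray, b: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Resolve CCA sign indeterminacy.

    Each pair is flipped so its training correlation is non-negative, then
    jointly flipped so the largest-magnitude CA1 weight is positive.
    """
    u = (x - x.mean(axis=0)) @ a
    v = (y - y.mean(axis=0)) @ b
    for j in range(a.shape[1]):
        r = np.corrcoef(u[:, j], v[:, j])[0, 1] if u[:, j].std() > 0 else 0.0
        if r < 0:
            b[:, j] *= -1
        lead = np.argmax(np.abs(a[:, j]))
        if a[lead, j] < 0:
            a[:, j] *= -1
            b[:, j] *= -1
    return a, b


def fit_cca(x: np.ndarray, y: np.ndarray, k: int, folds: int = 5, seed: int = 0) -> CcaFit:
    """Cross-validated CCA between two T × units matrices (z-scored upstream).

    Held-out ρ_j is the correlation of the j-th projected variate pair on
    each fold's test split (weights fit on the complementary training
    split); reported weights come from a final full-data fit with the sign
    convention fixed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    p, q = x.shape[1], y.shape[1]
    if k > min(p, q):
        raise ValueError(f"k={k} exceeds min(p, q)={min(p, q)}")
    T = x.shape[0]
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(T) % folds
    rho_folds = np.empty((folds, k))
    for f in range(folds):
        tr = fold_of != f
        a, b, _ = _cca_weights(x[tr], y[tr], k)
        u = (x[~tr] - x[tr].mean(axis=0)) @ a
        v = (y[~tr] - y[tr].mean(axis=0)) @ b
        for j in range(k):
            if u[:, j].std() == 0 or v[:, j].std() == 0:
                rho_folds[f, j] = 0.0
            else:
                rho_folds[f, j] = np.corrcoef(u[:, j], v[:, j])[0, 1]
    a, b, rho_train = _cca_weights(x, y, k)
    a, b = _fix_signs(a, b, x, y)
    return CcaFit(
        a=a,
        b=b,
        rho_train=rho_train,
        rho_heldout=rho_folds.mean(axis=0),
        rho_folds=rho_folds,
        k=k,
        fold_of=fold_of,
    )


def project_variates(
    fit: CcaFit, x: np.ndarray, y: np.ndarray, times: np.ndarray | None = None
) -> VariateSeries:
    """Continuous temporal readout U = X·A, V = Y·B at every bin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[1] != fit.a.shape[0] or y.shape[1] != fit.b.shape[0]:
        raise ValueError("unit count mismatch between data and fitted weights")
    if times is None:
        times = np.arange(x.shape[0], dtype=float)
    return VariateSeries(u=x @ fit.a, v=y @ fit.b, times=np.asarray(times, dtype=float))


def aligned_orthogonal(vs: VariateSeries) -> SharedLocalSeries:
    """Rotate each (U_j, V_j) pair onto the unity line and its orthogonal.

    aligned = (U+V)/√2 captures reciprocated activity, local = (U−V)/√2
    unreciprocated activity; the map is an isometry.
    """
    s = 1.0 / np.sqrt(2.0)
    return SharedLocalSeries(
        aligned=(vs.u + vs.v) * s, local=(vs.u - vs.v) * s, times=vs.times
    )


# ---------------------------------------------------------------------------
# Behavioral repeatability and spatial maps


def trajectory_repeatability(
    sl: SharedLocalSeries,
    behavior: pd.DataFrame,
    n_pos_bins: int = 100,
    n_components: int = 10,
    min_occupied: int = 10,
) -> pd.DataFrame:
    """Cosine similarity of position-binned aligned activity across trials.

    Each trial's aligned activity is averaged into ``n_pos_bins`` linearized
    position bins (missing bins linearly interpolated), giving one
    100-vector per trial per component.  Trial pairs are categorized
    "pure match" (identical trajectory label, e.g. two C-to-L runs),
    "same type" (same direction class: both outbound or both inbound) or
    "different type".  Trials occupying fewer than ``min_occupied`` bins
    are dropped with a warning.
    """
    n_components = min(n_components, sl.k)
    needed = {"time", "lin_pos", "trial", "traj_type", "outbound"}
    if not needed.issubset(behavior.columns):
        raise ValueError(f"behavior table must have columns {sorted(needed)}")
    # align behavior samples to variate bins (nearest bin)
    idx = np.searchsorted(sl.times, behavior["time"].to_numpy(), side="right") - 1
    ok = (idx >= 0) & (idx < len(sl.times))
    beh = behavior.loc[ok].reset_index(drop=True)
    idx = idx[ok]
    edges = np.linspace(0.0, 1.0, n_pos_bins + 1)
    profiles: dict[tuple, np.ndarray] = {}
    meta: dict[tuple, tuple[str, bool]] = {}
    for trial, g in beh.groupby("trial"):
        if trial < 0:
            continue
        rows = idx[g.index.to_numpy()]
        pos = g["lin_pos"].to_numpy()
        pbin = np.clip(np.digitize(pos, edges) - 1, 0, n_pos_bins - 1)
        prof = np.full((n_pos_bins, n_components), np.nan)
        for b in np.unique(pbin):
            sel = rows[pbin == b]
            prof[b] = sl.aligned[sel, :n_components].mean(axis=0)
        occupied = ~np.isnan(prof[:, 0])
        if occupied.sum() < min_occupied:
            warnings.warn(f"trial {trial}: only {occupied.sum()} occupied bins; dropped")
            continue
        # linear interpolation over missing position bins
        xs = np.nonzero(occupied)[0]
        for c in range(n_components):
            prof[:, c] = np.interp(np.arange(n_pos_bins), xs, prof[xs, c])
        profiles[trial] = prof
        meta[trial] = (str(g["traj_type"].iloc[0]), bool(g["outbound"].iloc[0]))
    rows_out = []
    trials = sorted(profiles)
    for i, ta in enumerate(trials):
        for tb in trials[i + 1 :]:
            type_a, out_a = meta[ta]
            type_b, out_b = meta[tb]
            if type_a == type_b:
                category = "pure match"
            elif out_a == out_b:
                category = "same type"
            else:
                category = "different type"
            for c in range(n_components):
                va, vb = profiles[ta][:, c], profiles[tb][:, c]
                na, nb = np.linalg.norm(va), np.linalg.norm(vb)
                cos = float(va @ vb / (na * nb)) if na > 0 and nb > 0 else 0.0
                rows_out.append(
                    {
                        "trial_a": ta,
                        "trial_b": tb,
                        "component": c + 1,
                        "category": category,
                        "cosine": cos,
                    }
                )
    return pd.DataFrame(rows_out)


def spatial_component_map(
    sl: SharedLocalSeries,
    behavior: pd.DataFrame,
    grid: tuple[int, int] = (20, 20),
    min_occupancy: int = 5,
    component: int = 1,
    which: str = "aligned",
):
    """Mean (z-scored) component activity per 2-D spatial bin.

    Returns (map, occupancy); bins visited fewer than ``min_occupancy``
    samples are masked to NaN.
    """
    data = sl.aligned if which == "aligned" else sl.local
    series = data[:, component - 1]
    idx = np.searchsorted(sl.times, behavior["time"].to_numpy(), side="right") - 1
    ok = (idx >= 0) & (idx < len(sl.times))
    x = behavior.loc[ok, "x"].to_numpy()
    y = behavior.loc[ok, "y"].to_numpy()
    vals = series[idx[ok]]
    sd = vals.std()
    vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    nx, ny = grid
    xe = np.linspace(x.min(), x.max() + 1e-9, nx + 1)
    ye = np.linspace(y.min(), y.max() + 1e-9, ny + 1)
    occupancy, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    total, _, _ = np.histogram2d(x, y, bins=[xe, ye], weights=vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_map = total / occupancy
    mean_map[occupancy < min_occupancy] = np.nan
    return mean_map, occupancy
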