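"""Regularized NMF spectral unmixing and supporting analyses.

The data matrix X (one spectrum per row) is factored as X ~ WH with
W, H >= 0, minimizing

    1/2 ||X - WH||_F^2 + a*r*(||W||_1 + ||H||_1)
        + 1/2 * a*(1-r) * (||W||_F^2 + ||H||_F^2)

where a (alpha) sets the overall regularization strength and r (rho) the
L1/L2 mix.  Penalties are applied exactly as written -- no division by
matrix size -- so the objective value reported in the trace is the same
quantity :func:`nmf_objective` evaluates.  Optimization is block
coordinate descent (HALS): each column of W, then each row of H, is
updated by its closed-form nonnegative minimizer, so the objective is
non-increasing by construction.  Initialization is deterministic NNDSVD.

Component order after a fit is arbitrary; all downstream reporting goes
through :func:`label_components` rather than component index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .bands import BandRange, default_band_table
from .errors import ParameterError
from .io import SpectralDataset, WavenumberGrid, canonical_grid

__all__ = [
    "NMFConfig",
    "NMFResult",
    "EvolutionSummary",
    "pca_variance_profile",
    "select_n_components",
    "nndsvd_init",
    "nmf_objective",
    "fit_regularized_nmf",
    "l_curve_select",
    "label_components",
    "component_evolution",
    "tsne_embed",
]


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of the regularized NMF fit."""

    k: int = 5
    alpha: float = 1e-2
    rho: float = 1e-3
    tol: float = 1e-5
    max_iter: int = 2000
    init: str = "nndsvd"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ParameterError("rho must be in [0, 1]")
        if self.init not in {"nndsvd", "random"}:
            raise ParameterError(f"unknown init {self.init!r}")


@dataclass
class NMFResult:
    """Factorization output: coefficients W (n x k), components H (k x m)."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    config: NMFConfig
    labels: list | None = None

    def normalized(self) -> "NMFResult":
        """Max-normalize each H row, rescaling W columns to compensate.

        Resolves the W/H scale indeterminacy for reporting; WH is
        unchanged."""
        scale = self.H.max(axis=1)
        scale[scale == 0] = 1.0
        return replace(self, H=self.H / scale[:, None],
                       W=self.W * scale[None, :])


def pca_variance_profile(X: np.ndarray) -> np.ndarray:
    """Cumulative explained-variance fractions of mean-centered X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with >= 2 rows")
    Xc = X - X.mean(axis=0, keepdims=True)
    svals = np.linalg.svd(Xc, compute_uv=False)
    power = svals ** 2
    total = power.sum()
    if total == 0.0:
        raise ParameterError("matrix has no variance (rank 0 after centering)")
    profile = np.cumsum(power) / total
    profile[-1] = 1.0  # guard rounding
    return profile


def select_n_components(profile: np.ndarray, threshold: float = 0.9997
                        ) -> int:
    """Smallest k whose cumulative explained variance reaches ``threshold``."""
    if threshold > 1.0:
        raise ParameterError("threshold must be <= 1")
    profile = np.asarray(profile, dtype=float)
    hits = np.nonzero(profile >= threshold)[0]
    if hits.size == 0:
        raise ParameterError("profile never reaches the threshold")
    return int(hits[0]) + 1


def nndsvd_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (deterministic, zeros kept).

    Each of the k leading singular triplets is split into positive and
    negative parts; the dominant part (larger norm product) seeds the
    corresponding W column / H row.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ParameterError("NNDSVD requires a nonnegative matrix")
    n, m = X.shape
    if not 1 <= k <= min(n, m):
        raise ParameterError(f"k = {k} outside [1, min(n, m) = {min(n, m)}]")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        pnorm = np.linalg.norm(up) * np.linalg.norm(vp)
        nnorm = np.linalg.norm(un) * np.linalg.norm(vn)
        if pnorm >= nnorm:
            if pnorm > 0:
                W[:, j] = np.sqrt(S[j] * pnorm) * up / np.linalg.norm(up)
                H[j, :] = np.sqrt(S[j] * pnorm) * vp / np.linalg.norm(vp)
        else:
            W[:, j] = np.sqrt(S[j] * nnorm) * un / np.linalg.norm(un)
            H[j, :] = np.sqrt(S[j] * nnorm) * vn / np.linalg.norm(vn)
    return W, H


def nmf_objective(X: np.ndarray, W: np.ndarray, H: np.ndarray,
                  alpha: float, rho: float) -> float:
    """The regularized NMF objective, with penalties exactly as written
    (no sample-size normalization)."""
    X, W, H = (np.asarray(a, dtype=float) for a in (X, W, H))
    if W.shape[0] != X.shape[0] or H.shape[1] != X.shape[1] \
            or W.shape[1] != H.shape[0]:
        raise ParameterError(
            f"shape mismatch: X{X.shape}, W{W.shape}, H{H.shape}")
    resid = X - W @ H
    return float(
        0.5 * np.sum(resid ** 2)
        + alpha * rho * (np.sum(np.abs(W)) + np.sum(np.abs(H)))
        + 0.5 * alpha * (1.0 - rho) * (np.sum(W ** 2) + np.sum(H ** 2))
    )


def _hals_sweep(X, W, H, l1, l2):
    """One full coordinate-descent sweep: all W columns, then all H rows.

    Each block update is the exact nonnegative minimizer of the objective
    in that block, so the sweep cannot increase the objective.
    """
    HHt = H @ H.T
    XHt = X @ H.T
    for j in range(W.shape[1]):
        denom = HHt[j, j] + l2
        if denom <= 0:
            continue
        num = XHt[:, j] - W @ HHt[:, j] + W[:, j] * HHt[j, j] - l1
        W[:, j] = np.maximum(0.0, num / denom)
    WtW = W.T @ W
    WtX = W.T @ X
    for j in range(H.shape[0]):
        denom = WtW[j, j] + l2
        if denom <= 0:
            continue
        num = WtX[j, :] - WtW[j, :] @ H + WtW[j, j] * H[j, :] - l1
        H[j, :] = np.maximum(0.0, num / denom)


def fit_regularized_nmf(X: np.ndarray, config: NMFConfig = NMFConfig()
                        ) -> NMFResult:
    """Fit the regularized NMF by alternating coordinate descent.

    Stops when the relative per-iteration objective decrease drops below
    ``config.tol`` or at ``config.max_iter`` (then ``converged=False``).
    The objective trace is recorded every iteration, starting from the
    initialization, and is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ParameterError("NMF requires a nonnegative matrix")
    if config.init == "nndsvd":
        W, H = nndsvd_init(X, config.k)
    else:
        rng = np.random.default_rng(config.seed)
        scale = np.sqrt(max(X.mean(), np.finfo(float).tiny) / config.k)
        W = scale * rng.random((X.shape[0], config.k))
        H = scale * rng.random((config.k, X.shape[1]))
    l1 = config.alpha * config.rho
    l2 = config.alpha * (1.0 - config.rho)

    def objective(W, H):
        # inline evaluation; independently cross-checked by nmf_objective
        resid = X - W @ H
        return (0.5 * np.sum(resid * resid)
                + l1 * (W.sum() + H.sum())
                + 0.5 * l2 * (np.sum(W * W) + np.sum(H * H)))

    trace = [objective(W, H)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        _hals_sweep(X, W, H, l1, l2)
        obj = objective(W, H)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < config.tol:
            converged = True
            break
        if prev == 0.0:
            converged = True
            break
    return NMFResult(W=W, H=H, objective_trace=np.asarray(trace),
                     n_iter=n_iter, converged=converged, config=config)


def _menger_curvature(pts: np.ndarray) -> np.ndarray:
    """Discrete curvature at interior points of a 2-D polyline."""
    curv = np.zeros(len(pts))
    for i in range(1, len(pts) - 1):
        a, b, c = pts[i - 1], pts[i], pts[i + 1]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1])
                    - (c[0] - a[0]) * (b[1] - a[1]))
        la, lb, lc = (np.linalg.norm(b - a), np.linalg.norm(c - b),
                      np.linalg.norm(c - a))
        if la * lb * lc > 0:
            curv[i] = 2.0 * area2 / (la * lb * lc)
    return curv


def l_curve_select(X: np.ndarray, k: int, alpha_grid, rho_grid,
                   tol: float = 1e-4, max_iter: int = 500
                   ) -> tuple[float, float]:
    """Pick (alpha, rho) at the L-curve corner.

    For each rho, NMF is fit along the alpha sweep; the corner is the
    point of maximum discrete (Menger) curvature of log residual vs log
    penalty; the rho with the sharpest corner wins.  Deterministic.
    """
    alpha_grid = [float(a) for a in np.atleast_1d(alpha_grid)]
    rho_grid = [float(r) for r in np.atleast_1d(rho_grid)]
    if len(alpha_grid) == 1 and len(rho_grid) == 1:
        return alpha_grid[0], rho_grid[0]
    if len(alpha_grid) < 3:
        raise ParameterError("alpha grid needs >= 3 points for curvature")
    best = None
    for rho in rho_grid:
        pts = []
        for alpha in alpha_grid:
            cfg = NMFConfig(k=k, alpha=alpha, rho=rho, tol=tol,
                            max_iter=max_iter)
            res = fit_regularized_nmf(X, cfg)
            resid = np.linalg.norm(X - res.W @ res.H)
            pen = (rho * (np.abs(res.W).sum() + np.abs(res.H).sum())
                   + 0.5 * (1 - rho) * (np.sum(res.W ** 2)
                                        + np.sum(res.H ** 2)))
            eps = np.finfo(float).tiny
            pts.append((np.log(resid + eps), np.log(pen + eps)))
        curv = _menger_curvature(np.asarray(pts))
        i = int(np.argmax(curv))
        if best is None or curv[i] > best[0]:
            best = (curv[i], alpha_grid[i], rho)
    return best[1], best[2]


#: labels used beyond the plain band-table ranges
INTERMOLECULAR_LABEL = "intermolecular beta-sheet"
BACKGROUND_LABEL = "background/medium or laser profile"


def label_components(H: np.ndarray,
                     grid: WavenumberGrid | None = None,
                     band_table: list[BandRange] | None = None,
                     flatness_ratio: float = 1.5) -> list[str]:
    """Assign a structural label to each component spectrum (H row).

    A component peaking in 1,615-1,625 cm^-1 with a secondary local
    maximum in 1,672-1,694 cm^-1 is the intermolecular beta-sheet doublet.
    Near-flat components (peak/median < ``flatness_ratio``) are labeled as
    background/medium or laser profile.  Otherwise the component carries
    the band-table label(s) containing its peak.  Labels are invariant to
    rescaling of H rows.
    """
    grid = grid or canonical_grid()
    table = band_table if band_table is not None else default_band_table()
    labels = []
    for row in np.asarray(H, dtype=float):
        peak = row.max()
        if peak <= 0:
            labels.append(BACKGROUND_LABEL)
            continue
        med = np.median(row)
        if med > 0 and peak / med < flatness_ratio:
            labels.append(BACKGROUND_LABEL)
            continue
        argmax_wn = float(grid.values[np.argmax(row)])
        if 1615.0 <= argmax_wn <= 1625.0 and _has_local_max(
                row, grid, 1672.0, 1694.0, rel_height=0.1):
            labels.append(INTERMOLECULAR_LABEL)
            continue
        hits = [b.label for b in table if argmax_wn in b]
        labels.append(" + ".join(hits) if hits else "unassigned")
    return labels


def _has_local_max(row: np.ndarray, grid: WavenumberGrid,
                   lo: float, hi: float, rel_height: float) -> bool:
    sel = np.nonzero((grid.values >= lo) & (grid.values <= hi))[0]
    peak = row.max()
    for i in sel:
        if 0 < i < len(row) - 1 and row[i] >= row[i - 1] \
                and row[i] >= row[i + 1] and row[i] >= rel_height * peak:
            return True
    return False


@dataclass
class EvolutionSummary:
    """Coefficient statistics per (component, arm, time)."""

    table: pd.DataFrame  # columns: component, label, arm, time_h, mean, sd,
                         #          q25, q50, q75, n

    def percent_change(self, component: int, arm: str,
                       t0: float, t1: float) -> float:
        """100 * (mean_t1 - mean_t0) / mean_t0 for one component/arm."""
        sub = self.table[(self.table.component == component)
                         & (self.table.arm == arm)]
        means = sub.set_index("time_h")["mean"]
        for t in (t0, t1):
            if t not in means.index:
                raise ParameterError(f"no time point {t} h for {arm} arm")
        m0, m1 = float(means[t0]), float(means[t1])
        if m0 <= 0:
            raise ParameterError("percent change undefined for mean_t0 <= 0")
        return 100.0 * (m1 - m0) / m0


def component_evolution(result: NMFResult, dataset: SpectralDataset
                        ) -> EvolutionSummary:
    """Summarize each W column over (arm, time): mean, sd, quartiles.

    Rows of W must correspond one-to-one with ``dataset.records``.
    """
    if result.W.shape[0] != len(dataset.records):
        raise ParameterError("W rows do not match dataset records")
    labels = result.labels or label_components(result.H, dataset.grid)
    rows = []
    meta = pd.DataFrame({
        "arm": [r.arm for r in dataset.records],
        "time_h": [r.time_h for r in dataset.records],
    })
    for comp in range(result.W.shape[1]):
        col = pd.Series(result.W[:, comp])
        for (arm, time_h), idx in meta.groupby(["arm", "time_h"]).groups.items():
            vals = col.loc[idx]
            rows.append({
                "component": comp,
                "label": labels[comp],
                "arm": arm,
                "time_h": float(time_h),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "q25": float(vals.quantile(0.25)),
                "q50": float(vals.quantile(0.50)),
                "q75": float(vals.quantile(0.75)),
                "n": int(len(vals)),
            })
    return EvolutionSummary(pd.DataFrame(rows))


def tsne_embed(W: np.ndarray, perplexity: float = 30.0, seed: int = 0
               ) -> np.ndarray:
    """2-D t-SNE embedding of NMF coefficients (visualization only)."""
    W = np.asarray(W, dtype=float)
    if W.shape[0] < 5:
        raise ParameterError("t-SNE needs at least 5 rows")
    if perplexity >= W.shape[0]:
        raise ParameterError("perplexity must be smaller than the number "
                             "of rows")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(W)
    return np.asarray(emb)
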