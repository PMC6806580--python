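"""RDA-based variation partitioning with VIF filtering and forward selection.

The community matrix Y (Hellinger-transformed counts) is regressed on an
environmental predictor set and a spatial predictor set (PCNM or AEM
eigenfunctions).  Explained variance is measured by the RDA R² — the trace
of the fitted sum of squares over the total — adjusted for the number of
predictors by Ezekiel's formula

    adjR² = 1 - (1 - R²) (n - 1) / (n - p - 1).

The two-set partition reports pure environmental [a], shared [b], pure
spatial [c] and unexplained [d] fractions; adjusted fractions can be
slightly negative and are reported as-is.  A parallel partition based on
(partial) Mantel correlations of distance matrices is provided for
comparison but never mixed with the RDA version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta import DistanceMatrix, _check_labels, _corr, _mantel_vectors, partial_mantel


@dataclass
class VarpartResult:
    """Adjusted-R² fractions and the predictor sets that produced them."""

    fractions: dict  # pure_env, shared, pure_spatial, unexplained
    selected_env: list[str]
    selected_spatial: list[str]
    method: str  # "rda" | "partial-mantel"
    details: dict

    @property
    def has_negative_fractions(self) -> bool:
        return any(v < 0 for v in self.fractions.values())


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, [f"x{i}" for i in range(x.shape[1])]


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """Raw RDA R²: trace of fitted SS over total SS (centered Y on centered X)."""
    yc = y - y.mean(axis=0, keepdims=True)
    sstot = float(np.sum(yc**2))
    if sstot == 0:
        raise ValueError("community matrix has no variance")
    if x.shape[1] == 0:
        return 0.0
    xc = x - x.mean(axis=0, keepdims=True)
    coef, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    return float(np.sum(fitted**2)) / sstot


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    if x.shape[1] == 0:
        return
    xc = x - x.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        # name a minimal set of dependent columns by greedy QR screening
        bad = []
        kept: list[int] = []
        for j in range(xc.shape[1]):
            trial = xc[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"collinear predictor columns: {bad}")


def ezekiel_adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R²; NaN when the model is saturated (n <= p + 1)."""
    if p == 0:
        return 0.0
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _adjusted_r2_rank(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted R² using the column-space rank as the predictor count.

    Tolerates collinear columns (the projection onto the column space is
    well defined regardless), which arises by construction when the union
    of two predictor sets is rank deficient.
    """
    n = y.shape[0]
    if x.shape[1] == 0:
        return 0.0
    xc = x - x.mean(axis=0, keepdims=True)
    rank = int(np.linalg.matrix_rank(xc))
    if n <= rank + 1:
        raise ValueError(f"need n > rank + 1 rows (n={n}, rank={rank})")
    return ezekiel_adjust(_r2(y, x), n, rank)


def rda_adjusted_r2(Y, X) -> float:
    """Adjusted RDA R² of a (Hellinger-transformed) community matrix on X."""
    y, _ = _as_matrix(Y)
    x, names = _as_matrix(X)
    if y.shape[0] != x.shape[0]:
        raise ValueError("Y and X must have the same number of rows")
    n, p = x.shape
    if p > 0 and n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (n={n}, p={p})")
    _check_rank(x, names)
    return ezekiel_adjust(_r2(y, x), n, p)


def vif_filter(X: pd.DataFrame, threshold: float = 20.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the highest-VIF column until all VIF <= threshold.

    VIF_j = 1 / (1 - R²_j) from regressing column j on the remaining
    columns.  Exactly collinear columns have infinite VIF and go first.
    Returns the reduced frame and the removal log (in removal order).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    removed: list[str] = []
    cols = list(X.columns)
    while len(cols) >= 2:
        x = X[cols].to_numpy(dtype=float)
        vifs = np.empty(len(cols))
        for j in range(len(cols)):
            others = np.delete(x, j, axis=1)
            target = x[:, j : j + 1]
            r2_j = _r2(target, others)
            vifs[j] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        removed.append(cols[worst])
        cols.pop(worst)
    return X[cols], removed


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    permutations: int = 999,
    seed: int = 0,
) -> list[str]:
    """Forward selection of predictors with Blanchet's double stopping rule.

    Prerequisite: the global model (all candidates) must itself be
    significant under permutation, otherwise nothing is selected.  Then
    candidates are added greedily by largest R² gain; a candidate is
    accepted only if its marginal permutation p-value (residual permutation
    under the current model) is <= alpha, and selection stops once the
    cumulative adjusted R² reaches the global model's adjusted R² (the
    crossing variable is retained, matching the reference implementations
    of this procedure).  Deterministic given ``seed``.
    """
    y, _ = _as_matrix(Y)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    candidates = list(X.columns)
    if not candidates:
        return []

    x_all = X.to_numpy(dtype=float)
    r2_full = _r2(y, x_all)
    adj_full = ezekiel_adjust(r2_full, n, x_all.shape[1])
    # global permutation test (permute Y rows)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if _r2(y[perm], x_all) >= r2_full:
            count += 1
    p_global = (1 + count) / (1 + permutations)
    if p_global > alpha:
        return []

    selected: list[str] = []
    resid = y - y.mean(axis=0, keepdims=True)
    while candidates:
        gains = []
        for c in candidates:
            x_try = X[selected + [c]].to_numpy(dtype=float)
            gains.append(_r2(y, x_try))
        best = int(np.argmax(gains))
        cand = candidates[best]
        x_new = X[selected + [cand]].to_numpy(dtype=float)
        r2_new = gains[best]
        adj_new = ezekiel_adjust(r2_new, n, len(selected) + 1)
        r2_old = _r2(y, X[selected].to_numpy(dtype=float)) if selected else 0.0
        gain_obs = r2_new - r2_old
        # marginal test: permute residuals of the current model
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            y_perm = (y - resid) + resid[perm]
            r2_perm = _r2(y_perm, x_new)
            r2_perm_old = _r2(y_perm, X[selected].to_numpy(dtype=float)) if selected else 0.0
            if r2_perm - r2_perm_old >= gain_obs:
                count += 1
        p_cand = (1 + count) / (1 + permutations)
        if p_cand > alpha:
            break
        selected.append(cand)
        candidates.remove(cand)
        # second stopping criterion: once the cumulative adjusted R² reaches
        # the global model's, stop; the crossing variable is retained (the
        # convention of the reference forward-selection implementations)
        if not np.isnan(adj_full) and not np.isnan(adj_new) and adj_new > adj_full:
            break
        # refresh residuals under the enlarged model
        xs = X[selected].to_numpy(dtype=float)
        xc = np.column_stack([np.ones(n), xs - xs.mean(axis=0, keepdims=True)])
        coef, *_ = np.linalg.lstsq(xc, y, rcond=None)
        resid = y - xc @ coef
    return selected


def varpart2(Y, X_env, X_spatial) -> VarpartResult:
    """Two-set variation partition by adjusted RDA R².

    a = adjR²(env ∪ spa) - adjR²(spa)   (pure environment)
    c = adjR²(env ∪ spa) - adjR²(env)   (pure space)
    b = adjR²(env) - a                  (shared)
    d = 1 - adjR²(env ∪ spa)            (unexplained)
    """
    y, _ = _as_matrix(Y)
    xe, env_names = _as_matrix(X_env)
    xs, spa_names = _as_matrix(X_spatial)
    if xe.shape[1] == 0 or xs.shape[1] == 0:
        warnings.warn("a predictor set is empty; two-fraction report", stacklevel=2)
        x = xe if xe.shape[1] else xs
        adj = rda_adjusted_r2(y, x) if x.shape[1] else 0.0
        which = "env" if xe.shape[1] else "spatial"
        fr = {
            "pure_env": adj if which == "env" else 0.0,
            "shared": 0.0,
            "pure_spatial": adj if which == "spatial" else 0.0,
            "unexplained": 1.0 - adj,
        }
        return VarpartResult(fr, env_names, spa_names, "rda", {"degenerate": which})
    adj_env = _adjusted_r2_rank(y, xe)
    adj_spa = _adjusted_r2_rank(y, xs)
    adj_both = _adjusted_r2_rank(y, np.hstack([xe, xs]))
    a = adj_both - adj_spa
    c = adj_both - adj_env
    b = adj_env - a
    d = 1.0 - adj_both
    result = VarpartResult(
        fractions={"pure_env": a, "shared": b, "pure_spatial": c, "unexplained": d},
        selected_env=env_names,
        selected_spatial=spa_names,
        method="rda",
        details={"adj_env": adj_env, "adj_spatial": adj_spa, "adj_both": adj_both},
    )
    if result.has_negative_fractions:
        warnings.warn("negative adjusted fraction(s) reported as-is", stacklevel=2)
    return result


def varpart_mantel(
    dm_comm: DistanceMatrix,
    dm_env: DistanceMatrix,
    dm_spa: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int = 0,
) -> VarpartResult:
    """Distance-matrix analogue of the two-set partition.

    Fractions come from squared (partial) Mantel correlations: the combined
    fraction is the R² of the multiple regression of the community distances
    on both explanatory distance vectors; a and c follow by subtracting the
    single-matrix r².  Reported alongside the RDA version, never mixed.
    """
    _check_labels(dm_comm, dm_env, dm_spa)
    a_v = _mantel_vectors(dm_comm, method)
    e_v = _mantel_vectors(dm_env, method)
    s_v = _mantel_vectors(dm_spa, method)
    r_env = _corr(a_v, e_v)
    r_spa = _corr(a_v, s_v)
    design = np.column_stack([np.ones_like(e_v), e_v, s_v])
    coef, *_ = np.linalg.lstsq(design, a_v, rcond=None)
    fitted = design @ coef
    sst = float(np.sum((a_v - a_v.mean()) ** 2))
    r2_both = float(np.sum((fitted - a_v.mean()) ** 2)) / sst if sst else np.nan
    ab = r_env**2
    bc = r_spa**2
    a = r2_both - bc
    c = r2_both - ab
    b = ab - a
    d = 1.0 - r2_both
    pm_env = partial_mantel(
        dm_comm, dm_env, dm_spa, method=method, permutations=permutations, seed=seed
    )
    pm_spa = partial_mantel(
        dm_comm, dm_spa, dm_env, method=method, permutations=permutations,
        seed=seed + 1,
    )
    return VarpartResult(
        fractions={"pure_env": a, "shared": b, "pure_spatial": c, "unexplained": d},
        selected_env=["env-distance"],
        selected_spatial=["spatial-distance"],
        method="partial-mantel",
        details={
            "r_env": r_env,
            "r_spatial": r_spa,
            "r2_both": r2_both,
            "partial_env_given_spatial": pm_env,
            "partial_spatial_given_env": pm_spa,
        },
    )
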