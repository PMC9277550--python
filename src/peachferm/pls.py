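"""NIPALS partial least squares (PLS2) with VIP scores.

Implements the classical two-block NIPALS algorithm with deflation of both
blocks, written out in full because the variable-importance-in-projection
(VIP) statistic is the screening engine of this package:

    VIP_j = sqrt( p * sum_a ssy_a * w_ja^2 / sum_a ssy_a ),

with unit-norm weight columns ``w_a`` and per-component explained Y sum of
squares ``ssy_a = (t_a' t_a)(q_a' q_a)``.  The identity sum_j VIP_j^2 = p
makes VIP > 1 the natural "above average importance" cut.

Both blocks are autoscaled (column mean 0, unit variance) by default, the
convention of the commercial PLS tools this mirrors; scaling parameters are
stored on the model so predictions return to the original units.
Cross-validated component selection uses leave-one-out Q^2 with a
SIMCA-style "keep adding while the marginal Q^2 gain exceeds 0.05" rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSModel", "CVReport", "fit_pls2", "vip_scores", "predict", "select_components_cv"]


@dataclass
class PLSModel:
    A: int
    W: np.ndarray        # p x A, unit-norm weight columns
    T: np.ndarray        # n x A, orthogonal score columns
    P_load: np.ndarray   # p x A X-loadings
    Q: np.ndarray        # m x A Y-loadings
    ssy: np.ndarray      # per-component explained SS of (scaled) Y
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    x_names: list = field(default_factory=list)
    y_names: list = field(default_factory=list)
    dropped_x: list = field(default_factory=list)
    dropped_y: list = field(default_factory=list)

    @property
    def vip(self) -> pd.Series:
        return pd.Series(vip_scores(self), index=self.x_names, name="vip")

    @property
    def r2y(self) -> np.ndarray:
        """Cumulative fraction of (scaled) Y sum of squares explained."""
        total = self._total_ssy
        return np.cumsum(self.ssy) / total

    _total_ssy: float = 0.0


@dataclass
class CVReport:
    q2: np.ndarray       # Q^2 per number of components 1..A_max
    chosen_A: int
    rule: str = "marginal Q2 gain > 0.05, minimum 1 component"


def _prepare(M, names_hint: str) -> tuple[np.ndarray, list]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.columns)
    arr = np.asarray(M, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{names_hint}{j}" for j in range(arr.shape[1])]


def _autoscale(M: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
    else:
        sd = np.ones(M.shape[1])
    return (M - mean) / sd, mean, sd


def fit_pls2(X, Y, A: int, scale: bool = True, tol: float = 1e-10,
             max_iter: int = 5000) -> PLSModel:
    """Fit a PLS2 model by NIPALS with deflation of both blocks.

    Per component: iterate w = X'u/||X'u||, t = Xw, q = Y't/(t't),
    u = Yq/(q'q) until t moves by less than ``tol`` relative to ||t||
    (near-degenerate component pairs converge slowly, hence the generous
    iteration cap); deflate X by t p'
    (p = X't/(t't)) and Y by t q'.  u is initialised from the first Y
    column (ties in the dominant direction are thereby broken
    deterministically).  Constant columns are dropped with a warning before
    autoscaling; non-convergence raises naming the component.
    """
    Xm, x_names = _prepare(X, "x")
    Ym, y_names = _prepare(Y, "y")
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (np.isfinite(Xm).all() and np.isfinite(Ym).all()):
        raise ValueError("X and Y must be finite")

    keep_x = Xm.std(axis=0) > 0
    keep_y = Ym.std(axis=0) > 0
    dropped_x = [nm for nm, k in zip(x_names, keep_x) if not k]
    dropped_y = [nm for nm, k in zip(y_names, keep_y) if not k]
    if dropped_x or dropped_y:
        warnings.warn(f"dropping constant columns: {dropped_x + dropped_y}")
    Xm, x_names = Xm[:, keep_x], [nm for nm, k in zip(x_names, keep_x) if k]
    Ym, y_names = Ym[:, keep_y], [nm for nm, k in zip(y_names, keep_y) if k]
    p, m = Xm.shape[1], Ym.shape[1]
    if not (1 <= A <= min(n - 1, p)):
        raise ValueError(f"A={A} out of range (max {min(n - 1, p)})")

    Xs, x_mean, x_scale = _autoscale(Xm, scale)
    Ys, y_mean, y_scale = _autoscale(Ym, scale)
    total_ssy = float((Ys**2).sum())

    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P_load = np.zeros((p, A))
    Q = np.zeros((m, A))
    ssy = np.zeros(A)
    Xr, Yr = Xs.copy(), Ys.copy()
    for a in range(A):
        u = Yr[:, 0].copy()
        if np.allclose(u, 0):
            u = Yr[:, np.argmax((Yr**2).sum(axis=0))].copy()
        t_old = None
        rel_change = np.inf
        converged = False
        for _ in range(max_iter):
            w = Xr.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise RuntimeError(f"component {a + 1}: X residual orthogonal to u")
            w /= norm
            t = Xr @ w
            tt = float(t @ t)
            if tt == 0:
                raise RuntimeError(f"component {a + 1}: degenerate score vector")
            q = Yr.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                raise RuntimeError(f"component {a + 1}: Y residual unexplained")
            u = Yr @ q / qq
            if t_old is not None:
                rel_change = np.linalg.norm(t - t_old) / np.linalg.norm(t)
                if rel_change < tol:
                    converged = True
                    break
            t_old = t
        if not converged:
            # a nearly tied pair of components converges geometrically with
            # ratio ~1; any vector in the tied subspace is an equally valid
            # component and deflation recovers its complement next, so a
            # stagnated iterate is accepted (with a warning) rather than
            # rejected
            if rel_change < 1e-5:
                warnings.warn(
                    f"component {a + 1}: accepting stagnated NIPALS iterate "
                    f"(relative change {rel_change:.1e}; near-degenerate pair)"
                )
            else:
                raise RuntimeError(f"NIPALS did not converge on component {a + 1}")
        p_vec = Xr.T @ t / tt
        W[:, a], T[:, a], P_load[:, a], Q[:, a] = w, t, p_vec, q
        ssy[a] = tt * qq
        Xr = Xr - np.outer(t, p_vec)
        Yr = Yr - np.outer(t, q)

    model = PLSModel(A, W, T, P_load, Q, ssy, x_mean, x_scale, y_mean, y_scale,
                     x_names, y_names, dropped_x, dropped_y)
    model._total_ssy = total_ssy
    return model


def vip_scores(model: PLSModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a ssy_a w_ja^2 / sum_a ssy_a)."""
    s = model.ssy
    if s.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.W.shape[0]
    wnorm2 = model.W**2 / np.maximum((model.W**2).sum(axis=0), 1e-300)
    return np.sqrt(p * (wnorm2 * s).sum(axis=1) / s.sum())


def _coefficients(model: PLSModel, A: int | None = None) -> np.ndarray:
    A = model.A if A is None else A
    W, P, Q = model.W[:, :A], model.P_load[:, :A], model.Q[:, :A]
    return W @ np.linalg.solve(P.T @ W, Q.T)


def predict(model: PLSModel, X, A: int | None = None) -> np.ndarray:
    """Predict Y (original units) for new X rows using A components."""
    Xm, names = _prepare(X, "x")
    if isinstance(X, pd.DataFrame):
        Xm = X[model.x_names].to_numpy(dtype=float)
    Xs = (Xm - model.x_mean) / model.x_scale
    Ys = Xs @ _coefficients(model, A)
    return Ys * model.y_scale + model.y_mean


def select_components_cv(X, Y, A_max: int = 5, scale: bool = True) -> CVReport:
    """Leave-one-out Q^2(A) = 1 - PRESS(A)/SS(Y), SIMCA-style selection.

    PRESS and SS(Y) are accumulated on the autoscaled response (each
    column weighted by the inverse of its overall standard deviation), so
    a compound with large absolute concentrations cannot mask predictive
    gains on the others.  Components are added while the marginal Q^2 gain
    exceeds 0.05; at least one component is always kept (pure-noise Y then
    simply reports a non-positive Q^2).
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    Xm, _ = _prepare(X, "x")
    Ym, _ = _prepare(Y, "y")
    n = Xm.shape[0]
    if n < 4:
        raise ValueError("LOO cross-validation needs at least 4 samples")
    A_max = min(A_max, n - 2, Xm.shape[1])
    y_sd = Ym.std(axis=0, ddof=1)
    y_sd[y_sd == 0] = 1.0
    press = np.zeros(A_max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask = np.arange(n) != i
            fold = fit_pls2(Xm[mask], Ym[mask], A_max, scale=scale)
            kept = [j for j, nm in enumerate([f"x{j}" for j in range(Xm.shape[1])])
                    if nm not in fold.dropped_x]
            kept_y = [j for j in range(Ym.shape[1]) if f"y{j}" not in fold.dropped_y]
            xi = Xm[i][kept][None, :]
            yi = Ym[i][kept_y]
            for a in range(1, A_max + 1):
                yhat = predict(fold, xi, A=a)[0]
                press[a - 1] += float((((yi - yhat) / y_sd[kept_y]) ** 2).sum())
    ss = float((((Ym - Ym.mean(axis=0)) / y_sd) ** 2).sum())
    q2 = 1.0 - press / ss
    chosen = 1
    for a in range(2, A_max + 1):
        if q2[a - 1] - q2[a - 2] > 0.05:
            chosen = a
        else:
            break
    return CVReport(q2=q2, chosen_A=chosen)
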