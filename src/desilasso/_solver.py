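"""Proximal-gradient solver for L1-penalized multinomial logistic regression.

Objective, over standardized features X_s = (X - mean) / scale:

    f(W, b) = (1/n) * sum_i [ logsumexp(z_i) - z_{i, y_i} ] + lam * sum |W|,
    z_i = X_s[i] @ W + b

solved by FISTA (accelerated proximal gradient with backtracking line search
and adaptive restart) on a working set of features (the warm-start support
plus KKT-bound violators), with a full KKT sweep guaranteeing optimality
over all features.  Standardization is applied implicitly -- the raw matrix is
never copied -- so the solver is cheap to warm-start along a penalty path.

The intercepts are unpenalized; because the softmax is invariant to adding a
constant to every class score, the returned intercepts are centered to sum
to zero.

KKT certificate at the solution (G = gradient of the smooth part w.r.t. W):
``|G_jk| <= lam + tol`` where ``W_jk = 0`` and ``G_jk = -lam * sign(W_jk)``
(within tol) where ``W_jk != 0``; the intercept gradient vanishes.
"""

from __future__ import annotations

import numpy as np


def one_hot(labels: np.ndarray, classes: tuple) -> np.ndarray:
    index = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and scale; constant features get scale 1."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _scores(X, W, b, mean, scale):
    # X_s @ W + b without materializing X_s
    V = W / scale[:, None]
    return X @ V + (b - mean @ V)


def _nll_of_scores(Z, Y) -> float:
    m = Z.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(Z - m).sum(axis=1))
    return float((lse - (Z * Y).sum(axis=1)).mean())


def nll(X, Y, W, b, mean, scale) -> float:
    """(1/n) multinomial negative log-likelihood (smooth part)."""
    return _nll_of_scores(_scores(X, W, b, mean, scale), Y)


def objective(X, Y, W, b, lam, mean, scale) -> float:
    return nll(X, Y, W, b, mean, scale) + lam * np.abs(W).sum()


def _softmax(Z):
    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    return P


def _grad(X, Y, W, b, mean, scale):
    """Gradient of the smooth part w.r.t. (W, b); also returns probs."""
    n = X.shape[0]
    P = _softmax(_scores(X, W, b, mean, scale))
    R = (P - Y) / n
    col = R.sum(axis=0)
    GW = (X.T @ R - np.outer(mean, col)) / scale[:, None]
    return GW, col, P


def _value_and_grad(X, Y, W, b, mean, scale):
    """Smooth value and gradient sharing one score evaluation."""
    n = X.shape[0]
    Z = _scores(X, W, b, mean, scale)
    f = _nll_of_scores(Z, Y)
    R = (_softmax(Z) - Y) / n
    col = R.sum(axis=0)
    GW = (X.T @ R - np.outer(mean, col)) / scale[:, None]
    return f, GW, col


def lambda_max(X, Y, mean, scale) -> float:
    """Smallest penalty at which every weight is exactly zero.

    At W = 0 the optimal intercepts reproduce the class frequencies; the
    penalty saturates when it dominates every component of the smooth
    gradient there.
    """
    n = X.shape[0]
    pi = Y.mean(axis=0)
    R = (pi[None, :] - Y) / n
    GW = (X.T @ R - np.outer(mean, R.sum(axis=0))) / scale[:, None]
    return float(np.abs(GW).max())


def null_intercepts(Y: np.ndarray) -> np.ndarray:
    """Centered intercepts of the zero-weight model (log class frequencies)."""
    pi = Y.mean(axis=0)
    if np.any(pi == 0):
        raise ValueError("every class must appear in the training labels")
    b = np.log(pi)
    return b - b.mean()


def kkt_violation(GW: np.ndarray, W: np.ndarray, lam: float) -> float:
    """Largest violation of the L1 stationarity conditions."""
    zero = W == 0
    v_zero = np.maximum(np.abs(GW) - lam, 0.0)[zero].max(initial=0.0)
    v_nz = np.abs(GW + lam * np.sign(W))[~zero].max(initial=0.0)
    return max(v_zero, v_nz)


def _soft(A, t):
    return np.sign(A) * np.maximum(np.abs(A) - t, 0.0)


def _fista(X, Y, lam, mean, scale, W, b, tol, max_iter, L0):
    """FISTA with backtracking and restart on the given (sub)problem.

    Stops when the KKT violation (including the intercept gradient) falls
    below ``tol``.  Returns (W, b, L, n_iter).
    """
    n, p = X.shape
    W = W.copy()
    b = b.copy()
    Wy, by = W.copy(), b.copy()
    t_mom = 1.0
    L = L0
    f_prev = None
    check_every = 5
    for it in range(1, max_iter + 1):
        fy, GW, Gb = _value_and_grad(X, Y, Wy, by, mean, scale)
        # backtracking line search on the smooth part
        for _ in range(60):
            W_new = _soft(Wy - GW / L, lam / L)
            b_new = by - Gb / L
            dW, db = W_new - Wy, b_new - by
            quad = fy + (GW * dW).sum() + (Gb * db).sum() + 0.5 * L * (
                (dW * dW).sum() + (db * db).sum()
            )
            f_new = nll(X, Y, W_new, b_new, mean, scale)
            if f_new <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            L *= 2.0
        obj_new = f_new + lam * np.abs(W_new).sum()
        if f_prev is not None and obj_new > f_prev:  # adaptive restart
            Wy, by = W, b
            t_mom = 1.0
            f_prev = None
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        Wy = W_new + ((t_mom - 1.0) / t_next) * (W_new - W)
        by = b_new + ((t_mom - 1.0) / t_next) * (b_new - b)
        W, b = W_new, b_new
        t_mom = t_next
        f_prev = obj_new
        if it % check_every == 0 or it == max_iter:
            GW, Gb, _ = _grad(X, Y, W, b, mean, scale)
            if max(kkt_violation(GW, W, lam), np.abs(Gb).max()) <= tol:
                break
        L *= 0.9  # allow the step to grow again
    return W, b, L, it


def fit_l1_multinomial(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    mean: np.ndarray,
    scale: np.ndarray,
    W0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 20000,
    lam_prev: float | None = None,
    screen: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the penalized problem at one penalty value.

    ``tol`` bounds the final KKT violation over *all* features.  When
    ``screen`` is enabled (default for wide problems) the solver iterates on
    a working set -- the warm-start support plus every feature at or above
    the KKT bound ``|G_jk| >= lam`` at the warm start -- and re-sweeps the
    full gradient, growing the set, until no feature violates the KKT
    conditions.
    """
    n, p = X.shape
    K = Y.shape[1]
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    W = np.zeros((p, K)) if W0 is None else W0.copy()
    b = null_intercepts(Y) if b0 is None else b0.copy()
    if screen is None:
        screen = p > 200 and lam > 0
    if not screen:
        W, b, _, _ = _fista(X, Y, lam, mean, scale, W, b, tol, max_iter, L0=1.0)
        return _cleanup(W), b - b.mean()

    # working set: warm-start support plus features at/above the KKT bound
    # at the warm start (the outer loop adds any violators it missed)
    GW, _, _ = _grad(X, Y, W, b, mean, scale)
    ws = (np.abs(GW).max(axis=1) >= lam * (1.0 - 1e-12)) | (
        np.abs(W).sum(axis=1) > 0
    )
    L0 = 1.0
    for _ in range(100):
        if not ws.any():
            ws[np.abs(GW).max(axis=1).argmax()] = True
        idx = np.nonzero(ws)[0]
        Ws, bs, L0, _ = _fista(
            X[:, idx], Y, lam, mean[idx], scale[idx], W[idx], b, tol, max_iter, L0
        )
        W[:] = 0.0
        W[idx] = Ws
        b = bs
        GW, Gb, _ = _grad(X, Y, W, b, mean, scale)
        viol = np.maximum(np.abs(GW) - lam, 0.0)
        viol[idx] = 0.0  # working set is converged
        if viol.max() <= tol:
            break
        ws |= viol.max(axis=1) > tol
    return _cleanup(W), b - b.mean()


def _cleanup(W: np.ndarray) -> np.ndarray:
    """Zero numerical dust (|w| below 1e-10) and normalize -0.0 to 0.0."""
    W[np.abs(W) < 1e-10] = 0.0
    return W + 0.0


# ---------------------------------------------------------------------------
# independent oracle (generic convex optimizer on the same objective)
# ---------------------------------------------------------------------------


def oracle_fit(X, Y, lam, mean, scale, tol: float = 1e-12, maxiter: int = 20000):
    """Reference solution via L-BFGS-B on the split W = W+ - W-.

    A generic convex optimizer on the identical objective, used as the
    independent cross-check of the proximal solver; it shares no code path
    with :func:`fit_l1_multinomial`.
    """
    from scipy.optimize import minimize

    n, p = X.shape
    K = Y.shape[1]
    m = p * K

    def fun(theta):
        Wp = theta[:m].reshape(p, K)
        Wm = theta[m : 2 * m].reshape(p, K)
        b = theta[2 * m :]
        W = Wp - Wm
        GW, Gb, _ = _grad(X, Y, W, b, mean, scale)
        f = nll(X, Y, W, b, mean, scale) + lam * (Wp.sum() + Wm.sum())
        g = np.concatenate([(GW + lam).ravel(), (-GW + lam).ravel(), Gb])
        return f, g

    x0 = np.zeros(2 * m + K)
    bounds = [(0, None)] * (2 * m) + [(None, None)] * K
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
    )
    Wp = res.x[:m].reshape(p, K)
    Wm = res.x[m : 2 * m].reshape(p, K)
    b = res.x[2 * m :]
    W = Wp - Wm
    return W, b - b.mean(), objective(X, Y, W, b, lam, mean, scale)
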