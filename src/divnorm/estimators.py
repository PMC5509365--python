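"""Feature-estimation dynamics under the linear generative model.

Two gradient flows on the feature estimate ``x_hat``:

* **divisive** (signal-dependent / Poisson noise):
  ``dx_i/dt = eta * sum_j w_ji (s_j / (W x_hat + w0)_j - 1)`` — a weighted
  sum of *fractional* prediction errors.  This is gradient ascent on the
  Poisson log-likelihood, so interior fixed points are maximum-likelihood
  feature estimates.
* **subtractive** (constant Gaussian noise):
  ``dx_i/dt = eta * sum_j w_ji (s_j - (W x_hat + w0)_j)`` — absolute
  prediction errors; the unconstrained fixed point is the ordinary
  least-squares solution ``(W^T W)^-1 W^T (s - w0)``.

Both flows are integrated with explicit Euler steps and (by default) a
projection onto the nonnegative orthant after each step, so clamped fixed
points solve the corresponding *constrained* problem (Poisson ML / NNLS).

:func:`ml_estimate` provides a fast multiplicative-update solver
(Richardson–Lucy / EM with a known background) for the same Poisson ML
problem; it supports batches of input vectors and is what the large
measurement protocols use.  Its fixed points coincide with those of
:func:`run_to_convergence` in divisive mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .basis import FeatureBasis

__all__ = [
    "EstimatorConfig",
    "EstimatorState",
    "fractional_errors",
    "absolute_errors",
    "poisson_loglik",
    "divisive_step",
    "subtractive_step",
    "run_to_convergence",
    "subtractive_closed_form",
    "subtractive_linear",
    "subtractive_nnls",
    "ml_estimate",
    "effective_weights",
    "save_estimator_trace",
    "default_eta",
    "stationarity_residual",
]


@dataclass
class EstimatorConfig:
    """Numerical parameters of the estimation dynamics.

    ``eta`` is the update rate; if None it defaults to
    ``1e-3 / max column sum of W`` which keeps the Euler iteration smooth for
    every basis in this package.  Convergence is declared when the largest
    per-step change of ``x_hat`` falls below ``tol``.
    """

    eta: float | None = None
    max_iters: int = 100_000
    tol: float = 1e-8
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.eta is not None and not self.eta > 0:
            raise ValueError("eta must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")

    def resolved_eta(self, basis: FeatureBasis) -> float:
        return self.eta if self.eta is not None else default_eta(basis)


def default_eta(basis: FeatureBasis) -> float:
    """Default update rate: 1e-3 over the largest column sum of W."""
    colsum = basis.weights.sum(axis=0).max()
    return 1e-3 / max(colsum, 1e-12)


@dataclass
class EstimatorState:
    """Current estimate with convergence bookkeeping."""

    x_hat: np.ndarray
    iter: int = 0
    converged: bool = False
    loglik_trace: list = field(default_factory=list)
    trajectory: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float)


def _check_inputs(basis: FeatureBasis, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != basis.n_inputs:
        raise ValueError(
            f"input axis mismatch: s has {s.shape[-1]} inputs, basis expects m={basis.n_inputs}"
        )
    return s


def _predictions(basis: FeatureBasis, x_hat: np.ndarray) -> np.ndarray:
    x_hat = np.asarray(x_hat, dtype=float)
    return x_hat @ basis.weights.T + basis.background


def fractional_errors(basis: FeatureBasis, x_hat: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Fractional prediction errors ``s_j / <s_j(x_hat)> - 1``.

    Zero when the input is perfectly predicted; bounded below by -1 since
    inputs are nonnegative and predictions are at least ``w0 > 0``.
    """
    s = _check_inputs(basis, s)
    return s / _predictions(basis, x_hat) - 1.0


def absolute_errors(basis: FeatureBasis, x_hat: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Absolute prediction errors ``s_j - <s_j(x_hat)>`` (Gaussian-noise case)."""
    s = _check_inputs(basis, s)
    return s - _predictions(basis, x_hat)


def poisson_loglik(basis: FeatureBasis, x_hat: np.ndarray, s: np.ndarray) -> float | np.ndarray:
    """Poisson log-likelihood ``sum_j [s_j log lam_j - lam_j]`` with
    ``lam = W x_hat + w0`` (the constant ``log s_j!`` terms are dropped).

    Accepts batched ``x_hat``/``s`` with matching leading axes.
    """
    s = _check_inputs(basis, s)
    lam = _predictions(basis, x_hat)
    val = np.sum(s * np.log(lam) - lam, axis=-1)
    return float(val) if np.ndim(val) == 0 else val


def _apply_step(state: EstimatorState, grad: np.ndarray, eta: float, clamp: bool,
                record_loglik: float | None) -> EstimatorState:
    delta = eta * grad
    if not np.all(np.isfinite(delta)):
        bad = int(np.argmax(~np.isfinite(delta)))
        raise FloatingPointError(f"non-finite update for feature index {bad}")
    x_new = state.x_hat + delta
    if clamp:
        np.maximum(x_new, 0.0, out=x_new)
    trace = state.loglik_trace
    if record_loglik is not None:
        trace = trace + [record_loglik]
    return EstimatorState(x_new, iter=state.iter + 1, converged=state.converged,
                          loglik_trace=trace)


def divisive_step(
    basis: FeatureBasis,
    state: EstimatorState,
    s: np.ndarray,
    config: EstimatorConfig,
) -> EstimatorState:
    """One Euler step of the divisive (fractional-error) dynamics."""
    grad = fractional_errors(basis, state.x_hat, s) @ basis.weights
    return _apply_step(state, grad, config.resolved_eta(basis),
                       config.clamp_nonnegative, None)


def subtractive_step(
    basis: FeatureBasis,
    state: EstimatorState,
    s: np.ndarray,
    config: EstimatorConfig,
) -> EstimatorState:
    """One Euler step of the subtractive (absolute-error) dynamics."""
    grad = absolute_errors(basis, state.x_hat, s) @ basis.weights
    return _apply_step(state, grad, config.resolved_eta(basis),
                       config.clamp_nonnegative, None)


def run_to_convergence(
    basis: FeatureBasis,
    s: np.ndarray,
    config: EstimatorConfig | None = None,
    mode: str = "divisive",
    x0: np.ndarray | None = None,
    record_loglik: bool = False,
    record_trajectory: bool = False,
) -> EstimatorState:
    """Iterate the chosen dynamics from ``x0`` (default all-zero) until the
    largest per-step change drops below ``config.tol`` or ``max_iters`` is
    reached.  Non-convergence is flagged on the returned state, never raised.
    """
    if mode not in ("divisive", "subtractive"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or EstimatorConfig()
    s = _check_inputs(basis, s)
    x = np.zeros(basis.n_features) if x0 is None else np.asarray(x0, dtype=float).copy()
    eta = config.resolved_eta(basis)
    W = basis.weights
    clamp = config.clamp_nonnegative
    trace: list[float] = []
    trajectory: list[np.ndarray] = [x.copy()] if record_trajectory else []
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        if mode == "divisive":
            err = s / (x @ W.T + basis.background) - 1.0
        else:
            err = s - (x @ W.T + basis.background)
        delta = eta * (err @ W)
        if not np.all(np.isfinite(delta)):
            bad = int(np.argmax(~np.isfinite(delta)))
            raise FloatingPointError(f"non-finite update for feature index {bad}")
        x_new = x + delta
        if clamp:
            np.maximum(x_new, 0.0, out=x_new)
        if record_loglik:
            trace.append(float(np.sum(s * np.log(x @ W.T + basis.background)
                                      - (x @ W.T + basis.background))))
        step = np.max(np.abs(x_new - x)) if x.size else 0.0
        x = x_new
        if record_trajectory:
            trajectory.append(x.copy())
        if step < config.tol:
            converged = True
            break
    return EstimatorState(x, iter=it, converged=converged, loglik_trace=trace,
                          trajectory=np.array(trajectory) if record_trajectory
                          else None)


def subtractive_closed_form(
    basis: FeatureBasis,
    s: np.ndarray,
    ridge: float = 0.0,
    clamp: bool = True,
) -> np.ndarray:
    """Closed-form subtractive estimate ``(W^T W)^-1 W^T (s - w0)``.

    The background is subtracted first so that noiseless inputs recover the
    generating features exactly.  The result is clamped at zero by default
    for comparison with the clamped dynamics; pass ``clamp=False`` for the
    raw least-squares solution.  Raises on singular ``W^T W`` (suggesting a
    ridge), e.g. for even-sized paired bases which are rank deficient.
    """
    s = _check_inputs(basis, s)
    W = basis.weights
    G = W.T @ W
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    rhs = (s - basis.background) @ W
    try:
        # solve G x = rhs for (possibly batched) rhs
        x = np.linalg.solve(G, np.asarray(rhs)[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "W^T W is singular; pass ridge > 0 to regularize the closed form"
        ) from exc
    if np.linalg.cond(G) > 1e12 and not ridge:
        raise np.linalg.LinAlgError(
            "W^T W is numerically singular (cond > 1e12); pass ridge > 0"
        )
    return np.clip(x, 0.0, None) if clamp else x


def subtractive_linear(basis: FeatureBasis, s: np.ndarray) -> np.ndarray:
    """Unconstrained (fully linear) subtractive readout: the minimum-norm
    least-squares solution of ``W x = s - w0``.

    This is the subtractive model in its defining linear regime — a static
    center-surround feed-forward filter — and remains well defined for
    rank-deficient bases (e.g. the even-sized paired basis), where it picks
    the minimum-norm representative.  ``s`` may be batched.
    """
    s = _check_inputs(basis, s)
    sol, *_ = np.linalg.lstsq(basis.weights, np.atleast_2d(s - basis.background).T,
                              rcond=None)
    return sol.T[0] if s.ndim == 1 else sol.T


def subtractive_nnls(basis: FeatureBasis, s: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares fixed point of the clamped subtractive
    dynamics, computed directly (active-set NNLS).  ``s`` may be batched."""
    s = _check_inputs(basis, s)
    W = basis.weights
    if s.ndim == 1:
        return nnls(W, s - basis.background)[0]
    return np.stack([nnls(W, row - basis.background)[0] for row in s])


def ml_estimate(
    basis: FeatureBasis,
    s: np.ndarray,
    max_iters: int = 2000,
    tol: float = 1e-9,
    x0: np.ndarray | None = None,
    polish: bool = False,
) -> np.ndarray:
    """Poisson maximum-likelihood feature estimate by multiplicative updates.

    Iterates ``x <- x * (W^T (s / (W x + w0))) / colsum(W)``, the EM /
    Richardson–Lucy update for a linear-Poisson model with known background.
    Each iteration is guaranteed not to decrease the likelihood, and fixed
    points satisfy the same stationarity conditions as the divisive gradient
    dynamics.  ``s`` may be a batch ``(..., m)``; the solver is vectorized
    over the batch.  Convergence is on the largest relative change of the
    prediction ``W x + w0`` (robust to features sliding to the zero
    boundary).

    ``polish=True`` finishes each solution with projected-Newton steps on
    the negative log-likelihood (the problem is convex): on severely
    ill-conditioned bases the first-order multiplicative updates approach
    the optimum only slowly along the flattest directions, and the
    second-order polish drives the stationarity residual to near machine
    level.
    """
    s = _check_inputs(basis, s)
    W = basis.weights
    colsum = W.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("every feature must drive at least one input")
    if x0 is None:
        # rough positive init: explain the mean excess input uniformly
        excess = np.clip(s.mean(axis=-1, keepdims=True) - basis.background, 1e-6, None)
        x = np.broadcast_to(excess / colsum.mean(), s.shape[:-1] + (basis.n_features,)).copy()
    else:
        x = np.asarray(x0, dtype=float).copy()
        if np.any(x <= 0):
            raise ValueError("multiplicative updates need a strictly positive x0")
    lam_prev = x @ W.T + basis.background
    for _ in range(max_iters):
        ratio = (s / lam_prev) @ W
        x *= ratio / colsum
        lam = x @ W.T + basis.background
        if np.max(np.abs(lam - lam_prev) / np.maximum(lam, 1e-12)) < tol:
            break
        lam_prev = lam
    if polish:
        flat_s = np.atleast_2d(s.reshape(-1, basis.n_inputs))
        flat_x = np.atleast_2d(x.reshape(-1, basis.n_features))
        for i in range(flat_s.shape[0]):
            flat_x[i] = _projected_newton(basis, flat_s[i], flat_x[i])
        x = flat_x.reshape(x.shape)
    return x


def _projected_newton(basis: FeatureBasis, s: np.ndarray, x0: np.ndarray,
                      max_iters: int = 200, res_tol: float = 1e-12) -> np.ndarray:
    """High-precision solver for the nonnegative Poisson-ML problem:
    Newton steps on the free (non-bound) variables with backtracking and
    projection onto the nonnegative orthant."""
    W = basis.weights
    w0 = basis.background
    n = basis.n_features
    x = np.clip(np.asarray(x0, dtype=float), 0.0, None)

    def negll(xv):
        lam = W @ xv + w0
        return -(np.sum(s * np.log(lam) - lam))

    mu = 0.0  # Levenberg damping, adapted per step
    for _ in range(max_iters):
        lam = W @ x + w0
        g = -((s / lam - 1.0) @ W)           # gradient of the negative loglik
        res = np.where(x > 1e-12, np.abs(g), np.clip(-g, 0.0, None)).max()
        if res < res_tol:
            break
        free = (x > 1e-12) | (g < 0)
        idx = np.nonzero(free)[0]
        H = (W[:, idx].T * (s / lam**2)) @ W[:, idx]
        scale = max(np.diag(H).max(), 1e-300)
        if mu == 0.0:
            mu = 1e-12 * scale
        f0 = negll(x)
        accepted = False
        for _damp in range(60):
            d = np.zeros(n)
            try:
                d[idx] = np.linalg.solve(H + mu * np.eye(len(idx)), -g[idx])
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            xn = np.clip(x + d, 0.0, None)
            if negll(xn) < f0:
                accepted = True
                mu = max(mu / 10.0, 1e-14 * scale)
                break
            mu *= 10.0
        if not accepted:
            break
        x = xn
    return x


def save_estimator_trace(state: EstimatorState, path: str) -> None:
    """Write the recorded iterate trajectory as delimited text: one row per
    iteration with columns ``iter, x_hat_0..x_hat_{n-1}[, loglik]``.

    Requires the state to have been produced with
    ``run_to_convergence(..., record_trajectory=True)``.
    """
    if state.trajectory is None:
        raise ValueError("state has no trajectory; rerun with record_trajectory=True")
    traj = state.trajectory
    n = traj.shape[1]
    cols = ["iter"] + [f"x_hat_{i}" for i in range(n)]
    have_ll = len(state.loglik_trace) == len(traj) - 1
    if have_ll:
        cols.append("loglik")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for k, row in enumerate(traj):
            vals = [str(k)] + [f"{v:.12g}" for v in row]
            if have_ll:
                vals.append("nan" if k == 0 else f"{state.loglik_trace[k - 1]:.12g}")
            fh.write("\t".join(vals) + "\n")


def effective_weights(basis: FeatureBasis, r: np.ndarray) -> np.ndarray:
    """Response-dependent effective input weights
    ``w~_ji(r) = w_ji / (sum_k w_jk r_k + w0)``.

    Divisive feedback shrinks the weight of any input whose activity is
    already explained by the population; every entry is at most
    ``w_ji / w0``.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (basis.n_features,):
        raise ValueError(f"r must have shape ({basis.n_features},)")
    denom = basis.weights @ r + basis.background
    return basis.weights / denom[:, None]


def stationarity_residual(
    basis: FeatureBasis,
    x_hat: np.ndarray,
    s: np.ndarray,
    mode: str = "divisive",
    active_tol: float = 1e-10,
) -> float:
    """Projected-gradient (KKT) residual of the clamped fixed point.

    For features above the zero boundary the residual is ``|g_i|`` with
    ``g = W^T err``; at the boundary only a *positive* gradient (a push into
    the feasible region) counts.  Coincides with ``||W^T err||_inf`` for
    interior solutions.
    """
    err = (fractional_errors if mode == "divisive" else absolute_errors)(basis, x_hat, s)
    g = err @ basis.weights
    x_hat = np.asarray(x_hat, dtype=float)
    res = np.where(x_hat > active_tol, np.abs(g), np.clip(g, 0.0, None))
    return float(res.max()) if res.size else 0.0
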