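"""Two-population excitatory/inhibitory rate network.

Excitatory units (one per sensory input) encode *fractional prediction
errors*; inhibitory units (one per feature) encode the running feature
estimate.  Divisive coupling — inhibition multiplies the leak of the
excitatory units:

    a dr_exc_j/dt = s_j - (w0 + sum_k w_jk r_inh_k) * r_exc_j
    b dr_inh_i/dt = sum_j w_ji (r_exc_j - 1)

so in steady state ``r_exc_j = s_j / (w0 + (W r_inh)_j)`` (the fractional
prediction ratio; exactly 1 when the input is perfectly predicted) and the
inhibitory fixed point equals the divisive estimator's ML estimate.  Both
rates are clamped at zero.

A subtractive control network implements classical (Gaussian-noise)
predictive coding: error units carry the *signed* absolute prediction
error — zero, not one, when the input is perfectly predicted — with a
constant leak and additive inhibition,

    a dr_exc_j/dt = (s_j - w0) - w0 * r_exc_j - (W r_inh)_j
    b dr_inh_i/dt = sum_j w_ji r_exc_j

Neither population is rectified (the error code is signed), so the system
is linear; its excitatory time constant ``a / w0`` is input-independent,
which is what makes its temporal dynamics contrast-invariant, and its
fixed point is the subtractive estimator's closed form
``r_inh = (W^T W)^+ W^T (s - w0)`` with the error units carrying the
least-squares residual over ``w0`` (zero whenever the input is perfectly
predicted/representable).

Integration is explicit Euler with step ``dt`` (default ``1e-4 * a``); an
optional numba-compiled kernel accelerates constant-input simulations, with
an equivalent pure-numpy path used when numba is unavailable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .basis import FeatureBasis

try:  # optional acceleration
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

__all__ = [
    "NetworkParams",
    "NetworkState",
    "TraceRecord",
    "network_step",
    "subtractive_network_step",
    "simulate",
    "simulate_to_steady_state",
    "steady_state_two_unit",
    "steady_state_simple",
    "steady_exc_given_inh",
    "time_to_fraction",
    "time_to_peak",
    "wavefront_latency",
    "save_trace",
]


@dataclass
class NetworkParams:
    """Network constants: ``a`` sets the excitatory timescale, ``b`` the
    inhibitory integration rate (defaults 0.08 and 40), ``dt`` the Euler
    step (default ``1e-4 * a``)."""

    basis: FeatureBasis
    a: float = 0.08
    b: float = 40.0
    dt: float | None = None

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be > 0")
        if self.dt is None:
            self.dt = 1e-4 * self.a
        if not self.dt > 0:
            raise ValueError("dt must be > 0")


@dataclass
class NetworkState:
    """Rates of both populations at time ``t``.

    The divisive network's rates are clamped nonnegative by its dynamics;
    the subtractive control network's error units are signed.
    """

    r_exc: np.ndarray
    r_inh: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r_exc = np.asarray(self.r_exc, dtype=float)
        self.r_inh = np.asarray(self.r_inh, dtype=float)


@dataclass
class TraceRecord:
    """Recorded simulation trace: ``r_exc`` is (steps, m), ``r_inh`` (steps, n)."""

    times: np.ndarray
    r_exc: np.ndarray
    r_inh: np.ndarray
    input_desc: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r_exc = np.asarray(self.r_exc, dtype=float)
        self.r_inh = np.asarray(self.r_inh, dtype=float)
        if not (len(self.times) == len(self.r_exc) == len(self.r_inh)):
            raise ValueError("trace row counts are inconsistent")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be monotone")

    def final_state(self) -> NetworkState:
        return NetworkState(self.r_exc[-1].copy(), self.r_inh[-1].copy(),
                            t=float(self.times[-1]))


def _check_input(basis: FeatureBasis, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (basis.n_inputs,):
        raise ValueError(f"input s must have shape ({basis.n_inputs},)")
    return s


def _stability_guard(params: NetworkParams, leak: np.ndarray) -> None:
    if np.max(leak) * params.dt / params.a > 1.0:
        raise RuntimeError(
            f"Euler step unstable: leak * dt / a = "
            f"{np.max(leak) * params.dt / params.a:.3g} > 1; reduce dt={params.dt:g}"
        )


def _euler_once(params: NetworkParams, r_exc, r_inh, s, divisive: bool):
    W = params.basis.weights
    w0 = params.basis.background
    if divisive:
        leak = w0 + W @ r_inh
        d_exc = (s - leak * r_exc) / params.a
        d_inh = ((r_exc - 1.0) @ W) / params.b
        _stability_guard(params, leak)
        r_exc = np.maximum(r_exc + params.dt * d_exc, 0.0)
        r_inh = np.maximum(r_inh + params.dt * d_inh, 0.0)
    else:
        d_exc = ((s - w0) - w0 * r_exc - W @ r_inh) / params.a
        d_inh = (r_exc @ W) / params.b
        _stability_guard(params, np.full_like(s, w0))
        r_exc = r_exc + params.dt * d_exc
        r_inh = r_inh + params.dt * d_inh
    if not (np.all(np.isfinite(r_exc)) and np.all(np.isfinite(r_inh))):
        raise RuntimeError(f"network rates diverged (non-finite); reduce dt={params.dt:g}")
    return r_exc, r_inh


def network_step(params: NetworkParams, state: NetworkState, s: np.ndarray) -> NetworkState:
    """One Euler update of the divisive network (both populations, clamped)."""
    s = _check_input(params.basis, s)
    r_exc, r_inh = _euler_once(params, state.r_exc, state.r_inh, s, divisive=True)
    return NetworkState(r_exc, r_inh, t=state.t + params.dt)


def subtractive_network_step(params: NetworkParams, state: NetworkState,
                             s: np.ndarray) -> NetworkState:
    """One Euler update of the subtractive (signed-error, linear) control
    network."""
    s = _check_input(params.basis, s)
    r_exc, r_inh = _euler_once(params, state.r_exc, state.r_inh, s, divisive=False)
    return NetworkState(r_exc, r_inh, t=state.t + params.dt)


# ---------------------------------------------------------------------------
# Fast constant-input integration kernel
# ---------------------------------------------------------------------------

def _run_kernel_numpy(W, w0, s, a, b, dt, n_steps, rec_stride, r_exc, r_inh,
                      out_exc, out_inh, divisive):
    WT = W.T
    rec = 0
    max_leak = 0.0
    for step in range(n_steps):
        if divisive:
            leak = w0 + W @ r_inh
            d_exc = (s - leak * r_exc) / a
            d_inh = WT @ (r_exc - 1.0) / b
            ml = leak.max()
            if ml > max_leak:
                max_leak = ml
            r_exc = np.maximum(r_exc + dt * d_exc, 0.0)
            r_inh = np.maximum(r_inh + dt * d_inh, 0.0)
        else:
            d_exc = ((s - w0) - w0 * r_exc - W @ r_inh) / a
            d_inh = WT @ r_exc / b
            max_leak = w0
            r_exc = r_exc + dt * d_exc
            r_inh = r_inh + dt * d_inh
        if (step + 1) % rec_stride == 0 and rec < out_exc.shape[0]:
            out_exc[rec] = r_exc
            out_inh[rec] = r_inh
            rec += 1
    return r_exc, r_inh, max_leak


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _run_kernel_numba(W, w0, s, a, b, dt, n_steps, rec_stride, r_exc, r_inh,
                          out_exc, out_inh, divisive):  # pragma: no cover - jit
        m, n = W.shape
        rec = 0
        max_leak = 0.0
        new_exc = np.empty(m)
        new_inh = np.empty(n)
        for step in range(n_steps):
            for j in range(m):
                inh_in = 0.0
                for k in range(n):
                    inh_in += W[j, k] * r_inh[k]
                if divisive:
                    leak = w0 + inh_in
                    if leak > max_leak:
                        max_leak = leak
                    d = (s[j] - leak * r_exc[j]) / a
                    v = r_exc[j] + dt * d
                    new_exc[j] = v if v > 0.0 else 0.0
                else:
                    if w0 > max_leak:
                        max_leak = w0
                    d = ((s[j] - w0) - w0 * r_exc[j] - inh_in) / a
                    new_exc[j] = r_exc[j] + dt * d
            for i in range(n):
                acc = 0.0
                for j in range(m):
                    if divisive:
                        acc += W[j, i] * (r_exc[j] - 1.0)
                    else:
                        acc += W[j, i] * r_exc[j]
                v = r_inh[i] + dt * acc / b
                if divisive:
                    new_inh[i] = v if v > 0.0 else 0.0
                else:
                    new_inh[i] = v
            for j in range(m):
                r_exc[j] = new_exc[j]
            for i in range(n):
                r_inh[i] = new_inh[i]
            if (step + 1) % rec_stride == 0 and rec < out_exc.shape[0]:
                for j in range(m):
                    out_exc[rec, j] = r_exc[j]
                for i in range(n):
                    out_inh[rec, i] = r_inh[i]
                rec += 1
        return r_exc, r_inh, max_leak


def _run_constant(params: NetworkParams, s, r_exc, r_inh, n_steps, rec_stride,
                  n_rec, divisive):
    W = params.basis.weights
    out_exc = np.empty((n_rec, W.shape[0]))
    out_inh = np.empty((n_rec, W.shape[1]))
    kernel = _run_kernel_numba if _HAVE_NUMBA else _run_kernel_numpy
    r_exc, r_inh, max_leak = kernel(
        np.ascontiguousarray(W), params.basis.background, np.ascontiguousarray(s),
        params.a, params.b, params.dt, n_steps, rec_stride,
        r_exc.copy(), r_inh.copy(), out_exc, out_inh, divisive,
    )
    if max_leak * params.dt / params.a > 1.0:
        raise RuntimeError(
            f"Euler step unstable (leak*dt/a = {max_leak * params.dt / params.a:.3g} > 1); "
            f"reduce dt={params.dt:g}"
        )
    if not (np.all(np.isfinite(r_exc)) and np.all(np.isfinite(r_inh))):
        raise RuntimeError(f"network rates diverged (non-finite); reduce dt={params.dt:g}")
    return r_exc, r_inh, out_exc, out_inh


def simulate(
    params: NetworkParams,
    input_fn,
    duration: float,
    record_every: float | None = None,
    mode: str = "divisive",
    state0: NetworkState | None = None,
) -> TraceRecord:
    """Integrate the network for ``duration`` seconds and record the rates.

    ``input_fn`` is either a constant input vector (length m, a step input
    applied at t = 0) or a callable ``t -> input vector``.  The trace holds
    the initial state plus one row every ``record_every`` seconds (default:
    ~1000 rows).  Constant inputs take a fast compiled path.
    """
    if mode not in ("divisive", "subtractive"):
        raise ValueError(f"unknown mode {mode!r}")
    divisive = mode == "divisive"
    basis = params.basis
    n_steps = max(1, int(round(duration / params.dt)))
    if record_every is None:
        rec_stride = max(1, n_steps // 1000)
    else:
        rec_stride = max(1, int(round(record_every / params.dt)))
    if state0 is None:
        state0 = NetworkState(np.zeros(basis.n_inputs), np.zeros(basis.n_features))
    n_rec = n_steps // rec_stride
    if callable(input_fn):
        r_exc, r_inh = state0.r_exc.copy(), state0.r_inh.copy()
        rows_e, rows_i = [], []
        for step in range(n_steps):
            s = _check_input(basis, input_fn(state0.t + step * params.dt))
            r_exc, r_inh = _euler_once(params, r_exc, r_inh, s, divisive)
            if (step + 1) % rec_stride == 0 and len(rows_e) < n_rec:
                rows_e.append(r_exc.copy())
                rows_i.append(r_inh.copy())
        out_exc = np.array(rows_e).reshape(-1, basis.n_inputs)
        out_inh = np.array(rows_i).reshape(-1, basis.n_features)
        desc = {"kind": "time-varying"}
    else:
        s = _check_input(basis, input_fn)
        r_exc, r_inh, out_exc, out_inh = _run_constant(
            params, s, state0.r_exc, state0.r_inh, n_steps, rec_stride, n_rec, divisive
        )
        desc = {"kind": "constant", "s": np.asarray(input_fn, dtype=float).tolist()}
    n_rec_actual = out_exc.shape[0]
    times = state0.t + params.dt * rec_stride * np.arange(1, n_rec_actual + 1)
    times = np.concatenate([[state0.t], times])
    out_exc = np.vstack([state0.r_exc[None, :], out_exc])
    out_inh = np.vstack([state0.r_inh[None, :], out_inh])
    return TraceRecord(times, out_exc, out_inh, input_desc=desc)


def simulate_to_steady_state(
    params: NetworkParams,
    s: np.ndarray,
    mode: str = "divisive",
    tol: float = 1e-8,
    chunk: float = 0.1,
    max_time: float = 300.0,
    state0: NetworkState | None = None,
) -> tuple[NetworkState, bool]:
    """Run with constant input until both populations change by less than
    ``tol`` over a ``chunk``-second window (or ``max_time`` elapses).

    Returns the final state and a convergence flag.
    """
    divisive = mode == "divisive"
    basis = params.basis
    s = _check_input(basis, s)
    if state0 is None:
        state0 = NetworkState(np.zeros(basis.n_inputs), np.zeros(basis.n_features))
    r_exc, r_inh = state0.r_exc.copy(), state0.r_inh.copy()
    t = state0.t
    steps_per_chunk = max(1, int(round(chunk / params.dt)))
    n_chunks = int(np.ceil(max_time / chunk))
    converged = False
    for _ in range(n_chunks):
        prev_e, prev_i = r_exc.copy(), r_inh.copy()
        r_exc, r_inh, _, _ = _run_constant(
            params, s, r_exc, r_inh, steps_per_chunk, steps_per_chunk, 1, divisive
        )
        t += steps_per_chunk * params.dt
        if max(np.max(np.abs(r_exc - prev_e), initial=0.0),
               np.max(np.abs(r_inh - prev_i), initial=0.0)) < tol:
            converged = True
            break
    return NetworkState(r_exc, r_inh, t=t), converged


# ---------------------------------------------------------------------------
# Closed-form steady states
# ---------------------------------------------------------------------------

def steady_state_two_unit(s1: float, s2: float, w0: float) -> float:
    """Canonical divisive-normalization closed form for the two-input,
    one-feature network: ``r1 = s1 / max(s1 + s2, w0)`` (up to a global
    proportionality constant)."""
    denom = max(s1 + s2, w0)
    return s1 / denom if denom > 0 else 0.0


def steady_state_simple(basis: FeatureBasis, s: np.ndarray) -> np.ndarray:
    """Divisive-normalization approximation for 'simple' inputs:
    ``r_j ~ s_j / max(pool_j, w0)`` where ``pool = (W W^T / w_max^2) s``.

    Valid only for inputs that do not co-activate overlapping feature
    detectors; the pooling matrix is scaled so that the two-unit network
    reduces exactly to :func:`steady_state_two_unit`.  Ratios (not absolute
    values) are comparable with simulation.
    """
    s = _check_input(basis, s)
    w_max = basis.weights.max()
    pool = (basis.weights @ (basis.weights.T @ s)) / w_max**2
    return s / np.maximum(pool, basis.background)


def steady_exc_given_inh(basis: FeatureBasis, s: np.ndarray, r_inh: np.ndarray) -> np.ndarray:
    """Excitatory steady state for fixed inhibition:
    ``r_exc_j = s_j / (w0 + (W r_inh)_j)``; exactly 1 everywhere when the
    input is perfectly predicted (``s = W r_inh + w0``)."""
    s = _check_input(basis, s)
    return s / (basis.background + basis.weights @ np.asarray(r_inh, dtype=float))


# ---------------------------------------------------------------------------
# Temporal metrics
# ---------------------------------------------------------------------------

def _unit_trace(trace: TraceRecord, unit: int, population: str) -> np.ndarray:
    if population == "exc":
        return trace.r_exc[:, unit]
    if population == "inh":
        return trace.r_inh[:, unit]
    raise ValueError("population must be 'exc' or 'inh'")


def time_to_fraction(trace: TraceRecord, unit: int, fraction: float,
                     population: str = "exc") -> float:
    """Time of the first crossing of ``fraction * max`` for one unit's trace
    (linear interpolation between recorded samples).  Returns NaN when the
    trace never crosses (e.g. all-zero response)."""
    y = _unit_trace(trace, unit, population)
    peak = y.max()
    if peak <= 0:
        return float("nan")
    if fraction >= 1.0:
        return float(trace.times[int(np.argmax(y))])
    thr = fraction * peak
    above = np.nonzero(y >= thr)[0]
    if len(above) == 0:
        return float("nan")
    k = int(above[0])
    if k == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[k - 1], trace.times[k]
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (thr - y0) / (y1 - y0) * (t1 - t0))


def wavefront_latency(trace: TraceRecord, unit: int, fraction: float = 0.7,
                      population: str = "exc", prominence_frac: float = 0.05) -> float:
    """Arrival time of the activity wavefront at one unit: the first
    crossing of ``fraction`` times the unit's *first substantial peak*.

    The reference peak is the first local maximum with prominence at least
    ``prominence_frac`` of the global maximum (first peak of the front,
    robust to numerical micro-wiggles).  For monotone or front-dominated
    responses this coincides with :func:`time_to_fraction`; for weakly
    driven units of the linear subtractive network, whose late ringing or
    slow relaxation can exceed the front, it times the front itself.
    Returns NaN for non-positive traces.
    """
    from scipy.signal import find_peaks

    y = _unit_trace(trace, unit, population)
    t = trace.times
    peak = y.max()
    if peak <= 0:
        return float("nan")
    peaks, _ = find_peaks(y, prominence=prominence_frac * peak)
    k_ref = int(peaks[0]) if len(peaks) else int(np.argmax(y))
    thr = fraction * y[k_ref]
    above = np.nonzero(y[: k_ref + 1] >= thr)[0]
    if len(above) == 0:
        return float(t[k_ref])
    j = int(above[0])
    if j == 0:
        return float(t[0])
    return float(t[j - 1] + (thr - y[j - 1]) / (y[j] - y[j - 1]) * (t[j] - t[j - 1]))


def time_to_peak(trace: TraceRecord, unit: int, population: str = "exc",
                 refine: bool = True) -> float:
    """Time of the maximum response, optionally refined to sub-sample
    precision with a 3-point parabolic fit around the discrete peak."""
    y = _unit_trace(trace, unit, population)
    k = int(np.argmax(y))
    t = trace.times
    if not refine or k == 0 or k == len(y) - 1:
        return float(t[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom >= 0:  # flat or non-concave sample triple: keep discrete peak
        return float(t[k])
    shift = 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(t[k] + shift * (t[k + 1] - t[k]))


def save_trace(trace: TraceRecord, prefix: str, manifest: dict | None = None) -> None:
    """Write a long-format delimited-text trace (time, population, unit, rate)
    and a JSON manifest."""
    import pandas as pd

    frames = []
    for pop, mat in (("exc", trace.r_exc), ("inh", trace.r_inh)):
        n_units = mat.shape[1]
        frames.append(pd.DataFrame({
            "time": np.repeat(trace.times, n_units),
            "population": pop,
            "unit": np.tile(np.arange(n_units), len(trace.times)),
            "rate": mat.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(f"{prefix}.csv", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"input": trace.input_desc, **(manifest or {})}, fh, indent=1)
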