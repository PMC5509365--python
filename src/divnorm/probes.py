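"""Measurement protocols applied to response models.

A *response model* here is any deterministic callable mapping a batch of
input vectors ``(..., m)`` to steady-state population responses
``(..., n)`` — all trial-to-trial noise lives in the stimulus sampler, as
in the underlying theory.  Adapters are provided for the divisive
(Poisson-ML) estimator, the subtractive (nonnegative least squares)
estimator, and fitted LN models, so the same probes (reverse-correlation
receptive fields, contextual tuning curves, linear readout decoding) run
unchanged on each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FeatureBasis, mean_input
from .baselines import LNModel, ln_response
from .estimators import ml_estimate, subtractive_nnls

__all__ = [
    "ReceptiveFieldEstimate",
    "TuningCurve",
    "ReadoutFilter",
    "divisive_response_model",
    "subtractive_response_model",
    "ln_response_model",
    "reverse_correlation_rf",
    "save_rf",
    "tuning_curve",
    "rescale_curve",
    "fit_readout",
    "reconstruction_error",
    "peak_location",
    "peak_shift",
    "curve_msd",
    "context_shift_metrics",
]


# ---------------------------------------------------------------------------
# Response-model adapters
# ---------------------------------------------------------------------------

def divisive_response_model(basis: FeatureBasis, max_iters: int = 2000,
                            tol: float = 1e-9):
    """Steady-state divisive responses: the Poisson-ML feature estimate
    (each neuron's rate proportional to its encoded feature)."""

    def model(s: np.ndarray) -> np.ndarray:
        return ml_estimate(basis, s, max_iters=max_iters, tol=tol)

    return model


def subtractive_response_model(basis: FeatureBasis):
    """Steady-state subtractive responses: nonnegative least-squares
    feature estimates."""

    def model(s: np.ndarray) -> np.ndarray:
        return subtractive_nnls(basis, s)

    return model


def ln_response_model(model: LNModel):
    """Adapter giving an LN model the response-model calling convention."""

    def _model(s: np.ndarray) -> np.ndarray:
        return ln_response(model, s)

    return _model


# ---------------------------------------------------------------------------
# Reverse-correlation receptive fields
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveFieldEstimate:
    """Decorrelated reverse-correlation RF of one neuron."""

    rf: np.ndarray
    neuron: int
    n_presentations: int
    context: str | None = None

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        if self.n_presentations < 1:
            raise ValueError("n_presentations must be >= 1")


def reverse_correlation_rf(
    model,
    stimulus_sampler,
    n_presentations: int,
    neuron_ids,
    ridge: float = 0.0,
    rng: np.random.Generator | int | None = None,
    context: str | None = None,
    return_stimuli: bool = False,
):
    """Receptive fields by decorrelated reverse correlation.

    Presents ``n_presentations`` stimuli drawn from
    ``stimulus_sampler(n, rng)`` (an ``(n, m)`` array), collects the model
    responses, and solves ``Q_ss w_hat = q_rs`` with the *uncentered* second
    moments ``Q_ss = <s s^T>`` and ``q_rs = <s r>``.  A ridge is added to
    the diagonal automatically when ``Q_ss`` is ill-conditioned
    (condition number above 1e12); an exactly singular moment matrix without
    ridge raises.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng)
    S = np.asarray(stimulus_sampler(n_presentations, rng), dtype=float)
    if S.ndim != 2 or S.shape[0] != n_presentations:
        raise ValueError("stimulus_sampler must return an (n_presentations, m) array")
    R = np.asarray(model(S), dtype=float)
    neuron_ids = np.atleast_1d(neuron_ids)
    Qss = S.T @ S / n_presentations
    qrs = S.T @ R[:, neuron_ids] / n_presentations
    cond = np.linalg.cond(Qss)
    eff_ridge = ridge
    if cond > 1e12 and eff_ridge == 0.0:
        eff_ridge = 1e-8 * np.trace(Qss) / Qss.shape[0]
    if eff_ridge:
        Qss = Qss + eff_ridge * np.eye(Qss.shape[0])
    try:
        W_hat = np.linalg.solve(Qss, qrs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular stimulus moment matrix; pass ridge > 0"
        ) from exc
    ests = [
        ReceptiveFieldEstimate(W_hat[:, k], neuron=int(nid),
                               n_presentations=n_presentations, context=context)
        for k, nid in enumerate(neuron_ids)
    ]
    if return_stimuli:
        return ests, S, R
    return ests


def save_rf(estimate: ReceptiveFieldEstimate, prefix: str,
            grid_shape: tuple[int, int] | None = None) -> None:
    """Write an RF map as a delimited-text matrix (``<prefix>.tsv``) with a
    JSON sidecar (``<prefix>.json``) recording neuron id, presentation count
    and context."""
    import json

    rf = estimate.rf
    if grid_shape is not None:
        rf = rf.reshape(grid_shape)
    np.savetxt(f"{prefix}.tsv", np.atleast_2d(rf), delimiter="\t")
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"neuron": estimate.neuron,
                   "n_presentations": estimate.n_presentations,
                   "context": estimate.context,
                   "grid_shape": list(grid_shape) if grid_shape else None}, fh)


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Mean response of one neuron against a 1-D stimulus index."""

    stimulus_values: np.ndarray
    responses: np.ndarray
    context: str | None = None
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.stimulus_values = np.asarray(self.stimulus_values, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.stimulus_values.shape != self.responses.shape:
            raise ValueError("stimulus_values and responses must align")


def rescale_curve(curve: TuningCurve) -> TuningCurve:
    """Zero-mean, unit-standard-deviation rescaling (context-comparable shape)."""
    y = curve.responses
    sd = y.std()
    if sd == 0:
        raise ValueError("cannot rescale a constant tuning curve")
    return TuningCurve(curve.stimulus_values.copy(), (y - y.mean()) / sd,
                       context=curve.context, rescaled=True)


def tuning_curve(
    model,
    basis: FeatureBasis,
    neuron: int,
    trials: int = 200,
    clamp_mask: dict[int, float] | None = None,
    feature_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    context: str | None = None,
) -> TuningCurve:
    """Mean response of ``neuron`` to each single-feature stimulus.

    For stimulus index ``i`` the inputs are Poisson draws with means
    ``w_ji + w0`` (feature ``i`` at unit amplitude), averaged over
    ``trials``.  Two kinds of contextual mask are supported:

    * ``clamp_mask``: receptors held at fixed values on every trial
      (e.g. ``{j: 200.0}``), overriding their sampled value;
    * ``feature_mask``: a constant feature-space mask added to the stimulus
      before the Poisson means are formed.
    """
    rng = np.random.default_rng(rng)
    n = basis.n_features
    X = np.eye(n)
    if feature_mask is not None:
        X = X + np.asarray(feature_mask, dtype=float)[None, :]
    means = mean_input(basis, X)                     # (n_values, m)
    S = rng.poisson(np.broadcast_to(means, (trials,) + means.shape)).astype(float)
    if clamp_mask:
        for j, val in clamp_mask.items():
            S[:, :, j] = val
    R = np.asarray(model(S.reshape(-1, basis.n_inputs)))
    R = R.reshape(trials, n, -1)[:, :, neuron]
    return TuningCurve(np.arange(n, dtype=float), R.mean(axis=0), context=context)


# ---------------------------------------------------------------------------
# Linear readout decoding
# ---------------------------------------------------------------------------

@dataclass
class ReadoutFilter:
    """Linear decoder ``U`` mapping centered responses back to inputs:
    ``s_hat = U (r - <r>) + <s>`` with the means taken on the training
    context."""

    U: np.ndarray
    s_mean: np.ndarray
    r_mean: np.ndarray
    context: str | None = None

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if not np.all(np.isfinite(self.U)):
            raise ValueError("readout filter must be finite")

    def reconstruct(self, responses: np.ndarray) -> np.ndarray:
        r = np.asarray(responses, dtype=float)
        return (r - self.r_mean) @ self.U.T + self.s_mean


def fit_readout(
    stimuli: np.ndarray,
    responses: np.ndarray,
    ridge: float = 0.0,
    context: str | None = None,
) -> ReadoutFilter:
    """Least-squares readout ``U = <s_bar r_bar^T> <r_bar r_bar^T>^-1``
    from centered cross- and auto-moments.

    A singular response covariance triggers an automatic small ridge with a
    warning.
    """
    S = np.atleast_2d(np.asarray(stimuli, dtype=float))
    R = np.atleast_2d(np.asarray(responses, dtype=float))
    if len(S) != len(R):
        raise ValueError("stimuli and responses must have the same number of rows")
    s_mean, r_mean = S.mean(axis=0), R.mean(axis=0)
    Sb, Rb = S - s_mean, R - r_mean
    Crr = Rb.T @ Rb / len(R)
    Csr = Sb.T @ Rb / len(R)
    if ridge:
        Crr = Crr + ridge * np.eye(Crr.shape[0])
    elif np.linalg.cond(Crr) > 1e12:
        import warnings

        warnings.warn("singular response covariance; adding small ridge",
                      RuntimeWarning, stacklevel=2)
        Crr = Crr + 1e-8 * max(np.trace(Crr) / Crr.shape[0], 1e-300) * np.eye(Crr.shape[0])
    U = np.linalg.solve(Crr, Csr.T).T
    return ReadoutFilter(U, s_mean, r_mean, context=context)


def reconstruction_error(
    readout: ReadoutFilter, stimuli: np.ndarray, responses: np.ndarray
) -> float:
    """Normalized rms reconstruction error.

    Root-mean-square of ``s - s_hat`` over the evaluation set, divided by
    the rms of the centered stimulus, so that a zero decoder scores 1 and a
    perfect one scores 0.
    """
    S = np.atleast_2d(np.asarray(stimuli, dtype=float))
    err = S - readout.reconstruct(responses)
    denom = np.sqrt(np.mean((S - S.mean(axis=0)) ** 2))
    if denom == 0:
        raise ValueError("degenerate (constant) stimulus set")
    return float(np.sqrt(np.mean(err**2)) / denom)


# ---------------------------------------------------------------------------
# Context-shift metrics
# ---------------------------------------------------------------------------

def peak_location(curve: TuningCurve, circular: bool = True) -> float:
    """Sub-index peak location by 3-point parabolic interpolation around the
    argmax (indices wrap when ``circular``)."""
    y = curve.responses
    n = len(y)
    k = int(np.argmax(y))
    if circular:
        ym, yp = y[(k - 1) % n], y[(k + 1) % n]
    else:
        if k == 0 or k == n - 1:
            return float(curve.stimulus_values[k])
        ym, yp = y[k - 1], y[k + 1]
    denom = ym - 2 * y[k] + yp
    if denom >= 0:
        return float(curve.stimulus_values[k])
    shift = 0.5 * (ym - yp) / denom
    step = float(np.mean(np.diff(curve.stimulus_values))) if n > 1 else 1.0
    return float(curve.stimulus_values[k] + shift * step)


def peak_shift(curve_a: TuningCurve, curve_b: TuningCurve,
               circular: bool = True) -> float:
    """Signed peak shift (b relative to a) in stimulus-index units; the
    minimal wrapped difference when ``circular``."""
    pa, pb = peak_location(curve_a, circular), peak_location(curve_b, circular)
    d = pb - pa
    if circular:
        n = len(curve_a.responses)
        d = (d + n / 2) % n - n / 2
    return float(d)


def curve_msd(curves: list[TuningCurve]) -> float:
    """Mean squared difference between rescaled curves, averaged over all
    context pairs."""
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    resc = [c.responses if c.rescaled else rescale_curve(c).responses for c in curves]
    diffs = [np.mean((resc[i] - resc[j]) ** 2)
             for i in range(len(resc)) for j in range(i + 1, len(resc))]
    return float(np.mean(diffs))


def context_shift_metrics(curves: list[TuningCurve],
                          circular: bool = True) -> dict[str, float]:
    """Summary of cross-context variability: the mean absolute pairwise peak
    shift (index units) and the mean squared cross-context difference of the
    rescaled curves.  Also applicable to RFs wrapped as curves."""
    shifts = [abs(peak_shift(curves[i], curves[j], circular))
              for i in range(len(curves)) for j in range(i + 1, len(curves))]
    return {"peak_shift": float(np.mean(shifts)), "msd": curve_msd(curves)}
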