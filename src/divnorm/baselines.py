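"""Linear-nonlinear (LN) comparison model.

The null model against which the divisive model's context effects are
judged: a static linear filter of the sensory inputs followed by a
rectifier, ``r_i = max(sum_j v_ji s_j + v0_i, 0)``.  The filter and offsets
are fitted by (ridge) least squares to reproduce the divisive model's
responses on a training ensemble; the rectifier is applied at evaluation
time.  Because the model is static, it can reproduce gain changes but not
the context-dependent reshaping of tuning curves and receptive fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["LNModel", "ln_response", "fit_ln"]


@dataclass
class LNModel:
    """Linear filters ``V`` (m inputs x n output neurons), per-neuron offset
    ``v0``, rectifier nonlinearity."""

    filters: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        self.offset = np.atleast_1d(np.asarray(self.offset, dtype=float))
        if self.offset.shape[0] != self.filters.shape[1]:
            raise ValueError("offset length must equal the number of output neurons")
        if not (np.all(np.isfinite(self.filters)) and np.all(np.isfinite(self.offset))):
            raise ValueError("LN parameters must be finite")

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return ln_response(self, s)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"filters": self.filters.tolist(),
                       "offset": self.offset.tolist()}, fh)

    @classmethod
    def from_json(cls, path: str) -> "LNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["filters"]), np.array(d["offset"]))


def ln_response(model: LNModel, s: np.ndarray) -> np.ndarray:
    """Rectified linear response ``max(V^T s + v0, 0)``; ``s`` may be a
    batch ``(..., m)``."""
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != model.filters.shape[0]:
        raise ValueError(
            f"input axis mismatch: s has {s.shape[-1]} inputs, "
            f"filters expect m={model.filters.shape[0]}"
        )
    return np.maximum(s @ model.filters + model.offset, 0.0)


def fit_ln(
    stimuli: np.ndarray,
    targets: np.ndarray,
    ridge: float = 1e-6,
    refine_active_set: bool = False,
    max_refits: int = 5,
) -> LNModel:
    """Least-squares fit of the LN filters and offsets to target responses.

    Fits ordinary (ridge-regularized) least squares of the targets on the
    stimuli with an intercept, then rectifies at evaluation.  This one-shot
    fit is used because the target responses live predominantly in the
    supra-threshold regime; ``refine_active_set=True`` additionally refits
    each output neuron on the samples its current prediction leaves
    unrectified, iterating a few times (a simple heuristic for the nonconvex
    rectified fit).

    Requires at least ``m + 1`` stimuli for identifiability unless a ridge
    is supplied.
    """
    S = np.atleast_2d(np.asarray(stimuli, dtype=float))
    R = np.asarray(targets, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if len(S) != len(R):
        raise ValueError("stimuli and targets must have the same number of rows")
    n_samples, m = S.shape
    if n_samples < m + 1 and not ridge > 0:
        raise ValueError(
            f"need at least m+1={m + 1} stimuli for an unregularized fit "
            f"(got {n_samples}); supply ridge > 0"
        )
    X = np.hstack([S, np.ones((n_samples, 1))])
    coef = _ridge_solve(X, R, ridge)
    if refine_active_set:
        for _ in range(max_refits):
            changed = False
            pred = X @ coef
            for i in range(R.shape[1]):
                active = pred[:, i] > 0
                if active.sum() < m + 1 or active.all():
                    continue
                new_i = _ridge_solve(X[active], R[active, i:i + 1], ridge)[:, 0]
                if not np.allclose(new_i, coef[:, i], atol=1e-10):
                    coef[:, i] = new_i
                    changed = True
            if not changed:
                break
    return LNModel(coef[:-1], coef[-1])


def _ridge_solve(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    G = X.T @ X
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    else:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient design; supply ridge > 0 to regularize the LN fit"
            )
    return np.linalg.solve(G, X.T @ Y)
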