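"""Linear-Poisson generative model of sensory inputs, and the feature bases
used throughout the package.

The world model: nonnegative stimulus features ``x = (x_1 .. x_n)`` drive a
population of ``m`` sensory inputs linearly, so that the mean activation of
input ``j`` is ``<s_j|x> = sum_k w_jk x_k + w_0``, with ``w_0 > 0`` a
feature-independent background rate.  Observed inputs are trial-by-trial
noisy versions of these means — independent Poisson counts over a window of
``T`` seconds (the paradigm of signal-dependent noise, variance equal to the
mean), or optionally constant-variance Gaussian noise as a control.

The same weights ``W`` that define the generative model also define the
connectivity of every network in this package: nothing is learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureBasis",
    "BasisBuilderSpec",
    "mean_input",
    "sample_inputs",
    "build_basis",
    "paired_basis",
    "circular_basis",
    "blob_grid_basis",
    "multiblob_basis",
    "letters_basis",
    "topographic_pair_basis",
    "letter_bitmap",
    "save_basis",
    "load_basis",
]

BASIS_KINDS = (
    "paired",
    "circular",
    "blob_grid",
    "multiblob",
    "letters",
    "topographic_pair",
)


@dataclass
class FeatureBasis:
    """Generative weights ``W`` (m inputs x n features) plus background rate.

    ``weights[j, k]`` is the drive of feature ``k`` onto input ``j`` (rate
    gain); ``background`` is the baseline mean rate ``w_0`` of every input
    when all features are zero.  ``input_geometry`` optionally records a 2-D
    ``(rows, cols)`` layout of the inputs (``rows * cols == m``).
    """

    weights: np.ndarray
    background: float
    input_geometry: tuple[int, int] | None = None
    feature_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (m_inputs x n_features) array")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        self.background = float(self.background)
        if not self.background > 0:
            raise ValueError("background rate w0 must be > 0")
        if self.input_geometry is not None:
            rows, cols = self.input_geometry
            if rows * cols != self.n_inputs:
                raise ValueError(
                    f"input_geometry {self.input_geometry} incompatible with "
                    f"m={self.n_inputs} inputs"
                )
            self.input_geometry = (int(rows), int(cols))

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def mean_input(self, x: np.ndarray) -> np.ndarray:
        return mean_input(self, x)

    def sample_inputs(self, x, noise="poisson", sigma=1.0, rng=None, size=None):
        return sample_inputs(self, x, noise=noise, sigma=sigma, rng=rng, size=size)


@dataclass
class BasisBuilderSpec:
    """Declarative recipe for :func:`build_basis`.

    ``sigma_w`` is the blob width on the 0->1 grid coordinates; ``w_max`` is
    the peak feature drive.  Randomized kinds (``multiblob``) take a ``seed``;
    ``centers`` may fix blob centers explicitly instead.
    """

    kind: str
    n_features: int | None = None
    m_inputs: int | None = None
    w_max: float = 40.0
    background: float = 1.0
    sigma_w: float = 0.1
    n_blobs: int = 4
    grid_shape: tuple[int, int] | None = None
    centers: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in BASIS_KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {BASIS_KINDS}")
        if not self.w_max > 0:
            raise ValueError("w_max must be > 0")
        if not self.sigma_w > 0:
            raise ValueError("sigma_w must be > 0")


# ---------------------------------------------------------------------------
# Generative model evaluation and sampling
# ---------------------------------------------------------------------------

def _check_features(basis: FeatureBasis, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.n_features:
        raise ValueError(
            f"feature axis mismatch: stimulus has {x.shape[-1]} features, "
            f"basis expects n={basis.n_features}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("stimulus features must be finite")
    if np.any(x < 0):
        raise ValueError("stimulus features must be nonnegative")
    return x


def mean_input(basis: FeatureBasis, x: np.ndarray) -> np.ndarray:
    """Mean input activations ``W x + w0`` for feature vector(s) ``x``.

    ``x`` may be a single length-``n`` vector or a batch ``(..., n)``; the
    result has shape ``(..., m)`` and every component is at least ``w0``.
    """
    x = _check_features(basis, x)
    return x @ basis.weights.T + basis.background


def sample_inputs(
    basis: FeatureBasis,
    x: np.ndarray,
    noise: str = "poisson",
    sigma: float = 1.0,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw noisy inputs around ``mean_input(basis, x)``.

    ``noise='poisson'`` draws independent Poisson counts over the T = 1 s
    window (so counts equal rates); ``noise='gaussian'`` adds constant
    N(0, sigma^2) noise, clipped at zero since inputs are nonnegative
    activations.  ``size`` requests that many independent trials (leading
    axis).  Passing the same seed twice yields identical draws.
    """
    rng = np.random.default_rng(rng)
    mu = mean_input(basis, x)
    shape = mu.shape if size is None else (size,) + mu.shape
    if noise == "poisson":
        return rng.poisson(np.broadcast_to(mu, shape)).astype(float)
    if noise == "gaussian":
        if not sigma > 0:
            raise ValueError("gaussian noise requires sigma > 0")
        return np.clip(mu + rng.normal(0.0, sigma, size=shape), 0.0, None)
    raise ValueError(f"unknown noise model {noise!r}; expected 'poisson' or 'gaussian'")


# ---------------------------------------------------------------------------
# Basis builders
# ---------------------------------------------------------------------------

def paired_basis(n_features: int, w_max: float = 40.0, background: float = 1.0) -> FeatureBasis:
    """Each feature drives two neighbouring inputs with equal strength.

    ``w[i, i] = w[i+1, i] = w_max`` with circular wrap-around; ``m = n``.
    """
    n = int(n_features)
    W = np.zeros((n, n))
    idx = np.arange(n)
    W[idx, idx] = w_max
    W[(idx + 1) % n, idx] = w_max
    return FeatureBasis(W, background)


def topographic_pair_basis(
    n_features: int, w_max: float = 40.0, background: float = 1.0
) -> FeatureBasis:
    """Topographic sensory sheet: inhibitory feature ``i`` pools inputs
    ``i`` and ``i+1`` with equal weight — structurally the paired basis,
    named for its use in the traveling-wave protocol."""
    return paired_basis(n_features, w_max=w_max, background=background)


def circular_basis(
    n_features: int, w_max: float = 40.0, background: float = 1.0
) -> FeatureBasis:
    """Circular (orientation-like) basis on a ring of ``m = n`` inputs.

    ``w_ji = w_max * exp(4 [cos(2 pi (j - i)/n) - 1])``: each feature drives
    a bell-shaped neighbourhood of inputs, peaking at ``w_max`` on input
    ``j = i``.  The matrix is circulant.
    """
    n = int(n_features)
    j = np.arange(n)[:, None]
    i = np.arange(n)[None, :]
    W = w_max * np.exp(4.0 * (np.cos(2.0 * np.pi * (j - i) / n) - 1.0))
    return FeatureBasis(W, background)


def _grid_coords(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    # input j at row r, col c maps to (x, y) on the unit square
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c / max(cols - 1, 1)
    y = r / max(rows - 1, 1)
    return x, y


def _blob_columns(
    centers: np.ndarray, rows: int, cols: int, w_max: float, sigma_w: float
) -> np.ndarray:
    """Gaussian blob profiles, one column per center, on a rows x cols grid."""
    x, y = _grid_coords(rows, cols)
    dx = x[:, None] - centers[None, :, 0]
    dy = y[:, None] - centers[None, :, 1]
    return w_max * np.exp(-(dx**2 + dy**2) / (2.0 * sigma_w**2))


def blob_grid_basis(
    n_features: int = 400,
    grid_shape: tuple[int, int] = (30, 30),
    w_max: float = 40.0,
    sigma_w: float = 0.1,
    background: float = 1.0,
) -> FeatureBasis:
    """Retinotopic blob basis: feature ``i`` is a circular Gaussian blob of
    width ``sigma_w`` (0->1 grid units) centred at ``(x0_i, y0_i)``, the
    centers laid out on a uniform sub-grid of the unit square."""
    rows, cols = grid_shape
    side = int(round(np.sqrt(n_features)))
    if side * side != n_features:
        raise ValueError("blob_grid expects a square number of features")
    cx = np.linspace(0.0, 1.0, side)
    centers = np.stack(np.meshgrid(cx, cx, indexing="xy"), axis=-1).reshape(-1, 2)
    W = _blob_columns(centers, rows, cols, w_max, sigma_w)
    return FeatureBasis(W, background, input_geometry=(rows, cols))


def multiblob_basis(
    n_features: int = 10,
    grid_shape: tuple[int, int] = (30, 30),
    w_max: float = 40.0,
    sigma_w: float = 0.1,
    n_blobs: int = 4,
    centers: np.ndarray | None = None,
    seed: int | None = None,
    background: float = 1.0,
) -> FeatureBasis:
    """Distributed ('olfactory') basis: each feature is a sum of ``n_blobs``
    Gaussian blobs with centers placed uniformly at random on the unit
    square (seed-controlled), each blob with the blob-grid amplitude and
    width."""
    rows, cols = grid_shape
    if centers is None:
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0.0, 1.0, size=(n_features, n_blobs, 2))
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (n_features, n_blobs, 2):
        raise ValueError(f"centers must have shape ({n_features}, {n_blobs}, 2)")
    cols_flat = _blob_columns(centers.reshape(-1, 2), rows, cols, w_max, sigma_w)
    W = cols_flat.reshape(rows * cols, n_features, n_blobs).sum(axis=2)
    return FeatureBasis(W, background, input_geometry=(rows, cols))


_LETTERS = ("V", "I", "A")


def letter_bitmap(letter: str) -> np.ndarray:
    """Load the packaged 30x20 binary raster for 'V', 'I' or 'A'.

    The rasters are fixed synthetic package fixtures (plain-text 0/1 grids)
    standing in for the hand-drawn letter features of the original figures.
    """
    if letter not in _LETTERS:
        raise ValueError(f"no bitmap for {letter!r}; available: {_LETTERS}")
    text = resources.files("divnorm.data").joinpath(f"letter_{letter}.txt").read_text()
    rows = [list(line) for line in text.strip().splitlines()]
    return np.array(rows, dtype=int)


def letters_basis(w_max: float = 40.0, background: float = 1.0) -> FeatureBasis:
    """Three-feature toy basis: the letters 'V', 'I', 'A' rasterized onto a
    30x20 grid of 600 inputs, each scaled to amplitude ``w_max``."""
    cols = [letter_bitmap(c).ravel() for c in _LETTERS]
    W = w_max * np.stack(cols, axis=1).astype(float)
    bitmap_shape = letter_bitmap("V").shape
    return FeatureBasis(
        W, background, input_geometry=bitmap_shape, feature_labels=list(_LETTERS)
    )


def build_basis(spec: BasisBuilderSpec) -> FeatureBasis:
    """Construct a :class:`FeatureBasis` from a declarative spec."""
    k = spec.kind
    if k in ("paired", "topographic_pair"):
        if spec.n_features is None:
            raise ValueError(f"{k} basis requires n_features")
        fn = paired_basis if k == "paired" else topographic_pair_basis
        return fn(spec.n_features, w_max=spec.w_max, background=spec.background)
    if k == "circular":
        if spec.n_features is None:
            raise ValueError("circular basis requires n_features")
        return circular_basis(spec.n_features, w_max=spec.w_max, background=spec.background)
    if k == "blob_grid":
        return blob_grid_basis(
            n_features=spec.n_features or 400,
            grid_shape=spec.grid_shape or (30, 30),
            w_max=spec.w_max,
            sigma_w=spec.sigma_w,
            background=spec.background,
        )
    if k == "multiblob":
        return multiblob_basis(
            n_features=spec.n_features or 10,
            grid_shape=spec.grid_shape or (30, 30),
            w_max=spec.w_max,
            sigma_w=spec.sigma_w,
            n_blobs=spec.n_blobs,
            centers=spec.centers,
            seed=spec.seed,
            background=spec.background,
        )
    if k == "letters":
        return letters_basis(w_max=spec.w_max, background=spec.background)
    raise ValueError(f"unknown basis kind {k!r}")


# ---------------------------------------------------------------------------
# Serialization: JSON header + delimited-text weight matrix
# ---------------------------------------------------------------------------

def save_basis(basis: FeatureBasis, prefix: str) -> None:
    """Write ``<prefix>.json`` (metadata) and ``<prefix>.tsv`` (weights)."""
    header = {
        "n_inputs": basis.n_inputs,
        "n_features": basis.n_features,
        "background": basis.background,
        "input_geometry": basis.input_geometry,
        "feature_labels": basis.feature_labels,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(header, fh, indent=1)
    np.savetxt(f"{prefix}.tsv", basis.weights, delimiter="\t")


def load_basis(prefix: str) -> FeatureBasis:
    with open(f"{prefix}.json") as fh:
        header = json.load(fh)
    W = np.loadtxt(f"{prefix}.tsv", delimiter="\t", ndmin=2)
    geom = header.get("input_geometry")
    return FeatureBasis(
        W,
        header["background"],
        input_geometry=tuple(geom) if geom else None,
        feature_labels=header.get("feature_labels"),
    )
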