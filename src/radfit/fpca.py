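"""Functional principal component analysis of voxel time-activity curves.

Curves sampled at frame mid-times are treated as functional data with a
piecewise-constant quadrature rule whose weights are the frame durations
(seconds).  The sample is centred by the mean curve and the
duration-weighted covariance is eigendecomposed; eigenfunctions are
orthonormal under the quadrature inner product

    <f, g> = sum_t w_t f(t) g(t),      w_t = frame duration.

The number of retained components m is the smallest m whose cumulative
variance fraction exceeds the threshold (default 0.85); per-voxel scores
are projections of the centred curves onto the retained eigenfunctions.
Eigenfunction signs are fixed by requiring the largest-magnitude
coordinate of each eigenfunction to be positive, making repeated fits
and downstream first-component ranking deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FrameSchedule, SchemaError, TACTable, ValidationError

__all__ = ["FPCModel", "FPCScores", "fit_fpca", "transform"]


@dataclass
class FPCModel:
    """Fitted FPCA basis.

    All components are stored (for exact reconstruction); ``m`` is the
    retained count under the variance threshold.
    """

    mean_curve: np.ndarray       # (T,)
    eigenfunctions: np.ndarray   # (n_components, T)
    eigenvalues: np.ndarray      # (n_components,) descending
    m: int
    weights: np.ndarray          # (T,) quadrature weights, seconds
    var_threshold: float

    @property
    def n_frames(self) -> int:
        return self.mean_curve.size

    @property
    def cumulative_variance(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            return np.ones_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / tot


@dataclass
class FPCScores:
    """Per-voxel component scores plus the voxel index mapping."""

    scores: np.ndarray           # (n_voxels, m)
    coords: np.ndarray | None    # (n_voxels, 3) voxel indices, or None

    @property
    def n_voxels(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]


def _fix_signs(eigenfunctions: np.ndarray) -> np.ndarray:
    out = eigenfunctions.copy()
    for j in range(out.shape[0]):
        i = int(np.argmax(np.abs(out[j])))
        if out[j, i] < 0:
            out[j] = -out[j]
    return out


def fit_fpca(tacs: TACTable, schedule: FrameSchedule,
             var_threshold: float = 0.85) -> FPCModel:
    """Fit discretised FPCA to a TAC ensemble.

    Eigendecomposes the duration-weighted sample covariance of the
    centred curves and retains the smallest m components whose cumulative
    variance fraction exceeds ``var_threshold`` (m >= 1 always).
    """
    X = np.asarray(tacs.values, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("FPCA needs at least 2 curves")
    if X.shape[1] < 2:
        raise ValidationError("FPCA needs at least 2 frames")
    if X.shape[1] != schedule.n_frames:
        raise SchemaError("TAC frame count does not match schedule")
    if not 0 < var_threshold <= 1:
        raise ValidationError("var_threshold must be in (0, 1]")

    w = schedule.duration.astype(float)          # quadrature weights, s
    sqw = np.sqrt(w)
    mean = X.mean(axis=0)
    Xc = X - mean
    B = Xc * sqw                                  # weighted coordinates
    # covariance in the weighted space; eigh gives ascending order
    S = (B.T @ B) / X.shape[0]
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    U = evecs[:, order].T                         # (T, T) rows = components
    phi = _fix_signs(U / sqw)                     # orthonormal under <.,.>_w

    tot = evals.sum()
    if tot <= 0:
        warnings.warn("all curves identical: zero covariance, m = 1")
        m = 1
    else:
        cum = np.cumsum(evals) / tot
        m = int(np.searchsorted(cum, var_threshold, side="right")) + 1
        m = min(max(m, 1), evals.size)
    return FPCModel(mean_curve=mean, eigenfunctions=phi, eigenvalues=evals,
                    m=m, weights=w, var_threshold=var_threshold)


def transform(model: FPCModel, tacs: TACTable, n_components: int | None = None
              ) -> FPCScores:
    """Project TACs onto the retained eigenfunctions.

    score(v, j) = sum_t w_t (TAC_v(t) - mean(t)) phi_j(t).
    """
    X = np.asarray(tacs.values, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_frames:
        raise SchemaError("TAC frame count does not match the FPCA model")
    m = model.m if n_components is None else int(n_components)
    if not 1 <= m <= model.eigenfunctions.shape[0]:
        raise ValidationError("invalid component count")
    proj = (model.eigenfunctions[:m] * model.weights)  # (m, T)
    scores = (X - model.mean_curve) @ proj.T
    return FPCScores(scores=scores, coords=tacs.coords)


def reconstruct(model: FPCModel, scores: FPCScores) -> np.ndarray:
    """Inverse transform: mean curve plus the retained-component expansion."""
    m = scores.m
    return model.mean_curve + scores.scores @ model.eigenfunctions[:m]
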