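"""Distributed LORETA-style source imaging on a spherical head model.

A quasi-static dipole-in-homogeneous-sphere forward model (analytic monopole
Green's function of the insulated unit sphere, dipoles by central finite
differences) feeds a Laplacian-weighted minimum-norm (LORETA-type) inverse.
Estimated current densities are norm-reduced over the three orientations per
solution point, standardized across time per point, and averaged over
microstate-labeled frames that pass the 0.9 spatial-correlation gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import UNASSIGNED, Montage, Recording, Segmentation


@dataclass
class LeadField:
    gain: np.ndarray          # (n_sensors, 3 * n_points)
    point_coords: np.ndarray  # (n_points, 3)
    model_desc: str = "homogeneous unit sphere"

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.point_coords = np.asarray(self.point_coords, dtype=float)
        n_points = self.point_coords.shape[0]
        if n_points < 1:
            raise ValueError("lead field needs at least one solution point")
        if self.gain.shape[1] != 3 * n_points:
            raise ValueError("gain must have 3 columns per solution point")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_points(self) -> int:
        return self.point_coords.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]


@dataclass
class SourceEstimate:
    current_density: np.ndarray  # (n_points, n_frames), orientation-norm
    standardized: bool = False

    def __post_init__(self) -> None:
        self.current_density = np.atleast_2d(
            np.asarray(self.current_density, dtype=float))
        if not self.standardized and np.any(self.current_density < -1e-12):
            raise ValueError("norm-reduced current density must be non-negative")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _monopole_potential(sensors: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Surface potential of unit point current sources inside the insulated
    unit sphere (conductivity 1), up to an additive constant.

    Closed form of (1/4pi) sum_{n>=1} ((2n+1)/n) f^n P_n(cos gamma):
    2/d + log(2 / (1 - f cos(gamma) + d)) with d the sensor-source distance.
    The additive constant is irrelevant under average reference.
    """
    cosg = sensors @ sources.T / np.linalg.norm(sources, axis=1)[None, :].clip(1e-300)
    f = np.linalg.norm(sources, axis=1)[None, :]
    x = f * cosg
    d = np.sqrt(np.clip(1.0 - 2.0 * x + f ** 2, 1e-300, None))
    return (2.0 / d + np.log(2.0 / np.clip(1.0 - x + d, 1e-300, None))) / (4 * np.pi)


def dipole_topography(montage: Montage, position: np.ndarray,
                      moment: np.ndarray, delta: float = 1e-4) -> np.ndarray:
    """Average-referenced scalp potentials of one dipole (finite-difference)."""
    position = np.asarray(position, dtype=float)
    moment = np.asarray(moment, dtype=float)
    plus = position + 0.5 * delta * moment
    minus = position - 0.5 * delta * moment
    v = (_monopole_potential(montage.positions, plus[None, :])
         - _monopole_potential(montage.positions, minus[None, :])).ravel() / delta
    return v - v.mean()


def _fibonacci_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform points inside a ball: Fibonacci directions, cube-root radii."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1 - 2 * i / n
    r_xy = np.sqrt(np.clip(1 - z ** 2, 0, None))
    dirs = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    radii = radius * ((i + rng.uniform(0, 0.5)) / n) ** (1 / 3)
    return dirs * radii[:, None]


def build_spherical_leadfield(montage: Montage, n_points: int = 800,
                              seed: int | None = None,
                              max_radius: float = 0.85) -> LeadField:
    """Forward gain matrix for an equally spaced grid inside the unit sphere.

    Solution points are quasi-uniform inside ``max_radius`` (Fibonacci-spiral
    directions with cube-root radial spacing). Three columns per point
    (x/y/z unit dipole moments); every column is average-referenced so the
    model lives in the same reference frame as the data.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    coords = _fibonacci_ball(n_points, max_radius, rng)
    n_actual = coords.shape[0]
    gain = np.empty((montage.n_channels, 3 * n_actual))
    eye = np.eye(3)
    for p in range(n_actual):
        for o in range(3):
            gain[:, 3 * p + o] = dipole_topography(montage, coords[p], eye[o])
    return LeadField(gain=gain, point_coords=coords,
                     model_desc=f"homogeneous unit sphere, {n_actual} points, "
                                f"radius {max_radius}")


# ---------------------------------------------------------------------------
# Inverse operator
# ---------------------------------------------------------------------------

def _grid_laplacian(coords: np.ndarray, n_neighbors: int = 6) -> np.ndarray:
    """Symmetric graph Laplacian over the solution grid (kNN adjacency)."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    k = min(n_neighbors, n - 1)
    adj = np.zeros((n, n))
    if k > 0:
        idx = np.argsort(d, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        adj[rows, idx.ravel()] = 1.0
        adj = np.maximum(adj, adj.T)
    return np.diag(adj.sum(axis=1)) - adj


def loreta_inverse(leadfield: LeadField, regularization: float = 0.1,
                   laplacian_mix: float = 1e-2,
                   depth_weight: float = 0.5) -> np.ndarray:
    """Laplacian-weighted minimum-norm (LORETA-type) inverse operator.

    Solves min ||L j - v||^2 + lambda j' (B'B kron I3 + eps I) j via
    T = A L' (L A L' + lambda I)^+, with B the grid Laplacian. At lambda=0 on
    an invertible square system the reconstruction is exact; at lambda -> inf
    the currents shrink to zero. Input topographies must be
    average-referenced; the operator maps sensors -> 3 * n_points currents.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    lap = _grid_laplacian(leadfield.point_coords)
    # lead-field (depth) normalization: without it minimum-norm solutions
    # collapse onto superficial points
    g3 = leadfield.gain.reshape(leadfield.n_sensors, leadfield.n_points, 3)
    omega = np.sqrt(np.einsum("spo,spo->p", g3, g3)) ** depth_weight
    omega /= omega.mean()
    prior = (omega[:, None] * (lap.T @ lap) * omega[None, :]
             + laplacian_mix * np.diag(omega ** 2))
    a_small = np.linalg.inv(prior)               # points x points
    gain = leadfield.gain
    n_s = leadfield.n_sensors
    # A = a_small kron I3 applied blockwise: (L A L')_{ij} over orientations
    g3 = gain.reshape(n_s, leadfield.n_points, 3)
    alt = np.einsum("spo,pq->sqo", g3, a_small).reshape(n_s, -1)
    gram = alt @ gain.reshape(n_s, -1).T
    core = gram + regularization * np.trace(gram) / n_s * np.eye(n_s)
    try:
        core_inv = np.linalg.inv(core)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular sensor covariance; use regularization > 0") from err
    if regularization == 0 and np.linalg.cond(core) > 1e12:
        raise np.linalg.LinAlgError(
            "system is singular at lambda=0; use regularization > 0")
    return alt.T @ core_inv  # (3*points) x sensors


def apply_inverse(inverse_op: np.ndarray, topographies: np.ndarray) -> SourceEstimate:
    """Map average-referenced topographies (channels x frames) to point norms."""
    topo = np.atleast_2d(np.asarray(topographies, dtype=float))
    if topo.shape[0] != inverse_op.shape[1]:
        topo = topo.T
    currents = inverse_op @ (topo - topo.mean(axis=0, keepdims=True))
    n_points = currents.shape[0] // 3
    norms = np.linalg.norm(currents.reshape(n_points, 3, -1), axis=1)
    return SourceEstimate(current_density=norms, standardized=False)


def standardize_points(estimate: SourceEstimate) -> SourceEstimate:
    """Z-score each solution point's time course (mean 0, SD 1 across frames).

    Removes per-point activation bias so frame averages compare shape, not
    depth-dependent gain. Constant time courses map to zero with a warning.
    """
    x = estimate.current_density
    if x.shape[1] < 2:
        raise ValueError("standardization needs at least 2 frames")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = (sd.ravel() == 0)
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} solution points have constant "
                      "time courses; standardized to zero")
    out = np.where(sd == 0, 0.0, (x - mean) / np.where(sd == 0, 1.0, sd))
    return SourceEstimate(current_density=out, standardized=True)


def microstate_source_average(recording: Recording, segmentation: Segmentation,
                              state: int, inverse_op: np.ndarray,
                              corr_gate: float = 0.9
                              ) -> tuple[np.ndarray | None, int]:
    """Mean standardized current density over gated frames of one microstate.

    Frames must carry winning correlations (from backfitting); only frames
    labeled ``state`` with correlation above ``corr_gate`` enter the average.
    Returns (per-point mean, n_frames_used); (None, 0) when no frame
    qualifies.
    """
    if segmentation.corr is None:
        raise ValueError("segmentation lacks per-frame winning correlations")
    estimate = standardize_points(apply_inverse(inverse_op, recording.data))
    mask = (segmentation.labels == state) & (segmentation.corr > corr_gate)
    mask &= segmentation.labels != UNASSIGNED
    n_used = int(mask.sum())
    if n_used == 0:
        warnings.warn(f"no frames of state {state} pass the {corr_gate} gate")
        return None, 0
    return estimate.current_density[:, mask].mean(axis=1), n_used
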