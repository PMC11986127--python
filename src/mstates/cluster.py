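"""Polarity-invariant modified k-means for microstate topographies.

The algorithm clusters scalp maps at GFP peaks, treating a topography and its
sign-inverse as identical: assignment is by maximum absolute spatial
correlation and the centroid update is the first principal component of the
assigned (GFP-weighted) topographies. Cluster-number selection uses a
three-criterion median vote (Krzanowski-Lai, a predictive-residual
cross-validation criterion, and a dispersion-curve elbow) standing in for
proprietary meta-criteria; the recipe is documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import UNASSIGNED, ChannelMismatchError, MicrostateMapSet, Recording
from .preprocess import average_reference, gfp, gfp_peaks


@dataclass
class ClusterParams:
    """Knobs of the modified k-means and the cluster-number search."""

    k_range: tuple[int, ...] = tuple(range(1, 13))
    n_restarts: int = 100
    min_assign_corr: float = 0.5
    ignore_polarity: bool = True
    convergence_tol: float = 1e-6
    max_iter: int = 300
    seed: int | None = None

    def __post_init__(self) -> None:
        self.k_range = tuple(sorted(set(int(k) for k in self.k_range)))
        if not self.k_range:
            raise ValueError("k_range must be nonempty")
        if not (0.0 <= self.min_assign_corr <= 1.0):
            raise ValueError("min_assign_corr must lie in [0, 1]")


GROUP_DEFAULTS = dict(k_range=tuple(range(1, 16)), n_restarts=200)


@dataclass
class ClusterSolution:
    maps: MicrostateMapSet
    assignment: np.ndarray        # per-sample state index, UNASSIGNED below threshold
    gev: float                    # GFP^2-weighted explained variance, in [0, 1]
    corr: np.ndarray | None = None  # winning |spatial correlation| per sample
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValueError("GEV must lie in [0, 1]")

    @property
    def k(self) -> int:
        return self.maps.n_maps


# ---------------------------------------------------------------------------
# Spatial correlation
# ---------------------------------------------------------------------------

def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        ignore_polarity: bool = True) -> float:
    """Pearson correlation over channels of two scalp maps.

    Both maps are re-centered across channels; with ``ignore_polarity`` the
    absolute value is returned, reflecting that oscillatory generators make a
    topography and its sign-flip equivalent.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ChannelMismatchError(
            f"maps have {a.size} vs {b.size} channels")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a zero-variance map")
    r = float(a @ b / (na * nb))
    return abs(r) if ignore_polarity else r


def _center_normalize(x: np.ndarray) -> np.ndarray:
    """Row-wise average reference + unit norm; rejects all-zero rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance topography cannot be normalized")
    return x / norms


# ---------------------------------------------------------------------------
# GEV
# ---------------------------------------------------------------------------

def gev_of_solution(topographies: np.ndarray, gfp_at_samples: np.ndarray,
                    labels: np.ndarray, maps: np.ndarray,
                    ignore_polarity: bool = True) -> float:
    """Global explained variance of a labeling.

    GEV = sum_t (GFP_t * corr_t)^2 / sum_t GFP_t^2, where corr_t is the
    spatial correlation between frame t and its assigned map; unassigned
    samples contribute zero to the numerator but their full GFP^2 to the
    denominator.
    """
    g = np.asarray(gfp_at_samples, dtype=float)
    labels = np.asarray(labels, dtype=int)
    denom = float(np.sum(g ** 2))
    if denom == 0:
        raise ValueError("GEV undefined: all-zero GFP")
    xn = _center_normalize(topographies)
    mn = _center_normalize(maps)
    corr = xn @ mn.T
    if ignore_polarity:
        corr = np.abs(corr)
    assigned = labels != UNASSIGNED
    c = np.zeros(len(labels))
    c[assigned] = corr[assigned, labels[assigned]]
    return float(np.sum((g * c) ** 2) / denom)


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def _principal_map(xn: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """First principal component of weighted normalized topographies.

    Maximizes sum_t w_t^2 (x_hat_t . m)^2 over unit-norm m: the leading
    eigenvector of sum w^2 x x^T. Polarity-invariant by construction.
    """
    y = xn * weights[:, None]
    s = y.T @ y
    vals, vecs = np.linalg.eigh(s)
    m = vecs[:, -1]
    m = m - m.mean()
    n = np.linalg.norm(m)
    if n == 0:  # degenerate: all mass in the mean direction
        m = xn[np.argmax(weights)]
        n = np.linalg.norm(m)
    return m / n


def _assign(xn: np.ndarray, maps: np.ndarray, min_corr: float,
            ignore_polarity: bool) -> tuple[np.ndarray, np.ndarray]:
    corr = xn @ maps.T
    a = np.abs(corr) if ignore_polarity else corr
    labels = np.argmax(a, axis=1)
    best = a[np.arange(len(labels)), labels]
    labels = np.where(best >= min_corr, labels, UNASSIGNED)
    return labels, best


def modified_kmeans(topographies: np.ndarray, k: int,
                    params: ClusterParams | None = None,
                    gfp_at_samples: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> ClusterSolution:
    """Best-of-restarts polarity-invariant k-means on scalp topographies.

    ``gfp_at_samples`` weights both the centroid update and the GEV; when
    omitted it is taken as each topography's own GFP (spatial SD).
    """
    params = params or ClusterParams()
    x = np.atleast_2d(np.asarray(topographies, dtype=float))
    n, n_ch = x.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available topographies")
    if gfp_at_samples is None:
        gfp_at_samples = x.std(axis=1, ddof=0)
    g = np.asarray(gfp_at_samples, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    xn = _center_normalize(x)
    denom = float(np.sum(g ** 2))
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None

    for _ in range(params.n_restarts):
        maps = xn[rng.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        for _it in range(params.max_iter):
            labels, bestcorr = _assign(xn, maps, params.min_assign_corr,
                                       params.ignore_polarity)
            for c in range(k):
                members = labels == c
                if not np.any(members):
                    # reseed the empty cluster from the worst-fit topography
                    maps[c] = xn[np.argmin(bestcorr)]
                    continue
                maps[c] = _principal_map(xn[members], g[members])
            labels, bestcorr = _assign(xn, maps, params.min_assign_corr,
                                       params.ignore_polarity)
            assigned = labels != UNASSIGNED
            num = float(np.sum((g[assigned] * bestcorr[assigned]) ** 2))
            gev = num / denom
            if gev - prev_gev < params.convergence_tol * max(prev_gev, 1e-12):
                prev_gev = gev
                break
            prev_gev = gev
        if best is None or prev_gev > best[0]:
            best = (prev_gev, maps.copy(), labels.copy(), bestcorr.copy())

    gev, maps, labels, bestcorr = best
    mapset = MicrostateMapSet(maps=maps,
                              channel_names=[f"ch{i}" for i in range(n_ch)],
                              level="subject", fit_gev=min(max(gev, 0.0), 1.0))
    return ClusterSolution(maps=mapset, assignment=labels,
                           gev=min(max(gev, 0.0), 1.0), corr=bestcorr)


# ---------------------------------------------------------------------------
# Cluster-number selection
# ---------------------------------------------------------------------------

def select_optimal_k(solutions: dict[int, ClusterSolution],
                     topographies: np.ndarray,
                     gfp_at_samples: np.ndarray | None = None) -> tuple[int, dict]:
    """Median vote of three criteria over candidate cluster counts.

    Criteria: Krzanowski-Lai index on the GFP^2-weighted dispersion curve,
    Pascual-Marqui's predictive-residual cross-validation criterion, and the
    elbow (maximum second difference) of the dispersion curve. Diagnostics
    carry every criterion's vote and curve.
    """
    ks = sorted(solutions)
    x = np.atleast_2d(np.asarray(topographies, dtype=float))
    n, n_ch = x.shape
    if gfp_at_samples is None:
        gfp_at_samples = x.std(axis=1, ddof=0)
    g = np.asarray(gfp_at_samples, dtype=float)

    if len(ks) == 1:
        return ks[0], {"votes": {}, "note": "single candidate"}

    xn = _center_normalize(x)
    w_curve, sigma2 = {}, {}
    for k in ks:
        sol = solutions[k]
        labels = np.asarray(sol.assignment)
        mn = _center_normalize(sol.maps.maps)
        corr = np.abs(xn @ mn.T)
        c = np.zeros(n)
        assigned = labels != UNASSIGNED
        c[assigned] = corr[assigned, labels[assigned]]
        w_curve[k] = float(np.sum(g ** 2 * (1 - c ** 2)))
        # predictive residual variance (unnormalized amplitudes)
        norms2 = np.sum((x - x.mean(axis=1, keepdims=True)) ** 2, axis=1)
        resid = float(np.sum(norms2 * (1 - c ** 2))) / (n * (n_ch - 1))
        shrink = ((n_ch - 1) / max(n_ch - 1 - k, 1)) ** 2
        sigma2[k] = resid * shrink

    votes: dict[str, int] = {}
    interior = [k for k in ks if (k - 1) in w_curve and (k + 1) in w_curve]
    if interior:
        def diff(k: int) -> float:
            return ((k - 1) ** (2 / n_ch) * w_curve[k - 1]
                    - k ** (2 / n_ch) * w_curve[k]) if k - 1 >= 1 else np.nan
        kl = {}
        for k in interior:
            d1, d2 = diff(k), diff(k + 1)
            if np.isfinite(d1) and np.isfinite(d2) and abs(d2) > 1e-300:
                kl[k] = abs(d1) / abs(d2)
        if kl:
            votes["krzanowski_lai"] = max(kl, key=kl.get)
        elbow = {k: w_curve[k - 1] - 2 * w_curve[k] + w_curve[k + 1]
                 for k in interior}
        votes["elbow"] = max(elbow, key=elbow.get)
    votes["cross_validation"] = min(sigma2, key=sigma2.get)

    if not votes:
        chosen = max(ks, key=lambda k: solutions[k].gev)
    else:
        chosen = int(np.median(sorted(votes.values())))
        if chosen not in ks:  # median of an even vote count can fall between ks
            chosen = min(ks, key=lambda k: abs(k - chosen))
    return chosen, {"votes": votes, "w_curve": w_curve, "cv": sigma2}


# ---------------------------------------------------------------------------
# Stage 1 and stage 2 drivers
# ---------------------------------------------------------------------------

def spatial_smooth(recording: Recording, n_neighbors: int = 6,
                   self_weight: float = 0.5) -> Recording:
    """Instantaneous spatial filter: blend each channel with its neighbors' mean."""
    if recording.montage is None:
        raise ValueError("spatial smoothing requires a montage")
    pos = recording.montage.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1)[:, :n_neighbors]
    neighbor_mean = recording.data[idx].mean(axis=1)
    out = self_weight * recording.data + (1 - self_weight) * neighbor_mean
    return recording.with_data(out, note=f"spatial_smooth({n_neighbors})")


def subject_segmentation(recording: Recording,
                         params: ClusterParams | None = None,
                         min_peak_separation: int = 0,
                         apply_spatial_filter: bool = False) -> ClusterSolution:
    """Stage-1 clustering of one subject's GFP-peak topographies.

    Clusters only the maps at GFP peaks over the subject's k-range, picks the
    optimal k by the meta-criterion vote, and returns that solution with its
    map set tagged subject-level.
    """
    params = params or ClusterParams()
    rec = spatial_smooth(recording) if apply_spatial_filter else recording
    rec = average_reference(rec)
    series = gfp(rec)
    peaks = gfp_peaks(series, min_peak_separation)
    if peaks.size == 0:
        raise ValueError("no GFP peaks found")
    topos = rec.data[:, peaks].T
    g = series.values[peaks]

    k_range = params.k_range
    if max(k_range) > peaks.size:
        warnings.warn(
            f"only {peaks.size} GFP peaks: truncating k_range at {peaks.size}")
        k_range = tuple(k for k in k_range if k <= peaks.size)
    rng = np.random.default_rng(params.seed)
    solutions = {k: modified_kmeans(topos, k, params, g, rng) for k in k_range}
    chosen, diag = select_optimal_k(solutions, topos, g)
    sol = solutions[chosen]
    sol.diagnostics = diag
    sol.maps.channel_names = list(recording.channel_names)
    sol.maps.level = "subject"
    return sol


def canonical_templates(montage) -> np.ndarray:
    """Idealized A-D scalp patterns built from sensor positions.

    A: right-frontal to left-posterior gradient; B: left-frontal to
    right-posterior; C: frontal-occipital; D: frontocentral focal maximum.
    """
    x, y, z = montage.positions.T
    focal = np.exp(-np.sum((montage.positions - np.array([0.0, 0.35, 0.94])) ** 2,
                           axis=1) / 0.5)
    return _center_normalize(np.stack([x + y, y - x, y, focal]))


def order_canonically(mapset: MicrostateMapSet, montage) -> tuple[MicrostateMapSet, np.ndarray]:
    """Sort maps to best match the canonical A-D templates (Hungarian match).

    Maps beyond the four matched ones are appended in their existing order.
    Returns the reordered set and the permutation applied.
    """
    templates = canonical_templates(montage)
    mn = _center_normalize(mapset.maps)
    score = np.abs(templates @ mn.T)  # 4 x K
    rows, cols = linear_sum_assignment(-score)
    order = list(cols[np.argsort(rows)])
    order += [i for i in range(mapset.n_maps) if i not in order]
    labels = [chr(ord("A") + i) if i < 26 else f"M{i}" for i in range(mapset.n_maps)]
    out = MicrostateMapSet(maps=mapset.maps[order], channel_names=mapset.channel_names,
                           level=mapset.level, labels=labels, fit_gev=mapset.fit_gev)
    return out, np.asarray(order)


def group_clustering(subject_solutions: list[ClusterSolution],
                     params: ClusterParams | None = None,
                     montage=None) -> MicrostateMapSet:
    """Stage-2 pooled clustering of all subjects' retained maps.

    All participants' subject-level maps are pooled into a single clustering
    (separate subgroup clusterings inflate false positives), run over the
    group k-range with the same polarity-invariant algorithm and the same
    meta-criterion. The result is the canonical group map set used for
    backfitting, ordered against the A-D templates when a montage is given.
    """
    if len(subject_solutions) < 2:
        raise ValueError("group clustering needs at least 2 subjects")
    channel_sets = {tuple(s.maps.channel_names) for s in subject_solutions}
    if len(channel_sets) != 1:
        raise ChannelMismatchError("subjects have differing channel sets")
    if params is None:
        params = ClusterParams(**GROUP_DEFAULTS)

    pooled = np.vstack([s.maps.maps for s in subject_solutions])
    weights = np.ones(pooled.shape[0])
    k_range = tuple(k for k in params.k_range if k <= pooled.shape[0])
    rng = np.random.default_rng(params.seed)
    solutions = {k: modified_kmeans(pooled, k, params, weights, rng)
                 for k in k_range}
    chosen, diag = select_optimal_k(solutions, pooled, weights)
    sol = solutions[chosen]
    mapset = MicrostateMapSet(maps=sol.maps.maps,
                              channel_names=list(channel_sets.pop()),
                              level="group", fit_gev=sol.gev)
    if montage is not None:
        mapset, _ = order_canonically(mapset, montage)
    return mapset
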