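"""Synthetic resting-state EEG with planted microstate structure.

The generator emulates the study conditions every downstream stage is tested
against: eyes-closed recordings a few minutes long, a few dozen sensors,
four recurring quasi-stable topographies with mean durations in the
50-80 ms range, a three-group cohort (patient / older control / younger
control) with group-wise shifts planted on one state's duration and
occurrence (down) and another's (up), and Likert questionnaire scores weakly
correlated with one state's occurrence.

Signal model: x(t) = a(t) * m_{s(t)} + noise, with s(t) a semi-Markov state
sequence (gamma-distributed dwell times, shape 2), a(t) a rectified sinusoid
(GFP waxing and waning at the dominant oscillation frequency), and spatially
smoothed white sensor noise scaled to the requested SNR. Group effects are
planted on generator parameters, never on extracted metrics, so the whole
pipeline is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MicrostateMapSet, Montage, Recording, Segmentation
from .io import METRIC_COLUMNS


# ---------------------------------------------------------------------------
# Montage helper
# ---------------------------------------------------------------------------

def demo_montage(n_channels: int = 32) -> Montage:
    """Quasi-uniform sensor layout on the upper portion of the unit sphere.

    Fibonacci-spiral directions restricted to z > -0.25, emulating scalp
    coverage without neck/cheek positions.
    """
    i = np.arange(n_channels) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    # z spans the scalp cap only
    z = 1.0 - 1.25 * i / n_channels
    r_xy = np.sqrt(np.clip(1 - z ** 2, 0, None))
    pos = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    names = [f"E{j + 1}" for j in range(n_channels)]
    return Montage(channel_names=names, positions=pos)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

def _uniform_offdiag(k: int) -> np.ndarray:
    if k == 1:
        return np.zeros((1, 1))
    t = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class SimulationSpec:
    """Per-recording generator parameters (study-condition defaults)."""

    n_channels: int = 32
    sampling_rate: float = 250.0
    duration_s: float = 300.0
    n_states: int = 4
    mean_durations_ms: tuple[float, ...] = (55.0, 60.0, 70.0, 65.0)
    transition_matrix: np.ndarray | None = None
    oscillation_freq_hz: float = 10.0
    snr: float = 5.0
    signal_rms_uv: float = 10.0
    gamma_shape: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.mean_durations_ms) != self.n_states:
            raise ValueError("one mean duration per state required")
        if any(d <= 0 for d in self.mean_durations_ms):
            raise ValueError("mean durations must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.transition_matrix is None:
            self.transition_matrix = _uniform_offdiag(self.n_states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.n_states
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix must be K x K")
        if np.any(np.diag(self.transition_matrix) != 0):
            raise ValueError("transition matrix must have a zero diagonal")
        if k > 1 and not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))


@dataclass
class CohortSpec:
    """Three-group cohort design with planted effects.

    Multipliers are relative to the baseline (last) group; the defaults
    plant a decrease of the third state's (C-like) duration and occurrence
    in the two older groups and an increase of the first state's (A-like)
    parameters in the patient group, plus a weak positive correlation
    between the C-like state's occurrence and one questionnaire domain.
    """

    group_names: tuple[str, ...] = ("mci", "ho", "hy")
    group_sizes: tuple[int, ...] = (30, 60, 60)
    duration_multipliers: dict = field(default_factory=lambda: {
        "mci": {2: 0.85, 0: 1.15}, "ho": {2: 0.85, 0: 1.07}, "hy": {}})
    occurrence_multipliers: dict = field(default_factory=lambda: {
        "mci": {2: 0.90, 0: 1.25}, "ho": {2: 0.90, 0: 1.10}, "hy": {}})
    subject_jitter_sd: float = 0.10
    questionnaire_state: int = 2
    questionnaire_domain: str = "visual_thought"
    correlation_target: float = 0.21
    item_noise_sd: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("one size per group name required")
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        for table in (self.duration_multipliers, self.occurrence_multipliers):
            for g, mults in table.items():
                if any(m <= 0 for m in mults.values()):
                    raise ValueError(f"multipliers must be positive (group {g})")


# ---------------------------------------------------------------------------
# Template maps
# ---------------------------------------------------------------------------

def _harmonic_basis(montage: Montage, max_degree: int) -> np.ndarray:
    """Low-order polynomial (solid-harmonic) fields at the sensor positions."""
    x, y, z = montage.positions.T
    cols = [x, y, z]
    if max_degree >= 2:
        cols += [x * y, x * z, y * z, x ** 2 - y ** 2, 2 * z ** 2 - x ** 2 - y ** 2]
    if max_degree >= 3:
        cols += [x * y * z, x * (x ** 2 - 3 * y ** 2), y * (3 * x ** 2 - y ** 2),
                 z * (2 * z ** 2 - 3 * x ** 2 - 3 * y ** 2)]
    return np.stack(cols, axis=1)


def make_template_maps(montage: Montage, n_states: int = 4,
                       smoothness: int = 2, seed: int | None = None,
                       max_pairwise_corr: float = 0.6,
                       max_tries: int = 200) -> MicrostateMapSet:
    """K smooth, average-referenced, unit-norm template topographies.

    Each map is a random combination of low-degree spherical-harmonic fields
    of the sensor positions; candidate sets are redrawn until every pair has
    |spatial correlation| <= ``max_pairwise_corr``.
    """
    if n_states > montage.n_channels:
        raise ValueError("cannot plant more maps than channels")
    rng = np.random.default_rng(seed)
    basis = _harmonic_basis(montage, max_degree=max(1, smoothness + 1))
    for _try in range(max_tries):
        weights = rng.standard_normal((n_states, basis.shape[1]))
        maps = weights @ basis.T
        maps = maps - maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(maps, axis=1, keepdims=True)
        if np.any(norms == 0):
            continue
        maps = maps / norms
        corr = np.abs(maps @ maps.T)
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= max_pairwise_corr:
            return MicrostateMapSet(maps=maps,
                                    channel_names=list(montage.channel_names),
                                    level="group")
    raise RuntimeError(
        f"could not draw {n_states} maps with pairwise |corr| <= "
        f"{max_pairwise_corr} in {max_tries} tries; lower n_states")


# ---------------------------------------------------------------------------
# State sequence and EEG
# ---------------------------------------------------------------------------

def simulate_state_sequence(spec: SimulationSpec,
                            rng: np.random.Generator | None = None) -> Segmentation:
    """Semi-Markov label sequence: gamma dwell times, matrix-driven successors."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    labels = np.empty(n, dtype=int)
    k = spec.n_states
    state = int(rng.integers(k))
    t = 0
    while t < n:
        mean_frames = spec.mean_durations_ms[state] * spec.sampling_rate / 1000.0
        dwell = rng.gamma(spec.gamma_shape, mean_frames / spec.gamma_shape)
        length = max(1, int(round(dwell)))
        labels[t:t + length] = state
        t += length
        if k > 1:
            state = int(rng.choice(k, p=spec.transition_matrix[state]))
    return Segmentation(labels=labels, sampling_rate=spec.sampling_rate)


def _smooth_noise(montage: Montage, n_frames: int,
                  rng: np.random.Generator, n_neighbors: int = 4) -> np.ndarray:
    """Spatially correlated sensor noise: neighbor-averaged white noise."""
    white = rng.standard_normal((montage.n_channels, n_frames))
    pos = montage.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1)[:, :n_neighbors]
    noise = 0.5 * white + 0.5 * white[idx].mean(axis=1)
    return noise - noise.mean(axis=0, keepdims=True)


def simulate_eeg(maps: MicrostateMapSet, sequence: Segmentation,
                 spec: SimulationSpec, montage: Montage,
                 rng: np.random.Generator | None = None) -> Recording:
    """Render a label sequence into sensor space.

    The active map is amplitude-modulated by a rectified sinusoid at the
    dominant oscillation frequency (GFP waxes and wanes, peaking twice per
    cycle); spatially smoothed white noise is added at the requested SNR
    (RMS of map signal over RMS of noise). Every frame is average-referenced
    by construction.
    """
    if maps.n_maps < spec.n_states:
        raise ValueError("map set has fewer maps than the sequence has states")
    if sequence.n_frames != spec.n_frames:
        raise ValueError("sequence length does not match the spec")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) / spec.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)
    amplitude = np.abs(np.sin(2 * np.pi * spec.oscillation_freq_hz * t + phase))
    m = maps.normalized().maps
    signal = amplitude[None, :] * m[sequence.labels].T
    signal_rms = np.sqrt(np.mean(signal ** 2))
    signal *= spec.signal_rms_uv / signal_rms
    if np.isfinite(spec.snr):
        noise = _smooth_noise(montage, spec.n_frames, rng)
        noise *= spec.signal_rms_uv / spec.snr / np.sqrt(np.mean(noise ** 2))
    else:
        noise = 0.0
    return Recording(data=signal + noise, sampling_rate=spec.sampling_rate,
                     channel_names=list(montage.channel_names), montage=montage,
                     history=[f"simulate_eeg(snr={spec.snr}, "
                              f"f={spec.oscillation_freq_hz} Hz)"])


# ---------------------------------------------------------------------------
# Ground-truth metrics (independent arithmetic, no shared code path)
# ---------------------------------------------------------------------------

def truth_metrics_from_labels(labels: np.ndarray, sampling_rate: float,
                              n_states: int, subject_id: str,
                              group: str) -> pd.DataFrame:
    """Temporal parameters computed directly from a label sequence.

    Deliberately re-derives run lengths with a plain scan (no shared code
    with the metrics module) so the two paths can cross-check each other.
    """
    runs: list[tuple[int, int]] = []
    prev, run_len = int(labels[0]), 0
    for lab in labels:
        if lab == prev:
            run_len += 1
        else:
            runs.append((prev, run_len))
            prev, run_len = int(lab), 1
    runs.append((prev, run_len))
    total_frames = len(labels)
    total_s = total_frames / sampling_rate
    rows = []
    for s in range(n_states):
        lens = [ln for st, ln in runs if st == s]
        n_segs = len(lens)
        frames = sum(lens)
        rows.append({
            "subject_id": subject_id, "group": group,
            "state": chr(ord("A") + s),
            "gev_pct": float("nan"),
            "duration_ms": (sum(lens) / n_segs * 1000.0 / sampling_rate
                            if n_segs else float("nan")),
            "coverage_pct": frames / total_frames * 100.0,
            "occurrence_per_s": n_segs / total_s,
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    recording: Recording | None
    truth_labels: Segmentation
    true_mean_durations_ms: tuple[float, ...]


@dataclass
class CohortResult:
    subjects: list[SubjectRecord]
    templates: MicrostateMapSet
    truth_metrics: pd.DataFrame
    questionnaire: pd.DataFrame  # subjects x 30 items
    montage: Montage


def _occurrence_to_transition(base: np.ndarray, mults: dict[int, float]) -> np.ndarray:
    """Bias successor probabilities toward/away from states, keeping rows valid."""
    t = base.copy()
    for s, m in mults.items():
        t[:, s] *= m
    np.fill_diagonal(t, 0.0)
    rows = t.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return t / rows


def simulate_cohort(cohort: CohortSpec | None = None,
                    spec: SimulationSpec | None = None,
                    render_eeg: bool = True) -> CohortResult:
    """Generate a full three-group cohort with ground truth.

    Per subject: group multipliers applied to the generator's mean durations
    and successor probabilities, mild lognormal between-subject jitter on the
    durations, a fresh state sequence and (optionally) rendered EEG.
    Questionnaire: the designated domain's latent score is a linear function
    of the subject's true occurrence of the designated state, calibrated to
    the requested correlation, discretized item-wise to 1-5; the other nine
    domains are effect-free.
    """
    cohort = cohort or CohortSpec()
    spec = spec or SimulationSpec()
    root = np.random.SeedSequence(cohort.seed if cohort.seed is not None else 0)
    master = np.random.default_rng(root)

    templates = make_template_maps(demo_montage(spec.n_channels), spec.n_states,
                                   seed=master.integers(2 ** 31))
    montage = demo_montage(spec.n_channels)
    subjects: list[SubjectRecord] = []
    truth_frames = []
    sid = 0
    for gname, gsize in zip(cohort.group_names, cohort.group_sizes):
        dur_mult = cohort.duration_multipliers.get(gname, {})
        occ_mult = cohort.occurrence_multipliers.get(gname, {})
        transition = _occurrence_to_transition(spec.transition_matrix, occ_mult)
        for _ in range(gsize):
            rng = np.random.default_rng(root.spawn(1)[0])
            jitter = np.exp(rng.normal(0.0, cohort.subject_jitter_sd,
                                       spec.n_states))
            durations = tuple(
                d * dur_mult.get(s, 1.0) * jitter[s]
                for s, d in enumerate(spec.mean_durations_ms))
            subj_spec = SimulationSpec(
                n_channels=spec.n_channels, sampling_rate=spec.sampling_rate,
                duration_s=spec.duration_s, n_states=spec.n_states,
                mean_durations_ms=durations, transition_matrix=transition,
                oscillation_freq_hz=spec.oscillation_freq_hz, snr=spec.snr,
                signal_rms_uv=spec.signal_rms_uv, gamma_shape=spec.gamma_shape)
            seq = simulate_state_sequence(subj_spec, rng)
            rec = (simulate_eeg(templates, seq, subj_spec, montage, rng)
                   if render_eeg else None)
            name = f"sub-{sid:03d}"
            subjects.append(SubjectRecord(name, gname, rec, seq, durations))
            truth_frames.append(truth_metrics_from_labels(
                seq.labels, spec.sampling_rate, spec.n_states, name, gname))
            sid += 1

    truth = pd.concat(truth_frames, ignore_index=True)
    questionnaire = _simulate_questionnaire(cohort, truth, master)
    return CohortResult(subjects=subjects, templates=templates,
                        truth_metrics=truth, questionnaire=questionnaire,
                        montage=montage)


def _simulate_questionnaire(cohort: CohortSpec, truth: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
    from .stats import ARSQ_DOMAINS, DEFAULT_ITEM_MAP

    state_label = chr(ord("A") + cohort.questionnaire_state)
    occ = (truth[truth["state"] == state_label]
           .set_index("subject_id")["occurrence_per_s"])
    z_occ = (occ - occ.mean()) / occ.std(ddof=0)
    n = len(occ)
    rho = cohort.correlation_target
    latent = {}
    for domain in ARSQ_DOMAINS:
        if domain == cohort.questionnaire_domain:
            z = rho * z_occ.to_numpy() + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        latent[domain] = 9.0 + 2.5 * z  # domain scale: 3-15, centered mid-range
    items = np.empty((n, 30))
    for domain, idx in DEFAULT_ITEM_MAP.items():
        per_item = latent[domain][:, None] / 3.0
        raw = per_item + rng.normal(0, cohort.item_noise_sd, (n, 3))
        items[:, idx] = np.clip(np.round(raw), 1, 5)
    return pd.DataFrame(items.astype(int), index=occ.index,
                        columns=[f"item{j + 1:02d}" for j in range(30)])
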