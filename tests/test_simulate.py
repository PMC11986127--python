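import numpy as np
import pytest

import mstates as ms
from mstates.core import UNASSIGNED, segments_from_labels
from mstates.simulate import CohortSpec, SimulationSpec, truth_metrics_from_labels


class TestTemplateMaps:
    def test_single_map_is_centered_unit_norm(self, montage24):
        mset = ms.make_template_maps(montage24, 1, seed=0)
        assert mset.n_maps == 1
        assert abs(mset.maps[0].mean()) < 1e-12
        assert np.linalg.norm(mset.maps[0]) == pytest.approx(1.0)

    def test_deterministic_under_seed(self, montage24):
        a = ms.make_template_maps(montage24, 4, seed=5)
        b = ms.make_template_maps(montage24, 4, seed=5)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_pairwise_correlation_bounded_over_seeds(self, montage24):
        for seed in range(100):
            mset = ms.make_template_maps(montage24, 4, seed=seed)
            corr = np.abs(mset.maps @ mset.maps.T)
            np.fill_diagonal(corr, 0.0)
            assert corr.max() <= 0.6 + 1e-12

    def test_too_many_maps_rejected(self, montage24):
        with pytest.raises(ValueError):
            ms.make_template_maps(montage24, 25)


class TestStateSequence:
    def test_single_state_spans_recording(self):
        spec = SimulationSpec(n_states=1, mean_durations_ms=(60.0,),
                              duration_s=2.0)
        seq = ms.simulate_state_sequence(spec, np.random.default_rng(0))
        segs = segments_from_labels(seq.labels)
        assert len(segs) == 1 and segs[0].length == seq.n_frames

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_empirical_mean_duration_within_5pct(self, seed):
        spec = SimulationSpec(mean_durations_ms=(80.0,) * 4, duration_s=300.0)
        seq = ms.simulate_state_sequence(spec, np.random.default_rng(seed))
        lengths = [s.length for s in segments_from_labels(seq.labels)]
        mean_ms = np.mean(lengths) * 1000 / spec.sampling_rate
        assert abs(mean_ms - 80.0) / 80.0 < 0.05

    def test_uniform_transitions_give_uniform_successors(self):
        spec = SimulationSpec(duration_s=600.0)
        seq = ms.simulate_state_sequence(spec, np.random.default_rng(4))
        segs = segments_from_labels(seq.labels)
        counts = np.zeros((4, 4))
        for a, b in zip(segs, segs[1:]):
            counts[a.state, b.state] += 1
        from scipy.stats import chisquare
        for s in range(4):
            row = np.delete(counts[s], s)
            assert chisquare(row).pvalue > 0.001

    def test_transition_rows_must_sum_to_one(self):
        bad = np.array([[0.0, 0.5], [0.7, 0.0]])
        with pytest.raises(ValueError, match="sum"):
            SimulationSpec(n_states=2, mean_durations_ms=(60.0, 60.0),
                           transition_matrix=bad)


class TestSimulateEeg:
    def test_noise_free_frames_match_active_map(self, montage24, templates4):
        spec = SimulationSpec(n_channels=24, duration_s=2.0, snr=np.inf)
        rng = np.random.default_rng(0)
        seq = ms.simulate_state_sequence(spec, rng)
        rec = ms.simulate_eeg(templates4, seq, spec, montage24, rng)
        g = ms.gfp(rec).values
        active = g > 0.1 * g.max()
        for t in np.flatnonzero(active)[::50]:
            corr = ms.spatial_correlation(rec.data[:, t],
                                          templates4.maps[seq.labels[t]])
            assert corr == pytest.approx(1.0, abs=1e-9)

    def test_fixed_seed_bit_identical(self, montage24, templates4):
        spec = SimulationSpec(n_channels=24, duration_s=5.0, seed=9)
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            seq = ms.simulate_state_sequence(spec, rng)
            recs.append(ms.simulate_eeg(templates4, seq, spec, montage24, rng))
        np.testing.assert_array_equal(recs[0].data, recs[1].data)

    def test_average_referenced_every_frame(self, montage24, templates4):
        spec = SimulationSpec(n_channels=24, duration_s=3.0, snr=3.0)
        rng = np.random.default_rng(1)
        seq = ms.simulate_state_sequence(spec, rng)
        rec = ms.simulate_eeg(templates4, seq, spec, montage24, rng)
        np.testing.assert_allclose(rec.data.mean(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("snr,floor", [(10.0, 0.95), (2.0, 0.80)])
    def test_gfp_peak_label_recovery(self, montage24, templates4, snr, floor):
        spec = SimulationSpec(n_channels=24, duration_s=30.0, snr=snr)
        rng = np.random.default_rng(11)
        seq = ms.simulate_state_sequence(spec, rng)
        rec = ms.simulate_eeg(templates4, seq, spec, montage24, rng)
        peaks = ms.gfp_peaks(ms.gfp(rec))
        xn = rec.data[:, peaks].T
        xn = xn - xn.mean(axis=1, keepdims=True)
        xn /= np.linalg.norm(xn, axis=1, keepdims=True)
        labels = np.argmax(np.abs(xn @ templates4.maps.T), axis=1)
        assert np.mean(labels == seq.labels[peaks]) >= floor


class TestCohort:
    def test_truth_metrics_show_planted_multipliers(self):
        cohort = CohortSpec(group_names=("lo", "base"), group_sizes=(25, 25),
                            duration_multipliers={"lo": {2: 0.75}},
                            occurrence_multipliers={}, seed=3)
        spec = SimulationSpec(n_channels=8, duration_s=60.0)
        res = ms.simulate_cohort(cohort, spec, render_eeg=False)
        truth = res.truth_metrics
        c = truth[truth.state == "C"].groupby("group")["duration_ms"].mean()
        ratio = c["lo"] / c["base"]
        assert abs(ratio - 0.75) < 0.075

    def test_questionnaire_correlation_near_target(self):
        cohort = CohortSpec(group_names=("g",), group_sizes=(100,),
                            duration_multipliers={}, occurrence_multipliers={},
                            correlation_target=0.3, seed=5)
        spec = SimulationSpec(n_channels=8, duration_s=120.0)
        res = ms.simulate_cohort(cohort, spec, render_eeg=False)
        domains = ms.arsq_domains(res.questionnaire)
        occ = (res.truth_metrics[res.truth_metrics.state == "C"]
               .set_index("subject_id")["occurrence_per_s"]
               .reindex(domains.index))
        r, _ = ms.pearson_corr(occ.to_numpy(),
                               domains["visual_thought"].to_numpy())
        assert abs(r - 0.3) < 0.15

    def test_item_values_in_likert_range(self):
        cohort = CohortSpec(group_names=("g",), group_sizes=(10,), seed=0,
                            duration_multipliers={}, occurrence_multipliers={})
        res = ms.simulate_cohort(cohort, SimulationSpec(n_channels=8,
                                                        duration_s=10.0),
                                 render_eeg=False)
        q = res.questionnaire.to_numpy()
        assert q.min() >= 1 and q.max() <= 5
        assert q.shape == (10, 30)

    def test_fixed_seed_reproducible(self):
        cohort = CohortSpec(group_names=("g",), group_sizes=(3,), seed=7)
        spec = SimulationSpec(n_channels=8, duration_s=5.0)
        a = ms.simulate_cohort(cohort, spec)
        b = ms.simulate_cohort(cohort, spec)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)
            np.testing.assert_array_equal(sa.truth_labels.labels,
                                          sb.truth_labels.labels)
        assert a.questionnaire.equals(b.questionnaire)

    def test_truth_metrics_match_metrics_module(self):
        cohort = CohortSpec(group_names=("g",), group_sizes=(2,), seed=1,
                            duration_multipliers={}, occurrence_multipliers={})
        spec = SimulationSpec(n_channels=8, duration_s=20.0)
        res = ms.simulate_cohort(cohort, spec, render_eeg=False)
        for subj in res.subjects:
            seq = subj.truth_labels
            truth = res.truth_metrics[res.truth_metrics.subject_id
                                      == subj.subject_id]
            for s in range(4):
                row = truth[truth.state == chr(ord("A") + s)].iloc[0]
                assert ms.duration_ms(seq, s) == pytest.approx(row.duration_ms)
                assert ms.coverage_pct(seq, s) == pytest.approx(row.coverage_pct)
                assert ms.occurrence_per_s(seq, s) == pytest.approx(
                    row.occurrence_per_s)
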