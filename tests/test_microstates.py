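import itertools

import numpy as np
import pytest

import ratstates as rs
from ratstates.microstates import UNASSIGNED, expected_transitions

FS = 250.0


def _rec(data, fs=FS):
    return rs.Recording(np.asarray(data, float), fs,
                        rs.generate_montage(np.asarray(data).shape[0]))


class TestGfp:
    def test_population_sd_of_pair(self):
        rec = _rec([[1.0], [-1.0]])
        assert rs.compute_gfp(rec, find_peaks=False).values[0] == 1.0

    def test_zero_map_gives_zero(self):
        rec = _rec([[0.0, 1.0], [0.0, -1.0], [0.0, 0.0]])
        g = rs.compute_gfp(rec, find_peaks=False)
        assert g.values[0] == 0.0

    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(size=(6, 50)))
        g1 = rs.compute_gfp(rec, find_peaks=False).values
        g3 = rs.compute_gfp(_rec(3 * rec.data), find_peaks=False).values
        assert np.allclose(g3, 3 * g1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rs.compute_gfp(_rec([[np.nan, 1.0], [0.0, 2.0]]))


class TestGfpPeaks:
    def test_monotone_has_no_peaks(self):
        assert rs.find_gfp_peaks(np.arange(10.0)).size == 0

    def test_simple_series(self):
        assert list(rs.find_gfp_peaks([0, 1, 0, 2, 0])) == [1, 3]

    def test_plateau_first_sample_wins(self):
        assert list(rs.find_gfp_peaks([0, 2, 2, 2, 0])) == [1]
        assert rs.find_gfp_peaks([2, 2, 1, 0, 0]).size == 0  # edge plateau

    def test_rectified_envelope_peak_count(self):
        # |sin(2*pi*10 t)| has 2 maxima per 10-Hz cycle: ~200 in 10 s
        t = np.arange(int(10 * FS)) / FS
        env = np.abs(np.sin(2 * np.pi * 10 * t))
        n = rs.find_gfp_peaks(env).size
        assert abs(n - 200) <= 2


class TestSpatialCorrelation:
    def test_self_and_negation(self):
        u = np.array([1.0, -2.0, 0.5, 0.5])
        assert rs.spatial_correlation(u, u) == pytest.approx(1.0)
        assert rs.spatial_correlation(u, -u) == pytest.approx(1.0)
        assert rs.spatial_correlation(u, -u, ignore_polarity=False) == \
            pytest.approx(-1.0)

    def test_orthogonal_construction(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=8)
        u -= u.mean()
        v = rng.normal(size=8)
        v -= v.mean()
        v -= (v @ u) / (u @ u) * u  # Gram-Schmidt
        assert rs.spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            rs.spatial_correlation(np.ones(5), np.arange(5.0))


def _enumerate_best_gev(x, k):
    """Oracle: exhaustive max over partitions into k non-empty clusters of
    the GEV with the dominant-component template rule."""
    p, c = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    denom = np.sum(x**2) / c  # sum of gfp^2 with gfp = ||x||/sqrt(C)

    def partitions(items, k):
        if k == 1:
            yield [list(items)]
            return
        if len(items) == k:
            yield [[i] for i in items]
            return
        head, rest = items[0], items[1:]
        for part in partitions(rest, k):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1:]
        for part in partitions(rest, k - 1):
            yield [[head]] + part

    best = -np.inf
    for part in partitions(list(range(p)), k):
        gev = 0.0
        for block in part:
            s = sum(np.outer(x[i], x[i]) / c for i in block)
            gev += np.linalg.eigvalsh(s)[-1]
        best = max(best, gev / denom)
    return best


class TestAahc:
    def test_single_cluster_of_sign_flipped_copies(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        base -= base.mean()
        signs = rng.choice([-1, 1], size=20)
        peaks = np.outer(signs, base) * rng.uniform(0.5, 2.0, 20)[:, None]
        model = rs.aahc_cluster(peaks, k_min=1, k_max=1)[1]
        assert rs.spatial_correlation(model.maps[0], base) == \
            pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_clusters_recovered(self):
        rng = np.random.default_rng(3)
        maps = rs.random_maps(2, 10, rng)
        amp = rng.uniform(1, 3, 100)
        labels = np.repeat([0, 1], 50)
        peaks = maps[labels] * amp[:, None]
        model = rs.aahc_cluster(peaks, k_min=2, k_max=2)[2]
        match = sorted(
            max(rs.spatial_correlation(m, p) for m in model.maps)
            for p in maps)
        assert all(r >= 0.999 for r in match)
        assert model.training_gev == pytest.approx(1.0, abs=1e-12)

    def test_polarity_invariance_of_clustering(self):
        rng = np.random.default_rng(4)
        peaks = rng.normal(size=(40, 8))
        flipped = peaks * rng.choice([-1.0, 1.0], size=40)[:, None]
        a = rs.aahc_cluster(peaks, k_min=3, k_max=3)[3]
        b = rs.aahc_cluster(flipped, k_min=3, k_max=3)[3]
        assert np.array_equal(a.training_assignments, b.training_assignments)
        assert np.allclose(np.abs(a.maps), np.abs(b.maps), atol=1e-9)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            rs.aahc_cluster(np.random.default_rng(0).normal(size=(5, 4)),
                            k_min=2, k_max=5)

    def test_training_gev_nondecreasing_in_k(self, rec5):
        models = rs.fit_recording(rec5, 10, k_min=1)
        gevs = [models[k].training_gev for k in sorted(models)]
        assert np.all(np.diff(gevs) >= -1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_enumeration_on_separated_data(self, k):
        # well-separated planted clusters of balanced total strength:
        # greedy attains the optimum (with unbalanced strengths the greedy
        # dissolves the weakest true cluster first — see the bound test)
        rng = np.random.default_rng(5)
        maps = rs.random_maps(k, 6, rng)
        labels = np.arange(12) % k
        peaks = 1.5 * maps[labels] + 0.02 * rng.normal(size=(12, 6))
        model = rs.aahc_cluster(peaks, k_min=k, k_max=k)[k]
        best = _enumerate_best_gev(peaks, k)
        assert model.training_gev <= best + 1e-9
        assert model.training_gev == pytest.approx(best, abs=1e-9)

    def test_never_exceeds_exhaustive_optimum_on_random_data(self):
        rng = np.random.default_rng(6)
        peaks = rng.normal(size=(10, 6))
        for k in (2, 3):
            model = rs.aahc_cluster(peaks, k_min=k, k_max=k)[k]
            best = _enumerate_best_gev(peaks, k)
            assert model.training_gev <= best + 1e-9


class TestBackfit:
    def test_exact_and_negated_match(self, model5, rec5):
        data = np.column_stack([model5.maps[3], -model5.maps[3]]) * 5
        rec = rs.Recording(data, FS, rec5.montage)
        seq = rs.backfit(rec, model5)
        assert list(seq.labels) == [3, 3]
        assert seq.correlations[0] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recording_labels_at_peaks(self, noiseless_rec):
        truth, labels, rec = noiseless_rec
        model = rs.MicrostateModel(truth.maps, training_gev=1.0)
        seq = rs.backfit(rec, model)
        peaks = rs.compute_gfp(rec).peak_indices
        assert np.array_equal(seq.labels[peaks], labels[peaks])

    def test_zero_gfp_samples_unassigned(self, model5):
        data = np.zeros((19, 3))
        data[:, 1] = model5.maps[0]
        seq = rs.backfit(rs.Recording(data, FS, rs.generate_montage(19)),
                         model5)
        assert seq.labels[0] == UNASSIGNED and seq.labels[2] == UNASSIGNED
        assert seq.labels[1] == 0


class TestGev:
    def test_perfect_fit_gives_one(self, noiseless_rec):
        truth, _, rec = noiseless_rec
        single = rs.MicrostateModel(truth.maps[:1], training_gev=1.0)
        data = truth.maps[0][:, None] * np.abs(np.sin(np.arange(500) / 10))
        rec1 = rs.Recording(data, FS, rec.montage)
        seq = rs.backfit(rec1, single)
        _, tot = rs.compute_gev(rec1, single, seq)
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_assignment_gives_zero(self):
        rng = np.random.default_rng(7)
        maps = rs.random_maps(3, 10, rng)
        env = np.abs(np.sin(np.arange(400) / 7)) + 0.1
        rec = rs.Recording(maps[0][:, None] * env, FS,
                           rs.generate_montage(10))
        # force labels onto maps orthogonal to every sample
        seq = rs.LabelSequence(np.full(400, 1), np.zeros(400), 3)
        model = rs.MicrostateModel(maps, training_gev=1.0)
        gev_k, tot = rs.compute_gev(rec, model, seq)
        assert tot == pytest.approx(0.0, abs=1e-12)

    def test_structured_beats_noise(self, rec5, model5):
        seq = rs.backfit(rec5, model5)
        _, tot_structured = rs.compute_gev(rec5, model5, seq)
        rng = np.random.default_rng(8)
        noise = rs.Recording(rng.normal(size=(19, 5000)), FS, rec5.montage)
        noise_model = rs.fit_recording(noise, 5)[5]
        nseq = rs.backfit(noise, noise_model)
        _, tot_noise = rs.compute_gev(noise, noise_model, nseq)
        assert tot_structured - tot_noise >= 0.2

    def test_totgev_is_sum_of_classes(self, rec5, model5):
        seq = rs.backfit(rec5, model5)
        gev_k, tot = rs.compute_gev(rec5, model5, seq)
        assert tot == pytest.approx(gev_k.sum(), abs=0)
        assert 0 <= tot <= 1


def _oracle_parameters(labels, fs, k):
    """Brute-force run-length oracle with the halfway-boundary convention
    (an L-sample run spans L/fs seconds; recording edges sit half a sample
    outside the first/last sample)."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] != UNASSIGNED:
            runs.append((labels[i], (j - i) / fs))
        i = j
    assigned = sum(1 for l in labels if l != UNASSIGNED)
    total = assigned / fs
    out = {}
    for cls in range(k):
        durs = [d for c, d in runs if c == cls]
        out[cls] = {
            "duration": float(np.mean(durs)) if durs else 0.0,
            "occurrence": len(durs) / total,
            "coverage": sum(durs) / total,
        }
    return out


class TestParameters:
    def test_two_runs_hand_case(self):
        seq = rs.LabelSequence(np.array([0, 0, 0, 1, 1, 1]), np.ones(6), 2)
        gfp = rs.GfpSeries(np.ones(6), np.array([], dtype=int))
        st = rs.microstate_parameters(seq, gfp, FS)
        assert np.allclose(st.duration_s, [3 / 250, 3 / 250])
        assert np.allclose(st.duration_ms, [12.0, 12.0])
        assert np.allclose(st.coverage, [0.5, 0.5])

    def test_single_class_degenerate(self):
        seq = rs.LabelSequence(np.zeros(100, dtype=int), np.ones(100), 1)
        gfp = rs.GfpSeries(np.ones(100), np.array([], dtype=int))
        st = rs.microstate_parameters(seq, gfp, FS)
        assert st.coverage[0] == 1.0
        assert st.occurrence[0] == pytest.approx(1 / (100 / FS))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(-1, 4, size=200)
        if np.all(labels == UNASSIGNED):
            labels[0] = 0
        seq = rs.LabelSequence(labels, np.ones(200), 4)
        gfp = rs.GfpSeries(np.abs(rng.normal(size=200)) + 0.1,
                           np.array([], dtype=int))
        st = rs.microstate_parameters(seq, gfp, FS)
        oracle = _oracle_parameters(list(labels), FS, 4)
        for cls in range(4):
            assert st.duration_s[cls] == pytest.approx(oracle[cls]["duration"])
            assert st.occurrence[cls] == pytest.approx(oracle[cls]["occurrence"])
            assert st.coverage[cls] == pytest.approx(oracle[cls]["coverage"])
        assert st.coverage.sum() == pytest.approx(1.0, abs=1e-9)

    def test_conservation_identities(self, rec5, model5):
        seq = rs.backfit(rec5, model5)
        gfp = rs.compute_gfp(rec5)
        st = rs.microstate_parameters(seq, gfp, FS)
        assert st.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(st.coverage, st.occurrence * st.duration_s,
                           atol=1 / FS)

    def test_empty_labels_rejected(self):
        seq = rs.LabelSequence(np.full(10, UNASSIGNED), np.zeros(10), 3)
        gfp = rs.GfpSeries(np.ones(10), np.array([], dtype=int))
        with pytest.raises(ValueError):
            rs.microstate_parameters(seq, gfp, FS)


class TestTransitions:
    def test_expected_hand_case(self):
        # Occ = (2, 4, 6), MeanOcc = 4: ExpTM(0,1) = (0.5*1)/(1-0.5) = 1.0
        exp = expected_transitions(np.array([2.0, 4.0, 6.0]))
        assert exp[0, 1] == pytest.approx(1.0, abs=0)

    def test_absent_class_row_is_zero(self):
        exp = expected_transitions(np.array([0.0, 4.0, 6.0]))
        assert np.all(exp[0] == 0)

    def test_degenerate_occurrence_warns_inf(self):
        with pytest.warns(RuntimeWarning):
            exp = expected_transitions(np.array([4.0, 4.0, 4.0]))
        assert np.all(np.isinf(exp))

    def test_alternating_runs(self):
        labels = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        seq = rs.LabelSequence(labels, np.ones(8), 2)
        ta = rs.transition_analysis(seq, FS)
        assert ta.observed[0, 1] == 1.0
        assert ta.observed[1, 0] == 1.0
        assert np.all(np.diag(ta.observed) == 0)

    def test_difference_uses_normalized_expected(self, rec5, model5):
        seq = rs.backfit(rec5, model5)
        ta = rs.transition_analysis(seq, FS)
        finite_rows = np.all(np.isfinite(ta.expected_normalized), axis=1)
        sums = ta.expected_normalized[finite_rows].sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)
        assert np.allclose(
            ta.difference[finite_rows],
            ta.observed[finite_rows] - ta.expected_normalized[finite_rows])

    def test_single_run_rejected(self):
        seq = rs.LabelSequence(np.zeros(10, dtype=int), np.ones(10), 2)
        with pytest.raises(ValueError):
            rs.transition_analysis(seq, FS)
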