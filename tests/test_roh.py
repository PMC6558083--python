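"""Viterbi decoding, seed/extend ROH calling and F_ROH arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mosaicf as mf
from conftest import (chain_distances, emission_table, enum_viterbi,
                      random_small_instance)
from mosaicf.hmm import HBDPosterior


def path_log_prob(path, emis, dists, rates, pi):
    from conftest import dense_transition
    logp = np.log(pi[path[0]]) + np.log(emis[0, path[0]])
    for t, d in enumerate(dists):
        T = dense_transition(d, rates, pi)
        logp += np.log(T[path[t], path[t + 1]]) + np.log(emis[t + 1, path[t + 1]])
    return logp


def make_posterior_map(total_hbd, bp=None):
    """Single-chromosome posterior with given total-HBD probabilities."""
    total_hbd = np.asarray(total_hbd, dtype=float)
    m = total_hbd.size
    bp = np.arange(m) * 100_000 if bp is None else np.asarray(bp)
    mm = mf.MarkerMap(np.array(["chr1"] * m, dtype=object),
                      np.array([f"m{j}" for j in range(m)], dtype=object),
                      bp, bp / 1e6)
    gamma = np.zeros((m, 2))
    gamma[:, 0] = total_hbd
    gamma[:, 1] = 1.0 - total_hbd
    path = np.where(total_hbd > 0.5, 0, 1)
    return HBDPosterior(gamma, 0.0), path, mm


class TestViterbi:
    @pytest.mark.parametrize("seed", range(6))
    def test_path_matches_exhaustive_search(self, seed):
        config, mm, freqs, genotypes = random_small_instance(seed)
        rng = np.random.default_rng(seed + 200)
        pi = rng.dirichlet(np.ones(3))
        got = mf.viterbi_decode(genotypes, mm, freqs, config, pi)
        emis = emission_table(genotypes, freqs, config)
        want, _ = enum_viterbi(emis, chain_distances(mm, config),
                               config.rates, pi)
        np.testing.assert_array_equal(got, want)

    def test_all_missing_chain_decodes_constant_map_path(self):
        config, mm, freqs, genotypes = random_small_instance(3)
        genotypes[:] = -1
        pi = np.array([0.25, 0.3, 0.45])
        got = mf.viterbi_decode(genotypes, mm, freqs, config, pi)
        assert len(set(got.tolist())) == 1          # no observation: one segment
        emis = emission_table(genotypes, freqs, config)
        want, _ = enum_viterbi(emis, chain_distances(mm, config),
                               config.rates, pi)
        np.testing.assert_array_equal(got, want)

    @pytest.mark.parametrize("seed", range(3))
    def test_path_beats_random_paths(self, seed):
        config, mm, freqs, genotypes = random_small_instance(seed, n_markers=8)
        rng = np.random.default_rng(seed + 300)
        pi = rng.dirichlet(np.ones(3))
        path = mf.viterbi_decode(genotypes, mm, freqs, config, pi)
        emis = emission_table(genotypes, freqs, config)
        dists = chain_distances(mm, config)
        best = path_log_prob(path, emis, dists, config.rates, pi)
        for _ in range(1000):
            rand = rng.integers(0, 3, size=8)
            assert best >= path_log_prob(rand, emis, dists, config.rates, pi) \
                - 1e-9


class TestSeedExtend:
    def test_hand_applied_rule(self):
        post, path, mm = make_posterior_map([0.50, 0.992, 0.9995, 0.995, 0.80])
        segs = mf.call_roh_segments(post, path, mm)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start == mm.bp[1] and seg.end == mm.bp[3] + 1
        assert seg.n_markers == 3

    def test_no_seed_means_no_segment(self):
        post, path, mm = make_posterior_map([0.995] * 6)
        assert mf.call_roh_segments(post, path, mm) == []

    def test_saturated_posterior_spans_whole_chromosome(self):
        post, path, mm = make_posterior_map([1.0] * 6)
        segs = mf.call_roh_segments(post, path, mm)
        assert len(segs) == 1
        assert segs[0].start == mm.bp[0] and segs[0].end == mm.bp[-1] + 1

    def test_viterbi_mode_takes_hbd_runs(self):
        post, _, mm = make_posterior_map([0.9] * 6)
        path = np.array([1, 0, 0, 1, 0, 1])
        segs = mf.call_roh_segments(post, path, mm, mode="viterbi")
        assert [(s.n_markers,) for s in segs] == [(2,), (1,)]

    def test_modal_viterbi_class_assigned(self):
        post, _, mm = make_posterior_map([1.0] * 5)
        path = np.array([0, 1, 1, 0, 0])
        K = 2  # two HBD classes in the fake path, non-HBD would be 2
        gamma = np.zeros((5, 3))
        gamma[:, 0] = 1.0
        segs = mf.call_roh_segments(HBDPosterior(gamma, 0.0), path, mm)
        assert len(segs) == 1 and segs[0].class_index == 0   # 3 vs 2 markers

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.choice([0.2, 0.985, 0.992, 0.996, 0.9995, 1.0], size=30)
        post, path, mm = make_posterior_map(probs)
        base = mf.call_roh_segments(post, path, mm, seed_prob=0.999,
                                    extend_prob=0.99)
        tighter_ext = mf.call_roh_segments(post, path, mm, seed_prob=0.999,
                                           extend_prob=0.995)
        tighter_seed = mf.call_roh_segments(post, path, mm, seed_prob=0.9999,
                                            extend_prob=0.99)
        # raising extend_prob never lengthens any segment
        assert sum(s.length for s in tighter_ext) <= \
            sum(s.length for s in base)
        # raising seed_prob never increases the segment count
        assert len(tighter_seed) <= len(base)


class TestFroh:
    def _map_100mb(self):
        bp = np.concatenate([[0], np.arange(1, 999) * 100_000, [99_999_999]])
        return mf.MarkerMap(np.array(["chr1"] * 1000, dtype=object),
                            np.array([f"m{j}" for j in range(1000)],
                                     dtype=object), bp, bp / 1e6)

    def test_no_segments_zero(self):
        assert mf.roh_inbreeding([], self._map_100mb()) == 0.0

    def test_single_segment_ratio(self):
        mm = self._map_100mb()
        seg = mf.ROHSegment("i", "chr1", 10_000_000, 15_000_000, 50, 0)
        assert mf.roh_inbreeding([seg], mm) == pytest.approx(0.05)

    def test_length_threshold_split(self):
        mm = self._map_100mb()
        segs = [mf.ROHSegment("i", "chr1", 0, 1_500_000, 15, 0),
                mf.ROHSegment("i", "chr1", 50_000_000, 53_000_000, 30, 0)]
        assert mf.roh_inbreeding(segs, mm, 0) == pytest.approx(0.045)
        assert mf.roh_inbreeding(segs, mm, 2_000_000) == pytest.approx(0.03)
        inb = mf.compute_roh_inbreeding(segs, mm, "i")
        assert inb.f_roh == pytest.approx(0.045)
        assert inb.f_roh_2mb == pytest.approx(0.03)

    def test_strictly_longer_than_cutoff(self):
        mm = self._map_100mb()
        seg = mf.ROHSegment("i", "chr1", 0, 2_000_000, 20, 0)
        assert mf.roh_inbreeding([seg], mm, 2_000_000) == 0.0

    def test_empty_map_rejected(self):
        mm = self._map_100mb()
        with pytest.raises(ValueError):
            mf.roh_inbreeding([], mf.MarkerMap(
                np.array([], dtype=object), np.array([], dtype=object),
                np.array([], dtype=np.int64), np.array([])))

    def test_invariant_to_chromosome_order(self):
        bp = np.arange(100) * 1_000_000
        def mm(order):
            chroms = np.array(sum(([c] * 50 for c in order), []), dtype=object)
            ids = np.array([f"{c}_{j}" for c in order for j in range(50)],
                           dtype=object)
            b = np.concatenate([bp[:50]] * 2)
            return mf.MarkerMap(chroms, ids, b, b / 1e6)
        segs = [mf.ROHSegment("i", "chr2", 0, 5_000_000, 5, 0)]
        f1 = mf.roh_inbreeding(segs, mm(["chr1", "chr2"]))
        f2 = mf.roh_inbreeding(segs, mm(["chr2", "chr1"]))
        assert f1 == f2


class TestLengthDistribution:
    def test_single_short_segment(self):
        segs = [mf.ROHSegment("a", "chr1", 0, 500_000, 5, 0)]
        dist = mf.roh_length_distribution(segs, {"a": "BR1"})
        assert dist.loc["BR1", "<1Mb"] == 1.0

    def test_proportions_sum_to_one_and_empty_breed_flagged(self):
        segs = [mf.ROHSegment("a", "chr1", 0, 1_500_000, 5, 0),
                mf.ROHSegment("a", "chr1", 5_000_000, 14_000_000, 50, 0),
                mf.ROHSegment("b", "chr1", 0, 3_000_000, 9, 0)]
        labels = {"a": "BR1", "b": "BR1", "c": "BR2"}
        dist = mf.roh_length_distribution(segs, labels)
        assert dist.loc["BR1"].sum() == pytest.approx(1.0)
        assert dist.loc["BR2"].isna().all()


def segment_recovery_stats(ds, segments_by_ind):
    """Recall of truth HBD segments >= 2 Mb and per-boundary errors in
    marker intervals (shared with the acceptance checks)."""
    recovered, total, errors = 0, 0, []
    for iid, tind in zip(ds.individuals, ds.truth.individuals):
        segs = segments_by_ind[iid]
        for t in tind.hbd_segments(ds.truth.nonhbd_index):
            if t.end - t.start < 2_000_000:
                continue
            t_idx = ds.intensity.marker_indices_in(t.chrom, t.start, t.end)
            if t_idx.size == 0:
                continue
            total += 1
            best = None
            for s in segs:
                if s.chrom != t.chrom or s.end <= t.start or s.start >= t.end:
                    continue
                s_idx = ds.intensity.marker_indices_in(s.chrom, s.start, s.end)
                pair = (abs(int(s_idx[0]) - int(t_idx[0])),
                        abs(int(s_idx[-1]) - int(t_idx[-1])))
                if best is None or sum(pair) < sum(best):
                    best = pair
            if best is not None:
                recovered += 1
                errors.extend(best)
    return recovered, total, np.asarray(errors)


def test_segment_recovery_on_simulated_truth(small_cohort):
    """Viterbi-decoded segments recover >=2 Mb truth HBD segments with
    change points a couple of marker intervals from truth on average."""
    ds = small_cohort
    gds = ds.to_genotype_dataset()
    res = mf.run_pipeline(gds, mf.HBDModelConfig(), roh_mode="viterbi")
    recovered, total, errors = segment_recovery_stats(ds, res.segments)
    assert total >= 10
    assert recovered / total >= 0.9
    assert errors.mean() <= 2.0
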