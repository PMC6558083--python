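"""Synthetic-cohort generator: statistical structure and serialization."""

import filecmp
import os

import numpy as np
import pytest

import mosaicf as mf
from mosaicf import io
from mosaicf.simulate import _marker_classes


def _cfg(**kw):
    base = dict(n_individuals=1, chromosomes=[("chr1", 100_000_000)],
                marker_density=0.5, seed=5)
    base.update(kw)
    return mf.SimulationConfig(**base)


class TestMarkerMap:
    def test_count_and_order(self):
        mm = mf.simulate_marker_map(_cfg())
        assert mm.n_markers == 50                      # 100 Mb x 0.5 per Mb
        assert np.all(np.diff(mm.bp) > 0)

    def test_genetic_position_unit_conversion(self):
        mm = mf.simulate_marker_map(_cfg(marker_density=2.0))
        # 1 cM/Mb: a marker at 10 Mb sits at 0.10 Morgan
        np.testing.assert_allclose(mm.morgans(), (mm.bp + 1) / 1e8)

    def test_determinism_and_seed_sensitivity(self):
        a = mf.simulate_marker_map(_cfg())
        b = mf.simulate_marker_map(_cfg())
        c = mf.simulate_marker_map(_cfg(seed=6))
        assert np.array_equal(a.bp, b.bp) and np.array_equal(a.freq, b.freq)
        assert not np.array_equal(a.freq, c.freq)

    def test_frequencies_truncated(self):
        mm = mf.simulate_marker_map(_cfg(
            allele_freq_law=lambda rng, n: rng.uniform(-1, 2, n)))
        assert mm.freq.min() >= 0.01 and mm.freq.max() <= 0.99

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="non-positive length"):
            _cfg(chromosomes=[("chr1", 0)])


class TestMosaic:
    def test_pure_nonhbd_has_zero_autozygosity(self):
        cfg = _cfg(class_rates=(4.0, 2048.0), mixing_proportions=(0.0, 1.0))
        truth = mf.simulate_hbd_mosaic(cfg)
        assert truth.realized()[0] == 0.0
        assert all(not t.hbd_segments(1) for t in truth.individuals)

    def test_segment_length_matches_exponential_mean(self):
        # all mass on R=4 on a 10,000-Morgan chromosome: untruncated
        # segment lengths average 1/4 Morgan = 25 Mb at 1 cM/Mb
        cfg = _cfg(chromosomes=[("chr1", int(1e12))],
                   class_rates=(4.0, 2048.0), mixing_proportions=(1.0, 0.0))
        truth = mf.simulate_hbd_mosaic(cfg)
        lengths = np.array([s.end - s.start
                            for s in truth.individuals[0].segments[:-1]])
        assert lengths.size > 10_000
        assert abs(lengths.mean() - 25e6) < 0.5e6      # ~4 se

    def test_longrun_hbd_fraction_matches_renewal_expectation(self):
        cfg = _cfg(chromosomes=[("chr1", int(1e12))],
                   class_rates=(4.0, 2048.0), mixing_proportions=(0.5, 0.5))
        expected = mf.expected_autozygosity(cfg.class_rates,
                                            cfg.mixing_proportions)
        assert abs(expected - (0.5 / 4) / (0.5 / 4 + 0.5 / 2048)) < 1e-12
        truth = mf.simulate_hbd_mosaic(cfg)
        assert abs(truth.realized()[0] - expected) < 0.005

    def test_tiling_covers_genome_exactly_once(self):
        cfg = _cfg(chromosomes=[("chr1", 50_000_000), ("chr2", 30_000_000)],
                   n_individuals=3)
        truth = mf.simulate_hbd_mosaic(cfg)
        for tind in truth.individuals:
            for chrom, length in cfg.chromosomes:
                segs = [s for s in tind.segments if s.chrom == chrom]
                assert segs[0].start == 0 and segs[-1].end == length
                for a, b in zip(segs[:-1], segs[1:]):
                    assert a.end == b.start


class TestGenotypes:
    def test_no_heterozygotes_in_hbd_without_error(self):
        cfg = _cfg(chromosomes=[("chr1", int(1e11))], marker_density=1.0,
                   class_rates=(4.0, 2048.0), mixing_proportions=(1.0, 0.0),
                   genotype_error=0.0)
        mm = mf.simulate_marker_map(cfg)
        truth = mf.simulate_hbd_mosaic(cfg)
        geno = mf.emit_genotypes(truth, mm, cfg)
        assert not np.any(geno == 1)

    def test_hardy_weinberg_heterozygosity_outside_hbd(self):
        cfg = _cfg(chromosomes=[("chr1", int(1e11))], marker_density=1.0,
                   class_rates=(4.0, 2048.0), mixing_proportions=(0.0, 1.0),
                   allele_freq_law=lambda rng, n: np.full(n, 0.5))
        mm = mf.simulate_marker_map(cfg)
        truth = mf.simulate_hbd_mosaic(cfg)
        geno = mf.emit_genotypes(truth, mm, cfg)
        het = (geno == 1).mean()
        assert abs(het - 0.5) < 0.01                   # 2pq at p = q

    def test_error_rate_sets_hbd_heterozygote_count(self):
        # 100,000 HBD markers at p=0.5, e=0.001: E[hets] = e*2pq*N = 50
        cfg = _cfg(chromosomes=[("chr1", int(1e12))], marker_density=0.1,
                   class_rates=(4.0, 2048.0), mixing_proportions=(1.0, 0.0),
                   genotype_error=0.001,
                   allele_freq_law=lambda rng, n: np.full(n, 0.5))
        mm = mf.simulate_marker_map(cfg)
        assert mm.n_markers == 100_000
        truth = mf.simulate_hbd_mosaic(cfg)
        geno = mf.emit_genotypes(truth, mm, cfg)
        hets = int((geno == 1).sum())
        assert 20 <= hets <= 90                        # 50 +- ~4 sd

    def test_missing_rate_injection(self):
        cfg = _cfg(missing_rate=0.1, marker_density=10.0)
        ds = mf.simulate_dataset(cfg)
        frac = (ds.genotypes == io.MISSING).mean()
        assert 0.05 < frac < 0.15


class TestDeletions:
    def _deleted_cfg(self, **kw):
        spec = mf.DeletionSpec(count_per_individual=3, length_min_bp=500_000,
                               length_max_bp=500_000, **kw)
        return _cfg(n_individuals=10, marker_density=25.0,
                    chromosomes=[(f"chr{i}", 50_000_000) for i in range(1, 5)],
                    class_rates=(4.0, 2048.0), mixing_proportions=(0.0, 1.0),
                    deletion_spec=spec)

    def test_deletions_force_apparent_homozygosity(self):
        ds = mf.simulate_dataset(self._deleted_cfg())
        n_checked = 0
        for i, tind in enumerate(ds.truth.individuals):
            for chrom, start, end in tind.deletions:
                idx = ds.intensity.marker_indices_in(chrom, start, end)
                assert not np.any(ds.genotypes[i, idx] == 1)
                n_checked += len(idx)
        assert n_checked > 100

    def test_deletion_lrr_depressed_and_baf_polarised(self):
        ds = mf.simulate_dataset(self._deleted_cfg())
        for i, tind in enumerate(ds.truth.individuals):
            for chrom, start, end in tind.deletions:
                idx = ds.intensity.marker_indices_in(chrom, start, end)
                if len(idx) >= 10:
                    assert ds.intensity.lrr[i, idx].mean() < -0.3
                    baf = ds.intensity.baf[i, idx]
                    assert np.all((baf < 0.25) | (baf > 0.75))

    def test_cnv_calls_match_injected_deletions(self):
        ds = mf.simulate_dataset(self._deleted_cfg())
        assert len(ds.cnv_calls) == 30
        assert all(c.cn == 1 for c in ds.cnv_calls)

    def test_no_deletions_null_case(self):
        ds = mf.simulate_dataset(_cfg(marker_density=10.0))
        assert ds.cnv_calls == []
        assert abs(ds.intensity.lrr.mean()) < 0.02

    def test_oversized_deletion_rejected(self):
        spec = mf.DeletionSpec(count_per_individual=1,
                               length_min_bp=10**9, length_max_bp=10**9)
        cfg = _cfg(deletion_spec=spec)
        ds = mf.simulate_marker_map(cfg)
        truth = mf.simulate_hbd_mosaic(cfg)
        geno = mf.emit_genotypes(truth, ds, cfg)
        with pytest.raises(ValueError, match="exceeds every chromosome"):
            mf.inject_hemizygous_deletions(geno, truth, ds, cfg)


class TestSerialization:
    def test_write_is_byte_deterministic(self, tmp_path):
        cfg = _cfg(n_individuals=3, marker_density=2.0)
        for d in ("a", "b"):
            mf.write_dataset(mf.simulate_dataset(cfg), tmp_path / d)
        for name in os.listdir(tmp_path / "a"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_round_trip_through_loader(self, tmp_path):
        cfg = _cfg(n_individuals=4, marker_density=2.0, missing_rate=0.05)
        ds = mf.simulate_dataset(cfg)
        paths = mf.write_dataset(ds, tmp_path)
        loaded = mf.load_genotype_data(paths["ped"], paths["map"])
        assert np.array_equal(loaded.calls, ds.genotypes)
        assert np.array_equal(loaded.markers.bp, ds.markers.bp)
        assert loaded.individuals == ds.individuals

    def test_truth_bed_is_half_open_and_valid(self, tmp_path):
        rates = (4.0, 2048.0)
        cfg = _cfg(n_individuals=3, marker_density=2.0, class_rates=rates,
                   mixing_proportions=tuple(
                       mf.mixing_for_autozygosity(0.2, rates)))
        ds = mf.simulate_dataset(cfg)
        paths = mf.write_dataset(ds, tmp_path)
        with open(paths["truth_hbd"]) as fh:
            lines = [l.rstrip("\n").split("\t") for l in fh]
        assert lines
        for row in lines:
            start, end = int(row[1]), int(row[2])
            assert 0 <= start < end <= 100_000_000

    def test_manifest_echoes_seed(self, tmp_path):
        import json
        cfg = _cfg(n_individuals=2, marker_density=1.0, seed=77)
        paths = mf.write_dataset(mf.simulate_dataset(cfg), tmp_path)
        with open(paths["manifest"]) as fh:
            manifest = json.load(fh)
        assert manifest["seed"] == 77
        assert manifest["config"]["seed"] == 77


def test_marker_classes_require_full_tiling(toy_map):
    truth = mf.simulate_hbd_mosaic(_cfg(chromosomes=[("chr1", 100_000_000)]))
    # corrupt the tiling: drop the final segment
    bounds, classes = truth.individuals[0].tiling["chr1"]
    truth.individuals[0].tiling["chr1"] = (bounds[:-1], classes[:-1])
    with pytest.raises(RuntimeError, match="does not cover"):
        _marker_classes(truth.individuals[0], toy_map)
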