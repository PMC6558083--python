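"""Simulation-based validation experiments.

Each experiment generates a cohort with known truth under the model's own
assumptions, runs the full estimation chain, and measures how well the
truth is recovered.  They are used by the test suite and by
``scripts/acceptance.py``; all randomness flows from the ``seed``
argument.

Problem sizes are chosen to mirror a 50k-chip livestock cohort at desk
scale: 30 chromosomes of 100 Mb at 10 markers/Mb for the inbreeding-
recovery experiment (30,000 markers), and denser 25 markers/Mb genomes
for the segment-boundary and copy-loss experiments, where local
resolution is what is being measured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import LossRegion, classify_copy_loss
from .hmm import HBDModelConfig, fit_cohort
from .pipeline import run_pipeline
from .simulate import (DeletionSpec, SimulationConfig, mixing_for_autozygosity,
                       simulate_dataset)

__all__ = ["fg_recovery_experiment", "segment_recovery_stats",
           "segment_recovery_experiment", "copy_loss_flag_sensitivity",
           "copy_loss_correction_experiment"]

_RATES = (4.0, 2048.0)   # recent HBD class + non-HBD background


def fg_recovery_experiment(seed: int,
                           strata=(0.0, 0.05, 0.10, 0.25),
                           n_per_stratum=(13, 13, 12, 12),
                           config: HBDModelConfig | None = None) -> pd.DataFrame:
    """Estimate F_G for cohorts simulated at several autozygosity levels.

    Each stratum is a cohort whose expected HBD genome fraction is the
    stratum value, with the autozygous mass in the recent R=4 class; the
    estimator is the default 12-class model.  Returns one row per
    individual: stratum, realized truth and estimated F_G.
    """
    config = config or HBDModelConfig()
    rows = []
    for s, (f, n) in enumerate(zip(strata, n_per_stratum)):
        cfg = SimulationConfig(
            n_individuals=n,
            chromosomes=[(f"chr{i}", 100_000_000) for i in range(1, 31)],
            marker_density=10.0,
            class_rates=_RATES,
            mixing_proportions=tuple(mixing_for_autozygosity(f, _RATES)),
            seed=seed * 101 + s,
        )
        ds = simulate_dataset(cfg)
        fit = fit_cohort(ds.to_genotype_dataset(), config,
                         freqs=ds.markers.freq, store_posteriors=False)
        for iid, truth, fg in zip(ds.individuals, ds.truth.realized(),
                                  fit.f_g()):
            rows.append({"stratum": f, "individual": iid,
                         "truth": float(truth), "f_g": float(fg)})
    return pd.DataFrame(rows)


def segment_recovery_stats(ds, segments_by_ind):
    """Recall of truth HBD segments >= 2 Mb and the per-boundary errors,
    in marker intervals, of the matched called segments."""
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
    return recovered, total, np.asarray(errors, dtype=float)


def segment_recovery_experiment(seed: int, n_individuals: int = 5):
    """Recovery of >=2 Mb HBD segments by Viterbi decoding at 25
    markers/Mb.  Returns (recall, mean boundary error, n truth segments)."""
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        chromosomes=[(f"chr{i}", 50_000_000) for i in range(1, 9)],
        marker_density=25.0,
        class_rates=_RATES,
        mixing_proportions=tuple(mixing_for_autozygosity(0.2, _RATES)),
        seed=seed * 103 + 1,
    )
    ds = simulate_dataset(cfg)
    res = run_pipeline(ds.to_genotype_dataset(), HBDModelConfig(),
                       roh_mode="viterbi")
    recovered, total, errors = segment_recovery_stats(ds, res.segments)
    recall = recovered / total if total else float("nan")
    return recall, float(errors.mean()) if errors.size else float("nan"), total


def copy_loss_flag_sensitivity(seed: int, n_regions: int = 1000):
    """Fraction of injected hemizygous deletions (>=10 markers, LRR shift
    -0.55) whose mean LRR falls below -0.3.  Classification only — the
    regions are taken from truth, isolating the LRR discriminant."""
    spec = DeletionSpec(count_per_individual=12, length_min_bp=500_000,
                        length_max_bp=500_000)
    # ~20% of 500 kb deletions carry fewer than 10 markers at 25/Mb, so
    # oversample individuals to reach n_regions classifiable ones
    cfg = SimulationConfig(
        n_individuals=int(np.ceil(1.6 * n_regions / spec.count_per_individual)),
        chromosomes=[(f"chr{i}", 50_000_000) for i in range(1, 5)],
        marker_density=25.0,
        class_rates=_RATES, mixing_proportions=(0.0, 1.0),
        deletion_spec=spec, seed=seed * 107 + 2,
    )
    ds = simulate_dataset(cfg)
    flags, total = 0, 0
    for iid, tind in zip(ds.individuals, ds.truth.individuals):
        for chrom, start, end in tind.deletions:
            region = LossRegion(iid, chrom, start, end, "truth", "truth",
                                end - start)
            out = classify_copy_loss(region, ds.intensity)
            if out.n_markers >= 10:
                total += 1
                flags += bool(out.flagged)
            if total >= n_regions:
                break
        if total >= n_regions:
            break
    return flags / total, total


def copy_loss_correction_experiment(seed: int, n_individuals: int = 12):
    """Full-chain correction efficacy.

    A cohort with realized autozygosity ~0.1 receives 2.5 Mb hemizygous
    deletions in its non-HBD genome; at 25 markers/Mb such regions carry
    enough apparently homozygous markers for the HMM to call them as ROH
    with high confidence, so they masquerade as autozygosity and inflate
    raw F_ROH.  Returns a dict with the mean absolute error of raw and
    adjusted F_ROH against realized truth, plus the fraction of
    individuals with exactly zero adjustment in a deletion-free cohort of
    the same design (specificity).
    """
    spec = DeletionSpec(count_per_individual=3, length_min_bp=2_500_000,
                        length_max_bp=2_500_000)
    base = dict(
        n_individuals=n_individuals,
        chromosomes=[(f"chr{i}", 50_000_000) for i in range(1, 11)],
        marker_density=25.0,
        class_rates=_RATES,
        mixing_proportions=tuple(mixing_for_autozygosity(0.10, _RATES)),
    )
    cfg = SimulationConfig(**base, deletion_spec=spec, seed=seed * 109 + 3)
    ds = simulate_dataset(cfg)
    res = run_pipeline(ds.to_genotype_dataset(), HBDModelConfig(),
                       intensity=ds.intensity, cnv_calls=ds.cnv_calls)
    truth = ds.truth.realized()
    raw = res.metrics["F_ROH_raw"].to_numpy()
    adj = res.metrics["F_ROH"].to_numpy()
    out = {
        "froh_mae_raw": float(np.mean(np.abs(raw - truth))),
        "froh_mae_adjusted": float(np.mean(np.abs(adj - truth))),
        "n_with_deletions": n_individuals,
    }
    clean_cfg = SimulationConfig(**base, seed=seed * 109 + 4)
    clean = simulate_dataset(clean_cfg)
    clean_res = run_pipeline(clean.to_genotype_dataset(), HBDModelConfig(),
                             intensity=clean.intensity,
                             cnv_calls=clean.cnv_calls)
    untouched = (clean_res.metrics["flagged_length_bp"] == 0).mean()
    out["zero_adjustment_fraction"] = float(untouched)
    return out
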