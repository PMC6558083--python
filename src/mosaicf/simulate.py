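"""Synthetic cohorts with the exact statistical structure the HBD model
assumes.

Each diploid genome is tiled left to right as a renewal mosaic: segment
classes are drawn from the mixing proportions and lengths are exponential
with mean 1/R_k Morgans (converted to bp through the map scaling, default
1 cM/Mb).  Genotypes are emitted from population allele frequencies with
a genotyping error rate, Hardy-Weinberg outside HBD segments and
forced-homozygous (up to error) inside them.  Hemizygous deletions are
injected on top: genotypes inside a deletion collapse to homozygous for
the retained allele, the log R ratio shifts down, and matching
copy-number-1 CNV calls are emitted — the confound the copy-loss
correction exists to undo.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import io
from .cnv import CNVCall
from .intensity import IntensityMatrix
from .markers import MarkerMap

__all__ = [
    "DeletionSpec", "SimulationConfig", "TruthSegment", "IndividualTruth",
    "TruthTable", "SimulatedDataset", "simulate_marker_map",
    "simulate_hbd_mosaic", "emit_genotypes", "inject_hemizygous_deletions",
    "simulate_dataset", "write_dataset", "mixing_for_autozygosity",
    "expected_autozygosity",
]


def uniform_freq_law(rng: np.random.Generator, size: int) -> np.ndarray:
    """Default reference B-allele frequency law: Uniform(0.01, 0.99)."""
    return rng.uniform(0.01, 0.99, size)


@dataclass
class DeletionSpec:
    """Hemizygous-deletion injection parameters.

    Lengths are uniform in [length_min_bp, length_max_bp]; LRR inside a
    deletion is Normal(lrr_shift_mean, lrr_shift_sd).  With ``avoid_hbd``
    deletions are placed only in truly non-HBD genome, the scenario in
    which a deletion fakes an ROH.
    """

    count_per_individual: int = 0
    length_min_bp: int = 200_000
    length_max_bp: int = 1_000_000
    lrr_shift_mean: float = -0.55
    lrr_shift_sd: float = 0.20
    avoid_hbd: bool = True


# Default mosaic: 11 HBD classes on the doubling ladder plus non-HBD,
# ancient classes carrying most of the autozygous mass, tuned to an
# expected cohort autozygosity of about 0.07 (livestock-like).
_DEFAULT_RATES = tuple(float(2 ** g) for g in range(1, 12)) + (2048.0,)
_DEFAULT_HBD_WEIGHTS = (0.0, 0.0, 0.0, 0.0, 0.0, 0.05, 0.1, 0.2, 0.3, 0.25, 0.1)


def mixing_for_autozygosity(f: float, class_rates, hbd_weights=None):
    """Mixing proportions whose long-run HBD genome fraction equals ``f``.

    The length-weighted fraction of genome in class k is
    pi_k / R_k normalized over all classes, so the HBD mass c solves
    f = c A / (c A + (1 - c) B) with A = sum(w_k / R_k) over HBD classes
    and B = 1 / R_nonhbd.  ``hbd_weights`` are relative weights among the
    HBD classes (uniform by default); the non-HBD class is last.
    """
    rates = np.asarray(class_rates, dtype=float)
    K = rates.size - 1
    w = (np.full(K, 1.0 / K) if hbd_weights is None
         else np.asarray(hbd_weights, dtype=float))
    w = w / w.sum()
    if not 0.0 <= f < 1.0:
        raise ValueError("target autozygosity must lie in [0, 1)")
    if f == 0.0:
        return np.append(np.zeros(K), 1.0)
    A = float(np.sum(w / rates[:K]))
    B = 1.0 / rates[K]
    c = f * B / (A * (1.0 - f) + f * B)
    return np.append(c * w, 1.0 - c)


def expected_autozygosity(class_rates, mixing) -> float:
    """Long-run HBD genome fraction of a mosaic (renewal expectation):
    sum over HBD classes of pi_k / R_k, normalized over all classes."""
    rates = np.asarray(class_rates, float)
    pi = np.asarray(mixing, float)
    occ = pi / rates
    return float(occ[:-1].sum() / occ.sum())


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    ``class_rates`` and ``mixing_proportions`` run over the K HBD classes
    followed by the non-HBD class (last).  Defaults emulate a 50k-chip
    livestock cohort: ~30 autosomes, genotyping error 0.001, 1 cM/Mb,
    CN2 intensity noise LRR ~ N(0, 0.15) and CN1 LRR ~ N(-0.55, 0.20).
    """

    n_individuals: int = 25
    chromosomes: list = field(default_factory=lambda: [
        (f"chr{i}", 100_000_000) for i in range(1, 31)])
    marker_density: float = 10.0          # markers per Mb
    allele_freq_law: Callable = uniform_freq_law
    class_rates: tuple = _DEFAULT_RATES
    mixing_proportions: tuple = tuple(
        mixing_for_autozygosity(0.07, _DEFAULT_RATES, _DEFAULT_HBD_WEIGHTS))
    genotype_error: float = 0.001
    missing_rate: float = 0.0
    cm_per_mb: float = 1.0
    deletion_spec: DeletionSpec = field(default_factory=DeletionSpec)
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.mixing_proportions, float)
        rates = np.asarray(self.class_rates, float)
        if pi.size != rates.size:
            raise ValueError("mixing_proportions and class_rates lengths differ")
        if abs(pi.sum() - 1.0) > 1e-12 or np.any(pi < 0):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(rates <= 0):
            raise ValueError("all class rates must be positive")
        if not 0 <= self.genotype_error < 0.5:
            raise ValueError("genotype error must lie in [0, 0.5)")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.marker_density <= 0:
            raise ValueError("marker density must be positive")

    @property
    def nonhbd_index(self) -> int:
        return len(self.class_rates) - 1


@dataclass
class TruthSegment:
    chrom: str
    start: int
    end: int
    class_index: int


@dataclass
class IndividualTruth:
    """Full mosaic tiling (HBD and non-HBD) plus deletions for one genome.

    The tiling is stored compactly: per chromosome, an int64 boundary
    array of length n+1 (0 first, chromosome length last) and the n
    class indices of the segments between consecutive boundaries.
    """

    tiling: dict
    deletions: list = field(default_factory=list)
    realized_autozygosity: float = 0.0

    @property
    def segments(self) -> list:
        out = []
        for chrom, (bounds, classes) in self.tiling.items():
            for i in range(classes.size):
                out.append(TruthSegment(chrom, int(bounds[i]),
                                        int(bounds[i + 1]), int(classes[i])))
        return out

    def hbd_segments(self, nonhbd_index: int) -> list:
        out = []
        for chrom, (bounds, classes) in self.tiling.items():
            for i in np.flatnonzero(classes != nonhbd_index):
                out.append(TruthSegment(chrom, int(bounds[i]),
                                        int(bounds[i + 1]), int(classes[i])))
        return out


@dataclass
class TruthTable:
    individuals: list        # IndividualTruth per simulated genome
    class_rates: tuple
    nonhbd_index: int

    def realized(self) -> np.ndarray:
        return np.array([t.realized_autozygosity for t in self.individuals])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    individuals: list
    labels: list
    markers: MarkerMap
    genotypes: np.ndarray
    truth: TruthTable
    intensity: IntensityMatrix | None = None
    cnv_calls: list = field(default_factory=list)

    def to_genotype_dataset(self):
        from .qc import GenotypeDataset
        return GenotypeDataset(self.individuals, self.labels, self.markers,
                               self.genotypes)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


# ----------------------------------------------------------------------
# Stage 1: marker map
# ----------------------------------------------------------------------

def simulate_marker_map(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> MarkerMap:
    """Random marker map: per chromosome, round(density * length / 1 Mb)
    markers at distinct uniform positions; genetic position bp *
    cm_per_mb; frequencies from the configured law truncated to
    [0.01, 0.99]."""
    rng = rng if rng is not None else _rng(config, 1)
    chroms, ids, bps, cms = [], [], [], []
    counter = 0
    for name, length in config.chromosomes:
        n = int(round(config.marker_density * length / 1e6))
        n = max(1, min(n, length))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        while pos.size < n:
            extra = rng.integers(1, length + 1, size=n - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([name] * n)
        ids.extend(f"snp{counter + k}" for k in range(n))
        counter += n
        bps.append(pos - 1)                     # store 0-based
        cms.append(pos * config.cm_per_mb / 1e6)
    bp = np.concatenate(bps)
    cm = np.concatenate(cms)
    freq = np.clip(config.allele_freq_law(rng, counter), 0.01, 0.99)
    return MarkerMap(np.array(chroms, dtype=object),
                     np.array(ids, dtype=object), bp, cm, freq)


# ----------------------------------------------------------------------
# Stage 2: HBD mosaic
# ----------------------------------------------------------------------

def simulate_hbd_mosaic(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> TruthTable:
    """Tile each chromosome with class-labelled segments.

    Classes are stationary draws from the mixing proportions and lengths
    are exponential with mean 1/R_k Morgans (1e8 / R_k / cm_per_mb bp),
    truncated at the chromosome end; the first segment is drawn like any
    other.
    """
    rng = rng if rng is not None else _rng(config, 2)
    rates = np.asarray(config.class_rates, float)
    pi = np.asarray(config.mixing_proportions, float)
    bp_per_morgan = 1e8 / config.cm_per_mb
    genome = sum(length for _, length in config.chromosomes)
    individuals = []
    for _ in range(config.n_individuals):
        tiling = {}
        hbd_bp = 0
        for name, length in config.chromosomes:
            all_ends = []
            all_ks = []
            pos = 0
            while pos < length:
                # draw classes and lengths in chunks; the renewal process
                # is identical to drawing one segment at a time
                chunk = 4096
                ks = rng.choice(pi.size, size=chunk, p=pi)
                seg_bp = np.maximum(1, np.rint(
                    rng.exponential(1.0 / rates[ks]) * bp_per_morgan
                ).astype(np.int64))
                ends = pos + np.cumsum(seg_bp)
                stop = int(np.searchsorted(ends, length))
                take = min(stop + 1, chunk)
                all_ends.append(np.minimum(ends[:take], length))
                all_ks.append(ks[:take])
                pos = int(all_ends[-1][-1])
            ends = np.concatenate(all_ends)
            classes = np.concatenate(all_ks).astype(np.int64)
            bounds = np.concatenate([[0], ends]).astype(np.int64)
            tiling[name] = (bounds, classes)
            hbd = classes != config.nonhbd_index
            hbd_bp += int(np.sum((bounds[1:] - bounds[:-1])[hbd]))
        individuals.append(IndividualTruth(
            tiling=tiling, realized_autozygosity=hbd_bp / genome))
    return TruthTable(individuals, tuple(config.class_rates),
                      config.nonhbd_index)


def _marker_classes(truth_ind: IndividualTruth, marker_map: MarkerMap) -> np.ndarray:
    """Truth class per marker via the tiling (every marker must be covered)."""
    classes = np.full(marker_map.n_markers, -1, dtype=np.int64)
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        if chrom not in truth_ind.tiling:
            raise RuntimeError(f"truth tiling missing chromosome {chrom!r}")
        bounds, seg_classes = truth_ind.tiling[chrom]
        idx = np.searchsorted(bounds, marker_map.bp[sl], side="right") - 1
        if np.any(idx < 0) or np.any(marker_map.bp[sl] >= bounds[-1]):
            raise RuntimeError(f"truth tiling does not cover {chrom!r}")
        classes[sl] = seg_classes[idx]
    return classes


# ----------------------------------------------------------------------
# Stage 3: genotypes
# ----------------------------------------------------------------------

def emit_genotypes(truth: TruthTable, marker_map: MarkerMap,
                   config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """B-allele dosage matrix (individuals x markers).

    Inside an HBD segment the two haplotypes share one allele (B with
    probability p), except with probability e the call is replaced by a
    Hardy-Weinberg draw; outside, calls are Hardy-Weinberg.  Missing
    calls are injected at ``missing_rate``.
    """
    rng = rng if rng is not None else _rng(config, 3)
    p = marker_map.freq
    m = marker_map.n_markers
    out = np.empty((config.n_individuals, m), dtype=np.int8)
    for i, tind in enumerate(truth.individuals):
        classes = _marker_classes(tind, marker_map)
        hbd = classes != truth.nonhbd_index
        hw = rng.binomial(2, p).astype(np.int8)
        auto = (2 * (rng.random(m) < p)).astype(np.int8)
        err = rng.random(m) < config.genotype_error
        g = np.where(hbd & ~err, auto, hw)
        if config.missing_rate > 0:
            g = np.where(rng.random(m) < config.missing_rate,
                         np.int8(io.MISSING), g)
        out[i] = g
    return out


# ----------------------------------------------------------------------
# Stage 4: hemizygous deletions and intensities
# ----------------------------------------------------------------------

def inject_hemizygous_deletions(genotypes: np.ndarray, truth: TruthTable,
                                marker_map: MarkerMap,
                                config: SimulationConfig,
                                rng: np.random.Generator | None = None):
    """Place deletions, recode genotypes and build intensities.

    Returns ``(genotypes, IntensityMatrix, cnv_calls)``; the truth table
    is updated in place with the deletion intervals.  Inside a deletion
    every genotype is homozygous for the retained allele (B with
    probability p per marker) and LRR shifts to the configured CN1
    distribution; BAF is dosage/2 plus noise, clipped to [0, 1], so it
    concentrates at the homozygous poles under hemizygosity.
    """
    rng = rng if rng is not None else _rng(config, 4)
    spec = config.deletion_spec
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_len = {c: l for c, l in config.chromosomes}
    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    if spec.count_per_individual > 0 and spec.length_min_bp > lengths.max():
        raise ValueError("deletion length exceeds every chromosome")
    individuals = [f"ind{i}" for i in range(config.n_individuals)]

    genotypes = genotypes.copy()
    p = marker_map.freq
    n, m = genotypes.shape
    lrr = rng.normal(0.0, config.lrr_noise_sd, size=(n, m))
    cnv_calls = []

    for i, tind in enumerate(truth.individuals):
        placed = []
        hbd = tind.hbd_segments(truth.nonhbd_index)
        for _ in range(spec.count_per_individual):
            for _attempt in range(1000):
                ci = rng.choice(len(chrom_names), p=lengths / lengths.sum())
                chrom = chrom_names[ci]
                size = int(rng.integers(spec.length_min_bp,
                                        spec.length_max_bp + 1))
                if size > chrom_len[chrom]:
                    continue
                start = int(rng.integers(0, chrom_len[chrom] - size + 1))
                end = start + size
                if any(c == chrom and s < end and start < e
                       for c, s, e in placed):
                    continue
                if spec.avoid_hbd and any(
                        seg.chrom == chrom and seg.start < end
                        and start < seg.end for seg in hbd):
                    continue
                break
            else:
                raise RuntimeError("could not place a deletion after 1000 tries")
            placed.append((chrom, start, end))
            tind.deletions.append((chrom, start, end))
            cnv_calls.append(CNVCall(individual=individuals[i], chrom=chrom,
                                     start=start, end=end, cn=1))
            sl = marker_map.chrom_slice(chrom)
            bp = marker_map.bp[sl]
            lo = sl.start + np.searchsorted(bp, start, side="left")
            hi = sl.start + np.searchsorted(bp, end, side="left")
            idx = np.arange(lo, hi)
            if idx.size:
                genotypes[i, idx] = np.where(rng.random(idx.size) < p[idx],
                                             2, 0).astype(np.int8)
                lrr[i, idx] = rng.normal(spec.lrr_shift_mean,
                                         spec.lrr_shift_sd, size=idx.size)

    dosage = genotypes.astype(float)
    dosage[genotypes == io.MISSING] = np.nan
    baf = np.clip(dosage / 2.0 + rng.normal(0.0, config.baf_noise_sd,
                                            size=(n, m)), 0.0, 1.0)
    intensity = IntensityMatrix(individuals, marker_map, lrr, baf)
    return genotypes, intensity, cnv_calls


# ----------------------------------------------------------------------
# Pipeline + serialization
# ----------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, labels=None) -> SimulatedDataset:
    """Run all stages with seeds derived from ``config.seed``."""
    marker_map = simulate_marker_map(config)
    truth = simulate_hbd_mosaic(config)
    genotypes = emit_genotypes(truth, marker_map, config)
    genotypes, intensity, cnv_calls = inject_hemizygous_deletions(
        genotypes, truth, marker_map, config)
    individuals = [f"ind{i}" for i in range(config.n_individuals)]
    labels = list(labels) if labels is not None else ["POP1"] * len(individuals)
    return SimulatedDataset(config, individuals, labels, marker_map,
                            genotypes, truth, intensity, cnv_calls)


def _config_manifest(config: SimulationConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if callable(v):
            v = getattr(v, "__name__", repr(v))
        elif dataclasses.is_dataclass(v):
            v = dataclasses.asdict(v)
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, list):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        out[f.name] = v
    return out


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict:
    """Write the PED/MAP pair, intensity and CNV tables, truth BEDs and a
    manifest; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {key: os.path.join(out_dir, name) for key, name in [
        ("ped", "genotypes.ped"), ("map", "genotypes.map"),
        ("intensity", "intensity.tsv"), ("cnv", "cnv_calls.tsv"),
        ("truth_hbd", "truth_hbd.bed"), ("truth_deletions",
         "truth_deletions.bed"), ("manifest", "manifest.json")]}
    io.write_ped(dataset.genotypes, dataset.individuals, dataset.labels,
                 paths["ped"])
    io.write_map(dataset.markers, paths["map"])
    if dataset.intensity is not None:
        io.write_intensity(dataset.markers, dataset.individuals,
                           dataset.intensity.lrr, dataset.intensity.baf,
                           paths["intensity"])
    io.write_cnv_calls(dataset.cnv_calls, paths["cnv"])
    hbd_rows, del_rows = [], []
    for iid, tind in zip(dataset.individuals, dataset.truth.individuals):
        for seg in tind.hbd_segments(dataset.truth.nonhbd_index):
            hbd_rows.append((seg.chrom, seg.start, seg.end, iid,
                             f"R{dataset.truth.class_rates[seg.class_index]:g}"))
        for chrom, start, end in tind.deletions:
            del_rows.append((chrom, start, end, iid, "CN1"))
    io.write_bed(hbd_rows, paths["truth_hbd"])
    io.write_bed(del_rows, paths["truth_deletions"])
    manifest = {
        "seed": dataset.config.seed,
        "n_individuals": len(dataset.individuals),
        "n_markers": dataset.markers.n_markers,
        "config": _config_manifest(dataset.config),
        "files": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
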