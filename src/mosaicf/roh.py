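"""ROH extraction from HBD posteriors and Viterbi paths.

Two segment definitions are supported:

``posterior`` (default)
    Segments are centered on seed markers whose total HBD probability
    (1 minus the non-HBD posterior) exceeds ``seed_prob`` (0.999) and are
    extended in both directions over markers above ``extend_prob``
    (0.99), stopping at the first marker below it.  Overlapping
    extensions merge.
``viterbi``
    Maximal runs of markers whose Viterbi state is any HBD class.

Segment coordinates are 0-based half-open: start is the bp of the first
included marker, end is one past the bp of the last.  F_ROH divides
segment length by the mapped genome length (sum over chromosomes of the
first-to-last-marker span), so an individual whose whole map is one ROH
has F_ROH = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HBDModelConfig, HBDPosterior, _chains, _viterbi_kernel
from .markers import MarkerMap

__all__ = ["ROHSegment", "ROHInbreeding", "viterbi_decode",
           "call_roh_segments", "roh_inbreeding", "compute_roh_inbreeding",
           "roh_length_distribution"]


@dataclass
class ROHSegment:
    """One run of homozygosity-by-descent for one individual."""

    individual: str
    chrom: str
    start: int            # 0-based inclusive
    end: int              # exclusive
    n_markers: int
    class_index: int      # modal Viterbi class among included markers

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one marker")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ROHInbreeding:
    """ROH-based inbreeding for one individual."""

    individual: str
    f_roh: float
    f_roh_2mb: float
    denominator: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_roh_2mb <= self.f_roh <= 1.0:
            raise ValueError("need 0 <= F_ROH>2Mb <= F_ROH <= 1")


def viterbi_decode(genotypes, marker_map: MarkerMap, freqs,
                   config: HBDModelConfig, pi) -> np.ndarray:
    """Maximum a-posteriori state path, one chain per chromosome.

    Ties break toward the lower class index (the lower-rate, older-free
    class ordering is ascending in rate, non-HBD last), deterministically.
    """
    K = config.n_classes - 1
    pi = np.asarray(pi, dtype=float)
    paths = [
        _viterbi_kernel(bh, bn, a, pi, K)
        for _, bh, bn, a in _chains(genotypes, marker_map, freqs, config)
    ]
    return np.concatenate(paths)


def _segments_from_runs(runs, marker_map, sl, path, individual):
    segs = []
    for lo, hi in runs:            # marker index range [lo, hi] inclusive, chain-local
        idx = np.arange(sl.start + lo, sl.start + hi + 1)
        states = path[idx]
        counts = np.bincount(states)
        cls = int(np.argmax(counts))           # first max = lowest class index
        segs.append(ROHSegment(
            individual=individual,
            chrom=marker_map.chrom[idx[0]],
            start=int(marker_map.bp[idx[0]]),
            end=int(marker_map.bp[idx[-1]]) + 1,
            n_markers=len(idx),
            class_index=cls,
        ))
    return segs


def call_roh_segments(posterior: HBDPosterior, viterbi_path: np.ndarray,
                      marker_map: MarkerMap, individual: str = "ind",
                      seed_prob: float = 0.999, extend_prob: float = 0.99,
                      mode: str = "posterior") -> list:
    """Extract ROH segments for one individual.

    ``mode='posterior'`` applies the seed/extend rule to the total HBD
    posterior; ``mode='viterbi'`` takes maximal runs of HBD Viterbi
    states.  Returns segments ordered by (chromosome, start).
    """
    total_hbd = 1.0 - posterior.gamma[:, -1]
    K = posterior.gamma.shape[1] - 1
    segments = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        if mode == "viterbi":
            hbd = viterbi_path[sl] < K
            runs = _true_runs(hbd)
        elif mode == "posterior":
            p = total_hbd[sl]
            above = p > extend_prob
            runs = [r for r in _true_runs(above)
                    if np.any(p[r[0]:r[1] + 1] > seed_prob)]
        else:
            raise ValueError(f"unknown ROH mode {mode!r}")
        segments.extend(_segments_from_runs(runs, marker_map, sl,
                                            viterbi_path, individual))
    return segments


def _true_runs(mask: np.ndarray):
    """Maximal runs of True as inclusive (lo, hi) index pairs."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        runs.append((int(idx[s]), int(idx[e])))
    return runs


def roh_inbreeding(segments, marker_map: MarkerMap,
                   min_length_bp: int = 0) -> float:
    """Fraction of the mapped genome in ROH strictly longer than
    ``min_length_bp`` (0 gives F_ROH, 2_000_000 gives F_ROH>2Mb)."""
    denom = marker_map.mapped_length_bp()
    if denom <= 0:
        raise ValueError("empty marker map")
    total = sum(s.length for s in segments if s.length > min_length_bp)
    return total / denom


def compute_roh_inbreeding(segments, marker_map: MarkerMap,
                           individual: str = "ind") -> ROHInbreeding:
    return ROHInbreeding(
        individual=individual,
        f_roh=roh_inbreeding(segments, marker_map, 0),
        f_roh_2mb=roh_inbreeding(segments, marker_map, 2_000_000),
        denominator=marker_map.mapped_length_bp(),
    )


def roh_length_distribution(segments, labels: dict,
                            bins_mb=(1.0, 2.0, 4.0, 8.0)) -> pd.DataFrame:
    """Per-group proportion of ROH in each length bin.

    ``bins_mb`` are interior breakpoints in Mb; the default yields the
    five bins <1, 1-2, 2-4, 4-8 and >8 Mb.  Groups without segments get a
    row of NaN.
    """
    edges = [0.0] + [b * 1e6 for b in bins_mb] + [np.inf]
    names = ([f"<{bins_mb[0]:g}Mb"]
             + [f"{a:g}-{b:g}Mb" for a, b in zip(bins_mb[:-1], bins_mb[1:])]
             + [f">{bins_mb[-1]:g}Mb"])
    groups = sorted(set(labels.values()))
    out = pd.DataFrame(np.nan, index=groups, columns=names)
    for grp in groups:
        lengths = np.array([s.length for s in segments
                            if labels[s.individual] == grp])
        if lengths.size == 0:
            continue
        counts, _ = np.histogram(lengths, bins=edges)
        out.loc[grp] = counts / counts.sum()
    return out
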