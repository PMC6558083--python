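"""Correction of ROH-based inbreeding for hemizygous copy-number losses.

SNP arrays type a hemizygous (single-copy) region as a run of homozygous
calls, so copy-number deletions can be miscalled as ROH.  The correction
intersects called ROH with copy-loss CNV calls (copy number 0 or 1),
confirms hemizygosity where the mean log R ratio over the intersection
falls below a threshold (default -0.3), and subtracts the confirmed
lengths from F_ROH, F_ROH>2Mb and F_G (as length / mapped genome, the
only commensurate reading).

All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .hmm import ClassInbreeding
from .intensity import IntensityMatrix
from .markers import MarkerMap
from .roh import ROHInbreeding, ROHSegment

__all__ = ["CNVCall", "LossRegion", "AdjustedInbreeding",
           "intersect_roh_with_losses", "classify_copy_loss",
           "adjust_inbreeding", "region_evidence_report", "merge_intervals"]

ALLOWED_CN = {0, 1, 3, 4}
LOSS_CN = {0, 1}


@dataclass
class CNVCall:
    """A copy-number call for one individual (PennCNV-style region)."""

    individual: str
    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CNV interval empty: {self.chrom}:{self.start}-{self.end}")
        if self.cn not in ALLOWED_CN:
            raise ValueError(f"copy number {self.cn} not in {sorted(ALLOWED_CN)}")


@dataclass
class LossRegion:
    """An ROH / copy-loss intersection (candidate miscalled ROH)."""

    individual: str
    chrom: str
    start: int
    end: int
    source_roh: str
    source_cnv: str
    source_roh_length: int
    n_markers: int | None = None
    mean_lrr: float | None = None
    flagged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AdjustedInbreeding:
    """Raw and copy-loss-adjusted inbreeding for one individual."""

    individual: str
    f_roh_raw: float
    f_roh_adj: float
    f_roh_2mb_raw: float
    f_roh_2mb_adj: float
    f_g_raw: float
    f_g_adj: float
    flagged_length: int

    def __post_init__(self) -> None:
        for raw, adj in ((self.f_roh_raw, self.f_roh_adj),
                         (self.f_roh_2mb_raw, self.f_roh_2mb_adj),
                         (self.f_g_raw, self.f_g_adj)):
            if adj > raw + 1e-12 or adj < -1e-12:
                raise ValueError("adjusted metric must lie in [0, raw]")


def intersect_roh_with_losses(roh_segments, cnv_calls) -> list:
    """Pairwise intersections between each individual's ROH and their
    copy-loss CNV calls (CN 0 or 1); duplications are excluded."""
    trees: dict = {}
    for idx, c in enumerate(cnv_calls):
        if c.cn not in LOSS_CN:
            continue
        trees.setdefault((c.individual, c.chrom), IntervalTree()).addi(
            c.start, c.end, (idx, c))
    regions = []
    for sidx, seg in enumerate(roh_segments):
        tree = trees.get((seg.individual, seg.chrom))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(seg.start, seg.end)):
            cidx, c = iv.data
            start, end = max(seg.start, c.start), min(seg.end, c.end)
            if start < end:
                regions.append(LossRegion(
                    individual=seg.individual, chrom=seg.chrom,
                    start=start, end=end,
                    source_roh=f"roh{sidx}", source_cnv=f"cnv{cidx}",
                    source_roh_length=seg.length))
    return regions


def classify_copy_loss(region: LossRegion, intensity: IntensityMatrix,
                       lrr_threshold: float = -0.3) -> LossRegion:
    """Attach marker count and mean LRR; flag as a confirmed copy loss
    iff the mean LRR over markers inside the region is strictly below the
    threshold.  Regions containing no markers are never flagged."""
    i = intensity.individual_index(region.individual)
    idx = intensity.marker_indices_in(region.chrom, region.start, region.end)
    if idx.size == 0:
        return replace(region, n_markers=0, mean_lrr=None, flagged=False)
    mean_lrr = float(intensity.lrr[i, idx].mean())
    return replace(region, n_markers=int(idx.size), mean_lrr=mean_lrr,
                   flagged=mean_lrr < lrr_threshold)


def merge_intervals(intervals):
    """Union of (start, end) half-open intervals, sorted and merged."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _merged_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def adjust_inbreeding(roh_inb: ROHInbreeding, class_inb: ClassInbreeding,
                      flagged_regions, marker_map: MarkerMap) -> AdjustedInbreeding:
    """Subtract confirmed copy-loss lengths from the inbreeding metrics.

    Flagged regions are merged per chromosome before subtraction so
    overlaps are not double-counted.  F_ROH>2Mb only loses the flagged
    length that lies inside ROH longer than 2 Mb.  All metrics clamp at 0.
    """
    denom = roh_inb.denominator
    regions = [r for r in flagged_regions if r.flagged]
    for r in regions:
        if r.individual != roh_inb.individual:
            raise ValueError(
                f"region individual {r.individual!r} does not match "
                f"{roh_inb.individual!r}")
    by_chrom: dict = {}
    by_chrom_2mb: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        if r.source_roh_length > 2_000_000:
            by_chrom_2mb.setdefault(r.chrom, []).append((r.start, r.end))
    loss = sum(_merged_length(iv) for iv in by_chrom.values())
    loss_2mb = sum(_merged_length(iv) for iv in by_chrom_2mb.values())
    return AdjustedInbreeding(
        individual=roh_inb.individual,
        f_roh_raw=roh_inb.f_roh,
        f_roh_adj=max(0.0, roh_inb.f_roh - loss / denom),
        f_roh_2mb_raw=roh_inb.f_roh_2mb,
        f_roh_2mb_adj=max(0.0, roh_inb.f_roh_2mb - loss_2mb / denom),
        f_g_raw=class_inb.f_g,
        f_g_adj=max(0.0, class_inb.f_g - loss / denom),
        flagged_length=loss,
    )


def region_evidence_report(regions, intensity: IntensityMatrix) -> pd.DataFrame:
    """Per-region BAF/LRR evidence summary (the scatter-plot input for
    judging whether an intersection is a genuine copy loss).

    BAF mass columns give the fraction of markers with BAF within 0.15 of
    0, 0.5 and 1; hemizygous regions concentrate at the homozygous poles.
    """
    rows = []
    for r in regions:
        i = intensity.individual_index(r.individual)
        idx = intensity.marker_indices_in(r.chrom, r.start, r.end)
        lrr = intensity.lrr[i, idx]
        baf = intensity.baf[i, idx]
        baf = baf[~np.isnan(baf)]
        rows.append({
            "individual": r.individual, "chrom": r.chrom,
            "start": r.start, "end": r.end, "flagged": r.flagged,
            "n_markers": int(idx.size),
            "mean_lrr": float(lrr.mean()) if idx.size else np.nan,
            "min_lrr": float(lrr.min()) if idx.size else np.nan,
            "max_lrr": float(lrr.max()) if idx.size else np.nan,
            "baf_mass_0": float((baf < 0.15).mean()) if baf.size else np.nan,
            "baf_mass_half": float((np.abs(baf - 0.5) < 0.15).mean())
                             if baf.size else np.nan,
            "baf_mass_1": float((baf > 0.85).mean()) if baf.size else np.nan,
        })
    cols = ["individual", "chrom", "start", "end", "flagged", "n_markers",
            "mean_lrr", "min_lrr", "max_lrr", "baf_mass_0", "baf_mass_half",
            "baf_mass_1"]
    return pd.DataFrame(rows, columns=cols)
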