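"""Per-marker, per-individual array intensities (LRR and BAF)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import MarkerMap

__all__ = ["IntensityMatrix"]


@dataclass
class IntensityMatrix:
    """Log R ratio and B-allele frequency, individuals x markers.

    LRR is the log-scaled total probe intensity (0 at copy number 2,
    sustained negative values under copy loss); BAF is the normalized
    allelic ratio (near 0, 0.5, 1 for AA, AB, BB; NaN where the genotype
    is missing)."""

    individuals: list
    markers: MarkerMap
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.individuals), self.markers.n_markers)
        if self.lrr.shape != shape or self.baf.shape != shape:
            raise ValueError("intensity matrices must be individuals x markers")
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    def individual_index(self, individual: str) -> int:
        return self._row[individual]

    def marker_indices_in(self, chrom, start: int, end: int) -> np.ndarray:
        """Indices of markers whose position lies in [start, end) on chrom."""
        if chrom not in self.markers.chromosomes:
            return np.arange(0)
        sl = self.markers.chrom_slice(chrom)
        bp = self.markers.bp[sl]
        lo = np.searchsorted(bp, start, side="left")
        hi = np.searchsorted(bp, end, side="left")
        return np.arange(sl.start + lo, sl.start + hi)
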