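"""Ordered SNP marker map shared by every pipeline stage.

Coordinates are 0-based half-open internally; a marker is the point
interval ``[bp, bp + 1)``.  PLINK MAP files store 1-based positions and
are converted on ingest (see :mod:`mosaicf.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MarkerMap"]


@dataclass
class MarkerMap:
    """Genome-ordered marker map.

    Parameters
    ----------
    chrom
        Chromosome name per marker.  Chromosome blocks are kept in order
        of first appearance.
    marker_id
        Unique marker identifiers.
    bp
        Physical position, 0-based.
    cm
        Genetic position in centiMorgans.
    freq
        Population B-allele frequency per marker (NaN where unknown).
        Optional; attached by :func:`mosaicf.qc.allele_frequencies` or by
        the simulator.
    """

    chrom: np.ndarray
    marker_id: np.ndarray
    bp: np.ndarray
    cm: np.ndarray
    freq: np.ndarray | None = None

    _slices: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.freq is not None:
            self.freq = np.asarray(self.freq, dtype=np.float64)
        n = self.bp.shape[0]
        for arr, name in ((self.chrom, "chrom"), (self.marker_id, "marker_id"),
                          (self.cm, "cm")):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != bp length {n}")
        if len(set(self.marker_id.tolist())) != n:
            raise ValueError("duplicate marker ids")
        self._slices = {}
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chrom[i] != self.chrom[start]:
                name = self.chrom[start]
                if name in self._slices:
                    raise ValueError(
                        f"chromosome {name!r} appears in non-contiguous blocks; "
                        "sort the map first")
                self._slices[name] = slice(start, i)
                if not np.all(np.diff(self.bp[start:i]) > 0):
                    raise ValueError(
                        f"marker positions not strictly increasing on {name!r}")
                start = i

    # ------------------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return int(self.bp.shape[0])

    @property
    def chromosomes(self) -> list:
        """Chromosome names in map order."""
        return list(self._slices)

    def chrom_slice(self, chrom) -> slice:
        return self._slices[chrom]

    def mapped_length_bp(self) -> int:
        """Total mapped length: sum over chromosomes of the half-open span
        from the first to one past the last marker."""
        total = 0
        for sl in self._slices.values():
            total += int(self.bp[sl.stop - 1]) + 1 - int(self.bp[sl.start])
        return total

    def morgans(self, cm_per_mb: float = 1.0) -> np.ndarray:
        """Genetic position in Morgans.

        Uses the stored cM column when it carries information (any
        within-chromosome spread); otherwise falls back to scaling the
        physical positions by ``cm_per_mb``.
        """
        out = self.cm / 100.0
        for sl in self._slices.values():
            seg = self.cm[sl]
            if seg.size > 1 and np.ptp(seg) <= 0:
                out[sl] = self.bp[sl] * cm_per_mb / 1e8
        return out

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        mask = np.asarray(mask)
        freq = self.freq[mask] if self.freq is not None else None
        return MarkerMap(self.chrom[mask], self.marker_id[mask],
                         self.bp[mask], self.cm[mask], freq)

    def with_freq(self, freq: np.ndarray) -> "MarkerMap":
        return replace(self, freq=np.asarray(freq, dtype=np.float64))
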