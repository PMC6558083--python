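"""Genotype loading and quality control.

Filters follow the usual SNP-array protocol: markers whose missingness
exceeds 2% are dropped, then individuals whose missingness exceeds 4%,
then markers out of Hardy-Weinberg equilibrium (exact test, p < 0.001)
pooled across the whole cohort.  Low-MAF markers are not deleted but
masked as uninformative for the HMM, so the genomic coordinate system
(and hence ROH lengths) is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import io
from .markers import MarkerMap

logger = logging.getLogger(__name__)

__all__ = ["GenotypeDataset", "QCReport", "load_genotype_data",
           "apply_callrate_filters", "hwe_filter", "hwe_exact_pvalue",
           "allele_frequencies", "run_qc"]


@dataclass
class GenotypeDataset:
    """Cohort genotypes: individuals x markers B-allele dosages
    (``io.MISSING`` = -1 for no-calls) plus a breed/group label per
    individual."""

    individuals: list
    labels: list
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.individuals) != n:
            raise ValueError("individuals/calls row mismatch")
        if len(self.labels) != n:
            raise ValueError("labels/calls row mismatch")
        if self.markers.n_markers != m:
            raise ValueError("markers/calls column mismatch")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, ind_mask=None, marker_mask=None) -> "GenotypeDataset":
        ind_mask = (np.ones(self.n_individuals, bool) if ind_mask is None
                    else np.asarray(ind_mask, bool))
        marker_mask = (np.ones(self.n_markers, bool) if marker_mask is None
                       else np.asarray(marker_mask, bool))
        return GenotypeDataset(
            [x for x, k in zip(self.individuals, ind_mask) if k],
            [x for x, k in zip(self.labels, ind_mask) if k],
            self.markers.subset(marker_mask),
            self.calls[np.ix_(ind_mask, marker_mask)],
        )


@dataclass
class QCReport:
    n_markers_in: int
    n_markers_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed: dict = field(default_factory=dict)
    hwe_pvalues: pd.Series | None = None
    maf: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.n_markers_in != self.n_markers_out + sum(
                v for k, v in self.removed.items() if k.startswith("marker")):
            raise ValueError("marker counts do not reconcile")
        if self.n_individuals_in != self.n_individuals_out + sum(
                v for k, v in self.removed.items() if k.startswith("individual")):
            raise ValueError("individual counts do not reconcile")


def load_genotype_data(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    An unsorted map is sorted by (chromosome, bp) — chromosome blocks in
    order of first appearance — with the call matrix permuted to match,
    and a warning is logged.
    """
    table = io.read_map_table(map_path)
    chrom_rank = {}
    for c in table["chrom"]:
        chrom_rank.setdefault(c, len(chrom_rank))
    order = np.lexsort((table["bp"].to_numpy(),
                        table["chrom"].map(chrom_rank).to_numpy()))
    sorted_already = np.array_equal(order, np.arange(len(table)))
    if not sorted_already:
        logger.warning("map %s was not position-sorted; sorting markers and "
                       "permuting genotype columns to match", map_path)
        table = table.iloc[order].reset_index(drop=True)
    mm = io.map_from_table(table)
    ids, labels, calls = io.read_ped(ped_path, mm.n_markers)
    if not sorted_already:
        calls = calls[:, order]
    return GenotypeDataset(ids, labels, mm, calls)


def apply_callrate_filters(ds: GenotypeDataset, max_ind_missing: float = 0.04,
                           max_marker_missing: float = 0.02):
    """Drop markers, then individuals, whose missingness fraction is
    strictly greater than the respective threshold.

    Marker-before-individual order is fixed: individual missingness is
    judged on the markers that survived the marker filter.
    """
    for thr in (max_ind_missing, max_marker_missing):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    missing = ds.calls == io.MISSING
    marker_keep = missing.mean(axis=0) <= max_marker_missing
    ind_keep = missing[:, marker_keep].mean(axis=1) <= max_ind_missing \
        if marker_keep.any() else np.ones(ds.n_individuals, bool)
    out = ds.subset(ind_keep, marker_keep)
    report = QCReport(
        n_markers_in=ds.n_markers, n_markers_out=out.n_markers,
        n_individuals_in=ds.n_individuals, n_individuals_out=out.n_individuals,
        removed={"marker_callrate": int((~marker_keep).sum()),
                 "individual_callrate": int((~ind_keep).sum())},
    )
    return out, report


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more likely than the observed one.
    Monomorphic markers return p = 1.
    """
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    na = 2 * n_aa + n_ab
    if n == 0 or nb == 0 or na == 0:
        return 1.0
    rare = min(na, nb)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_r = (rare - hets) // 2
    homs_c = (max(na, nb) - hets) // 2
    logw = (hets * np.log(2.0) - gammaln(homs_r + 1) - gammaln(hets + 1)
            - gammaln(homs_c + 1))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    p_obs = w[hets == n_ab][0]
    return float(min(1.0, w[w <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(ds: GenotypeDataset, alpha: float = 0.001):
    """Remove markers whose pooled exact Hardy-Weinberg p-value is below
    ``alpha``.  Missing calls are ignored; monomorphic markers pass."""
    pvals = np.empty(ds.n_markers)
    for j in range(ds.n_markers):
        col = ds.calls[:, j]
        col = col[col != io.MISSING]
        pvals[j] = hwe_exact_pvalue(int((col == 0).sum()),
                                    int((col == 1).sum()),
                                    int((col == 2).sum()))
    keep = pvals >= alpha
    out = ds.subset(marker_mask=keep)
    report = QCReport(
        n_markers_in=ds.n_markers, n_markers_out=out.n_markers,
        n_individuals_in=ds.n_individuals, n_individuals_out=ds.n_individuals,
        removed={"marker_hwe": int((~keep).sum())},
        hwe_pvalues=pd.Series(pvals, index=ds.markers.marker_id),
    )
    return out, report


def allele_frequencies(ds: GenotypeDataset, maf_min: float = 0.01):
    """Pooled per-marker B-allele frequency and a low-MAF mask.

    Masked markers (MAF below ``maf_min``, or no non-missing calls —
    frequency NaN) are kept in the map but treated as uninformative by
    the HMM, which preserves coordinates and ROH lengths.
    """
    valid = ds.calls != io.MISSING
    n_alleles = 2 * valid.sum(axis=0)
    b_count = np.where(valid, ds.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, b_count / np.maximum(n_alleles, 1),
                        np.nan)
    freq = np.where(n_alleles > 0, freq, np.nan)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    mask = ~(maf >= maf_min)     # NaN compares False, hence masked
    n_undef = int(np.isnan(freq).sum())
    if n_undef:
        logger.warning("%d markers have no non-missing calls; frequency "
                       "undefined, marker masked as uninformative", n_undef)
    return freq, mask


def run_qc(ds: GenotypeDataset, max_ind_missing: float = 0.04,
           max_marker_missing: float = 0.02, hwe_alpha: float = 0.001,
           maf_min: float = 0.01):
    """Full QC chain: call-rate filters, HWE filter, allele frequencies.

    Returns ``(dataset, report)`` where the dataset's marker map carries
    the pooled frequencies and the report merges all per-filter counts.
    """
    ds1, r1 = apply_callrate_filters(ds, max_ind_missing, max_marker_missing)
    ds2, r2 = hwe_filter(ds1, hwe_alpha)
    freq, mask = allele_frequencies(ds2, maf_min)
    ds2 = GenotypeDataset(ds2.individuals, ds2.labels,
                          ds2.markers.with_freq(freq), ds2.calls)
    report = QCReport(
        n_markers_in=ds.n_markers, n_markers_out=ds2.n_markers,
        n_individuals_in=ds.n_individuals, n_individuals_out=ds2.n_individuals,
        removed={**r1.removed, **r2.removed},
        hwe_pvalues=r2.hwe_pvalues,
        maf=pd.Series(np.minimum(freq, 1.0 - freq),
                      index=ds2.markers.marker_id),
    )
    return ds2, report
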