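"""Readers and writers for the plain-text formats used by the pipeline.

Formats
-------
PED/MAP
    White-space-delimited PLINK text dialect.  PED rows are
    ``family id father mother sex phenotype`` followed by two alleles per
    marker; ``0 0`` marks a missing call.  MAP rows are
    ``chrom marker_id cm bp`` with 1-based bp positions.
Intensity TSV
    Long table ``marker  individual  lrr  baf``.
CNV TSV
    ``chrom  start  end  cn  individual`` with 0-based half-open intervals.
BED
    0-based half-open, tab separated, used for truth segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markers import MarkerMap

MISSING = -1  # genotype code for a missing call (otherwise B-allele dosage 0/1/2)


# ----------------------------------------------------------------------
# PED / MAP
# ----------------------------------------------------------------------

def read_map_table(map_path) -> pd.DataFrame:
    """MAP file as a raw table (bp still 1-based, original row order)."""
    return pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "marker_id", "cm", "bp"],
                       dtype={"chrom": str, "marker_id": str})


def map_from_table(df: pd.DataFrame) -> MarkerMap:
    return MarkerMap(df["chrom"].to_numpy(dtype=object),
                     df["marker_id"].to_numpy(dtype=object),
                     df["bp"].to_numpy(dtype=np.int64) - 1,  # 1-based -> 0-based
                     df["cm"].to_numpy(dtype=np.float64))


def write_map(marker_map: MarkerMap, map_path) -> None:
    with open(map_path, "w") as fh:
        for c, mid, cm, bp in zip(marker_map.chrom, marker_map.marker_id,
                                  marker_map.cm, marker_map.bp):
            fh.write(f"{c}\t{mid}\t{cm:.8g}\t{bp + 1}\n")


def read_ped(ped_path, n_markers: int):
    """Parse a PED file into ids, labels and a B-allele dosage matrix.

    Allele letters are recoded per marker: with the A/B dialect B counts
    toward the dosage; with nucleotide alleles the alphabetically later
    of the two observed alleles is taken as B.  More than two distinct
    alleles at a marker is an error.
    """
    ids, labels, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_markers} for {n_markers} markers")
            labels.append(fields[0])
            ids.append(fields[1])
            rows.append(np.array(fields[6:], dtype=object))
    if not ids:
        raise ValueError(f"{ped_path}: no genotype rows")
    alleles = np.stack(rows)                       # (n, 2m)
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    calls = np.zeros(a1.shape, dtype=np.int8)
    for j in range(n_markers):
        col = np.concatenate([a1[:, j], a2[:, j]])
        seen = sorted(set(col.tolist()) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"{ped_path}: marker column {j + 1} has more than "
                             f"two alleles: {seen}")
        b = "B" if set(seen) <= {"A", "B"} else seen[-1]
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        calls[:, j] = (a1[:, j] == b).astype(np.int8) + (a2[:, j] == b).astype(np.int8)
        calls[miss, j] = MISSING
    return ids, labels, calls


def write_ped(calls: np.ndarray, individuals, labels, ped_path) -> None:
    coded = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, (iid, lab) in enumerate(zip(individuals, labels)):
            geno = "\t".join(coded[int(g)] for g in calls[i])
            fh.write(f"{lab}\t{iid}\t0\t0\t0\t-9\t{geno}\n")


# ----------------------------------------------------------------------
# Intensity / CNV / BED
# ----------------------------------------------------------------------

def write_intensity(marker_map: MarkerMap, individuals, lrr, baf, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tindividual\tlrr\tbaf\n")
        for i, iid in enumerate(individuals):
            for j, mid in enumerate(marker_map.marker_id):
                fh.write(f"{mid}\t{iid}\t{lrr[i, j]:.5f}\t{baf[i, j]:.5f}\n")


def read_intensity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"marker": str, "individual": str,
                              "lrr": float, "baf": float})


def write_cnv_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcn\tindividual\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cn}\t{c.individual}\n")


def read_cnv_calls(path) -> list:
    from .cnv import CNVCall
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
    return [CNVCall(individual=r.individual, chrom=r.chrom, start=int(r.start),
                    end=int(r.end), cn=int(r.cn))
            for r in df.itertuples(index=False)]


def write_bed(rows, path) -> None:
    """Write 0-based half-open intervals; ``rows`` yields tuples whose first
    three entries are chrom, start, end."""
    with open(path, "w") as fh:
        for row in rows:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            if start >= end or start < 0:
                raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
            rest = "".join(f"\t{x}" for x in row[3:])
            fh.write(f"{chrom}\t{start}\t{end}{rest}\n")
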