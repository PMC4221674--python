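"""Plain-text genomic I/O: minimal BED6, GFF3 and interval overlap counting.

All coordinates are 0-based half-open internally (the BED convention); GFF3
is converted from/to 1-based closed on read/write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(frame: pd.DataFrame, path) -> None:
    """Write intervals as 6-column BED; missing name/score/strand are filled."""
    out = frame.copy()
    if "name" not in out:
        out["name"] = [f"iv{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame.columns = BED_COLUMNS[: frame.shape[1]]
    return frame


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write a gene annotation as minimal GFF3 (one ``gene`` feature per row).

    Input uses 0-based half-open [start, end); GFF3 stores 1-based closed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\tplastinet\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 back to 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", attrs.get("Name", "")),
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                }
            )
    return pd.DataFrame(rows)


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation from BED or GFF3, sniffed by content."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or "\tgene\t" in first:
        return read_gff3(path)
    frame = read_bed(path)
    frame = frame.rename(columns={"name": "gene_id"})
    return frame[["gene_id", "chrom", "start", "end"] + (["strand"] if "strand" in frame else [])]


def count_overlaps(
    intervals: pd.DataFrame, reads: pd.DataFrame, min_overlap_bp: int = 1
) -> np.ndarray:
    """Count reads overlapping each interval by >= ``min_overlap_bp``.

    Both frames carry chrom/start/end in 0-based half-open coordinates.  A
    sort + searchsorted sweep per chromosome; suitable for the moderate
    interval counts this pipeline handles.
    """
    counts = np.zeros(len(intervals), dtype=int)
    if len(reads) == 0 or len(intervals) == 0:
        return counts
    for chrom, read_grp in reads.groupby("chrom", sort=False):
        mask = (intervals["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        iv_start = intervals.loc[mask, "start"].to_numpy()
        iv_end = intervals.loc[mask, "end"].to_numpy()
        r_start = np.sort(read_grp["start"].to_numpy())
        r_end = read_grp["end"].to_numpy()[np.argsort(read_grp["start"].to_numpy(), kind="mergesort")]
        # overlap(iv, read) >= m  <=>  min(iv.end, r.end) - max(iv.start, r.start) >= m
        sub = np.zeros(mask.sum(), dtype=int)
        for i in range(len(iv_start)):
            lo = np.searchsorted(r_start, iv_start[i] - (r_end - r_start).max(), side="left")
            hi = np.searchsorted(r_start, iv_end[i] - min_overlap_bp, side="right")
            if hi <= lo:
                continue
            s = r_start[lo:hi]
            e = r_end[lo:hi]
            ov = np.minimum(iv_end[i], e) - np.maximum(iv_start[i], s)
            sub[i] = int((ov >= min_overlap_bp).sum())
        counts[np.where(mask)[0]] = sub
    return counts


def complement_intervals(
    intervals: pd.DataFrame, chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Genomic space not covered by ``intervals``, per chromosome."""
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = intervals[intervals["chrom"] == chrom].sort_values("start")
        cursor = 0
        for row in sub.itertuples():
            start = max(0, int(row.start))
            if start > cursor:
                rows.append({"chrom": chrom, "start": cursor, "end": start})
            cursor = max(cursor, int(row.end))
        if cursor < size:
            rows.append({"chrom": chrom, "start": cursor, "end": size})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def tile_intervals(intervals: pd.DataFrame, bin_bp: int) -> pd.DataFrame:
    """Cut intervals into successive bins of at most ``bin_bp`` bp."""
    rows = []
    for row in intervals.itertuples():
        pos = int(row.start)
        while pos < row.end:
            end = min(pos + bin_bp, int(row.end))
            rows.append({"chrom": row.chrom, "start": pos, "end": end})
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
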