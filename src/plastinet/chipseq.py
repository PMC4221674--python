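"""ChIP peak consolidation and signal normalization.

Turns per-sample peak calls plus read intervals into a background-corrected,
quantile-normalized peak-by-sample signal matrix ready for the differential
engine, and assigns candidate genes within a 2 kb window of each peak.

Merging rule: peaks from different samples are single-linkage clustered by
>= ``min_overlap_bp`` intersection; a merged peak (the union interval) is
kept only if it is supported by at least two distinct samples and its width
exceeds 146 bp, the span wrapped by one nucleosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffstat, io


def _merge_within_sample(peaks: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping intervals inside one sample (one contribution each)."""
    rows = []
    for chrom, grp in peaks.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for row in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end = int(row.start), int(row.end)
            elif int(row.start) < cur_end:  # >=1 bp overlap
                cur_end = max(cur_end, int(row.end))
            else:
                rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
                cur_start, cur_end = int(row.start), int(row.end)
        if cur_start is not None:
            rows.append({"chrom": chrom, "start": cur_start, "end": cur_end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge_peaks(
    peaks_by_sample: dict[str, pd.DataFrame],
    min_overlap_bp: int = 1,
    min_support: int = 2,
    min_width_bp: int = 147,
) -> pd.DataFrame:
    """Cross-sample consensus peaks.

    Overlapping calls within one sample are merged first and count as a single
    contribution.  Pooled intervals are then chained whenever consecutive
    intervals (sorted by start) intersect the growing cluster union by
    >= ``min_overlap_bp``; because every member overlaps the union when added,
    the union is a contiguous interval and the sweep realizes single linkage.

    Returns peak_id / chrom / start / end / support (distinct samples) /
    n_members, sorted by coordinate; filtered to support >= ``min_support``
    and width >= ``min_width_bp``.
    """
    pooled = []
    for sample_id in sorted(peaks_by_sample):
        merged = _merge_within_sample(peaks_by_sample[sample_id])
        merged["sample_id"] = sample_id
        pooled.append(merged)
    if not pooled:
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end", "support", "n_members"])
    pool = pd.concat(pooled, ignore_index=True)

    clusters = []
    for chrom, grp in pool.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for row in grp.itertuples():
            if cur is None:
                cur = {"chrom": chrom, "start": int(row.start), "end": int(row.end), "samples": {row.sample_id}, "n": 1}
            elif min(cur["end"], int(row.end)) - max(cur["start"], int(row.start)) >= min_overlap_bp:
                cur["end"] = max(cur["end"], int(row.end))
                cur["samples"].add(row.sample_id)
                cur["n"] += 1
            else:
                clusters.append(cur)
                cur = {"chrom": chrom, "start": int(row.start), "end": int(row.end), "samples": {row.sample_id}, "n": 1}
        if cur is not None:
            clusters.append(cur)

    rows = [
        {
            "chrom": c["chrom"],
            "start": c["start"],
            "end": c["end"],
            "support": len(c["samples"]),
            "n_members": c["n"],
        }
        for c in clusters
        if len(c["samples"]) >= min_support and (c["end"] - c["start"]) >= min_width_bp
    ]
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "support", "n_members"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "peak_id", [f"peak{i:04d}" for i in range(len(out))])
    return out


def count_and_fpkm(
    merged: pd.DataFrame,
    reads_by_sample: dict[str, pd.DataFrame] | None,
    library_sizes: dict[str, int],
    counts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read counts and FPKM over the merged peaks.

    FPKM(peak, sample) = count / ((width / 1e3) * (library_size / 1e6)).
    Either read intervals (counted by >=1 bp overlap) or a precomputed
    peak-by-sample count matrix may be supplied.
    """
    if any(v <= 0 for v in library_sizes.values()):
        raise ValueError("library sizes must be positive")
    if counts is None:
        if reads_by_sample is None:
            raise ValueError("need reads_by_sample or counts")
        counts = pd.DataFrame(
            {
                sample: io.count_overlaps(merged, reads)
                for sample, reads in reads_by_sample.items()
            },
            index=merged["peak_id"],
        )
    widths = (merged["end"] - merged["start"]).to_numpy(dtype=float)
    fpkm = counts.astype(float).copy()
    for sample in fpkm.columns:
        fpkm[sample] = counts[sample].to_numpy() / (
            (widths / 1_000.0) * (library_sizes[sample] / 1e6)
        )
    return counts, fpkm


@dataclass
class BackgroundModel:
    """Per-sample median FPKM over fixed-width non-peak bins."""

    median_fpkm: dict[str, float]
    bin_bp: int
    n_bins: int


def background_correct(
    fpkm: pd.DataFrame,
    reads_by_sample: dict[str, pd.DataFrame],
    merged: pd.DataFrame,
    chrom_sizes: dict[str, int],
    library_sizes: dict[str, int],
    bin_bp: int = 1_000,
    normalize: bool = True,
) -> tuple[pd.DataFrame, BackgroundModel]:
    """Subtract each sample's background level and quantile-normalize.

    The background level is the median FPKM over ``bin_bp`` bins tiling the
    genomic space outside the merged peaks.  Corrected signal is floored at 0
    (negative enrichment is not meaningful), then columns are quantile
    normalized so the per-peak values are comparable across samples.
    """
    non_peak = io.complement_intervals(merged, chrom_sizes)
    if non_peak.empty:
        raise ValueError("no non-peak space to estimate background from")
    bins = io.tile_intervals(non_peak, bin_bp)
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    medians = {}
    for sample in fpkm.columns:
        counts = io.count_overlaps(bins, reads_by_sample[sample])
        bin_fpkm = counts / ((widths / 1_000.0) * (library_sizes[sample] / 1e6))
        medians[sample] = float(np.median(bin_fpkm))
    corrected = fpkm.copy()
    for sample in corrected.columns:
        corrected[sample] = np.maximum(fpkm[sample] - medians[sample], 0.0)
    if normalize and corrected.shape[0] > 0:
        corrected = diffstat.quantile_normalize(corrected)
    model = BackgroundModel(median_fpkm=medians, bin_bp=bin_bp, n_bins=len(bins))
    return corrected, model


def assign_genes(
    merged: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = 2_000
) -> pd.DataFrame:
    """Candidate genes per peak: gene span +- ``window_bp`` intersects the peak.

    Strand is ignored; a peak may receive many genes and a gene many peaks.
    Returns a peak_id / gene_id mapping.
    """
    rows = []
    for chrom, genes in annotation.groupby("chrom", sort=False):
        peaks = merged[merged["chrom"] == chrom]
        if peaks.empty:
            continue
        g_start = genes["start"].to_numpy() - window_bp
        g_end = genes["end"].to_numpy() + window_bp
        for peak in peaks.itertuples():
            hits = (g_start < peak.end) & (g_end > peak.start)
            for gid in genes.loc[hits, "gene_id"]:
                rows.append({"peak_id": peak.peak_id, "gene_id": gid})
    return pd.DataFrame(rows, columns=["peak_id", "gene_id"])


def chip_signal_pipeline(
    peaks_by_sample: dict[str, pd.DataFrame],
    reads_by_sample: dict[str, pd.DataFrame],
    library_sizes: dict[str, int],
    chrom_sizes: dict[str, int],
    annotation: pd.DataFrame | None = None,
    min_overlap_bp: int = 1,
    min_support: int = 2,
    min_width_bp: int = 147,
    window_bp: int = 2_000,
    bin_bp: int = 1_000,
    normalize: bool = True,
) -> dict:
    """merge -> count -> FPKM -> background-correct -> assign genes.

    ``normalize=False`` skips the final quantile normalization; useful when
    the condition effect is expected to shift whole-column distributions
    (rank-preserving shifts are invisible to quantile normalization).
    """
    merged = merge_peaks(peaks_by_sample, min_overlap_bp, min_support, min_width_bp)
    counts, fpkm = count_and_fpkm(merged, reads_by_sample, library_sizes)
    corrected, background = background_correct(
        fpkm, reads_by_sample, merged, chrom_sizes, library_sizes, bin_bp,
        normalize=normalize,
    )
    peak2gene = (
        assign_genes(merged, annotation, window_bp) if annotation is not None else None
    )
    return {
        "merged": merged,
        "counts": counts,
        "fpkm": fpkm,
        "signal": corrected,
        "background": background,
        "peak2gene": peak2gene,
    }
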