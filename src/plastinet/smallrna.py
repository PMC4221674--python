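"""Small-RNA read-length profiling and degradation-fragment calling.

Small-RNA libraries show two canonical length modes: ~22 nt (miRNAs) and
~30 nt (rasiRNAs, the fly piRNA equivalent).  A transient 15-18 nt component
appearing only in young mated females reflects degradation of maternal mRNA
during the maternal-to-zygotic transition; genes shedding such fragments
exclusively in that condition are called here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import io
from .design import SampleDesign


@dataclass(frozen=True)
class FragmentClassSpec:
    """Length windows for the three small-RNA classes (nt, inclusive)."""

    degradation: tuple[int, int] = (15, 18)
    mirna_center: int = 22
    mirna_halfwidth: int = 3
    rasirna_center: int = 30
    rasirna_halfwidth: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.degradation
        if lo <= 0 or hi < lo:
            raise ValueError("degradation window must be positive and ordered")
        windows = [
            (lo, hi),
            (self.mirna_center - self.mirna_halfwidth, self.mirna_center + self.mirna_halfwidth),
            (self.rasirna_center - self.rasirna_halfwidth, self.rasirna_center + self.rasirna_halfwidth),
        ]
        windows.sort()
        for (a_lo, a_hi), (b_lo, b_hi) in zip(windows, windows[1:]):
            if b_lo <= a_hi:
                raise ValueError("length-class windows must not overlap")

    def in_degradation_window(self, lengths: pd.Series) -> pd.Series:
        lo, hi = self.degradation
        return (lengths >= lo) & (lengths <= hi)


def length_histogram(reads: pd.DataFrame) -> pd.Series:
    """Read counts per length, zero-filled over the observed length range."""
    if reads.empty:
        return pd.Series(dtype=int, name="count")
    lengths = reads["length"].astype(int)
    if (lengths < 1).any():
        raise ValueError("read lengths must be >= 1")
    counts = lengths.value_counts()
    full = range(int(lengths.min()), int(lengths.max()) + 1)
    hist = counts.reindex(full, fill_value=0).sort_index()
    hist.name = "count"
    hist.index.name = "length"
    return hist


def fragment_counts_per_gene(
    reads_by_sample: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    spec: FragmentClassSpec = FragmentClassSpec(),
) -> pd.DataFrame:
    """Degradation-window fragment counts per gene x sample.

    A fragment counts toward a gene if its interval intersects the gene span
    by at least 1 bp; strand is ignored.
    """
    if annotation["gene_id"].duplicated().any():
        raise ValueError("duplicated gene ids in annotation")
    genes = annotation.reset_index(drop=True)
    out = pd.DataFrame(index=genes["gene_id"])
    for sample, reads in reads_by_sample.items():
        frag = reads[spec.in_degradation_window(reads["length"])]
        out[sample] = io.count_overlaps(genes, frag)
    return out


def call_degradation_genes(
    reads_by_sample: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    design: SampleDesign,
    spec: FragmentClassSpec = FragmentClassSpec(),
    min_reads: int = 1,
    require_all_replicates: bool = True,
) -> pd.DataFrame:
    """Genes shedding 15-18 nt fragments exclusively in young mated females.

    A gene is called iff it has >= ``min_reads`` degradation-window fragments
    in every young-mated replicate (or at least one replicate when
    ``require_all_replicates`` is False) AND exactly zero such fragments in
    every other sample.  Returns called genes with their per-sample fragment
    counts and an ``exclusive`` flag that is True for every call by
    construction.
    """
    counts = fragment_counts_per_gene(reads_by_sample, annotation, spec)
    ym = design.samples_in("young_mated")
    others = [s for s in design.sample_ids if s not in ym]
    missing = [s for s in ym + others if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from reads: {missing}")

    present = counts[ym] >= min_reads
    in_ym = present.all(axis=1) if require_all_replicates else present.any(axis=1)
    clean_elsewhere = (counts[others] == 0).all(axis=1) if others else True
    called = counts[in_ym & clean_elsewhere].copy()
    called["exclusive"] = True
    called.insert(0, "gene_id", called.index)
    return called.reset_index(drop=True)
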