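"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design every stage is keyed on: four
physiological conditions (young/aged x virgin/mated females) with two
replicate pools each.  It produces

* negative-binomial feature-by-sample count tables with planted condition
  effects, including an on/off "maternal-cluster-like" miRNA expressed only
  in mated flies;
* per-sample ChIP peak calls (jittered copies of master intervals, widths
  straddling the 146 bp mono-nucleosome span) with read-level signal and
  uniform background reads, including planted persistent and
  accelerated-aging amplitude patterns;
* length-tagged small-RNA reads with modes at 22 nt (miRNA) and 30 nt
  (rasiRNA) plus a 15-18 nt degradation component confined to designated
  source genes in young mated samples only;
* miRNA->target and gene-gene interaction tables with partner link counts
  planted to exercise the network filter;
* replicate egg-laying counts for miRNA overexpression lines with planted
  percent effects.

All randomness flows from one master seed through named substreams, so a
fixed (seed, config) pair is byte-identical across runs.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, CONTRASTS, SampleDesign, make_design

_MATED = ("young_mated", "aged_mated")


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child stream of the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass
class SimulationConfig:
    """Knobs for every synthetic stage; defaults mirror the study design."""

    seed: int = 0
    n_replicates: int = 2

    # count model
    n_features: int = 200
    frac_plastic: float = 0.05
    lfc: float = 2.0  # planted log2 fold change in target conditions
    baseline_mean: float = 100.0
    mean_log_sigma: float = 1.0  # lognormal spread of per-feature baselines
    dispersion: float = 0.05  # NB dispersion; 0 => noise-free rounded means
    n_onoff: int = 1  # maternal-cluster-like on/off features (mated only)

    # genome model
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (1_000, 4_000)

    # ChIP peak model
    n_null_peaks: int = 20
    n_marker_peaks: int = 5  # accelerated-aging pattern
    n_persistent_only_peaks: int = 4  # persists in mated flies, no virgin aging
    n_reverting_peaks: int = 3  # reverses between young and aged mated
    n_narrow_peaks: int = 3  # merged width <= 146, removed by the width filter
    n_singleton_peaks: int = 3  # present in one sample only
    peak_width_range: tuple[int, int] = (180, 400)
    # narrow masters stay <=100 bp so +-jitter cannot push the union past 146
    narrow_width_range: tuple[int, int] = (60, 100)
    peak_jitter_bp: int = 20
    peak_base_reads: int = 2_000  # planted-pattern peak amplitude
    null_base_range: tuple[int, int] = (80, 400)  # null-peak amplitude spread
    peak_fold: float = 4.0
    read_length: int = 50
    n_background_reads: int = 3_000
    # total mapped reads per sample; the simulated intervals are a small part
    # of a library, so depth is a property of sequencing, not of the biology
    library_size: int = 1_000_000
    recurrence_frac: float = 1.0  # fraction of non-singleton peaks in all samples

    # small-RNA model
    n_smallrna_reads: int = 4_000
    mirna_len_center: int = 22
    rasirna_len_center: int = 30
    degradation_len_range: tuple[int, int] = (15, 18)
    degradation_weight: float = 0.15  # mixture weight in young mated samples
    n_degradation_genes: int = 5

    # interaction model
    n_mirnas: int = 6
    n_plastic_mirnas: int = 3
    targets_per_mirna: int = 3
    n_partners_multi: int = 4  # partners linked to >=2 targets
    n_partners_single: int = 3  # partners linked to exactly 1 target
    n_decoy_edges: int = 5  # interactions among non-target genes

    # oviposition model (percent effects of overexpression on eggs laid)
    egg_control_mean: float = 250.0
    egg_sd: float = 25.0
    egg_n_replicates: int = 10
    egg_effects: dict = field(
        default_factory=lambda: {
            "mir-286": 16.0,
            "mir-34": -34.0,
            "mir-92b": -37.0,
            "mir-988": 33.0,
        }
    )

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates")
        if min(self.gene_length_range) <= 0 or self.chrom_length <= 0:
            raise ValueError("genome lengths must be positive")
        lo, hi = self.degradation_len_range
        if not (0 < lo <= hi < self.mirna_len_center):
            raise ValueError("degradation window must be positive and below the miRNA mode")


def simulate_design(n_replicates: int = 2) -> SampleDesign:
    """The 4 x n_replicates factorial sample layout."""
    return make_design(n_replicates)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2.

    dispersion == 0 degrades to the noise-free rounded mean, which gives the
    exact-recovery regime used by zero-noise tests.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(int)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    config: SimulationConfig, kind: str = "mirna", design: SampleDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-by-sample counts with planted condition effects.

    Each planted feature receives the configured log2 fold change in a random
    nonempty proper subset of the four conditions; null features are
    exchangeable across conditions.  ``n_onoff`` extra features follow the
    maternal-cluster pattern: expressed in mated conditions, absent in
    virgins.

    Returns (counts, truth).  Truth has one row per feature with the planted
    condition set, effect size and the implied per-contrast plasticity flags.
    """
    config.validate()
    if design is None:
        design = simulate_design(config.n_replicates)
    rng = substream(config.seed, f"counts:{kind}")

    n = config.n_features
    n_plastic = int(round(config.frac_plastic * n))
    feature_ids = [f"{kind}{i:04d}" for i in range(n)]
    base_means = rng.lognormal(np.log(config.baseline_mean), config.mean_log_sigma, size=n)

    plastic_idx = rng.choice(n, size=n_plastic, replace=False)
    target_sets: list[frozenset[str]] = [frozenset() for _ in range(n)]
    subsets = [
        frozenset(s)
        for r in range(1, len(CONDITIONS))
        for s in itertools.combinations(CONDITIONS, r)
    ]
    for i in plastic_idx:
        target_sets[i] = subsets[rng.integers(len(subsets))]

    rows = []
    mean_matrix = np.empty((n, len(design.samples)))
    for i in range(n):
        fold = 2.0**config.lfc
        for j, cond in enumerate(design.condition_labels):
            mean_matrix[i, j] = base_means[i] * (fold if cond in target_sets[i] else 1.0)

    # maternal-cluster-like on/off features: high in mated, zero in virgin
    onoff_ids = []
    for k in range(config.n_onoff):
        fid = f"{kind}_onoff{k}"
        onoff_ids.append(fid)
        feature_ids.append(fid)
        mean_row = np.array(
            [config.baseline_mean * 4 if c in _MATED else 0.0 for c in design.condition_labels]
        )
        mean_matrix = np.vstack([mean_matrix, mean_row])
        target_sets.append(frozenset(_MATED))

    counts = _nb_draw(rng, mean_matrix, config.dispersion)
    counts_df = pd.DataFrame(counts, index=feature_ids, columns=design.sample_ids)
    counts_df.index.name = "feature"

    for i, fid in enumerate(feature_ids):
        tset = target_sets[i]
        record = {
            "feature": fid,
            "condition_set": ",".join(sorted(tset)),
            "lfc": config.lfc if tset else 0.0,
            "is_onoff": fid in onoff_ids,
        }
        for name, plus, minus in CONTRASTS:
            record[f"{name}_plastic"] = (plus in tset) != (minus in tset)
        rows.append(record)
    truth = pd.DataFrame(rows)
    return counts_df, truth


def simulate_genome(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Non-overlapping gene annotation on a toy genome.

    Genes are laid out left to right with random lengths and random gaps so
    they never overlap; coordinates are 0-based half-open.
    """
    config.validate()
    rng = substream(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: config.chrom_length for c in chroms}
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    rows = []
    gid = 0
    for chrom in chroms:
        cursor = 2_000
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length_range))
            gap = int(rng.integers(1_000, 4_000))
            start = cursor + gap
            end = start + length
            if end > config.chrom_length - 2_000:
                break
            rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            cursor = end
            gid += 1
    return pd.DataFrame(rows), chrom_sizes


def _peak_pattern(pattern: str, fold: float) -> dict[str, float]:
    """Amplitude multipliers per condition for each planted ChIP pattern.

    "marker": up after mating in young flies, the same change with aging in
    virgins, and no reversal in mated flies -- the accelerated-aging
    signature.  "persistent": up after mating and maintained in mated flies,
    but no virgin-aging change.  "reverting": up after mating, reversed back
    down in aged mated flies.

    The non-tied multipliers are deliberately slightly distinct so that at
    zero noise a planted feature has distinct per-condition values: its
    permutation null then ties only under the 4! group relabelings, keeping
    the attainable p-value at its combinatorial minimum.
    """
    if pattern == "null":
        return {c: 1.0 for c in CONDITIONS}
    if pattern == "marker":
        return {
            "young_virgin": 1.0,
            "young_mated": fold,
            "aged_virgin": 1.05 * fold,
            "aged_mated": 1.10 * fold,
        }
    if pattern == "persistent":
        return {
            "young_virgin": 1.0,
            "young_mated": fold,
            "aged_virgin": 1.0,
            "aged_mated": 1.05 * fold,
        }
    if pattern == "reverting":
        return {
            "young_virgin": 1.0,
            "young_mated": fold,
            "aged_virgin": 0.9,
            "aged_mated": 1.1,
        }
    raise ValueError(pattern)


def simulate_peaks(
    config: SimulationConfig,
    design: SampleDesign | None = None,
    annotation: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """Per-sample ChIP peak calls, reads and planted truth.

    Master intervals are placed in the gaps between genes (within 2 kb of a
    gene where possible, so gene assignment is exercised); each sample's call
    is the master interval jittered by up to ``peak_jitter_bp``.  Read
    intervals are generated inside each called peak at a condition-dependent
    rate, plus uniform background reads.

    Returns a dict with per-sample ``peaks`` (DataFrames), ``reads``
    (DataFrames of read intervals), ``library_sizes``, the ``truth`` master
    table and ``chrom_sizes``.
    """
    config.validate()
    if design is None:
        design = simulate_design(config.n_replicates)
    if annotation is None or chrom_sizes is None:
        annotation, chrom_sizes = simulate_genome(config)
    rng = substream(config.seed, "peaks")

    patterns = (
        ["marker"] * config.n_marker_peaks
        + ["persistent"] * config.n_persistent_only_peaks
        + ["reverting"] * config.n_reverting_peaks
        + ["null"] * config.n_null_peaks
    )
    widths = [int(rng.integers(*config.peak_width_range)) for _ in patterns]
    # narrow peaks exercise the width filter; singleton peaks the support filter
    patterns += ["narrow"] * config.n_narrow_peaks
    widths += [int(rng.integers(*config.narrow_width_range)) for _ in range(config.n_narrow_peaks)]
    patterns += ["singleton"] * config.n_singleton_peaks
    widths += [int(rng.integers(*config.peak_width_range)) for _ in range(config.n_singleton_peaks)]

    genes = annotation.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    if len(genes) < len(patterns):
        raise ValueError("need at least one gene per master peak")
    base_reads = {}
    rows = []
    for i, (pattern, width) in enumerate(zip(patterns, widths)):
        # each master sits downstream of its own gene, so masters never overlap
        gene = genes.iloc[i]
        start = int(gene["end"]) + int(rng.integers(100, 800))  # within the 2 kb flank
        base_reads[f"master{i:03d}"] = (
            config.peak_base_reads
            if pattern in ("marker", "persistent", "reverting")
            else int(rng.integers(*config.null_base_range))
        )
        rows.append(
            {
                "peak_id": f"master{i:03d}",
                "chrom": gene["chrom"],
                "start": start,
                "end": start + width,
                "pattern": pattern,
                "is_marker": pattern == "marker",
                "is_persistent": pattern in ("marker", "persistent"),
                "near_gene": gene["gene_id"],
            }
        )
    truth = pd.DataFrame(rows)

    peaks_by_sample: dict[str, pd.DataFrame] = {}
    reads_by_sample: dict[str, pd.DataFrame] = {}
    library_sizes: dict[str, int] = {}
    n_samples = len(design.samples)
    shared_mask = rng.random(len(truth)) < config.recurrence_frac
    singleton_owner = rng.integers(n_samples, size=len(truth))

    for s_idx, sample in enumerate(design.samples):
        sample_peaks = []
        read_rows = []
        for p_idx, master in enumerate(truth.itertuples()):
            if master.pattern == "singleton":
                present = s_idx == singleton_owner[p_idx]
            elif shared_mask[p_idx]:
                present = True
            else:  # non-recurrent: confine to one sample
                present = s_idx == singleton_owner[p_idx]
            if not present:
                continue
            jitter = config.peak_jitter_bp
            start = int(master.start + rng.integers(-jitter, jitter + 1)) if jitter else int(master.start)
            end = int(master.end + rng.integers(-jitter, jitter + 1)) if jitter else int(master.end)
            if end - start < 10:
                end = start + 10
            if master.pattern in ("marker", "persistent", "reverting"):
                mult = _peak_pattern(master.pattern, config.peak_fold)[sample.condition]
            else:
                mult = 1.0
            n_reads = int(
                _nb_draw(rng, np.array([base_reads[master.peak_id] * mult]), config.dispersion)[0]
            )
            sample_peaks.append(
                {
                    "chrom": master.chrom,
                    "start": start,
                    "end": end,
                    "name": f"{sample.sample_id}:{master.peak_id}",
                    "score": n_reads,
                }
            )
            if n_reads > 0:
                span = max(1, end - start - config.read_length)
                starts = rng.integers(start, start + span, size=n_reads)
                for rs in starts:
                    read_rows.append(
                        {"chrom": master.chrom, "start": int(rs), "end": int(rs) + config.read_length}
                    )
        # uniform background reads across the genome
        chroms = list(chrom_sizes)
        bg_chrom = rng.integers(len(chroms), size=config.n_background_reads)
        for ci in range(len(chroms)):
            n_bg = int((bg_chrom == ci).sum())
            starts = rng.integers(0, chrom_sizes[chroms[ci]] - config.read_length, size=n_bg)
            for rs in starts:
                read_rows.append(
                    {"chrom": chroms[ci], "start": int(rs), "end": int(rs) + config.read_length}
                )
        peaks_by_sample[sample.sample_id] = pd.DataFrame(
            sample_peaks, columns=["chrom", "start", "end", "name", "score"]
        )
        reads = pd.DataFrame(read_rows, columns=["chrom", "start", "end"])
        reads_by_sample[sample.sample_id] = reads
        library_sizes[sample.sample_id] = config.library_size

    return {
        "design": design,
        "annotation": annotation,
        "chrom_sizes": chrom_sizes,
        "peaks": peaks_by_sample,
        "reads": reads_by_sample,
        "library_sizes": library_sizes,
        "truth": truth,
    }


def simulate_smallrna_reads(
    config: SimulationConfig,
    design: SampleDesign | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Length-tagged small-RNA read intervals per sample.

    Lengths are a discrete mixture with modes at 22 nt (miRNA-like, support
    19-26) and 30 nt (rasiRNA-like, support 27-33).  In young mated samples an
    extra 15-18 nt degradation component is placed strictly inside designated
    source genes; no other sample receives any read in that window, matching
    fragments that appear only in young flies after mating.

    Returns (reads_by_sample, truth) where truth lists the degradation source
    genes.
    """
    config.validate()
    if design is None:
        design = simulate_design(config.n_replicates)
    if annotation is None:
        annotation, _ = simulate_genome(config)
    if annotation.empty:
        raise ValueError("annotation must be non-empty")
    rng = substream(config.seed, "smallrna")

    source = annotation.sample(
        n=min(config.n_degradation_genes, len(annotation)),
        random_state=int(rng.integers(2**31)),
    ).reset_index(drop=True)

    def _mode_lengths(center: int, size: int) -> np.ndarray:
        offsets = np.clip(np.rint(rng.normal(0, 1.2, size=size)).astype(int), -3, 3)
        return center + offsets

    reads_by_sample: dict[str, pd.DataFrame] = {}
    chroms = annotation["chrom"].unique()
    for sample in design.samples:
        n_total = config.n_smallrna_reads
        is_ym = sample.condition == "young_mated"
        w_deg = config.degradation_weight if is_ym else 0.0
        n_deg = int(round(n_total * w_deg))
        n_mirna = int(round((n_total - n_deg) * 0.65))
        n_rasi = n_total - n_deg - n_mirna

        rows = []
        lengths = np.concatenate(
            [
                _mode_lengths(config.mirna_len_center, n_mirna),
                _mode_lengths(config.rasirna_len_center, n_rasi),
            ]
        )
        # background reads placed uniformly, positions independent of genes
        for ln in lengths:
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, config.chrom_length - int(ln)))
            rows.append({"chrom": chrom, "start": start, "end": start + int(ln), "length": int(ln)})
        if n_deg:
            lo, hi = config.degradation_len_range
            for _ in range(n_deg):
                gene = source.iloc[int(rng.integers(len(source)))]
                ln = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(gene["start"], max(gene["start"] + 1, gene["end"] - ln)))
                rows.append({"chrom": gene["chrom"], "start": start, "end": start + ln, "length": ln})
        reads_by_sample[sample.sample_id] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "length"]
        )
    truth = pd.DataFrame({"gene_id": source["gene_id"], "is_degradation_source": True})
    return reads_by_sample, truth


def simulate_interactions(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """miRNA->target and gene-gene interaction tables with planted truth.

    A subset of miRNAs is marked plastic; their targets are marked as
    differentially expressed genes.  Partner genes are planted with exactly
    one link or with >=2 links into the target layer, so the network filter
    ("more than one miRNA target") has known positives and negatives.  Decoy
    edges among unrelated genes must never enter the network.
    """
    config.validate()
    rng = substream(config.seed, "interactions")

    mirnas = [f"mir-sim-{i + 1}" for i in range(config.n_mirnas)]
    plastic_mirnas = set(mirnas[: config.n_plastic_mirnas])

    gene_counter = 0

    def new_gene(prefix: str) -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{prefix}{gene_counter:03d}"

    target_rows = []
    plastic_genes: set[str] = set()
    all_targets: list[str] = []
    for m in mirnas:
        for _ in range(config.targets_per_mirna):
            g = new_gene("tg")
            target_rows.append({"mirna": m, "target": g})
            all_targets.append(g)
            if m in plastic_mirnas:
                plastic_genes.add(g)
    # one shared target between two plastic miRNAs, if possible
    if len(plastic_mirnas) >= 2:
        shared = sorted(plastic_genes)[0]
        second = sorted(plastic_mirnas)[1]
        target_rows.append({"mirna": second, "target": shared})

    plastic_target_list = sorted(plastic_genes)
    interaction_rows = []
    partners_multi = []
    partners_single = []
    for _ in range(config.n_partners_multi):
        p = new_gene("pm")
        partners_multi.append(p)
        k = 2 + int(rng.integers(0, max(1, len(plastic_target_list) - 1)))
        chosen = rng.choice(plastic_target_list, size=min(k, len(plastic_target_list)), replace=False)
        for t in chosen:
            interaction_rows.append({"gene_a": p, "gene_b": t})
    for _ in range(config.n_partners_single):
        p = new_gene("ps")
        partners_single.append(p)
        t = plastic_target_list[int(rng.integers(len(plastic_target_list)))]
        interaction_rows.append({"gene_a": p, "gene_b": t})
    for _ in range(config.n_decoy_edges):
        interaction_rows.append({"gene_a": new_gene("dx"), "gene_b": new_gene("dx")})

    targets = pd.DataFrame(target_rows)
    interactions = pd.DataFrame(interaction_rows)
    truth = {
        "plastic_mirnas": plastic_mirnas,
        "plastic_genes": plastic_genes,
        "expected_partners": set(partners_multi),
        "excluded_partners": set(partners_single),
    }
    return targets, interactions, truth


def simulate_oviposition(config: SimulationConfig) -> pd.DataFrame:
    """Replicate egg counts for control and overexpression lines.

    Counts are eggs laid by pools of 5 mated females over 18 h; each line gets
    ``egg_n_replicates`` replicates around the control mean shifted by the
    planted percent effect.
    """
    rng = substream(config.seed, "eggs")
    rows = []
    for rep in range(config.egg_n_replicates):
        rows.append(
            {
                "line": "control",
                "replicate": rep + 1,
                "eggs": max(0, int(round(rng.normal(config.egg_control_mean, config.egg_sd)))),
            }
        )
    for line, pct in config.egg_effects.items():
        mean = config.egg_control_mean * (1 + pct / 100.0)
        for rep in range(config.egg_n_replicates):
            rows.append(
                {
                    "line": line,
                    "replicate": rep + 1,
                    "eggs": max(0, int(round(rng.normal(mean, config.egg_sd)))),
                }
            )
    return pd.DataFrame(rows)
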