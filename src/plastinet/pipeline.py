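"""End-to-end orchestration: simulate -> diff -> smallrna -> chip -> plasticity
-> network -> validation, from a single config with deterministic seeding.

Each stage's outputs are written under the run directory and checksummed into
a JSON manifest; rerunning with the same config reproduces identical
checksums because every random draw descends from the master seed through
named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chipseq, diffstat, io, network, plasticity, smallrna, validation
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_design,
    simulate_genome,
    simulate_interactions,
    simulate_oviposition,
    simulate_peaks,
    simulate_smallrna_reads,
)

logger = logging.getLogger("plastinet")

ALL_STAGES = ("simulate", "diff", "smallrna", "chip", "plasticity", "network", "validation")


@dataclass
class RunConfig:
    outdir: str = "plastinet_run"
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 5_000
    window_bp: int = 2_000
    min_overlap_bp: int = 1
    min_support: int = 2
    min_width_bp: int = 147
    bin_bp: int = 1_000
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**{**raw, "simulation": sim})
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2^31 from the master seed."""
    return (master * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": {},
        "skipped": [s for s in ALL_STAGES if s not in config.stages],
    }
    written: dict[str, list[Path]] = {}
    sim = config.simulation
    sim.seed = stage_seed(config.seed, "simulate")
    state: dict = {}

    def record(stage: str, paths: list[Path], **params) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(p.relative_to(outdir)): _checksum(p) for p in paths},
        }
        written[stage] = paths
        logger.info("stage %s: wrote %d files", stage, len(paths))

    def fail(stage: str, err: Exception) -> None:
        logger.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"stage {stage!r} failed") from err

    if "simulate" in config.stages:
        try:
            design = simulate_design(sim.n_replicates)
            counts, counts_truth = simulate_counts(sim, kind="mirna", design=design)
            annotation, chrom_sizes = simulate_genome(sim)
            peaks = simulate_peaks(sim, design, annotation, chrom_sizes)
            sr_reads, sr_truth = simulate_smallrna_reads(sim, design, annotation)
            targets, interactions, int_truth = simulate_interactions(sim)
            eggs = simulate_oviposition(sim)

            paths = []
            design.write_tsv(outdir / "design.tsv")
            paths.append(outdir / "design.tsv")
            counts.to_csv(outdir / "mirna_counts.tsv", sep="\t")
            paths.append(outdir / "mirna_counts.tsv")
            counts_truth.to_csv(outdir / "mirna_truth.tsv", sep="\t", index=False)
            paths.append(outdir / "mirna_truth.tsv")
            io.write_gff3(annotation, outdir / "genes.gff3")
            paths.append(outdir / "genes.gff3")
            annotation.rename(columns={"gene_id": "name"}).pipe(
                io.write_bed, outdir / "genes.bed"
            )
            paths.append(outdir / "genes.bed")
            targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
            interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
            paths += [outdir / "targets.tsv", outdir / "interactions.tsv"]
            eggs.to_csv(outdir / "eggs.tsv", sep="\t", index=False)
            paths.append(outdir / "eggs.tsv")
            peak_dir = outdir / "peaks"
            read_dir = outdir / "reads"
            peak_dir.mkdir(exist_ok=True)
            read_dir.mkdir(exist_ok=True)
            for sample_id, frame in peaks["peaks"].items():
                io.write_bed(frame, peak_dir / f"{sample_id}.bed")
                paths.append(peak_dir / f"{sample_id}.bed")
            for sample_id, frame in sr_reads.items():
                bed = frame.rename(columns={"length": "score"})
                io.write_bed(bed, read_dir / f"{sample_id}.smallrna.bed")
                paths.append(read_dir / f"{sample_id}.smallrna.bed")
            peaks["truth"].to_csv(outdir / "peak_truth.tsv", sep="\t", index=False)
            sr_truth.to_csv(outdir / "smallrna_truth.tsv", sep="\t", index=False)
            paths += [outdir / "peak_truth.tsv", outdir / "smallrna_truth.tsv"]
            record("simulate", paths, seed=sim.seed)
            state.update(
                design=design, counts=counts, annotation=annotation,
                chrom_sizes=chrom_sizes, peaks=peaks, sr_reads=sr_reads,
                targets=targets, interactions=interactions, eggs=eggs,
                int_truth=int_truth,
            )
        except Exception as err:  # noqa: BLE001 - stage attribution
            fail("simulate", err)

    if "diff" in config.stages and "counts" in state:
        try:
            diff = diffstat.differential_analysis(
                state["counts"], state["design"], alpha=config.alpha,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "diff"),
            )
            diffstat.write_diff_table(diff, outdir / "mirna_diff.tsv")
            record("diff", [outdir / "mirna_diff.tsv"], alpha=config.alpha)
            state["diff"] = diff
        except Exception as err:  # noqa: BLE001
            fail("diff", err)

    if "smallrna" in config.stages and "sr_reads" in state:
        try:
            calls = smallrna.call_degradation_genes(
                state["sr_reads"], state["annotation"], state["design"]
            )
            calls.to_csv(outdir / "degradation_calls.tsv", sep="\t", index=False)
            paths = [outdir / "degradation_calls.tsv"]
            for sample_id, frame in state["sr_reads"].items():
                hist = smallrna.length_histogram(frame)
                p = outdir / f"lengths_{sample_id}.tsv"
                hist.to_csv(p, sep="\t")
                paths.append(p)
            record("smallrna", paths)
            state["degradation"] = calls
        except Exception as err:  # noqa: BLE001
            fail("smallrna", err)

    if "chip" in config.stages and "peaks" in state:
        try:
            peaks = state["peaks"]
            result = chipseq.chip_signal_pipeline(
                peaks["peaks"], peaks["reads"], peaks["library_sizes"],
                state["chrom_sizes"], state["annotation"],
                min_overlap_bp=config.min_overlap_bp,
                min_support=config.min_support,
                min_width_bp=config.min_width_bp,
                window_bp=config.window_bp, bin_bp=config.bin_bp,
            )
            chip_diff = diffstat.differential_analysis(
                result["signal"].set_axis(result["merged"]["peak_id"], axis=0),
                state["design"], alpha=config.alpha, normalize=False,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "chip"),
            )
            result["merged"].to_csv(outdir / "merged_peaks.tsv", sep="\t", index=False)
            result["signal"].to_csv(outdir / "peak_signal.tsv", sep="\t")
            result["peak2gene"].to_csv(outdir / "peak2gene.tsv", sep="\t", index=False)
            diffstat.write_diff_table(chip_diff, outdir / "chip_diff.tsv")
            record(
                "chip",
                [outdir / "merged_peaks.tsv", outdir / "peak_signal.tsv",
                 outdir / "peak2gene.tsv", outdir / "chip_diff.tsv"],
                min_width_bp=config.min_width_bp, window_bp=config.window_bp,
            )
            state["chip"] = result
            state["chip_diff"] = chip_diff
        except Exception as err:  # noqa: BLE001
            fail("chip", err)

    if "plasticity" in config.stages and "chip_diff" in state:
        try:
            membership = plasticity.classify_contrasts(state["chip_diff"])
            venn = plasticity.venn_overlap(membership)
            summary = plasticity.accelerated_aging_markers(
                membership, state["chip"]["peak2gene"]
            )
            membership.to_csv(outdir / "chip_membership.tsv", sep="\t", index=False)
            venn.to_csv(outdir / "chip_venn.tsv", sep="\t", index=False)
            summary.markers.to_csv(outdir / "aging_markers.tsv", sep="\t", index=False)
            record(
                "plasticity",
                [outdir / "chip_membership.tsv", outdir / "chip_venn.tsv",
                 outdir / "aging_markers.tsv"],
                n_markers=summary.n_markers, n_persistent=summary.n_persistent,
            )
            state["membership"] = membership
            state["markers"] = summary
        except Exception as err:  # noqa: BLE001
            fail("plasticity", err)

    if "network" in config.stages and "int_truth" in state:
        try:
            net = network.build_network(
                state["int_truth"]["plastic_mirnas"], state["targets"],
                state["int_truth"]["plastic_genes"], state["interactions"],
            )
            paths = [Path(p) for p in network.export_network(net, str(outdir / "network"), "tsv")]
            paths += [Path(p) for p in network.export_network(net, str(outdir / "network"), "graphml")]
            paths += [Path(p) for p in network.export_network(net, str(outdir / "network"), "sif")]
            record(
                "network", paths,
                n_mirnas=len(net.mirnas), n_targets=len(net.targets),
                n_partners=len(net.partners),
            )
            state["network"] = net
        except Exception as err:  # noqa: BLE001
            fail("network", err)

    if "validation" in config.stages:
        try:
            qpcr = validation.call_effects_table(validation.load_qpcr_table(), alpha=config.alpha)
            summary = validation.effect_summary(qpcr)
            qpcr.to_csv(outdir / "qpcr_effects.tsv", sep="\t", index=False)
            paths = [outdir / "qpcr_effects.tsv"]
            if "eggs" in state:
                eggs = validation.oviposition_analysis(
                    state["eggs"], seed=stage_seed(config.seed, "eggs")
                )
                eggs.to_csv(outdir / "oviposition.tsv", sep="\t", index=False)
                paths.append(outdir / "oviposition.tsv")
            record("validation", paths, percent_affected=summary.percent)
        except Exception as err:  # noqa: BLE001
            fail("validation", err)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
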