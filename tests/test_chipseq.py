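import numpy as np
import pandas as pd
import pytest

from plastinet import chipseq, diffstat
from plastinet.simulate import SimulationConfig, simulate_design, simulate_peaks


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture()
def toy_peak_calls():
    """Hand-constructed per-sample calls covering every merge rule.

    Expected after merging (>=1 bp overlap, support >=2, width >146):
      * locus A: s1 [1000,1200) + s2 [1050,1250) -> union [1000,1250),
        support 2, width 250 -> kept
      * locus B: identical 100 bp peak [5000,5100) in s1+s2 -> width <=146
        -> dropped
      * locus C: s1-only peak [9000,9400) -> support 1 -> dropped
      * locus D: s1 has two overlapping calls [20000,20200)+[20100,20350)
        which pre-merge into one contribution [20000,20350); with s2
        [20300,20500) the union is [20000,20500), support 2, 2 members
        -> kept
    """
    s1 = _peaks(
        [
            ("chr1", 1000, 1200),
            ("chr1", 5000, 5100),
            ("chr1", 9000, 9400),
            ("chr1", 20000, 20200),
            ("chr1", 20100, 20350),
        ]
    )
    s2 = _peaks([("chr1", 1050, 1250), ("chr1", 5000, 5100), ("chr1", 20300, 20500)])
    return {"s1": s1, "s2": s2}


class TestMergePeaks:
    def test_hand_computed_merge(self, toy_peak_calls):
        merged = chipseq.merge_peaks(toy_peak_calls)
        records = merged[["chrom", "start", "end", "support", "n_members"]].to_records(index=False)
        assert [tuple(r) for r in records] == [
            ("chr1", 1000, 1250, 2, 2),
            ("chr1", 20000, 20500, 2, 2),
        ]

    def test_width_filter_strictly_above_146(self):
        calls = {s: _peaks([("chr1", 100, 246)]) for s in ("a", "b")}  # width 146
        assert chipseq.merge_peaks(calls).empty
        calls147 = {s: _peaks([("chr1", 100, 247)]) for s in ("a", "b")}
        assert len(chipseq.merge_peaks(calls147)) == 1

    def test_support_filter(self):
        calls = {"a": _peaks([("chr1", 0, 400)]), "b": _peaks([])}
        assert chipseq.merge_peaks(calls).empty

    def test_order_independence(self, toy_peak_calls):
        fwd = chipseq.merge_peaks(toy_peak_calls)
        rev = chipseq.merge_peaks(dict(reversed(list(toy_peak_calls.items()))))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_min_overlap_breaks_chains(self):
        calls = {
            "a": _peaks([("chr1", 0, 200)]),
            "b": _peaks([("chr1", 195, 400)]),  # 5 bp overlap
        }
        assert len(chipseq.merge_peaks(calls, min_overlap_bp=1)) == 1
        assert chipseq.merge_peaks(calls, min_overlap_bp=10).empty


class TestFpkm:
    def test_closed_form(self):
        merged = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [0], "end": [500]}
        )
        counts = pd.DataFrame({"s1": [10]}, index=["p0"])
        _, fpkm = chipseq.count_and_fpkm(merged, None, {"s1": 1_000_000}, counts=counts)
        assert fpkm.loc["p0", "s1"] == pytest.approx(20.0)

    def test_zero_count_and_library_scaling(self):
        merged = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [0], "end": [500]}
        )
        counts = pd.DataFrame({"s1": [0], "s2": [10]}, index=["p0"])
        _, f1 = chipseq.count_and_fpkm(merged, None, {"s1": 1_000_000, "s2": 1_000_000}, counts=counts)
        _, f2 = chipseq.count_and_fpkm(merged, None, {"s1": 1_000_000, "s2": 2_000_000}, counts=counts)
        assert f1.loc["p0", "s1"] == 0.0
        assert f2.loc["p0", "s2"] == pytest.approx(f1.loc["p0", "s2"] / 2)

    def test_nonpositive_library_rejected(self):
        merged = pd.DataFrame({"peak_id": ["p0"], "chrom": ["chr1"], "start": [0], "end": [500]})
        with pytest.raises(ValueError):
            chipseq.count_and_fpkm(merged, None, {"s1": 0}, counts=pd.DataFrame({"s1": [1]}, index=["p0"]))


class TestBackgroundCorrect:
    def _uniform_setup(self, bg_per_kb):
        chrom_sizes = {"chr1": 100_000}
        merged = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [50_000], "end": [50_500]}
        )
        # place bg_per_kb reads per kb evenly across all non-peak space
        rows = []
        step = 1000 // bg_per_kb
        for lo, hi in ((0, 49_900), (50_600, 99_900)):
            for pos in range(lo, hi, step):
                rows.append({"chrom": "chr1", "start": pos, "end": pos + 50})
        reads = pd.DataFrame(rows)
        return chrom_sizes, merged, {"s1": reads}

    def test_constant_background_subtracted(self):
        chrom_sizes, merged, reads = self._uniform_setup(bg_per_kb=2)
        lib = {"s1": 1_000_000}
        counts = pd.DataFrame({"s1": [10]}, index=["p0"])
        _, fpkm = chipseq.count_and_fpkm(merged, None, lib, counts=counts)
        corrected, model = chipseq.background_correct(
            fpkm, reads, merged, chrom_sizes, lib, normalize=False
        )
        assert model.median_fpkm["s1"] == pytest.approx(2.0, rel=0.15)
        assert corrected.loc["p0", "s1"] == pytest.approx(20.0 - model.median_fpkm["s1"])

    def test_zero_background_is_identity(self):
        chrom_sizes = {"chr1": 100_000}
        merged = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [50_000], "end": [50_500]}
        )
        lib = {"s1": 1_000_000}
        counts = pd.DataFrame({"s1": [10]}, index=["p0"])
        _, fpkm = chipseq.count_and_fpkm(merged, None, lib, counts=counts)
        empty = {"s1": pd.DataFrame(columns=["chrom", "start", "end"])}
        corrected, _ = chipseq.background_correct(
            fpkm, empty, merged, chrom_sizes, lib, normalize=False
        )
        pd.testing.assert_frame_equal(corrected, fpkm)

    def test_no_nonpeak_space_rejected(self):
        chrom_sizes = {"chr1": 1_000}
        merged = pd.DataFrame({"peak_id": ["p0"], "chrom": ["chr1"], "start": [0], "end": [1_000]})
        fpkm = pd.DataFrame({"s1": [1.0]}, index=["p0"])
        with pytest.raises(ValueError):
            chipseq.background_correct(fpkm, {"s1": _peaks([])}, merged, chrom_sizes, {"s1": 10})


class TestAssignGenes:
    def test_window_boundaries(self, toy_annotation):
        merged = pd.DataFrame(
            {
                "peak_id": ["inside", "outside"],
                "chrom": ["chr1", "chr1"],
                # geneA spans [10000,12000); +-2kb window = [8000,14000)
                "start": [13_800, 14_000],
                "end": [13_999, 14_300],
            }
        )
        mapping = chipseq.assign_genes(merged, toy_annotation, window_bp=2_000)
        assert mapping[mapping["peak_id"] == "inside"]["gene_id"].tolist() == ["geneA"]
        assert mapping[mapping["peak_id"] == "outside"].empty

    def test_toy_mean_genes_per_peak(self, toy_annotation):
        # one peak between the two genes, within 2 kb of both
        merged = pd.DataFrame(
            {"peak_id": ["p0"], "chrom": ["chr1"], "start": [38_500], "end": [38_900]}
        )
        mapping = chipseq.assign_genes(merged, toy_annotation, window_bp=2_000)
        assert sorted(mapping["gene_id"]) == ["geneB"]
        wide = chipseq.assign_genes(merged, toy_annotation, window_bp=30_000)
        assert sorted(wide["gene_id"]) == ["geneA", "geneB"]


class TestPipelineComposition:
    def test_normalized_columns_share_sorted_vector(self):
        cfg = SimulationConfig(seed=31, n_replicates=2)
        sim = simulate_peaks(cfg)
        res = chipseq.chip_signal_pipeline(
            sim["peaks"], sim["reads"], sim["library_sizes"],
            sim["chrom_sizes"], sim["annotation"],
        )
        signal = res["signal"]
        ref = np.sort(signal.iloc[:, 0].to_numpy())
        for col in signal:
            assert np.allclose(np.sort(signal[col].to_numpy()), ref)
        assert ((res["merged"]["end"] - res["merged"]["start"]) > 146).all()
        assert (res["merged"]["support"] >= 2).all()

    def test_planted_masters_recovered_by_merge(self):
        cfg = SimulationConfig(seed=32, n_replicates=2)
        sim = simulate_peaks(cfg)
        merged = chipseq.merge_peaks(sim["peaks"])
        truth = sim["truth"]
        expected = truth[~truth["pattern"].isin(["narrow", "singleton"])]
        assert len(merged) == len(expected)
        # every surviving merged interval overlaps exactly one master
        for p in merged.itertuples():
            hits = expected[
                (expected["chrom"] == p.chrom)
                & (expected["start"] < p.end)
                & (expected["end"] > p.start)
            ]
            assert len(hits) == 1
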