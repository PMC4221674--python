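import itertools

import numpy as np
import pandas as pd
import pytest

from plastinet import plasticity
from plastinet.design import CONTRAST_NAMES


def _diff_row(feature, **sig):
    """A DiffResult-style row; sig maps contrast -> signed diff or None."""
    row = {"feature": feature, "p": 0.001, "q": 0.01, "pooled_sd": 1.0}
    for name in CONTRAST_NAMES:
        value = sig.get(name)
        row[f"{name}_diff"] = 0.0 if value is None else float(value)
        row[f"{name}_effect"] = value is not None
        row[f"{name}_sig"] = value is not None
    return row


def _membership(rows):
    return plasticity.classify_contrasts(pd.DataFrame(rows))


class TestClassifyContrasts:
    def test_single_contrast_passthrough(self):
        memb = _membership([_diff_row("f1", young_mating=2.5)])
        assert memb.loc[0, "young_mating"] == 1
        assert memb.loc[0, ["aged_mating", "virgin_aging", "mated_aging"]].tolist() == [0, 0, 0]

    def test_null_feature_empty_membership(self):
        memb = _membership([_diff_row("f1")])
        assert (memb[list(CONTRAST_NAMES)] == 0).all().all()

    def test_direction_sign(self):
        memb = _membership([_diff_row("f1", virgin_aging=-3.0)])
        assert memb.loc[0, "virgin_aging"] == -1

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            plasticity.classify_contrasts(pd.DataFrame({"feature": ["x"]}))


class TestVennOverlap:
    def test_disjoint_sets(self):
        memb = _membership(
            [_diff_row("a", young_mating=1), _diff_row("b", virgin_aging=1)]
        )
        venn = plasticity.venn_overlap(memb, ["young_mating", "virgin_aging"])
        counts = dict(zip(venn["region"], venn["count"]))
        assert counts["young_mating"] == 1
        assert counts["virgin_aging"] == 1
        assert counts["young_mating&virgin_aging"] == 0

    def test_identical_sets(self):
        memb = _membership([_diff_row("a", young_mating=1, virgin_aging=1)])
        venn = plasticity.venn_overlap(memb, ["young_mating", "virgin_aging"])
        counts = dict(zip(venn["region"], venn["count"]))
        assert counts["young_mating&virgin_aging"] == 1
        assert counts["young_mating"] == 0

    def test_matches_bruteforce_set_algebra(self, rng):
        rows = []
        for i in range(60):
            sig = {
                c: (1 if rng.random() < 0.5 else None) for c in CONTRAST_NAMES
            }
            rows.append(_diff_row(f"f{i}", **{k: v for k, v in sig.items() if v}))
        memb = _membership(rows)
        venn = plasticity.venn_overlap(memb, list(CONTRAST_NAMES))
        # brute force over features
        sets = {c: set(memb.loc[memb[c] != 0, "feature"]) for c in CONTRAST_NAMES}
        total_union = set().union(*sets.values())
        assert venn["count"].sum() == len(total_union)
        for r in range(1, 5):
            for combo in itertools.combinations(CONTRAST_NAMES, r):
                inside = set.intersection(*(sets[c] for c in combo))
                outside = set().union(*(sets[c] for c in CONTRAST_NAMES if c not in combo), set())
                expected = len(inside - outside)
                region = "&".join(c for c in CONTRAST_NAMES if c in combo)
                got = int(venn.loc[venn["region"] == region, "count"].iloc[0])
                assert got == expected


class TestPersistence:
    def test_flat_after_mating_is_persistent(self):
        memb = _membership([_diff_row("m1", young_mating=2)])
        assert plasticity.persistent_marks(memb).tolist() == ["m1"]

    def test_reversal_breaks_persistence(self):
        memb = _membership([_diff_row("m1", young_mating=2, mated_aging=-1)])
        assert plasticity.persistent_marks(memb).empty

    def test_same_direction_change_keeps_persistence(self):
        memb = _membership([_diff_row("m1", young_mating=2, mated_aging=1)])
        assert plasticity.persistent_marks(memb).tolist() == ["m1"]

    def test_empty_input(self):
        memb = _membership([_diff_row("m1")])
        assert plasticity.persistent_marks(memb).empty

    def test_aged_significance_mode(self):
        memb = _membership([_diff_row("m1", young_mating=2)])
        assert plasticity.persistent_marks(memb, mode="aged_significance").empty
        memb2 = _membership([_diff_row("m1", young_mating=2, aged_mating=1)])
        assert plasticity.persistent_marks(memb2, mode="aged_significance").tolist() == ["m1"]


class TestAcceleratedAgingMarkers:
    def test_marker_rule_and_fractions(self):
        rows = [
            # marker: up post-mating, persists, up with virgin aging
            _diff_row("mk", young_mating=2, virgin_aging=1),
            # persistent only: no virgin-aging co-occurrence
            _diff_row("pers", young_mating=2),
            # direction mismatch: up post-mating, down with virgin aging
            _diff_row("anti", young_mating=2, virgin_aging=-1),
            # reverting: excluded from persistence entirely
            _diff_row("rev", young_mating=2, mated_aging=-2, virgin_aging=1),
            _diff_row("null"),
        ]
        p2g = pd.DataFrame({"peak_id": ["mk", "mk"], "gene_id": ["g1", "g2"]})
        summary = plasticity.accelerated_aging_markers(_membership(rows), p2g)
        assert summary.markers["feature"].tolist() == ["mk"]
        assert summary.n_young_responsive == 4
        assert summary.n_persistent == 3  # mk, pers, anti
        assert summary.fraction_markers_of_persistent == pytest.approx(1 / 3)
        assert summary.n_unique_genes == 2
        # invariant chain: markers subset persistent subset young-responsive
        assert summary.n_markers <= summary.n_persistent <= summary.n_young_responsive

    def test_empty_membership_gives_nan_fraction(self):
        summary = plasticity.accelerated_aging_markers(
            _membership([_diff_row("x")]), pd.DataFrame(columns=["peak_id", "gene_id"])
        )
        assert summary.markers.empty
        assert np.isnan(summary.fraction_markers_of_persistent)

    def test_missing_map_warns_but_emits(self):
        memb = _membership([_diff_row("mk", young_mating=2, virgin_aging=1)])
        with pytest.warns(UserWarning):
            summary = plasticity.accelerated_aging_markers(memb, None)
        assert summary.markers["feature"].tolist() == ["mk"]
        assert summary.markers["genes"].tolist() == [""]
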