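"""Contrast classification, overlap structure and accelerated-aging markers.

A feature (transcript, miRNA or histone peak) is "plastic" in a contrast when
its omnibus q-value passes the FDR threshold and the condition-mean difference
exceeds one pooled SD.  Persistent histone marks are post-mating changes in
young flies that are not reversed as mated flies age; accelerated-aging
markers are the persistent marks whose change also arises, in the same
direction, with aging in virgin flies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONTRAST_NAMES


def classify_contrasts(diff: pd.DataFrame) -> pd.DataFrame:
    """Per-feature membership in each contrast: +1 / -1 when significant, 0 otherwise.

    Direction is the sign of the contrast difference (mated - virgin within
    age, aged - young within mating status) and is defined only for
    significant contrasts.
    """
    missing = [
        c for name in CONTRAST_NAMES for c in (f"{name}_diff", f"{name}_sig") if c not in diff
    ]
    if missing:
        raise ValueError(f"differential table lacks columns: {missing}")
    out = pd.DataFrame({"feature": diff["feature"]})
    for name in CONTRAST_NAMES:
        sign = np.sign(diff[f"{name}_diff"]).astype(int)
        out[name] = np.where(diff[f"{name}_sig"], sign, 0)
    return out


def venn_overlap(membership: pd.DataFrame, contrasts: list[str] | None = None) -> pd.DataFrame:
    """Exclusive region counts of the significance sets over the contrasts.

    For k contrasts, returns all 2^k - 1 non-empty regions; region counts sum
    to the size of the union of the significance sets.
    """
    if contrasts is None:
        contrasts = list(CONTRAST_NAMES)
    if len(contrasts) < 2:
        raise ValueError("need at least 2 contrasts")
    flags = membership[contrasts].ne(0)
    rows = []
    for bits in range(1, 2 ** len(contrasts)):
        selected = [c for i, c in enumerate(contrasts) if bits >> i & 1]
        others = [c for c in contrasts if c not in selected]
        mask = flags[selected].all(axis=1)
        if others:
            mask &= ~flags[others].any(axis=1)
        rows.append({"region": "&".join(selected), "count": int(mask.sum())})
    return pd.DataFrame(rows)


def persistent_marks(membership: pd.DataFrame, mode: str = "non_reversal") -> pd.Series:
    """Features whose post-mating change in young flies persists with age.

    ``mode="non_reversal"`` (default): significant in the young virgin-vs-mated
    contrast and NOT significantly reversed (opposite sign) in the mated
    young-vs-aged contrast.  ``mode="aged_significance"``: alternative reading
    requiring the aged virgin-vs-mated contrast to be significant in the same
    direction.
    """
    young = membership["young_mating"]
    if mode == "non_reversal":
        reversal = membership["mated_aging"] == -young
        keep = (young != 0) & ~reversal
    elif mode == "aged_significance":
        keep = (young != 0) & (membership["aged_mating"] == young)
    else:
        raise ValueError(f"unknown persistence mode {mode!r}")
    return membership.loc[keep, "feature"].reset_index(drop=True)


@dataclass
class MarkerSummary:
    """Accelerated-aging marker calls and the headline fractions."""

    markers: pd.DataFrame  # feature, direction, genes
    n_young_responsive: int
    n_persistent: int
    n_markers: int
    fraction_persistent_of_young: float
    fraction_markers_of_persistent: float  # the per-mark co-occurrence statistic
    n_unique_genes: int


def accelerated_aging_markers(
    membership: pd.DataFrame,
    peak2gene: pd.DataFrame | None = None,
    mode: str = "non_reversal",
) -> MarkerSummary:
    """Persistent post-mating marks that also arise with aging in virgins.

    markers = persistent marks whose virgin young-vs-aged contrast is
    significant with the same direction as the young post-mating change.
    Genes are attached through the peak->gene map when provided; without a map
    the markers are emitted with empty gene lists and a warning.
    """
    import warnings

    persistent = set(persistent_marks(membership, mode=mode))
    young = membership.set_index("feature")["young_mating"]
    virgin = membership.set_index("feature")["virgin_aging"]
    marker_features = [
        f for f in membership["feature"]
        if f in persistent and young[f] != 0 and virgin[f] == young[f]
    ]

    if peak2gene is None:
        warnings.warn("no peak->gene map supplied; markers emitted without genes")
        gene_map: dict[str, list[str]] = {}
    else:
        gene_map = (
            peak2gene.groupby("peak_id")["gene_id"].apply(sorted).to_dict()
        )
    markers = pd.DataFrame(
        {
            "feature": marker_features,
            "direction": [int(young[f]) for f in marker_features],
            "genes": [",".join(gene_map.get(f, [])) for f in marker_features],
        }
    )
    n_young = int((membership["young_mating"] != 0).sum())
    n_pers = len(persistent)
    n_mark = len(marker_features)
    unique_genes = {g for f in marker_features for g in gene_map.get(f, [])}
    return MarkerSummary(
        markers=markers,
        n_young_responsive=n_young,
        n_persistent=n_pers,
        n_markers=n_mark,
        fraction_persistent_of_young=(n_pers / n_young) if n_young else float("nan"),
        fraction_markers_of_persistent=(n_mark / n_pers) if n_pers else float("nan"),
        n_unique_genes=len(unique_genes),
    )
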