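"""Functional-validation statistics for miRNA overexpression experiments.

Two readouts: (1) qPCR expression of candidate target genes in virgin vs
mated females, compared between a control cross and a miRNA-overexpression
cross -- overexpression "has an effect" when the virgin-vs-mated difference is
significant in exactly one of the two crosses; (2) egg laying, compared
against the control line with Dunnett's many-to-one test.

A bundled 20-row qPCR summary table (p-values for six overexpression lines'
target genes) ships with the package for the worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


def load_qpcr_table() -> pd.DataFrame:
    """The bundled qPCR mating-response p-value table (20 miRNA-target pairs).

    Columns: mirna, target_gene, p_control, p_overexpression, reported_effect.
    """
    path = resources.files("plastinet.data").joinpath("mirna_overexpression_qpcr.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def normalize_expression(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reference-gene mean normalization of expression values.

    Each sample's target value is divided by the same sample's reference-gene
    (e.g. Gapdh) value, then rescaled by the cross-sample mean of those ratios
    so the output is centered at 1 for a flat profile.  Pluggable: any
    normalizer producing per-sample relative expression can replace this.
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape:
        raise ValueError("target and reference must align")
    if (reference <= 0).any():
        raise ValueError("reference expression must be positive")
    ratio = target / reference
    return ratio / ratio.mean()


def ttest_expression(group_a, group_b) -> float:
    """Two-sided pooled-variance Student's t-test p-value.

    Degenerate inputs with zero variance in both groups and equal means give
    p = 1 (no evidence of a difference), not an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def call_overexpression_effect(p_control: float, p_overexp: float, alpha: float = 0.05) -> str:
    """"+" iff significance status differs between the two crosses at alpha.

    The rule is symmetric in its two arguments: an effect is called when the
    virgin-vs-mated difference is significant only in the control cross or
    only in the overexpression cross.
    """
    for p in (p_control, p_overexp):
        if not (0 < p <= 1):
            raise ValueError("p-values must lie in (0, 1]")
    return "+" if (p_control < alpha) != (p_overexp < alpha) else "-"


@dataclass
class EffectSummary:
    n_calls: int
    n_affected: int
    fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def call_effects_table(
    qpcr: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the discordance rule to a table of (p_control, p_overexpression)."""
    out = qpcr.copy()
    out["effect"] = [
        call_overexpression_effect(pc, po, alpha)
        for pc, po in zip(out["p_control"], out["p_overexpression"])
    ]
    return out


def effect_summary(calls: pd.DataFrame) -> EffectSummary:
    """Fraction of tested target genes affected by miRNA overexpression."""
    if len(calls) == 0:
        raise ValueError("no effect calls to summarize")
    n_plus = int((calls["effect"] == "+").sum())
    return EffectSummary(n_calls=len(calls), n_affected=n_plus, fraction=n_plus / len(calls))


def dunnett_test(
    control_counts,
    counts_by_line: dict[str, list | np.ndarray],
    seed: int | None = None,
) -> pd.DataFrame:
    """Many-to-one comparison of treatment lines against the control.

    Familywise-adjusted two-sided p-values from the Dunnett multivariate-t
    null (scipy's implementation; the critical surface is evaluated by seeded
    stochastic integration, hence ``seed``).  Also reports each line's percent
    change relative to the control mean.
    """
    control = np.asarray(control_counts, dtype=float)
    if len(control) < 2 or any(len(v) < 2 for v in counts_by_line.values()):
        raise ValueError("need >=2 replicates per group")
    lines = sorted(counts_by_line)
    samples = [np.asarray(counts_by_line[l], dtype=float) for l in lines]
    res = stats.dunnett(*samples, control=control, rng=seed)
    ctrl_mean = control.mean()
    return pd.DataFrame(
        {
            "line": lines,
            "mean": [s.mean() for s in samples],
            "percent_change": [100.0 * (s.mean() - ctrl_mean) / ctrl_mean for s in samples],
            "p_adjusted": np.clip(res.pvalue, np.finfo(float).tiny, 1.0),
        }
    )


def oviposition_analysis(egg_table: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Dunnett analysis of an egg-count table with a ``control`` line.

    Expects columns line / replicate / eggs as produced by the synthetic
    oviposition generator or read from a TSV.
    """
    if "control" not in set(egg_table["line"]):
        raise ValueError("egg table must contain a 'control' line")
    control = egg_table.loc[egg_table["line"] == "control", "eggs"].to_numpy()
    by_line = {
        line: grp["eggs"].to_numpy()
        for line, grp in egg_table.groupby("line")
        if line != "control"
    }
    return dunnett_test(control, by_line, seed=seed)
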