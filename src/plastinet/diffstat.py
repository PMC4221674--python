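"""Shared differential-abundance engine.

The same machinery is applied to miRNA count tables and to background-corrected
ChIP peak signals: quantile normalization across samples, a permutation
one-way ANOVA per feature (model ``Y = mu + C + eps`` with C the four-level
condition factor), Benjamini-Yekutieli FDR adjustment (valid under arbitrary
dependence between features), and post hoc pairwise contrasts gated by one
pooled standard deviation.

The permutation p-value is exact whenever the number of distinct condition-label
assignments is small enough to enumerate (2520 for the 4 conditions x 2
replicates design), and seeded Monte Carlo otherwise.  The identity assignment
is always counted, so p > 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import CONDITIONS, CONTRASTS, SampleDesign, validate_columns

#: Enumerate the permutation space exactly when it has at most this many
#: distinct label assignments; switch to Monte Carlo above it.
EXHAUSTIVE_CAP = 10_000

# Relative tolerance for counting F-statistic ties across permutations
# (ties count as >=, which is conservative).
_F_TIE_RTOL = 1e-9


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common empirical distribution.

    Each column's rank-r value is replaced by the mean over columns of the
    rank-r sorted values.  Ties within a column receive the mean of the
    normalized values at their tied ranks (so a constant column maps to the
    grand mean of the reference distribution).

    Missing values are an error: quantile normalization has no principled
    imputation and the upstream tables are complete by construction.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 2:
        raise ValueError("need at least 1 feature and 2 samples")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average assigned reference values over tied input values
        tied = pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _condition_codes(design: SampleDesign) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(CONDITIONS)}
    return np.array([lookup[c] for c in design.condition_labels], dtype=np.intp)


def n_distinct_assignments(group_sizes: np.ndarray) -> int:
    """Number of distinct ways to assign the given label multiset."""
    total = int(group_sizes.sum())
    n = math.factorial(total)
    for g in group_sizes:
        n //= math.factorial(int(g))
    return n


def enumerate_assignments(group_sizes: np.ndarray) -> np.ndarray:
    """All distinct label assignments as an (n_assignments, n_samples) array.

    Generated by recursively choosing index sets for each group, which yields
    every multiset permutation exactly once in a deterministic order.
    """
    total = int(group_sizes.sum())
    assignments: list[np.ndarray] = []
    base = np.empty(total, dtype=np.intp)

    def recurse(free: tuple[int, ...], group: int) -> None:
        if group == len(group_sizes) - 1:
            row = base.copy()
            row[list(free)] = group
            assignments.append(row)
            return
        for chosen in itertools.combinations(free, int(group_sizes[group])):
            base[list(chosen)] = group
            remaining = tuple(i for i in free if i not in set(chosen))
            recurse(remaining, group + 1)

    recurse(tuple(range(total)), 0)
    return np.stack(assignments)


def _anova_f_matrix(values: np.ndarray, assignments: np.ndarray, group_sizes: np.ndarray) -> np.ndarray:
    """F statistics for every (assignment, feature) pair.

    ``values`` is (n_samples, n_features); ``assignments`` is
    (n_assignments, n_samples) of group codes.  Returns (n_assignments,
    n_features).  Uses the sums-of-squares identities so only group sums are
    needed per assignment.
    """
    n_samples, n_features = values.shape
    k = len(group_sizes)
    one_hot = np.zeros((assignments.shape[0], k, n_samples))
    rows = np.repeat(np.arange(assignments.shape[0]), n_samples)
    cols = np.tile(np.arange(n_samples), assignments.shape[0])
    one_hot[rows, assignments.ravel(), cols] = 1.0

    # center per feature: F is invariant and the SS identities lose far less
    # precision; residual cancellation is handled by the relative tolerance
    values = values - values.mean(axis=0, keepdims=True)
    sst = (values**2).sum(axis=0)
    group_sums = one_hot.reshape(-1, n_samples) @ values  # (P*k, F)
    group_sums = group_sums.reshape(assignments.shape[0], k, n_features)
    ssb = (group_sums**2 / group_sizes[None, :, None]).sum(axis=1)
    ssw = sst[None, :] - ssb
    ssw = np.where(ssw <= 1e-12 * np.maximum(sst[None, :], 1e-300), 0.0, ssw)
    msb = ssb / (k - 1)
    msw = ssw / (n_samples - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    # msw == 0: F is +inf when ssb > 0, and 0/0 when the feature is constant
    f = np.where(np.isnan(f), 0.0, f)
    return f


def _tie_threshold(f_obs: np.ndarray) -> np.ndarray:
    """Inclusive tie threshold for counting permutation F >= F_obs.

    Infinite F_obs (zero residual variance with a real group effect) must
    still count its own ties, so the threshold stays at +inf there.
    """
    finite = np.isfinite(f_obs)
    thr = f_obs.astype(float).copy()
    thr[finite] = f_obs[finite] - _F_TIE_RTOL * np.maximum(1.0, np.abs(f_obs[finite]))
    return thr


@dataclass
class PermAnovaResult:
    """Permutation one-way ANOVA for a single feature."""

    f_obs: float
    p_perm: float
    n_assignments: int
    exhaustive: bool
    group_means: dict[str, float] = field(default_factory=dict)
    pooled_sd: float = 0.0


def _check_design(design: SampleDesign) -> np.ndarray:
    codes = _condition_codes(design)
    sizes = np.bincount(codes, minlength=len(CONDITIONS))
    if (sizes < 2).any() or len(np.unique(codes)) < 2:
        raise ValueError("degenerate design: need >=2 conditions with >=2 samples each")
    return codes


def permutation_anova(
    values,
    design: SampleDesign,
    n_perm: int = 5_000,
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermAnovaResult:
    """Permutation p-value for the one-way condition effect on one feature.

    p = (number of label assignments with F >= F_obs, identity included) /
    (number of assignments evaluated).  Exhaustive when the distinct-assignment
    count is <= ``exhaustive_cap`` (2520 for the 4x2 design), else seeded
    Monte Carlo with the identity included in numerator and denominator.
    """
    values = np.asarray(values, dtype=float)
    codes = _check_design(design)
    if values.shape != (len(codes),):
        raise ValueError("values length does not match design")
    sizes = np.bincount(codes, minlength=len(CONDITIONS)).astype(float)

    n_exact = n_distinct_assignments(sizes)
    if n_exact <= exhaustive_cap:
        assignments = enumerate_assignments(sizes.astype(int))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])
        assignments = np.vstack([codes[None, :], perms])
        exhaustive = False

    f_all = _anova_f_matrix(values[:, None], assignments, sizes)[:, 0]
    f_obs = float(
        _anova_f_matrix(values[:, None], codes[None, :], sizes)[0, 0]
    )
    threshold = _tie_threshold(np.array([f_obs]))[0]
    p = float((f_all >= threshold).sum() / len(f_all))

    means = {
        cond: float(values[codes == i].mean()) for i, cond in enumerate(CONDITIONS)
    }
    return PermAnovaResult(
        f_obs=f_obs,
        p_perm=p,
        n_assignments=len(f_all),
        exhaustive=exhaustive,
        group_means=means,
        pooled_sd=pooled_sd(values, design),
    )


def pooled_sd(values, design: SampleDesign) -> float:
    """Square root of the within-condition mean-square error.

    This is the single residual SD pooled across the four conditions, used as
    the minimum-effect-size gate for post hoc pairwise comparisons.
    """
    values = np.asarray(values, dtype=float)
    codes = _check_design(design)
    ssw = 0.0
    for g in np.unique(codes):
        group = values[codes == g]
        ssw += float(((group - group.mean()) ** 2).sum())
    dof = len(values) - len(np.unique(codes))
    return math.sqrt(ssw / dof)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values (FDR under arbitrary dependence).

    q_(i) = min_{j>=i} p_(j) * m * c(m) / j capped at 1, with
    c(m) = sum_{k=1..m} 1/k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def differential_analysis(
    matrix: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.05,
    normalize: bool = True,
    log2_transform: bool = False,
    n_perm: int = 5_000,
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> pd.DataFrame:
    """Full per-feature differential pipeline over the four conditions.

    Optionally quantile-normalizes (and log2(x+1)-transforms) the matrix, runs
    the permutation ANOVA per feature, BY-adjusts the p-vector, and evaluates
    the four pairwise contrasts.  A contrast is called significant when the
    omnibus q < alpha AND |difference of condition means| > pooled SD.

    Returns one row per feature with columns: feature, p, q, mean_YV, mean_YM,
    mean_AV, mean_AM, pooled_sd, then per contrast ``{name}_diff``,
    ``{name}_effect`` (the pooled-SD gate alone) and ``{name}_sig``.
    """
    validate_columns(matrix.columns, design)
    matrix = matrix[design.sample_ids]
    codes = _check_design(design)
    sizes = np.bincount(codes, minlength=len(CONDITIONS)).astype(float)

    data = matrix.astype(float)
    if log2_transform:
        data = np.log2(data + 1.0)
    if normalize:
        data = quantile_normalize(data)
    values = data.to_numpy()  # features x samples
    n_features = values.shape[0]

    n_exact = n_distinct_assignments(sizes)
    if n_exact <= exhaustive_cap:
        assignments = enumerate_assignments(sizes.astype(int))
    else:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])
        assignments = np.vstack([codes[None, :], perms])

    f_obs = _anova_f_matrix(values.T, codes[None, :], sizes)[0]
    p = np.empty(n_features)
    chunk = max(1, int(2**22 // max(1, assignments.shape[0] * len(CONDITIONS))))
    for start in range(0, n_features, chunk):
        block = values[start : start + chunk].T  # samples x block
        f_all = _anova_f_matrix(block, assignments, sizes)
        thr = _tie_threshold(f_obs[start : start + chunk])
        p[start : start + chunk] = (f_all >= thr[None, :]).sum(axis=0) / f_all.shape[0]

    q = fdr_adjust(p)

    cond_means = {
        cond: values[:, codes == i].mean(axis=1) for i, cond in enumerate(CONDITIONS)
    }
    ssw = np.zeros(n_features)
    for i in range(len(CONDITIONS)):
        group = values[:, codes == i]
        ssw += ((group - group.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sd = np.sqrt(ssw / (values.shape[1] - len(CONDITIONS)))

    out = pd.DataFrame(
        {
            "feature": matrix.index,
            "p": p,
            "q": q,
            "mean_YV": cond_means["young_virgin"],
            "mean_YM": cond_means["young_mated"],
            "mean_AV": cond_means["aged_virgin"],
            "mean_AM": cond_means["aged_mated"],
            "pooled_sd": sd,
        }
    )
    for name, plus, minus in CONTRASTS:
        diff = cond_means[plus] - cond_means[minus]
        effect = np.abs(diff) > sd
        out[f"{name}_diff"] = diff
        out[f"{name}_effect"] = effect
        out[f"{name}_sig"] = (q < alpha) & effect
    return out.reset_index(drop=True)


def write_diff_table(diff: pd.DataFrame, path) -> None:
    diff.to_csv(path, sep="\t", index=False)


def read_diff_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
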