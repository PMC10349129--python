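"""Differential protein abundance with permutation-based FDR control.

Implements the label-free / isobaric-label quantitative workflow:
filtering on observation counts, log2 transformation, left-censored
("downshifted normal") missing-value imputation, quantile normalization
for reporter intensities, and a two-sided two-sample t-test whose
significance threshold is set by a permutation-based FDR estimate.

The test statistic is a Student (equal-variance) t with an optional
variance-stabilizing offset s0 added to the pooled standard error:

    t = (mean_a - mean_b) / (SE_pooled + s0)

The null distribution is built by permuting the condition labels over
the samples; at a candidate cutoff c, FDR(c) is the median over
permutations of the number of |t_perm| >= c, divided by the number of
observed |t| >= c.  The significance cutoff is the smallest c with
FDR(c) <= alpha (i.e. the largest significant set at that FDR).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMatrix",
    "ImputationParams",
    "DiffExprResult",
    "filter_valid",
    "log2_transform",
    "impute_downshift",
    "quantile_normalize",
    "ttest_s0",
    "permutation_fdr_ttest",
    "volcano_table",
]


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with its condition design.

    ``data`` holds raw (linear-scale) intensities with NaN for missing;
    ``design`` maps sample -> (condition, replicate); ``mode`` records
    the quantification source (label-free "lfq" or isobaric "tmt").
    """

    data: pd.DataFrame
    design: dict[str, tuple[str, int]]
    mode: str = "lfq"

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, (c, _) in self.design.items() if c == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.design.values():
            if c not in seen:
                seen.append(c)
        return seen


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation parameters, in units of each
    sample's observed standard deviation."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class DiffExprResult:
    """Per-protein statistics from the permutation-FDR t-test."""

    table: pd.DataFrame  # columns: log2fc, t, p, significant
    conditions: tuple[str, str]
    alpha: float
    s0: float
    n_perm_used: int
    t_cutoff: float


def filter_valid(m: AbundanceMatrix, min_valid: int = 2) -> AbundanceMatrix:
    """Keep proteins observed in at least ``min_valid`` replicates of at
    least one condition; row order preserved."""
    keep = pd.Series(False, index=m.data.index)
    for cond in m.conditions:
        cols = m.samples_for(cond)
        keep |= m.data[cols].notna().sum(axis=1) >= min_valid
    return AbundanceMatrix(m.data.loc[keep].copy(), dict(m.design), m.mode)


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; missing values stay missing."""
    bad = (m.data <= 0).any()
    if bad.any():
        col = bad[bad].index[0]
        row = m.data.index[(m.data[col] <= 0).to_numpy().nonzero()[0][0]]
        raise ValueError(f"non-positive intensity at protein {row!r}, sample {col!r}")
    return AbundanceMatrix(np.log2(m.data), dict(m.design), m.mode)


def impute_downshift(
    m: AbundanceMatrix, params: ImputationParams = ImputationParams()
) -> AbundanceMatrix:
    """Impute missing values from a downshifted normal, per sample.

    Each missing cell of a sample is drawn from
    Normal(mean_obs - downshift * sd_obs, width * sd_obs) where mean and
    SD are computed from that sample's observed values.  Observed cells
    are never altered.
    """
    rng = np.random.default_rng(params.seed)
    out = m.data.copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has fewer than 2 observed values; cannot impute"
            )
        mu = observed.mean()
        sd = observed.std(ddof=1)
        draws = rng.normal(mu - params.downshift * sd, params.width * sd, n_missing)
        out.loc[vals.isna(), col] = draws
    return AbundanceMatrix(out, dict(m.design), m.mode)


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample to the same value distribution (rank means).

    Each column's values are replaced by the across-column means of the
    order statistics at the value's (average, tie-aware) rank.  Used on
    reporter intensities in the isobaric-label path, which has no
    missing values.
    """
    if m.data.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    values = m.data.to_numpy(dtype=float)
    n = values.shape[0]
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), rank_means)
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        dict(m.design),
        m.mode,
    )


def ttest_s0(
    a: np.ndarray, b: np.ndarray, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Student t with an s0 offset on the pooled SE.

    Returns (t, two-sided p).  With s0=0 this is the ordinary
    equal-variance two-sample t-test.  p-values are computed from the
    Student t distribution of the (possibly moderated) statistic and are
    descriptive when s0 > 0; significance calls come from the
    permutation FDR, not from p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    ss = (a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))
    pooled_se = np.sqrt(ss / df * (1 / na + 1 / nb))
    t = mean_diff / (pooled_se + s0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def _label_assignments(
    n_total: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Index sets (rows) of which samples get condition-A labels."""
    from math import comb

    n_distinct = comb(n_total, n_a)
    if n_distinct < 10:
        warnings.warn(
            f"only {n_distinct} distinct label assignments; using all of them",
            stacklevel=3,
        )
    if n_distinct <= n_perm:
        return np.array(
            list(itertools.combinations(range(n_total), n_a)), dtype=int
        )
    picks = set()
    out = []
    while len(out) < n_perm:
        sel = tuple(sorted(rng.choice(n_total, n_a, replace=False).tolist()))
        if sel not in picks:
            picks.add(sel)
            out.append(sel)
    return np.array(out, dtype=int)


def permutation_fdr_ttest(
    m: AbundanceMatrix,
    conditions: tuple[str, str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 250,
    s0: float = 0.1,
    seed: int = 0,
) -> DiffExprResult:
    """Two-sided t-test with a permutation-based FDR significance cutoff.

    ``conditions`` orders the contrast: log2 fold change is
    condition[0] minus condition[1] (put the cellulose-like condition
    first to make upregulation positive).  The matrix must be complete
    (impute first).
    """
    if conditions is None:
        conds = m.conditions
        if len(conds) != 2:
            raise ValueError("specify the two conditions to contrast")
        conditions = (conds[0], conds[1])
    cols_a = m.samples_for(conditions[0])
    cols_b = m.samples_for(conditions[1])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if m.data[cols_a + cols_b].isna().any().any():
        raise ValueError("matrix contains missing values; impute before testing")

    rng = np.random.default_rng(seed)
    a = m.data[cols_a].to_numpy(dtype=float)
    b = m.data[cols_b].to_numpy(dtype=float)
    t_obs, p = ttest_s0(a, b, s0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    combined = np.hstack([a, b])
    n_total, n_a = combined.shape[1], len(cols_a)
    assignments = _label_assignments(n_total, n_a, n_perm, rng)

    abs_obs = np.abs(t_obs)
    # counts of permutation statistics exceeding each candidate cutoff
    all_idx = np.arange(n_total)
    perm_counts = np.empty((len(assignments), abs_obs.size))
    candidates = np.sort(abs_obs)  # ascending candidate cutoffs
    for k, sel in enumerate(assignments):
        rest = np.setdiff1d(all_idx, sel, assume_unique=True)
        t_perm, _ = ttest_s0(combined[:, sel], combined[:, rest], s0)
        abs_perm_sorted = np.sort(np.abs(t_perm))
        # number of permutation |t| >= each candidate
        perm_counts[k] = abs_perm_sorted.size - np.searchsorted(
            abs_perm_sorted, candidates, side="left"
        )
    v_med = np.median(perm_counts, axis=0)  # median false positives
    r_obs = abs_obs.size - np.arange(abs_obs.size)  # observed >= candidate
    fdr = v_med / r_obs

    passing = np.nonzero(fdr <= alpha)[0]
    if passing.size:
        t_cutoff = float(candidates[passing[0]])
        significant = abs_obs >= t_cutoff
    else:
        t_cutoff = float("inf")
        significant = np.zeros_like(abs_obs, dtype=bool)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_obs,
            "p": p,
            "significant": significant,
        },
        index=m.data.index,
    )
    return DiffExprResult(
        table=table,
        conditions=conditions,
        alpha=alpha,
        s0=s0,
        n_perm_used=len(assignments),
        t_cutoff=t_cutoff,
    )


def volcano_table(result: DiffExprResult) -> pd.DataFrame:
    """Volcano-ready table sorted by p: protein, log2FC, -log10 p, flag."""
    df = result.table.copy()
    df["neg_log10_p"] = -np.log10(df["p"])
    df = df.sort_values("p", kind="mergesort")
    df.index.name = "protein"
    return df.reset_index()[["protein", "log2fc", "t", "p", "neg_log10_p", "significant"]]
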