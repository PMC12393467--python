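"""IP-enrichment statistics for log2 protein-intensity matrices.

Reimplements the Perseus-style recipe used for immunoprecipitation
enrichment analysis: quantile normalization (missing values handled by rank
interpolation), left-censored Gaussian imputation (down-shifted normal,
width 0.3 and down-shift 1.8 column standard deviations), per-protein Welch
t-tests, and permutation-based FDR (with Benjamini-Hochberg available as an
alternative).

Matrices are pandas DataFrames with proteins as rows and samples as
columns; group labels map each sample to one of exactly two groups.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean reference distribution.

    After normalization every complete column has identical sorted values
    (the row-wise mean of the per-column quantile functions).  Missing
    values stay missing; columns with missing entries are mapped through
    rank interpolation on the common quantile grid.  The operation is
    idempotent.  A single-column matrix is returned unchanged with a
    warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning "
                      "input unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    n_rows = values.shape[0]
    grid = np.linspace(0.0, 1.0, n_rows)
    # reference distribution: mean across columns of each column's quantile
    # function evaluated on the common grid
    quantile_curves = []
    for j in range(values.shape[1]):
        col = values[:, j]
        observed = np.sort(col[~np.isnan(col)])
        if observed.size == 0:
            raise ValueError(f"column '{matrix.columns[j]}' has no observed values")
        if observed.size == 1:
            quantile_curves.append(np.full(n_rows, observed[0]))
        else:
            pts = np.linspace(0.0, 1.0, observed.size)
            quantile_curves.append(np.interp(grid, pts, observed))
    reference = np.mean(quantile_curves, axis=0)

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        ranks = stats.rankdata(col[mask], method="average")
        pts = (ranks - 1.0) / (m - 1.0) if m > 1 else np.zeros(m)
        out[mask, j] = np.interp(pts, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_gaussian(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Left-censored imputation from a down-shifted normal, per column.

    For a column with observed mean ``m`` and standard deviation ``s``,
    missing entries are drawn from ``Normal(m - downshift * s,
    (width * s)**2)``.  Observed entries are untouched; deterministic for a
    fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float).copy()
    for j, col_name in enumerate(matrix.columns):
        col = values[:, j]
        observed = col[~np.isnan(col)]
        missing = np.isnan(col)
        if not missing.any():
            continue
        if observed.size < 2:
            raise ValueError(
                f"column '{col_name}' needs >= 2 observed values to impute"
            )
        m = observed.mean()
        s = observed.std(ddof=1)
        col[missing] = rng.normal(m - downshift * s, width * s, missing.sum())
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def _group_indices(
    columns: Sequence[str], groups: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    labels = [groups[c] for c in columns]
    names: list[str] = []
    for lab in labels:
        if lab not in names:
            names.append(lab)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    idx_a = np.array([i for i, lab in enumerate(labels) if lab == names[0]])
    idx_b = np.array([i for i, lab in enumerate(labels) if lab == names[1]])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    return idx_a, idx_b, (names[0], names[1])


def differential(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: Optional[int] = None,
    method: str = "permutation",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided per-protein t-tests with permutation-based FDR.

    The matrix must be complete (imputed).  The log2 fold change is the
    second group's mean minus the first group's mean (groups ordered by
    first appearance among the columns).

    Permutation FDR: for each observed ``|t|`` threshold the q-value is the
    median permutation count of ``|t_perm| >=`` threshold divided by the
    observed count, monotonized so q never decreases as the threshold
    relaxes.  All distinct label permutations are enumerated when there are
    at most 500 of them, otherwise ``n_perm`` seeded Monte-Carlo draws are
    used.  ``method="bh"`` switches to Benjamini-Hochberg adjustment.

    Returns a DataFrame with columns log2fc, t, p, q, significant.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix contains missing values; impute first")
    values = matrix.to_numpy(dtype=float)
    idx_a, idx_b, (name_a, name_b) = _group_indices(matrix.columns, groups)

    res = stats.ttest_ind(values[:, idx_a], values[:, idx_b], axis=1,
                          equal_var=equal_var)
    # zero-variance rows (possible after quantile normalization when a row
    # holds the same rank in every column) carry no evidence: t = 0, p = 1
    t_obs = np.nan_to_num(np.asarray(res.statistic), nan=0.0)
    p_obs = np.where(np.isfinite(np.asarray(res.pvalue)),
                     np.asarray(res.pvalue), 1.0)
    log2fc = values[:, idx_b].mean(axis=1) - values[:, idx_a].mean(axis=1)

    if method == "bh":
        _, q, _, _ = multipletests(p_obs, method="fdr_bh")
    elif method == "permutation":
        q = _permutation_q(values, idx_a, idx_b, t_obs, n_perm, seed,
                           equal_var)
    else:
        raise ValueError(f"unknown method '{method}'")

    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_obs,
            "p": p_obs,
            "q": q,
            "significant": q <= fdr,
        },
        index=matrix.index,
    )
    frame.attrs["groups"] = (name_a, name_b)
    return frame


def _permutation_q(
    values: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    t_obs: np.ndarray,
    n_perm: int,
    seed: Optional[int],
    equal_var: bool,
) -> np.ndarray:
    n_samples = values.shape[1]
    k = len(idx_a)
    all_assignments = list(combinations(range(n_samples), k))
    if len(all_assignments) <= 500:
        assignments = all_assignments
    else:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(all_assignments), size=n_perm)
        assignments = [all_assignments[i] for i in picks]

    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs)  # descending
    sorted_abs = abs_obs[order]
    # observed count of |t| >= threshold for each threshold = rank + 1
    observed_counts = np.arange(1, len(sorted_abs) + 1)

    perm_counts = np.empty((len(assignments), len(sorted_abs)))
    for i, pick in enumerate(assignments):
        pa = np.array(pick)
        pb = np.array([j for j in range(n_samples) if j not in set(pick)])
        res = stats.ttest_ind(values[:, pa], values[:, pb], axis=1,
                              equal_var=equal_var)
        abs_perm = np.sort(np.abs(
            np.nan_to_num(np.asarray(res.statistic), nan=0.0)))
        # count of |t_perm| >= each threshold
        perm_counts[i] = len(abs_perm) - np.searchsorted(
            abs_perm, sorted_abs, side="left"
        )
    median_false = np.median(perm_counts, axis=0)
    q_sorted = np.clip(median_false / observed_counts, 0.0, 1.0)
    # monotonize conservatively: a protein's q is the worst estimated FDR
    # over all thresholds at least as strict as its own, so q never
    # benefits from noisy dips of the plug-in estimate (few distinct
    # permutations exist at small sample sizes)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_matrix_tsv(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, target) -> None:
    matrix.to_csv(target, sep="\t", float_format="%.6g")


def write_results_tsv(results: pd.DataFrame, target) -> None:
    out = results.copy()
    out.insert(0, "id", out.index)
    out.to_csv(target, sep="\t", index=False, float_format="%.6g")
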