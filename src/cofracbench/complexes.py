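"""Complex-level co-fractionation statistics.

For each complex the statistic is the mean pairwise (zero-fill) Pearson
correlation over all within-complex profile pairs, pooled flat across
datasets — every comparison weighted equally. Significance comes from a
permutation null that, in each dataset, resamples random protein sets of the
same size as the observed complex membership in that dataset, so the null
preserves each dataset's marginal profile statistics and the complex's
per-dataset pooling weights.

Two one-sided add-one p-values are computed per complex (high tail =
enriched for co-elution, low tail = depleted) and Benjamini-Hochberg
corrected separately across complexes within each family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataio import ComplexDatabase, Dataset
from .similarity import unit_row_matrix

__all__ = [
    "ComplexCofracStat",
    "complex_internal_correlation",
    "permutation_null",
    "complex_significance",
    "housekeeping_complexes",
    "connection_matrix",
]


@dataclass(frozen=True)
class ComplexCofracStat:
    complex_id: str
    n_observed_members: int
    n_pairwise: int
    mean_r: float
    p_high: float
    p_low: float
    q_high: float
    q_low: float
    klass: str  # enriched / depleted / neither


class _DatasetArrays:
    """Unit-norm row matrix of a dataset plus a protein → row lookup."""

    def __init__(self, dataset: Dataset):
        self.dataset_id = dataset.dataset_id
        self.Z, idx = unit_row_matrix(dataset)
        self.pos = {p: i for i, p in enumerate(idx)}
        self.n_proteins = len(idx)

    def rows(self, members: Iterable[str]) -> np.ndarray:
        return np.asarray(sorted(self.pos[m] for m in members if m in self.pos), dtype=int)


def _prepare(datasets: Sequence[Dataset]) -> list[_DatasetArrays]:
    return [d if isinstance(d, _DatasetArrays) else _DatasetArrays(d) for d in datasets]


def _pair_sum(Z: np.ndarray, rows: np.ndarray) -> float:
    """Sum of pairwise correlations among unit-norm rows via the Gram identity.

    For unit vectors, sum_{i<j} z_i.z_j = (|sum_i z_i|^2 - m) / 2.
    """
    s = Z[rows].sum(axis=0)
    m = len(rows)
    return float((s @ s - m) / 2.0)


def complex_internal_correlation(
    members: Iterable[str], datasets: Sequence[Dataset]
) -> tuple[float, int]:
    """Mean within-complex pairwise R pooled flat across datasets.

    Returns ``(nan, 0)`` when no dataset quantifies at least two members
    (the complex is unobserved, not an error).
    """
    members = set(members)
    arrays = _prepare(datasets)
    total = 0.0
    count = 0
    for arr in arrays:
        rows = arr.rows(members)
        m = len(rows)
        if m >= 2:
            total += _pair_sum(arr.Z, rows)
            count += m * (m - 1) // 2
    if count == 0:
        return float("nan"), 0
    return total / count, count


def _null_means(
    arrays: Sequence[_DatasetArrays],
    member_counts: Sequence[int],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled mean pairwise R for random protein sets matching per-dataset sizes."""
    pair_sums = np.zeros(n_perm)
    pair_counts = 0
    for arr, m in zip(arrays, member_counts):
        if m < 2:
            continue
        # n_perm random subsets of size m without replacement
        scores = rng.random((n_perm, arr.n_proteins))
        idx = np.argpartition(scores, m - 1, axis=1)[:, :m]
        S = arr.Z[idx].sum(axis=1)  # (n_perm, n_fractions)
        pair_sums += (np.einsum("ij,ij->i", S, S) - m) / 2.0
        pair_counts += m * (m - 1) // 2
    if pair_counts == 0:
        raise ValueError("no dataset can host a null set of the requested size")
    return pair_sums / pair_counts


def permutation_null(
    datasets: Sequence[Dataset],
    n_members: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Empirical null of the pooled mean pairwise R for random size-``n_members`` sets.

    Each permutation draws an independent random protein set of size
    ``n_members`` from every dataset with at least that many usable profiles,
    and records the pooled mean pairwise correlation. Reproducible under seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = _prepare(datasets)
    counts = [n_members if arr.n_proteins >= n_members else 0 for arr in arrays]
    if not any(c >= 2 for c in counts):
        raise ValueError(
            f"fewer than {n_members} quantified proteins in every dataset"
        )
    return _null_means(arrays, counts, n_perm, rng)


def _add_one_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    n = len(null)
    p_high = (1 + int((null >= observed).sum())) / (1 + n)
    p_low = (1 + int((null <= observed).sum())) / (1 + n)
    return p_high, p_low


def complex_significance(
    db: ComplexDatabase,
    datasets: Sequence[Dataset],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation significance of within-complex co-elution for every observed complex.

    Returns one row per observed complex (>= 2 members quantified in >= 1
    dataset) with the pooled mean R, add-one permutation p-values for the
    high and low tails, BH-adjusted q-values (the two one-sided families are
    corrected separately), and a class at the given alpha:
    ``enriched`` (q_high < alpha), ``depleted`` (q_low < alpha) or
    ``neither``. Unobserved complexes are absent from the table.
    """
    arrays = _prepare(datasets)
    rng = np.random.default_rng(seed)
    rows = []
    for cid in db.complex_ids:
        members = db.members(cid)
        per_ds_rows = [arr.rows(members) for arr in arrays]
        counts = [len(r) if len(r) >= 2 else 0 for r in per_ds_rows]
        n_pairwise = sum(m * (m - 1) // 2 for m in counts)
        if n_pairwise == 0:
            continue
        total = sum(
            _pair_sum(arr.Z, r)
            for arr, r, m in zip(arrays, per_ds_rows, counts)
            if m >= 2
        )
        mean_r = total / n_pairwise
        null = _null_means(arrays, counts, n_perm, rng)
        p_high, p_low = _add_one_p(null, mean_r)
        n_obs = len({m for arr in arrays for m in members if m in arr.pos})
        rows.append(
            {
                "complex_id": cid,
                "n_observed_members": n_obs,
                "n_pairwise": n_pairwise,
                "mean_r": mean_r,
                "p_high": p_high,
                "p_low": p_low,
            }
        )
    stats = pd.DataFrame(
        rows,
        columns=["complex_id", "n_observed_members", "n_pairwise", "mean_r",
                 "p_high", "p_low"],
    )
    if len(stats) == 0:
        raise ValueError("no complex is observed in the provided datasets")
    stats["q_high"] = multipletests(stats["p_high"], method="fdr_bh")[1]
    stats["q_low"] = multipletests(stats["p_low"], method="fdr_bh")[1]

    def classify(row) -> str:
        hi, lo = row["q_high"] < alpha, row["q_low"] < alpha
        if hi and lo:  # complementary tails make this near-impossible; break by p
            return "enriched" if row["p_high"] < row["p_low"] else "depleted"
        if hi:
            return "enriched"
        if lo:
            return "depleted"
        return "neither"

    stats["class"] = stats.apply(classify, axis=1)
    return stats


def housekeeping_complexes(
    tissue_datasets: Mapping[str, Sequence[Dataset] | Dataset],
    db: ComplexDatabase,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> frozenset[str]:
    """Complexes co-eluting significantly better than chance in *every* tissue.

    Per tissue, each complex's p_high is an uncorrected add-one permutation
    p-value (matched null); a complex is housekeeping iff it is observed and
    p_high < alpha in all tissues. Requires >= 2 tissues.
    """
    if len(tissue_datasets) < 2:
        raise ValueError("need datasets from at least 2 tissues")
    rng = np.random.default_rng(seed)
    selected: set[str] | None = None
    for tissue in sorted(tissue_datasets):
        ds = tissue_datasets[tissue]
        datasets = [ds] if isinstance(ds, Dataset) else list(ds)
        arrays = _prepare(datasets)
        passing: set[str] = set()
        candidates = db.complex_ids if selected is None else sorted(selected)
        for cid in candidates:
            members = db.members(cid)
            per_ds_rows = [arr.rows(members) for arr in arrays]
            counts = [len(r) if len(r) >= 2 else 0 for r in per_ds_rows]
            n_pairwise = sum(m * (m - 1) // 2 for m in counts)
            if n_pairwise == 0:
                continue
            total = sum(
                _pair_sum(arr.Z, r)
                for arr, r, m in zip(arrays, per_ds_rows, counts)
                if m >= 2
            )
            null = _null_means(arrays, counts, n_perm, rng)
            p_high, _ = _add_one_p(null, total / n_pairwise)
            if p_high < alpha:
                passing.add(cid)
        selected = passing if selected is None else (selected & passing)
        if not selected:
            break
    return frozenset(selected or set())


def connection_matrix(
    members: Iterable[str], datasets: Sequence[Dataset]
) -> pd.DataFrame:
    """Symmetric matrix of mean pairwise R averaged over datasets.

    Entry (i, j) averages pearson correlations over the datasets quantifying
    both proteins; NaN marks pairs never co-detected. Rows/columns are
    ordered by decreasing average pairwise correlation; the diagonal is 1.
    """
    members = sorted(set(members))
    if len(members) < 2:
        raise ValueError("need >= 2 members for a connection matrix")
    arrays = _prepare(datasets)
    n = len(members)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for arr in arrays:
        present = [i for i, m in enumerate(members) if m in arr.pos]
        if len(present) < 2:
            continue
        rows = np.asarray([arr.pos[members[i]] for i in present])
        sub = arr.Z[rows] @ arr.Z[rows].T
        ii = np.ix_(present, present)
        acc[ii] += sub
        cnt[ii] += 1
    with np.errstate(invalid="ignore"):
        mean = acc / cnt
    np.fill_diagonal(mean, 1.0)
    mat = pd.DataFrame(mean, index=members, columns=members)
    off = mat.where(~np.eye(n, dtype=bool))
    order = off.mean(axis=1, skipna=True).sort_values(ascending=False, kind="stable").index
    return mat.loc[order, order]
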