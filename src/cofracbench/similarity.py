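"""Pairwise co-fractionation similarity and anti-correlation summaries.

Two conventions govern everything here:

* missing chromatogram values are replaced by zeros before any comparison
  (a missing SILAC ratio is evidence of absence in that fraction);
* for Euclidean distance each chromatogram is first min-max normalized to
  [0, 1], after zero-filling.

Profiles that are constant after zero-filling have no defined correlation and
are excluded from both metrics (counted, not imputed).

The headline summary is the *anti-correlated fraction*: the share of pairs
with Pearson R below a threshold (default 0), a conservative marker of
non-interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataio import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_zero_fill",
    "euclidean_minmax",
    "pair_similarity_table",
    "anticorrelated_fraction",
    "stratify_by_evidence_code",
    "AnticorrelatedResult",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def zero_fill(x) -> np.ndarray:
    """Replace missing values (NaN) by zeros."""
    v = _as_array(x).copy()
    v[np.isnan(v)] = 0.0
    return v


def pearson_zero_fill(x, y) -> float:
    """Pearson correlation of two chromatograms after zero-filling missing values.

    Returns NaN when either vector is constant after filling (undefined
    correlation; callers exclude and count such pairs).
    """
    xv, yv = zero_fill(x), zero_fill(y)
    if xv.shape != yv.shape:
        raise ValueError("profiles must share the fraction axis")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    r = float((xc @ yc) / (nx * ny))
    return min(1.0, max(-1.0, r))


def minmax_normalize(x) -> np.ndarray:
    """Scale a zero-filled chromatogram to min 0, max 1. NaN vector if constant."""
    v = zero_fill(x)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, np.nan)
    return (v - lo) / (hi - lo)


def euclidean_minmax(x, y) -> float:
    """Euclidean distance between min-max normalized, zero-filled chromatograms.

    NaN for profiles that are constant after zero-filling (degenerate
    normalization).
    """
    xn, yn = minmax_normalize(x), minmax_normalize(y)
    if xn.shape != yn.shape:
        raise ValueError("profiles must share the fraction axis")
    if np.isnan(xn).any() or np.isnan(yn).any():
        return float("nan")
    d = xn - yn
    return float(np.sqrt(d @ d))


def _usable_rows(dataset: Dataset) -> tuple[np.ndarray, pd.Index]:
    """Zero-filled matrix restricted to rows non-constant after filling."""
    mat = dataset.data.to_numpy(copy=True)
    mat[np.isnan(mat)] = 0.0
    ok = mat.max(axis=1) > mat.min(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: excluding %d constant profiles", dataset.dataset_id, n_dropped)
    return mat[ok], dataset.proteins[ok]


def unit_row_matrix(dataset: Dataset) -> tuple[np.ndarray, pd.Index]:
    """Rows zero-filled, centered and scaled to unit norm.

    Pairwise Pearson correlations are then plain dot products, which the
    complex-level statistics exploit heavily.
    """
    mat, idx = _usable_rows(dataset)
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1)
    return mat / norms[:, None], idx


def _minmax_matrix(dataset: Dataset) -> tuple[np.ndarray, pd.Index]:
    mat, idx = _usable_rows(dataset)
    lo = mat.min(axis=1, keepdims=True)
    hi = mat.max(axis=1, keepdims=True)
    return (mat - lo) / (hi - lo), idx


def pair_similarity_table(
    dataset: Dataset,
    pairs: Iterable[tuple[str, str]],
    gold: Iterable[tuple[str, str]] = (),
    evidence: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Per-pair Pearson R and Euclidean distance in one dataset.

    Pairs with either protein absent from the dataset, or with a degenerate
    (constant) profile, are omitted; the omission count is recorded in
    ``table.attrs['n_excluded']``. Labels are ``gold`` / ``non-gold``.
    """
    gold = set(gold)
    pairs = list(pairs)
    Z, idx = unit_row_matrix(dataset)
    M, midx = _minmax_matrix(dataset)
    assert idx.equals(midx)
    pos = {p: i for i, p in enumerate(idx)}
    ia, ib, kept = [], [], []
    n_excluded = 0
    for a, b in pairs:
        if a in pos and b in pos:
            ia.append(pos[a])
            ib.append(pos[b])
            kept.append((a, b))
        else:
            n_excluded += 1
    ia = np.asarray(ia, dtype=int)
    ib = np.asarray(ib, dtype=int)
    if len(kept):
        r = np.einsum("ij,ij->i", Z[ia], Z[ib])
        np.clip(r, -1.0, 1.0, out=r)
        diff = M[ia] - M[ib]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    else:
        r = np.empty(0)
        d = np.empty(0)
    table = pd.DataFrame(
        {
            "protein_a": [p[0] for p in kept],
            "protein_b": [p[1] for p in kept],
            "dataset_id": dataset.dataset_id,
            "pearson_r": r,
            "euclidean_d": d,
            "label": ["gold" if p in gold else "non-gold" for p in kept],
        }
    )
    if evidence is not None:
        table["evidence_code"] = [evidence.get(p, "") for p in kept]
    table.attrs["n_excluded"] = n_excluded
    return table


@dataclass(frozen=True)
class AnticorrelatedResult:
    fraction: float
    n_below: int
    n_total: int


def anticorrelated_fraction(table: pd.DataFrame, r_threshold: float = 0.0) -> AnticorrelatedResult:
    """Fraction of pairs with Pearson R strictly below ``r_threshold`` (default 0)."""
    if len(table) == 0:
        raise ValueError("anticorrelated fraction is undefined on an empty table")
    r = table["pearson_r"].to_numpy()
    n_below = int((r < r_threshold).sum())
    return AnticorrelatedResult(n_below / len(r), n_below, len(r))


def stratify_by_evidence_code(
    table: pd.DataFrame,
    min_pairs_per_code: int = 100,
    r_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per (dataset, evidence code) anti-correlated fraction and mean R.

    Codes with fewer than ``min_pairs_per_code`` pairs in a dataset are
    omitted for that dataset (default 100).
    """
    if "evidence_code" not in table.columns:
        raise ValueError("table has no 'evidence_code' column")
    rows = []
    for (ds, code), grp in table.groupby(["dataset_id", "evidence_code"], sort=True):
        if len(grp) < min_pairs_per_code:
            continue
        r = grp["pearson_r"].to_numpy()
        rows.append(
            {
                "dataset_id": ds,
                "evidence_code": code,
                "n_pairs": len(grp),
                "frac_anticorrelated": float((r < r_threshold).mean()),
                "mean_r": float(r.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dataset_id", "evidence_code", "n_pairs", "frac_anticorrelated", "mean_r"],
    )
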