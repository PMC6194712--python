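"""Expression-consistency (Gini) analysis of complex membership groups.

The Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 xbar), computed per
protein across tissues, measures how unevenly a protein is expressed: 0 for
perfectly even expression, approaching 1 for expression confined to one
tissue. Housekeeping-like complexes should score low.

Groups (proteins of co-fractionation-specific complexes vs proteins of other
complexes) are compared with a Welch two-sample t-test; overlap of two
complex sets is tested with the shared hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import hypergeometric_upper_tail

logger = logging.getLogger(__name__)

__all__ = ["gini", "gini_profile", "group_gini_comparison", "overlap_test",
           "GiniComparison"]


def gini(values) -> float:
    """Gini coefficient of nonnegative values; NaN dropped.

    Computed with the sorted closed form
    G = (2 * sum_i i*x_(i)) / (n * sum x) - (n + 1)/n. Undefined (< 2
    non-missing values, or all zero) returns NaN; negative values raise.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if (v < 0).any():
        raise ValueError("Gini requires nonnegative values")
    if len(v) < 2 or v.sum() == 0:
        return float("nan")
    v = np.sort(v)
    n = len(v)
    i = np.arange(1, n + 1)
    g = 2.0 * (i @ v) / (n * v.sum()) - (n + 1) / n
    return float(max(0.0, g))


def gini_profile(expr: pd.DataFrame) -> pd.Series:
    """Per-protein Gini across tissue columns; undefined rows are NaN (logged)."""
    out = expr.apply(lambda row: gini(row.to_numpy()), axis=1)
    n_bad = int(out.isna().sum())
    if n_bad:
        logger.info("skipping %d proteins with undefined Gini", n_bad)
    out.name = "gini"
    return out


@dataclass(frozen=True)
class GiniComparison:
    mean_cf_specific: float
    mean_other: float
    t_stat: float
    p_value: float
    n_cf_specific: int
    n_other: int


def group_gini_comparison(
    expr: pd.DataFrame,
    cf_specific_proteins: Iterable[str],
    other_proteins: Iterable[str],
) -> GiniComparison:
    """Welch t-test of per-protein Gini between complex-membership groups.

    Proteins appearing in both groups are assigned to the cf-specific group.
    Both groups need >= 2 proteins with a defined Gini.
    """
    cf = set(cf_specific_proteins)
    other = set(other_proteins) - cf
    g = gini_profile(expr).dropna()
    g_cf = g[g.index.isin(cf)]
    g_other = g[g.index.isin(other)]
    if len(g_cf) < 2 or len(g_other) < 2:
        raise ValueError(
            f"degenerate group sizes: cf={len(g_cf)}, other={len(g_other)}"
        )
    t, p = stats.ttest_ind(g_cf, g_other, equal_var=False)
    return GiniComparison(
        mean_cf_specific=float(g_cf.mean()),
        mean_other=float(g_other.mean()),
        t_stat=float(t),
        p_value=float(p),
        n_cf_specific=len(g_cf),
        n_other=len(g_other),
    )


def overlap_test(set_a: Iterable, set_b: Iterable, universe_size: int) -> float:
    """Hypergeometric upper-tail p of the overlap |A ∩ B| in a finite universe."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    return hypergeometric_upper_tail(k, len(a), len(b), universe_size)
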