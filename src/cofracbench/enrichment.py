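"""Mapping published interactomes onto complexes and enrichment statistics.

An interactome "supports" a complex when the complex holds significantly more
of the interactome's edges than the database-wide within-complex edge rate
(one-sided hypergeometric test). The universe is restricted to within-complex
pair slots over proteins actually observed in the interactome, so the
"average rate" is the within-database edge density; this choice is explicit
and the only one whose degenerate cases (p = 1) are forced rather than
silent.

Detectability controls ("could a single interaction have been predicted at
all?") are technique-specific: CF needs two co-complex members in the raw
quantified roster, AP-MS (matrix model) needs two members among interactome
proteins, Y2H needs one member among the baits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataio import ComplexDatabase, Interactome

__all__ = [
    "hypergeometric_upper_tail",
    "map_edges_to_complexes",
    "enrich_complexes",
    "could_predict",
    "predicted_flag_matrix",
    "technique_specific_complexes",
    "technique_specific_chance",
    "ChanceResult",
]


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def map_edges_to_complexes(
    interactome: Interactome, db: ComplexDatabase
) -> pd.DataFrame:
    """Per-complex possible vs predicted within-complex pair counts.

    The universe is the set of interactome proteins that belong to at least
    one complex. A complex appears in the output only when >= 2 of its
    members are in the universe (otherwise it is unobserved by this
    interactome). ``n_pairs_possible`` counts within-complex pairs with both
    members in the universe; ``n_pairs_predicted`` counts those present as
    edges.
    """
    universe = interactome.proteins & db.protein_universe
    edges = interactome.edges
    rows = []
    for cid in db.complex_ids:
        present = sorted(db.members(cid) & universe)
        m = len(present)
        if m < 2:
            continue
        possible = m * (m - 1) // 2
        predicted = sum(
            1
            for i in range(m)
            for j in range(i + 1, m)
            if (present[i], present[j]) in edges
        )
        rows.append(
            {
                "complex_id": cid,
                "n_members_in_universe": m,
                "n_pairs_possible": possible,
                "n_pairs_predicted": predicted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["complex_id", "n_members_in_universe", "n_pairs_possible",
                 "n_pairs_predicted"],
    )


def could_predict(members: Iterable[str], interactome: Interactome) -> bool:
    """Whether at least one within-complex interaction could have been predicted.

    CF: >= 2 members in the quantified raw-data roster. AP-MS (matrix
    model): >= 2 members among interactome proteins. Y2H: >= 1 member among
    baits. A missing roster required by the technique is an error.
    """
    members = set(members)
    t = interactome.technique
    if t == "CF":
        if interactome.quantified is None:
            raise ValueError(f"{interactome.label}: CF requires a quantified roster")
        return len(members & interactome.quantified) >= 2
    if t == "AP-MS":
        return len(members & interactome.proteins) >= 2
    if t == "Y2H":
        if interactome.baits is None:
            raise ValueError(f"{interactome.label}: Y2H requires a bait list")
        return len(members & interactome.baits) >= 1
    raise ValueError(f"unknown technique {t!r}")


def enrich_complexes(interactome: Interactome, db: ComplexDatabase) -> pd.DataFrame:
    """Hypergeometric enrichment of interactome edges within every observed complex.

    For a complex with ``n`` possible and ``k`` predicted pairs, and database
    totals ``N`` possible and ``K`` predicted,
    ``p_hyper = P(X >= k), X ~ Hypergeom(N, K, n)``. ``predicted_flag`` marks
    complexes with >= 1 within-complex edge. ``could_predict`` is filled when
    the technique's roster is available, else left NA.
    """
    records = map_edges_to_complexes(interactome, db)
    records = records.copy()
    records["interactome_label"] = interactome.label
    if len(records) == 0:
        records["p_hyper"] = pd.Series(dtype=float)
        records["predicted_flag"] = pd.Series(dtype=bool)
        records["could_predict"] = pd.Series(dtype=object)
        return records
    N = int(records["n_pairs_possible"].sum())
    K = int(records["n_pairs_predicted"].sum())
    records["p_hyper"] = [
        hypergeometric_upper_tail(int(k), K, int(n), N)
        for k, n in zip(records["n_pairs_predicted"], records["n_pairs_possible"])
    ]
    records["predicted_flag"] = records["n_pairs_predicted"] >= 1
    try:
        records["could_predict"] = [
            could_predict(db.members(cid), interactome)
            for cid in records["complex_id"]
        ]
    except ValueError:
        records["could_predict"] = pd.NA
    return records


def predicted_flag_matrix(records: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Boolean complexes × interactomes matrix of predicted flags.

    ``records`` maps interactome label → enrichment record table. Complexes
    unobserved by an interactome get False there.
    """
    cols = {}
    for label in sorted(records):
        rec = records[label]
        cols[label] = rec.set_index("complex_id")["predicted_flag"]
    df = pd.DataFrame(cols)
    flags = df.notna() & df.eq(True)  # unobserved complexes -> False
    return flags.sort_index()


def _default_min_within(n_interactomes: int) -> int:
    # the 2-of-3 / 4-of-6 consensus rule, generalized to ceil(2n/3)
    return max(1, math.ceil(2 * n_interactomes / 3))


def technique_specific_complexes(
    flags: pd.DataFrame,
    techniques: Mapping[str, str],
    technique: str,
    min_within: int | None = None,
    max_other: int = 1,
) -> frozenset[str]:
    """Complexes predicted consistently by one technique and rarely by the others.

    Selected complexes have predicted_flag in >= ``min_within`` interactomes
    of ``technique`` (default: two-thirds of them, i.e. 4-of-6 or 2-of-3) and
    in <= ``max_other`` interactomes of *each* other technique (default 1).
    """
    within_cols = [c for c in flags.columns if techniques[c] == technique]
    if not within_cols:
        raise ValueError(f"no interactomes of technique {technique!r}")
    if min_within is None:
        min_within = _default_min_within(len(within_cols))
    other_techs = {techniques[c] for c in flags.columns} - {technique}
    within_counts = flags[within_cols].sum(axis=1)
    ok = within_counts >= min_within
    for t in sorted(other_techs):
        cols = [c for c in flags.columns if techniques[c] == t]
        ok &= flags[cols].sum(axis=1) <= max_other
    return frozenset(flags.index[ok])


@dataclass(frozen=True)
class ChanceResult:
    observed: int
    expected: float
    p_value: float


def technique_specific_chance(
    flags: pd.DataFrame,
    techniques: Mapping[str, str],
    technique: str,
    n_boot: int = 1000,
    seed: int = 0,
    min_within: int | None = None,
    max_other: int = 1,
) -> ChanceResult:
    """Bootstrap chance model for the technique-specific complex count.

    Each bootstrap independently permutes, per interactome, which complexes
    carry a predicted flag (preserving each interactome's number of predicted
    complexes), then reapplies the selection rule. Returns the observed
    count, the mean bootstrap count, and an add-one p-value
    P(bootstrap count >= observed).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    observed = len(
        technique_specific_complexes(flags, techniques, technique, min_within, max_other)
    )
    counts = np.empty(n_boot, dtype=int)
    values = flags.to_numpy()
    for b in range(n_boot):
        perm = np.column_stack(
            [rng.permutation(values[:, j]) for j in range(values.shape[1])]
        )
        shuffled = pd.DataFrame(perm, index=flags.index, columns=flags.columns)
        counts[b] = len(
            technique_specific_complexes(
                shuffled, techniques, technique, min_within, max_other
            )
        )
    p = (1 + int((counts >= observed).sum())) / (1 + n_boot)
    return ChanceResult(observed=observed, expected=float(counts.mean()), p_value=p)
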