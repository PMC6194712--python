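"""Co-fractionation-specific gold-standard subsets.

A complex enters the subset at threshold *t* when its hypergeometric
enrichment p-value is below *t* in **every** chosen held-out interactome
(conjunction). At the loose end, t = 1 reduces to "at least one
within-complex edge in each interactome". Subsets therefore nest across the
canonical threshold ladder (1, 1e-2, 1e-6, 1e-10).

Size-matched random pair subsets (sampled without replacement from the full
gold pair pool) are the control for the shrinking-gold-standard artefact:
precision estimates rise as a gold standard shrinks even without any signal,
because false-positive label pairs grow quadratically while true positives
grow linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ComplexDatabase, complex_to_pairs

__all__ = [
    "GoldSubset",
    "cf_specific_subset",
    "random_subset",
    "subset_table",
    "export_subset",
    "load_subset_table",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (1.0, 1e-2, 1e-6, 1e-10)


@dataclass(frozen=True)
class GoldSubset:
    threshold: float
    complex_ids: frozenset[str]
    pairs: frozenset[tuple[str, str]]
    provenance: tuple[str, ...]  # interactome labels the subset was derived from


def _passes(rec: pd.DataFrame, threshold: float) -> set[str]:
    rec = rec.set_index("complex_id")
    if threshold >= 1.0:
        return set(rec.index[rec["predicted_flag"]])
    return set(rec.index[(rec["p_hyper"] < threshold) & rec["predicted_flag"]])


def cf_specific_subset(
    db: ComplexDatabase,
    records: Mapping[str, pd.DataFrame],
    threshold: float,
    require_all: bool = True,
    min_interactomes: int | None = None,
) -> GoldSubset:
    """Complexes enriched below ``threshold`` in the chosen interactomes.

    ``records`` maps interactome label → enrichment record table
    (:func:`cofracbench.enrichment.enrich_complexes` output). By default the
    condition must hold in *all* interactomes; set ``require_all=False`` with
    ``min_interactomes=k`` for an any-k-of-n mode. The subset's pairs are the
    unique within-complex pairs of the selected complexes.
    """
    if not records:
        raise ValueError("no enrichment records provided")
    labels = sorted(records)
    hits = [_passes(records[lab], threshold) for lab in labels]
    if require_all:
        selected = set.intersection(*hits)
    else:
        if min_interactomes is None:
            raise ValueError("min_interactomes required when require_all=False")
        counts: dict[str, int] = {}
        for h in hits:
            for cid in h:
                counts[cid] = counts.get(cid, 0) + 1
        selected = {cid for cid, c in counts.items() if c >= min_interactomes}
    sub_db = ComplexDatabase(
        complexes={cid: db.complexes[cid] for cid in sorted(selected)},
        source_label=f"{db.source_label}|cf_specific<{threshold:g}",
    ) if selected else None
    pairs = frozenset(complex_to_pairs(sub_db)) if sub_db else frozenset()
    return GoldSubset(
        threshold=threshold,
        complex_ids=frozenset(selected),
        pairs=pairs,
        provenance=tuple(labels),
    )


def random_subset(
    pool: Iterable[tuple[str, str]],
    size: int,
    seed: int | np.random.Generator = 0,
) -> frozenset[tuple[str, str]]:
    """Uniform sample of ``size`` gold pairs without replacement."""
    pool = sorted(pool)
    if size > len(pool):
        raise ValueError(f"size {size} exceeds pool of {len(pool)} pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    return frozenset(pool[i] for i in idx)


def subset_table(
    db: ComplexDatabase,
    records: Mapping[str, pd.DataFrame],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Table-of-subsets export: one row per complex in the loosest subset,
    one boolean column per threshold."""
    thresholds = sorted(thresholds, reverse=True)
    subsets = {t: cf_specific_subset(db, records, t) for t in thresholds}
    loosest = subsets[thresholds[0]]
    rows = []
    for cid in sorted(loosest.complex_ids):
        row = {"complex_id": cid, "complex_name": db.complexes[cid][0]}
        for t in thresholds:
            row[_threshold_col(t)] = cid in subsets[t].complex_ids
        rows.append(row)
    cols = ["complex_id", "complex_name"] + [_threshold_col(t) for t in thresholds]
    return pd.DataFrame(rows, columns=cols)


def _threshold_col(t: float) -> str:
    return f"p < {t:g}"


def export_subset(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_subset_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col.startswith("p < "):
            df[col] = df[col].astype(bool)
    return df
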