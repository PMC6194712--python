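"""Domain types and I/O for co-fractionation benchmarking.

The central objects are:

* :class:`Dataset` — one co-fractionation experiment (a condition × replicate),
  holding one chromatogram per protein: SILAC ratios over ordered fractions,
  with explicit missing values (NaN).
* :class:`ComplexDatabase` — a curated complex catalogue (CORUM-core-like):
  complex id → (name, member accessions). Gold-standard *pairs* are derived
  from it with :func:`complex_to_pairs`.
* :class:`Interactome` — a published pairwise interaction set with its
  generating technique (CF, AP-MS or Y2H) and optional bait / quantified
  rosters used by detectability controls.

All protein identifiers are normalized on load: UniProt isoform suffixes
(``P07900-2`` → ``P07900``) are stripped, and protein groups (semicolon
separated accessions) collapse to their first accession.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FractionationProfile",
    "Dataset",
    "ComplexDatabase",
    "Interactome",
    "normalize_protein_id",
    "canonical_pair",
    "load_chromatograms",
    "write_chromatograms",
    "filter_min_fractions",
    "complex_to_pairs",
    "filter_by_publication_count",
    "load_expression",
    "write_expression",
]

#: tokens interpreted as a missing measurement on read; written back as empty cells
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na", "NULL", "null", "N/A")

# UniProt accession shapes (6 or 10 characters); only these get isoform stripping
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
_ISOFORM_RE = re.compile(r"^(?P<acc>.+?)-(?P<iso>\d+)$")


class FormatError(ValueError):
    """A structural problem in an input table (duplicate rows, bad cells...)."""


def normalize_protein_id(raw: str) -> str:
    """Strip a UniProt isoform tag (a single trailing ``-<digits>``) from an accession.

    Non-UniProt identifiers pass through unchanged; the operation is idempotent.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("protein identifier must be a non-empty string")
    acc = raw.strip()
    m = _ISOFORM_RE.match(acc)
    if m and _UNIPROT_RE.match(m.group("acc")):
        return m.group("acc")
    return acc


def _resolve_group(raw: str) -> str:
    """Collapse a semicolon-separated protein group to its first accession."""
    first = raw.split(";")[0]
    return normalize_protein_id(first)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in its unique canonical form (a < b)."""
    if a == b:
        raise ValueError(f"a protein cannot pair with itself: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class FractionationProfile:
    """One protein's SILAC-ratio trace over fractions in one dataset."""

    protein_id: str
    dataset_id: str
    values: pd.Series  # index: fraction 1..N (int), values: float, NaN = missing
    condition: str = ""
    replicate: str = ""

    @property
    def quantified_count(self) -> int:
        return int(self.values.notna().sum())


@dataclass
class Dataset:
    """A co-fractionation dataset: protein × fraction matrix of SILAC ratios.

    ``data`` is indexed by protein accession with integer fraction columns
    1..n_fractions; NaN marks a missing quantification.
    """

    dataset_id: str
    data: pd.DataFrame
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein rows in {self.dataset_id}: {dups}")
        n = self.data.shape[1]
        self.data = self.data.astype(float)
        self.data.columns = pd.RangeIndex(1, n + 1)
        self.data.index.name = "protein"
        if (self.data.to_numpy() < 0).any():
            raise FormatError(f"negative ratio values in {self.dataset_id}")

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def quantified_counts(self) -> pd.Series:
        """Number of non-missing fractions per protein."""
        return self.data.notna().sum(axis=1)

    def profile(self, protein_id: str) -> FractionationProfile:
        return FractionationProfile(
            protein_id=protein_id,
            dataset_id=self.dataset_id,
            values=self.data.loc[protein_id],
            condition=self.condition,
            replicate=self.replicate,
        )


def load_chromatograms(path: str | Path, dataset_id: str | None = None,
                       sep: str | None = None) -> Dataset:
    """Read a chromatogram table (first column protein IDs, then fractions in order).

    Empty cells and NA tokens denote missing values. Protein groups collapse to
    their first accession; isoform tags are stripped. Duplicate proteins (after
    normalization) and unparseable cells raise :class:`FormatError` with their
    location.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a protein column plus >=1 fraction column")
    proteins = [_resolve_group(p) for p in raw.iloc[:, 0]]
    values = raw.iloc[:, 1:].replace(list(MISSING_TOKENS), np.nan)
    try:
        mat = values.astype(float)
    except ValueError:
        for j, col in enumerate(values.columns):
            for i, cell in enumerate(values[col]):
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}: unparseable cell {cell!r} at row {i + 2}, "
                            f"column {j + 2}"
                        ) from None
        raise
    mat.index = pd.Index(proteins, name="protein")
    if mat.index.has_duplicates:
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate protein rows after ID normalization: {dups}")
    return Dataset(dataset_id=dataset_id or path.stem, data=mat)


def write_chromatograms(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset with header ``protein,frac1..fracN``; missing as empty cells."""
    out = dataset.data.copy()
    out.columns = [f"frac{i}" for i in out.columns]
    out.to_csv(path, sep=sep, na_rep="", index_label="protein")


def filter_min_fractions(dataset: Dataset, k: int = 5) -> Dataset:
    """Keep only profiles quantified in at least ``k`` fractions (default 5)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = dataset.quantified_counts >= k
    return Dataset(
        dataset_id=dataset.dataset_id,
        data=dataset.data.loc[keep],
        condition=dataset.condition,
        replicate=dataset.replicate,
    )


@dataclass
class ComplexDatabase:
    """Curated complex catalogue: complex_id → (name, member accession set)."""

    complexes: dict[str, tuple[str, frozenset[str]]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for cid, (_, members) in self.complexes.items():
            if len(members) < 2:
                raise FormatError(f"complex {cid} has < 2 members after normalization")

    def __len__(self) -> int:
        return len(self.complexes)

    def members(self, cid: str) -> frozenset[str]:
        return self.complexes[cid][1]

    @property
    def complex_ids(self) -> list[str]:
        return list(self.complexes)

    @property
    def protein_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.complexes.values():
            out |= members
        return frozenset(out)

    @classmethod
    def from_members(cls, members: Mapping[str, Iterable[str]],
                     source_label: str = "") -> "ComplexDatabase":
        complexes = {
            cid: (cid, frozenset(normalize_protein_id(m) for m in mem))
            for cid, mem in members.items()
        }
        return cls(complexes=complexes, source_label=source_label)

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str = "") -> "ComplexDatabase":
        """Read ``complex_id<TAB>complex_name<TAB>members`` (members ';'-separated)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"complex_id", "complex_name", "members"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        complexes: dict[str, tuple[str, frozenset[str]]] = {}
        for row in df.itertuples(index=False):
            members = frozenset(
                normalize_protein_id(m) for m in str(row.members).split(";") if m.strip()
            )
            if len(members) < 2:
                logger.warning("dropping complex %s: < 2 members after normalization",
                               row.complex_id)
                continue
            if row.complex_id in complexes:
                raise FormatError(f"{path}: duplicate complex id {row.complex_id}")
            complexes[row.complex_id] = (str(row.complex_name), members)
        return cls(complexes=complexes, source_label=source_label or str(path))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"complex_id": cid, "complex_name": name, "members": ";".join(sorted(mem))}
            for cid, (name, mem) in self.complexes.items()
        ]
        pd.DataFrame(rows, columns=["complex_id", "complex_name", "members"]).to_csv(
            path, sep="\t", index=False
        )


def complex_to_pairs(db: ComplexDatabase) -> set[tuple[str, str]]:
    """All unique unordered protein pairs co-member of at least one complex."""
    pairs: set[tuple[str, str]] = set()
    for _, members in db.complexes.values():
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                pairs.add((mem[i], mem[j]))
    return pairs


@dataclass
class Interactome:
    """A published interactome: canonical unique edges plus technique metadata.

    ``baits`` (Y2H) and ``quantified`` (CF raw-data roster) are optional and
    only needed by detectability controls.
    """

    label: str
    technique: str  # one of TECHNIQUES
    edges: frozenset[tuple[str, str]]
    baits: frozenset[str] | None = None
    quantified: frozenset[str] | None = None

    TECHNIQUES = ("CF", "AP-MS", "Y2H")

    def __post_init__(self) -> None:
        if self.technique not in self.TECHNIQUES:
            raise ValueError(
                f"technique must be one of {self.TECHNIQUES}, got {self.technique!r}"
            )
        for a, b in self.edges:
            if not a < b:
                raise ValueError(f"edge {(a, b)} is not in canonical order")

    @property
    def proteins(self) -> frozenset[str]:
        """Proteins appearing in at least one edge."""
        return frozenset(p for e in self.edges for p in e)

    @classmethod
    def from_edges(cls, label: str, technique: str,
                   edges: Iterable[tuple[str, str]],
                   baits: Iterable[str] | None = None,
                   quantified: Iterable[str] | None = None) -> "Interactome":
        canon = set()
        for a, b in edges:
            a, b = normalize_protein_id(a), normalize_protein_id(b)
            if a == b:  # isoform collapse can create self-pairs; drop them
                continue
            canon.add(canonical_pair(a, b))
        return cls(
            label=label,
            technique=technique,
            edges=frozenset(canon),
            baits=None if baits is None
            else frozenset(normalize_protein_id(p) for p in baits),
            quantified=None if quantified is None
            else frozenset(normalize_protein_id(p) for p in quantified),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, label: str, technique: str,
                 baits_path: str | Path | None = None,
                 quantified_path: str | Path | None = None) -> "Interactome":
        """Read ``protein_a<TAB>protein_b[<TAB>n_publications]`` edge lists."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"protein_a", "protein_b"}.issubset(df.columns):
            raise FormatError(f"{path}: expected columns protein_a, protein_b")
        baits = _read_roster(baits_path) if baits_path else None
        quantified = _read_roster(quantified_path) if quantified_path else None
        return cls.from_edges(
            label, technique, zip(df["protein_a"], df["protein_b"]),
            baits=baits, quantified=quantified,
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.edges)
        pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
            path, sep="\t", index=False
        )


def _read_roster(path: str | Path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def filter_by_publication_count(edges: pd.DataFrame, min_pubs: int = 2) -> frozenset[tuple[str, str]]:
    """Keep edges supported by at least ``min_pubs`` publications (default 2).

    ``edges`` must have columns ``protein_a``, ``protein_b``, ``n_publications``;
    a missing publication annotation is an error.
    """
    if "n_publications" not in edges.columns:
        raise FormatError("edge table lacks an 'n_publications' column")
    counts = pd.to_numeric(edges["n_publications"], errors="coerce")
    if counts.isna().any():
        bad = edges.index[counts.isna()].tolist()
        raise FormatError(f"missing/unparseable publication counts at rows {bad}")
    keep = edges.loc[counts >= min_pubs]
    return frozenset(
        canonical_pair(normalize_protein_id(a), normalize_protein_id(b))
        for a, b in zip(keep["protein_a"], keep["protein_b"])
    )


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a protein × tissue expression matrix (TSV, NaN for missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = pd.Index([_resolve_group(str(p)) for p in df.index], name="protein")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate tissue columns")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need >= 2 tissue columns")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", na_rep="", index_label="protein")
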