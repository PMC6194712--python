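"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of a co-fractionation
benchmarking study, so every pipeline stage can be exercised as a
parameter-recovery experiment:

* chromatograms — Gaussian elution peaks over fractions plus truncated
  Gaussian noise and uniform missingness. Complexes are planted in one of
  three classes: ``coeluting`` members share a peak center (jitter at most a
  quarter peak width), ``disrupted`` members get anti-phased centers spread
  evenly across the fraction axis (systematically worse than chance), and
  ``neutral`` members get independent random centers (indistinguishable from
  chance).
* interactomes — per technique (CF / AP-MS / Y2H), within-complex edges of
  that technique's detectable complexes are sampled at a detection
  probability, plus uniform cross noise edges; bait and quantified rosters
  are emitted where the technique requires them.
* expression — lognormal tissue profiles with low dispersion (CV) for
  housekeeping proteins (members of co-eluting complexes) and high
  dispersion for the rest.

All outputs are reproducible bytes-for-bytes under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import ComplexDatabase, Dataset, Interactome, canonical_pair

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_truth",
    "complex_database",
    "generate_dataset",
    "generate_datasets",
    "generate_interactomes",
    "generate_expression",
]

COMPLEX_CLASSES = ("coeluting", "disrupted", "neutral")
DEFAULT_INTERACTOME_COUNTS = {"CF": 6, "AP-MS": 3, "Y2H": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are sized so the full pipeline runs in minutes: 500 proteins,
    50 fractions, 60 complexes of size 2-10, 3 replicate datasets, 20%
    missing cells, noise at a tenth of the peak height, and a 60/20/20
    co-eluting / disrupted / neutral complex split.
    """

    n_proteins: int = 500
    n_fractions: int = 50
    n_complexes: int = 60
    complex_size_range: tuple[int, int] = (2, 10)
    frac_coeluting: float = 0.6
    frac_disrupted: float = 0.2
    peak_width: float = 3.0  # Gaussian sigma, in fractions
    peak_height: float = 10.0  # SILAC-ratio scale of the main peak
    envelope_sd: float | None = None  # spread of elution centers; default n_fractions/8
    coelution_jitter: float | None = None  # max member center shift; default peak_width/4
    noise_sd: float = 1.0
    missing_rate: float = 0.2
    n_datasets: int = 3
    n_tissues: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_coeluting", "frac_disrupted", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_coeluting + self.frac_disrupted > 1.0 + 1e-12:
            raise ValueError("frac_coeluting + frac_disrupted must be <= 1")
        lo, hi = self.complex_size_range
        if not (2 <= lo <= hi):
            raise ValueError("complex sizes must satisfy 2 <= lo <= hi")
        if (lo + hi) / 2.0 * self.n_complexes > self.n_proteins:
            raise ValueError("complexes cannot be disjoint: too few proteins")
        if self.n_fractions < 4 or self.n_proteins < 2:
            raise ValueError("degenerate simulation dimensions")
        if self.noise_sd < 0 or self.peak_height <= 0 or self.peak_width <= 0:
            raise ValueError("peak/noise parameters must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind one simulated study."""

    complex_members: dict[str, tuple[str, ...]]
    complex_class: dict[str, str]  # coeluting / disrupted / neutral
    technique_detectable: dict[str, frozenset[str]]
    housekeeping: frozenset[str]

    def complexes_of_class(self, klass: str) -> frozenset[str]:
        return frozenset(c for c, k in self.complex_class.items() if k == klass)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "complex_members": {c: list(m) for c, m in self.complex_members.items()},
            "complex_class": dict(self.complex_class),
            "technique_detectable": {
                t: sorted(s) for t, s in self.technique_detectable.items()
            },
            "housekeeping": sorted(self.housekeeping),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            complex_members={c: tuple(m) for c, m in payload["complex_members"].items()},
            complex_class=payload["complex_class"],
            technique_detectable={
                t: frozenset(s) for t, s in payload["technique_detectable"].items()
            },
            housekeeping=frozenset(payload["housekeeping"]),
        )


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SP{i:0{width}d}" for i in range(1, n + 1)]


def generate_truth(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> GroundTruth:
    """Plant disjoint complexes, their classes and technique detectability."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    proteins = np.array(_protein_ids(config.n_proteins))
    rng.shuffle(proteins)
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    while sizes.sum() > config.n_proteins:  # keep memberships disjoint
        sizes = np.maximum(lo, sizes - 1)
        if sizes.sum() == lo * config.n_complexes and sizes.sum() > config.n_proteins:
            raise ValueError("complexes cannot be disjoint: too few proteins")
    members: dict[str, tuple[str, ...]] = {}
    start = 0
    for i, size in enumerate(sizes):
        members[f"C{i + 1:03d}"] = tuple(sorted(proteins[start:start + size]))
        start += size
    cids = list(members)
    n_co = int(round(config.frac_coeluting * config.n_complexes))
    n_dis = int(round(config.frac_disrupted * config.n_complexes))
    n_dis = min(n_dis, config.n_complexes - n_co)
    classes = (["coeluting"] * n_co + ["disrupted"] * n_dis
               + ["neutral"] * (config.n_complexes - n_co - n_dis))
    order = rng.permutation(config.n_complexes)
    complex_class = {cids[i]: classes[j] for j, i in enumerate(order)}
    coeluting = frozenset(c for c in cids if complex_class[c] == "coeluting")
    non_cf = rng.permutation([c for c in cids if c not in coeluting])
    detectable = {
        "CF": coeluting,
        "AP-MS": frozenset(non_cf[: len(non_cf) // 2]),
        "Y2H": frozenset(non_cf[len(non_cf) // 2:]),
    }
    housekeeping = frozenset(p for c in coeluting for p in members[c])
    return GroundTruth(
        complex_members=members,
        complex_class=complex_class,
        technique_detectable=detectable,
        housekeeping=housekeeping,
    )


def complex_database(truth: GroundTruth,
                     source_label: str = "synthetic") -> ComplexDatabase:
    return ComplexDatabase(
        complexes={c: (c, frozenset(m)) for c, m in truth.complex_members.items()},
        source_label=source_label,
    )


def _gaussian(frac: np.ndarray, center: float, sigma: float,
              height: float) -> np.ndarray:
    return height * np.exp(-((frac - center) ** 2) / (2.0 * sigma ** 2))


def generate_dataset(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    dataset_id: str = "sim1",
    rng: np.random.Generator | None = None,
) -> tuple[Dataset, GroundTruth]:
    """One simulated co-fractionation dataset for the planted truth.

    Each protein's profile is a sum of 1-2 Gaussian peaks plus
    zero-truncated Gaussian noise. Elution centers are drawn from a shared
    envelope (Normal around the mid-axis with sd ``envelope_sd``) so that
    random protein pairs have a substantially positive chance correlation,
    as in real chromatograms. Co-eluting complex members share a peak center
    (jitter <= peak_width / 4 in this dataset); disrupted members get
    anti-phased centers spread evenly across the whole fraction axis;
    everything else gets an independent envelope draw. Cells go missing
    uniformly at ``missing_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if truth is None:
        truth = generate_truth(config, rng)
    F = config.n_fractions
    w = config.peak_width
    env_sd = config.envelope_sd if config.envelope_sd is not None else F / 8.0
    jitter = (config.coelution_jitter if config.coelution_jitter is not None
              else w / 4.0)
    frac = np.arange(1, F + 1, dtype=float)
    margin = min(2.0 * w, F / 4.0)

    def envelope_center() -> float:
        return float(np.clip(rng.normal(F / 2.0, env_sd), margin, F - margin))

    proteins = _protein_ids(config.n_proteins)
    centers: dict[str, float] = {}
    shared_only: set[str] = set()
    for cid, mem in truth.complex_members.items():
        klass = truth.complex_class[cid]
        if klass == "coeluting":
            c0 = envelope_center()
            for p in mem:
                centers[p] = c0 + rng.uniform(-jitter, jitter) if jitter else c0
                shared_only.add(p)
        elif klass == "disrupted":
            offset = rng.uniform(0.0, F)
            spread = rng.permutation(len(mem))
            for i, p in zip(spread, mem):
                centers[p] = (offset + i * F / len(mem)) % F
    profiles = np.empty((config.n_proteins, F))
    for row, p in enumerate(proteins):
        height = config.peak_height * rng.uniform(0.5, 1.5)
        center = centers.get(p)
        if center is None:
            center = envelope_center()
        y = _gaussian(frac, center, w, height)
        if p not in shared_only and rng.random() < 0.3:  # occasional second peak
            y = y + _gaussian(
                frac, envelope_center(), w, height * rng.uniform(0.3, 1.0)
            )
        y = y + rng.normal(0.0, config.noise_sd, size=F)
        profiles[row] = np.clip(y, 0.0, None)
    if config.missing_rate > 0:
        mask = rng.random(profiles.shape) < config.missing_rate
        profiles[mask] = np.nan
    data = pd.DataFrame(profiles, index=pd.Index(proteins, name="protein"),
                        columns=pd.RangeIndex(1, F + 1))
    return Dataset(dataset_id=dataset_id, data=data), truth


def generate_datasets(
    config: SimulationConfig,
    truth: GroundTruth,
    n: int | None = None,
    prefix: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[Dataset]:
    """Independent replicate datasets sharing one planted truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.n_datasets
    return [
        generate_dataset(config, truth, dataset_id=f"{prefix}{i + 1}", rng=rng)[0]
        for i in range(n)
    ]


def generate_interactomes(
    truth: GroundTruth,
    n_proteins: int,
    counts: Mapping[str, int] | int = None,
    detect_prob_within: float = 0.8,
    detect_prob_cross: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> list[Interactome]:
    """Synthetic published interactomes with technique-specific detectability.

    Each interactome of technique *t* samples within-complex edges of the
    complexes detectable by *t* at ``detect_prob_within``, plus uniform
    cross edges at rate ``detect_prob_cross`` over all protein pairs. Y2H
    interactomes get baits covering their detectable complexes plus random
    proteins; CF interactomes report all proteins as quantified.
    """
    if counts is None:
        counts = DEFAULT_INTERACTOME_COUNTS
    elif isinstance(counts, int):
        counts = {t: counts for t in DEFAULT_INTERACTOME_COUNTS}
    if not (0 <= detect_prob_within <= 1 and 0 <= detect_prob_cross <= 1):
        raise ValueError("detection probabilities must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins = _protein_ids(n_proteins)
    n_all_pairs = n_proteins * (n_proteins - 1) // 2
    out: list[Interactome] = []
    label_no = {t: 0 for t in counts}
    for tech in ("CF", "AP-MS", "Y2H"):
        for _ in range(counts.get(tech, 0)):
            label_no[tech] += 1
            label = f"{tech.replace('-MS', '')}{label_no[tech]}"
            edges: set[tuple[str, str]] = set()
            for cid in sorted(truth.technique_detectable.get(tech, ())):
                mem = sorted(truth.complex_members[cid])
                for i in range(len(mem)):
                    for j in range(i + 1, len(mem)):
                        if rng.random() < detect_prob_within:
                            edges.add((mem[i], mem[j]))
            n_cross = rng.binomial(n_all_pairs, detect_prob_cross)
            for _ in range(n_cross):
                a, b = rng.choice(n_proteins, size=2, replace=False)
                edges.add(canonical_pair(proteins[a], proteins[b]))
            baits = None
            quantified = None
            if tech == "Y2H":
                bait_set = {
                    mem[int(rng.integers(len(mem)))]
                    for cid in sorted(truth.technique_detectable["Y2H"])
                    for mem in [sorted(truth.complex_members[cid])]
                }
                extra = rng.choice(n_proteins, size=max(1, n_proteins // 10),
                                   replace=False)
                bait_set.update(proteins[i] for i in extra)
                baits = frozenset(bait_set)
            elif tech == "CF":
                quantified = frozenset(proteins)
            out.append(
                Interactome(label=label, technique=tech, edges=frozenset(edges),
                            baits=baits, quantified=quantified)
            )
    return out


def generate_expression(
    truth: GroundTruth,
    n_proteins: int,
    n_tissues: int = 7,
    housekeeping_cv: float = 0.2,
    specific_cv: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Protein × tissue expression with housekeeping vs tissue-specific dispersion.

    Tissue values are lognormal around a per-protein base abundance; the
    across-tissue coefficient of variation is ``housekeeping_cv`` for
    housekeeping proteins (members of co-eluting complexes) and
    ``specific_cv`` for everything else. Requires
    ``housekeeping_cv < specific_cv``.
    """
    if not housekeeping_cv < specific_cv:
        raise ValueError("housekeeping_cv must be below specific_cv")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins = _protein_ids(n_proteins)
    tissues = [f"tissue{i + 1}" for i in range(n_tissues)]
    values = np.empty((n_proteins, n_tissues))
    for i, p in enumerate(proteins):
        cv = housekeeping_cv if p in truth.housekeeping else specific_cv
        sigma = np.sqrt(np.log1p(cv ** 2))
        base = rng.lognormal(np.log(100.0), 0.5)
        values[i] = base * rng.lognormal(0.0, sigma, size=n_tissues)
    return pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                        columns=tissues)
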