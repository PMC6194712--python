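"""End-to-end orchestration of the synthetic benchmarking study.

:func:`run_all` executes simulate → similarity → complex-stats → enrichment
→ subsets → expression/housekeeping → prediction from a single nested config
dict (or YAML file), writing every intermediate table under an output
directory and returning a :class:`RunManifest` with per-stage outputs,
SHA-256 checksums and a summary of the headline quantities. Re-running with
the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import complexes as cstats
from . import enrichment as enr
from . import expression as expr_mod
from . import predictor as pred
from . import similarity as sim
from . import subsets as sub
from .dataio import (
    Dataset,
    complex_to_pairs,
    filter_min_fractions,
    write_chromatograms,
    write_expression,
)
from .simulate import (
    SimulationConfig,
    generate_datasets,
    generate_dataset,
    generate_expression,
    generate_interactomes,
    generate_truth,
    complex_database,
)

logger = logging.getLogger(__name__)

__all__ = ["run_all", "default_config", "load_config", "RunManifest", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; downstream stages were not run."""


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulation": {},  # overrides for SimulationConfig fields
        "similarity": {"r_threshold": 0.0, "min_fractions": 5},
        "complex_stats": {"n_perm": 1000, "alpha": 0.05},
        "enrichment": {"n_boot": 500, "max_other": 1},
        "subsets": {
            "thresholds": list(sub.DEFAULT_THRESHOLDS),
            "holdout_labels": ["CF4", "CF5", "CF6"],
            "subset_threshold": 1e-2,
        },
        "housekeeping": {"n_perm": 250, "alpha": 0.05},
        "expression": {"housekeeping_cv": 0.2, "specific_cv": 1.0},
        "predictor": {"n_folds": 10, "precisions": [0.5, 0.75, 0.9], "n_random": 5},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(seed=user.get("seed", 0))
    for key, val in user.items():
        if isinstance(val, Mapping) and key in cfg:
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


@dataclass
class RunManifest:
    config: dict
    out_dir: Path
    stages: dict[str, dict] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, k: int) -> int:
    # independent, reproducible per-stage seeds below 2**31
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_all(config: dict | str | Path | None = None,
            out_dir: str | Path = "cofracbench_run") -> RunManifest:
    """Run the full synthetic study; see module docstring.

    ``config`` may be a nested dict (missing keys take defaults), a YAML
    path, or None for the default study conditions.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        base = default_config(seed=config.get("seed", 0))
        merged = dict(base)
        for key, val in config.items():
            if isinstance(val, Mapping) and key in base:
                merged[key] = {**base[key], **val}
            else:
                merged[key] = val
        config = merged
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, out_dir=out)
    seed = int(config["seed"])
    state: dict[str, Any] = {}
    stage_fns = [
        ("simulate", _stage_simulate),
        ("similarity", _stage_similarity),
        ("complex_stats", _stage_complex_stats),
        ("enrichment", _stage_enrichment),
        ("subsets", _stage_subsets),
        ("expression", _stage_expression),
        ("predict", _stage_predict),
    ]
    for k, (name, fn) in enumerate(stage_fns):
        logger.info("stage %s starting", name)
        try:
            outputs, summary = fn(config, state, out, _stage_seed(seed, k))
        except Exception as exc:  # halt downstream stages with a clear message
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest.stages[name] = {"outputs": outputs, "summary": summary}
        manifest.summary.update(summary)
        for rel in outputs:
            manifest.checksums[rel] = _sha256(out / rel)
    _write_json(manifest.summary, out / "summary.json")
    _write_json(
        {
            "config": config,
            "stages": manifest.stages,
            "checksums": manifest.checksums,
        },
        out / "manifest.json",
    )
    return manifest


# ---------------------------------------------------------------- stages


def _stage_simulate(config, state, out: Path, seed: int):
    sim_cfg = SimulationConfig(**{**config.get("simulation", {}), "seed": seed})
    rng = np.random.default_rng(seed)
    truth = generate_truth(sim_cfg, rng)
    datasets = generate_datasets(sim_cfg, truth, prefix="dataset", rng=rng)
    db = complex_database(truth)
    interactomes = generate_interactomes(
        truth, sim_cfg.n_proteins,
        seed=np.random.default_rng(_stage_seed(seed, 101)),
    )
    expr_cfg = config.get("expression", {})
    expression = generate_expression(
        truth, sim_cfg.n_proteins, n_tissues=sim_cfg.n_tissues,
        housekeeping_cv=expr_cfg.get("housekeeping_cv", 0.2),
        specific_cv=expr_cfg.get("specific_cv", 1.0),
        seed=np.random.default_rng(_stage_seed(seed, 102)),
    )
    tissue_rng = np.random.default_rng(_stage_seed(seed, 103))
    tissue_datasets = {
        f"tissue{i + 1}": generate_dataset(
            sim_cfg, truth, dataset_id=f"tissue{i + 1}", rng=tissue_rng
        )[0]
        for i in range(sim_cfg.n_tissues)
    }
    state.update(
        sim_cfg=sim_cfg, truth=truth, datasets=datasets, db=db,
        interactomes=interactomes, expression=expression,
        tissue_datasets=tissue_datasets,
    )
    data_dir = out / "data"
    (data_dir / "chromatograms").mkdir(parents=True, exist_ok=True)
    outputs = []
    for ds in datasets:
        rel = f"data/chromatograms/{ds.dataset_id}.csv"
        write_chromatograms(ds, out / rel)
        outputs.append(rel)
    db.to_tsv(data_dir / "complexes.tsv")
    outputs.append("data/complexes.tsv")
    (data_dir / "interactomes").mkdir(exist_ok=True)
    man_rows = []
    for it in interactomes:
        rel = f"data/interactomes/{it.label}_edges.tsv"
        it.to_tsv(out / rel)
        outputs.append(rel)
        man_rows.append({"label": it.label, "technique": it.technique,
                         "edges_path": rel})
    pd.DataFrame(man_rows).to_csv(data_dir / "interactomes" / "manifest.tsv",
                                  sep="\t", index=False)
    outputs.append("data/interactomes/manifest.tsv")
    write_expression(expression, data_dir / "expression.tsv")
    outputs.append("data/expression.tsv")
    truth.to_json(data_dir / "truth.json")
    outputs.append("data/truth.json")
    summary = {
        "n_proteins": sim_cfg.n_proteins,
        "n_datasets": sim_cfg.n_datasets,
        "n_complexes": sim_cfg.n_complexes,
        "n_gold_pairs": len(complex_to_pairs(db)),
    }
    return outputs, summary


def _filtered_datasets(config, state) -> list[Dataset]:
    if "filtered" not in state:
        k = config["similarity"].get("min_fractions", 5)
        state["filtered"] = [filter_min_fractions(d, k) for d in state["datasets"]]
    return state["filtered"]


def _stage_similarity(config, state, out: Path, seed: int):
    datasets = _filtered_datasets(config, state)
    gold = complex_to_pairs(state["db"])
    r_thr = config["similarity"].get("r_threshold", 0.0)
    res_dir = out / "similarity"
    res_dir.mkdir(exist_ok=True)
    outputs = []
    per_dataset = []
    pooled_gold = []
    pooled_non = []
    for ds in datasets:
        prots = sorted(ds.proteins)
        all_pairs = list(itertools.combinations(prots, 2))
        table = sim.pair_similarity_table(ds, all_pairs, gold)
        rel = f"similarity/{ds.dataset_id}.tsv"
        table.to_csv(out / rel, sep="\t", index=False, float_format="%.6g")
        outputs.append(rel)
        g = table[table["label"] == "gold"]
        n = table[table["label"] == "non-gold"]
        pooled_gold.append(g)
        pooled_non.append(n)
        per_dataset.append(
            {
                "dataset_id": ds.dataset_id,
                "n_gold": len(g),
                "n_non_gold": len(n),
                "frac_anticorr_gold": sim.anticorrelated_fraction(g, r_thr).fraction,
                "frac_anticorr_non_gold": sim.anticorrelated_fraction(n, r_thr).fraction,
            }
        )
    per_df = pd.DataFrame(per_dataset)
    per_df.to_csv(res_dir / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    outputs.append("similarity/summary.tsv")
    gold_all = pd.concat(pooled_gold, ignore_index=True)
    non_all = pd.concat(pooled_non, ignore_index=True)
    res_gold = sim.anticorrelated_fraction(gold_all, r_thr)
    res_non = sim.anticorrelated_fraction(non_all, r_thr)
    summary = {
        "anticorrelated_gold_fraction": res_gold.fraction,
        "anticorrelated_gold_counts": [res_gold.n_below, res_gold.n_total],
        "anticorrelated_non_gold_fraction": res_non.fraction,
        "anticorrelated_non_gold_counts": [res_non.n_below, res_non.n_total],
        "anticorrelated_gold_per_dataset_mean": float(
            per_df["frac_anticorr_gold"].mean()
        ),
        "anticorrelated_gold_per_dataset_sd": float(
            per_df["frac_anticorr_gold"].std(ddof=1)
        ),
    }
    return outputs, summary


def _stage_complex_stats(config, state, out: Path, seed: int):
    datasets = _filtered_datasets(config, state)
    opts = config["complex_stats"]
    stats = cstats.complex_significance(
        state["db"], datasets, n_perm=opts.get("n_perm", 1000),
        alpha=opts.get("alpha", 0.05), seed=seed,
    )
    state["complex_stats"] = stats
    rel = "complex_stats.tsv"
    stats.to_csv(out / rel, sep="\t", index=False, float_format="%.6g")
    n_obs = len(stats)
    summary = {
        "n_complexes_observed": n_obs,
        "n_complexes_enriched": int((stats["class"] == "enriched").sum()),
        "n_complexes_depleted": int((stats["class"] == "depleted").sum()),
    }
    return [rel], summary


def _stage_enrichment(config, state, out: Path, seed: int):
    opts = config["enrichment"]
    db = state["db"]
    records: dict[str, pd.DataFrame] = {}
    enr_dir = out / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    outputs = []
    for it in state["interactomes"]:
        rec = enr.enrich_complexes(it, db)
        records[it.label] = rec
        rel = f"enrichment/{it.label}.tsv"
        rec.to_csv(out / rel, sep="\t", index=False, float_format="%.6g")
        outputs.append(rel)
    state["enrichment_records"] = records
    flags = enr.predicted_flag_matrix(records)
    techniques = {it.label: it.technique for it in state["interactomes"]}
    state["flags"] = flags
    state["techniques"] = techniques
    tech_summary = {}
    for k, tech in enumerate(sorted(set(techniques.values()))):
        chance = enr.technique_specific_chance(
            flags, techniques, tech, n_boot=opts.get("n_boot", 500),
            seed=_stage_seed(seed, k), max_other=opts.get("max_other", 1),
        )
        tech_summary[tech] = {
            "observed": chance.observed,
            "expected_by_chance": chance.expected,
            "p_value": chance.p_value,
        }
    _write_json(tech_summary, out / "technique_specific.json")
    outputs.append("technique_specific.json")
    summary = {"technique_specific": tech_summary}
    return outputs, summary


def _stage_subsets(config, state, out: Path, seed: int):
    opts = config["subsets"]
    db = state["db"]
    holdout = opts["holdout_labels"]
    missing = [lab for lab in holdout if lab not in state["enrichment_records"]]
    if missing:
        raise ValueError(f"hold-out interactomes not found: {missing}")
    records = {lab: state["enrichment_records"][lab] for lab in holdout}
    thresholds = opts["thresholds"]
    table = sub.subset_table(db, records, thresholds)
    rel = "subsets.tsv"
    sub.export_subset(table, out / rel)
    gsubsets = {t: sub.cf_specific_subset(db, records, t) for t in thresholds}
    state["gold_subsets"] = gsubsets
    state["clean_subset"] = gsubsets[opts["subset_threshold"]]
    summary = {
        "subset_n_complexes": {f"{t:g}": len(s.complex_ids) for t, s in gsubsets.items()},
        "subset_n_pairs": {f"{t:g}": len(s.pairs) for t, s in gsubsets.items()},
    }
    return [rel], summary


def _stage_expression(config, state, out: Path, seed: int):
    db = state["db"]
    clean = state["clean_subset"]
    cf_proteins = {p for cid in clean.complex_ids for p in db.members(cid)}
    other_proteins = db.protein_universe - cf_proteins
    comp = expr_mod.group_gini_comparison(
        state["expression"], cf_proteins, other_proteins
    )
    hk_opts = config["housekeeping"]
    hk = cstats.housekeeping_complexes(
        {t: filter_min_fractions(d, config["similarity"].get("min_fractions", 5))
         for t, d in state["tissue_datasets"].items()},
        db, alpha=hk_opts.get("alpha", 0.05),
        n_perm=hk_opts.get("n_perm", 250), seed=seed,
    )
    universe = len(state["complex_stats"])
    overlap_p = expr_mod.overlap_test(
        hk, clean.complex_ids & frozenset(state["complex_stats"]["complex_id"]),
        universe,
    )
    payload = {
        "gini_mean_cf_specific": comp.mean_cf_specific,
        "gini_mean_other": comp.mean_other,
        "welch_t": comp.t_stat,
        "welch_p": comp.p_value,
        "n_cf_specific": comp.n_cf_specific,
        "n_other": comp.n_other,
        "n_housekeeping_complexes": len(hk),
        "housekeeping_overlap_p": overlap_p,
    }
    _write_json(payload, out / "gini.json")
    return ["gini.json"], payload


def _stage_predict(config, state, out: Path, seed: int):
    opts = config["predictor"]
    datasets = _filtered_datasets(config, state)
    db = state["db"]
    proteins = sorted(set().union(*[set(d.proteins) for d in datasets]))
    candidate = list(itertools.combinations(proteins, 2))
    features = pred.build_features(datasets, candidate)
    pairs_idx = list(features.index)
    all_gold = complex_to_pairs(db)
    clean = state["clean_subset"]
    precisions = opts["precisions"]
    rng = np.random.default_rng(seed)

    def evaluate(gold_pairs, gold_proteins, cv_seed):
        labels = pred.label_pairs(pairs_idx, gold_pairs, gold_proteins)
        scores = pred.train_score_cv(features, labels, n_folds=opts["n_folds"],
                                     seed=cv_seed)
        ranked = pred.precision_recall(scores, labels)
        sizes = {
            f"{p:g}": pred.interactome_at_precision(ranked, p)[1] for p in precisions
        }
        return ranked, sizes

    clean_proteins = {p for cid in clean.complex_ids for p in db.members(cid)}
    ranked_full, sizes_full = evaluate(all_gold, db.protein_universe,
                                       _stage_seed(seed, 1))
    ranked_clean, sizes_clean = evaluate(clean.pairs, clean_proteins,
                                         _stage_seed(seed, 2))
    random_sizes: list[dict] = []
    for rep in range(opts.get("n_random", 5)):
        rnd = sub.random_subset(all_gold, len(clean.pairs), rng)
        _, sizes_r = evaluate(rnd, None, _stage_seed(seed, 10 + rep))
        random_sizes.append(sizes_r)
    rel = "predictions_clean.tsv"
    ranked_clean.to_csv(out / rel, sep="\t", index=False, float_format="%.6g")
    summary = {
        "interactome_size_full_gold": sizes_full,
        "interactome_size_clean_subset": sizes_clean,
        "interactome_size_random_mean": {
            f"{p:g}": float(np.mean([s[f"{p:g}"] for s in random_sizes]))
            for p in precisions
        },
        "n_candidate_pairs": len(pairs_idx),
    }
    _write_json(summary, out / "predict_summary.json")
    return [rel, "predict_summary.json"], summary
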