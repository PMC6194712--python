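"""Interactome prediction from co-elution features (PrInCE-style core).

Candidate protein pairs get similarity features (zero-fill Pearson R,
min-max Euclidean distance, and co-apex distance — the absolute difference
of peak fractions), averaged across datasets. Pairs are labeled against a
gold standard: TP = co-members of a gold complex, FP = both proteins occur
in the gold database but never in the same complex, otherwise unlabeled. A
Gaussian Naive Bayes classifier scores every pair (labeled pairs
out-of-fold via stratified k-fold CV; unlabeled pairs by the model fit on
all labeled pairs), and the evaluation reports cumulative precision /
recall down the ranked list and the interactome size at fixed precision.

Precision is computed over labeled pairs only; unlabeled pairs count toward
interactome size but carry no precision information.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB

from .dataio import Dataset
from .similarity import _minmax_matrix, unit_row_matrix

__all__ = [
    "label_pairs",
    "build_features",
    "train_score_cv",
    "precision_recall",
    "interactome_at_precision",
]

FEATURES = ("pearson_r", "euclidean_d", "coapex_d")


def label_pairs(
    pairs: Sequence[tuple[str, str]],
    gold_pairs: Iterable[tuple[str, str]],
    gold_proteins: Iterable[str] | None = None,
) -> pd.Series:
    """Label candidate pairs TP / FP / unlabeled against a gold standard.

    TP: pair is a gold pair (within-complex). FP: both proteins occur in the
    gold standard (``gold_proteins``, defaulting to the proteins of
    ``gold_pairs``) but the pair is not gold. Anything else is unlabeled.
    """
    gold_pairs = set(gold_pairs)
    if gold_proteins is None:
        gold_proteins = {p for e in gold_pairs for p in e}
    else:
        gold_proteins = set(gold_proteins)
    labels = []
    for p in pairs:
        if p in gold_pairs:
            labels.append("TP")
        elif p[0] in gold_proteins and p[1] in gold_proteins:
            labels.append("FP")
        else:
            labels.append("unlabeled")
    return pd.Series(labels, index=pd.MultiIndex.from_tuples(pairs), name="label")


def build_features(
    datasets: Sequence[Dataset] | Dataset,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair feature vectors (pearson_r, euclidean_d, coapex_d) averaged
    across the datasets in which the pair is computable.

    Pairs with no computable dataset (absent proteins or degenerate
    profiles) are dropped.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    pairs = list(pairs)
    sums = np.zeros((len(pairs), len(FEATURES)))
    counts = np.zeros(len(pairs))
    for ds in datasets:
        Z, idx = unit_row_matrix(ds)
        M, _ = _minmax_matrix(ds)
        apex = np.argmax(M, axis=1)
        pos = {p: i for i, p in enumerate(idx)}
        sel, ia, ib = [], [], []
        for i, (a, b) in enumerate(pairs):
            if a in pos and b in pos:
                sel.append(i)
                ia.append(pos[a])
                ib.append(pos[b])
        if not sel:
            continue
        sel = np.asarray(sel)
        ia = np.asarray(ia)
        ib = np.asarray(ib)
        r = np.clip(np.einsum("ij,ij->i", Z[ia], Z[ib]), -1.0, 1.0)
        diff = M[ia] - M[ib]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        co = np.abs(apex[ia] - apex[ib]).astype(float)
        sums[sel, 0] += r
        sums[sel, 1] += d
        sums[sel, 2] += co
        counts[sel] += 1
    keep = counts > 0
    feats = sums[keep] / counts[keep, None]
    kept_pairs = [p for p, k in zip(pairs, keep) if k]
    return pd.DataFrame(
        feats, index=pd.MultiIndex.from_tuples(kept_pairs), columns=list(FEATURES)
    )


def train_score_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Gaussian Naive Bayes posterior P(TP) for every candidate pair.

    Labeled pairs are scored out-of-fold (stratified k-fold, shuffled under
    ``seed``; the fold count shrinks automatically if a class has fewer
    members than folds). Unlabeled pairs are scored by the model trained on
    all labeled pairs. Requires >= 10 TP and >= 10 FP labels.
    """
    labels = labels.reindex(features.index)
    X = features.to_numpy()
    labeled = labels.isin(["TP", "FP"]).to_numpy()
    y = (labels == "TP").to_numpy()
    n_tp = int(y[labeled].sum())
    n_fp = int(labeled.sum()) - n_tp
    if n_tp < 10 or n_fp < 10:
        raise ValueError(f"need >= 10 TP and FP labels, got TP={n_tp}, FP={n_fp}")
    n_folds = min(n_folds, n_tp, n_fp)
    model = GaussianNB(var_smoothing=1e-9)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(features))
    proba = cross_val_predict(
        model, X[labeled], y[labeled], cv=cv, method="predict_proba"
    )
    scores[labeled] = proba[:, 1]
    if (~labeled).any():
        full = GaussianNB(var_smoothing=1e-9).fit(X[labeled], y[labeled])
        scores[~labeled] = full.predict_proba(X[~labeled])[:, 1]
    return pd.Series(scores, index=features.index, name="score")


def precision_recall(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Rank pairs by descending score and tabulate cumulative precision/recall.

    Ties are broken deterministically by canonical pair order. Precision at
    rank k is TP_k / (TP_k + FP_k) over labeled pairs among the top k (NaN
    until the first labeled pair); recall is TP_k over all TP labels.
    """
    labels = labels.reindex(scores.index)
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores.iloc[i], scores.index[i]),
    )
    ranked = pd.DataFrame(
        {
            "protein_a": [scores.index[i][0] for i in order],
            "protein_b": [scores.index[i][1] for i in order],
            "score": scores.to_numpy()[order],
            "label": labels.to_numpy()[order],
        }
    )
    is_tp = (ranked["label"] == "TP").to_numpy()
    is_fp = (ranked["label"] == "FP").to_numpy()
    ranked["cum_tp"] = np.cumsum(is_tp)
    ranked["cum_fp"] = np.cumsum(is_fp)
    total_tp = int(is_tp.sum())
    if total_tp == 0:
        raise ValueError("precision-recall requires at least one TP label")
    denom = (ranked["cum_tp"] + ranked["cum_fp"]).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ranked["precision"] = np.where(
            denom > 0, ranked["cum_tp"] / np.maximum(denom, 1), np.nan
        )
    ranked["recall"] = ranked["cum_tp"] / total_tp
    return ranked


def interactome_at_precision(
    ranked: pd.DataFrame, target_precision: float
) -> tuple[list[tuple[str, str]], int]:
    """All pairs in the deepest ranked prefix whose precision meets the target.

    Returns the pair list (labeled *and* unlabeled) of the largest rank k
    with cumulative precision >= ``target_precision``, and its size; an
    unreachable target yields an empty set.
    """
    if not (0 < target_precision <= 1):
        raise ValueError("target precision must be in (0, 1]")
    prec = ranked["precision"].to_numpy()
    ok = np.where(prec >= target_precision)[0]
    if len(ok) == 0:
        return [], 0
    k = int(ok[-1]) + 1
    pairs = list(zip(ranked["protein_a"].iloc[:k], ranked["protein_b"].iloc[:k]))
    return pairs, k
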