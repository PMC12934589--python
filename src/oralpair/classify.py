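"""Cross-validated specimen-type classification and pathway over-representation.

Classification trains an ensemble of randomised decision trees on TSS values
with patient-level folds: both members of a pair always land in the same
fold, so a held-out sample never shares a patient with the training set.
Accuracy is summarised per fold by the rank-based AUC, and feature importance
by mean-impurity-decrease ranks (1 = most important, ties broken by name).

Over-representation of pathways among significant items uses the one-sided
hypergeometric upper tail P(X >= k | N, K, n) with BH correction across
pathways and fold enrichment (k/n)/(K/N).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .da import PairedCohort
from .transforms import bh_fdr, tss


@dataclasses.dataclass
class CvResult:
    n_folds: int
    fold_auc: list[float]
    held_out: list[list[str]]  # sample ids per fold
    importance_ranks: pd.DataFrame  # taxa x folds, integer ranks (1 = top)
    seed: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _patient_folds(patients: list[str], n_folds: int, rng: np.random.Generator) -> list[list[str]]:
    order = list(patients)
    rng.shuffle(order)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, pid in enumerate(order):
        folds[i % n_folds].append(pid)
    return folds


def kfold_classify(
    cohort: PairedCohort,
    n_folds: int = 4,
    seed: int = 0,
    n_estimators: int = 500,
) -> CvResult:
    """Patient-stratified k-fold random-forest classification on TSS values."""
    pairs = cohort.md.pairs()
    patients = list(pairs.index)
    if len(patients) < n_folds:
        raise ValueError(f"need at least {n_folds} patients for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    folds = _patient_folds(patients, n_folds, rng)

    vals = tss(cohort.ct).values.T  # samples x taxa
    sample_index = {s: i for i, s in enumerate(cohort.ct.samples)}
    labels = cohort.md.frame["specimen_type"]
    taxa = np.array(cohort.ct.taxa)

    fold_auc: list[float] = []
    held_out: list[list[str]] = []
    rank_cols = {}
    for f, fold_patients in enumerate(folds):
        test_samples = [
            pairs.loc[pid, t] for pid in fold_patients for t in ("plaque", "abscess")
        ]
        train_samples = [
            pairs.loc[pid, t]
            for pid in patients
            if pid not in fold_patients
            for t in ("plaque", "abscess")
        ]
        y_train = (labels.loc[train_samples] == "abscess").to_numpy()
        y_test = (labels.loc[test_samples] == "abscess").to_numpy()
        if y_test.all() or not y_test.any() or y_train.all() or not y_train.any():
            raise ValueError(f"fold {f} has a single class")
        X_train = vals[[sample_index[s] for s in train_samples]]
        X_test = vals[[sample_index[s] for s in test_samples]]
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(X_train, y_train)
        prob = clf.predict_proba(X_test)[:, list(clf.classes_).index(True)]
        fold_auc.append(roc_auc(prob, y_test))
        held_out.append(list(test_samples))
        imp = clf.feature_importances_
        order = np.lexsort((taxa, -imp))
        ranks = np.empty(len(taxa), dtype=int)
        ranks[order] = np.arange(1, len(taxa) + 1)
        rank_cols[f"fold_{f+1}"] = ranks
    importance = pd.DataFrame(rank_cols, index=list(taxa))
    return CvResult(n_folds, fold_auc, held_out, importance, seed)


@dataclasses.dataclass
class OraRow:
    pathway: str
    k: int
    n: int
    K: int
    N: int
    p: float
    fold_enrichment: float


def over_representation(
    sig_items: Iterable[str],
    background: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway among sig_items."""
    background = set(background)
    if not background:
        raise ValueError("background set is empty")
    sig = set(sig_items)
    if not sig <= background:
        extra = sorted(sig - background)[:3]
        raise ValueError(f"significant items not in background: {extra}")
    N, n = len(background), len(sig)
    rows = []
    for name in sorted(pathways):
        members = set(pathways[name]) & background
        K = len(members)
        k = len(members & sig)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if (K > 0 and n > 0) else float("nan")
        rows.append({"pathway": name, "k": k, "n": n, "K": K, "N": N, "p": p, "fold_enrichment": fold})
    df = pd.DataFrame(rows).set_index("pathway")
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def read_pathway_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """TSV of (item_id, pathway_id, pathway_name) -> (pathway sets, names)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("item_id", "pathway_id"):
        if col not in df.columns:
            raise ValueError(f"pathway map missing column {col!r}")
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, r in df.iterrows():
        sets.setdefault(r["pathway_id"], set()).add(r["item_id"])
        if "pathway_name" in df.columns:
            names[r["pathway_id"]] = r["pathway_name"]
    return sets, names
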