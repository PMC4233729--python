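"""Random-Forest classification of phase modules from promoter elements.

A forest of 2000 trees is grown per phase class (one-vs-rest) on binary
motif-presence features, with mtry = floor(sqrt(#features)) candidate
features per split.  Training uses a stratified random two-thirds of the
genes with an equal number from each phase class (downsampled to the
smallest class); the held-out third provides vote-fraction scores for ROC
curves, AUC, the confusion table and permutation variable importance
(VIMP: mean decrease in held-out classification accuracy when a feature
column is shuffled).  VIMP rankings per class feed a progressive
presence/absence table of elements across the circadian day, and gene groups
carrying each class's element combination are summarized by their mean
projection (mean-phase vector) on the circadian plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .projection import ProjectionResult, MODULE_NAMES
from .promoter_motifs import MotifFeatureMatrix

__all__ = ["ForestConfig", "PhaseForestModel", "ClassifierReport",
           "train_phase_forests", "variable_importance", "roc_and_auc",
           "progressive_table", "mean_phase_of_combination", "DAY_ORDER"]

#: phase classes in circadian day order (dawn, noon, dusk, midnight)
DAY_ORDER = (1, 3, 2, 4)


@dataclass
class ForestConfig:
    """Forest and split settings; defaults follow the pipeline's fixed
    constants (2000 trees, mtry = floor(sqrt(p)), balanced 2/3 training)."""

    n_trees: int = 2000
    mtry: int | None = None  # None -> floor(sqrt(n_features))
    train_fraction: float = 2 / 3
    balanced_training: bool = True
    seed: int = 0
    vimp_repeats: int = 10
    n_splits: int = 1  # >1: repeated splits, AUC reported as mean +/- sd

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return self.mtry
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class PhaseForestModel:
    """Trained one-vs-rest forests plus the split they were trained on."""

    forests: dict[int, RandomForestClassifier]
    motifs: list[str]
    classes: list[int]
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    X: np.ndarray
    y: np.ndarray
    gene_ids: list[str]
    cfg: ForestConfig

    def vote_fractions(self, cls: int, idx: np.ndarray | None = None) -> np.ndarray:
        """Fraction of trees voting for membership of ``cls``."""
        idx = self.holdout_idx if idx is None else idx
        return self.forests[cls].predict_proba(self.X[idx])[:, 1]


@dataclass
class ClassifierReport:
    """Held-out evaluation of the phase forests."""

    vimp: dict[int, pd.DataFrame]            # class -> (motif, vimp) desc
    roc: dict[int, pd.DataFrame]             # class -> (fpr, tpr, threshold)
    auc: dict[int, float]
    auc_sd: dict[int, float] = field(default_factory=dict)  # repeated splits only
    confusion: pd.DataFrame | None = None
    progressive: pd.DataFrame | None = None
    mean_phase: dict[int, tuple[float, float]] = field(default_factory=dict)


def _balanced_split(y: np.ndarray, classes, train_fraction: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/holdout indices; train downsampled to equal class
    counts (the smallest class's two-thirds)."""
    per_class_train = {}
    holdout = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        per_class_train[c] = idx[:n_train]
        holdout.append(idx[n_train:])
    n_min = min(v.size for v in per_class_train.values())
    train = np.concatenate([v[:n_min] for v in per_class_train.values()])
    return np.sort(train), np.sort(np.concatenate(holdout))


def train_phase_forests(features: MotifFeatureMatrix, labels: dict[str, int],
                        cfg: ForestConfig | None = None,
                        ) -> tuple[PhaseForestModel, ClassifierReport]:
    """Train one one-vs-rest forest per phase class and evaluate it held out.

    ``labels`` maps gene id -> phase class (1..4); every labelled gene must
    have a feature row.  With ``cfg.n_splits > 1`` the split/train/evaluate
    cycle is repeated and AUCs are reported as mean with sd; the returned
    model and VIMP come from the first split.
    """
    cfg = cfg or ForestConfig()
    missing = [g for g in labels if g not in set(features.gene_ids)]
    if missing:
        raise ValueError(f"labelled genes without feature rows: {missing[:10]}")
    gene_ids = [g for g in features.gene_ids if g in labels]
    row_of = {g: i for i, g in enumerate(features.gene_ids)}
    X = features.values[[row_of[g] for g in gene_ids]].astype(float)
    y = np.array([labels[g] for g in gene_ids])
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 phase classes")
    for c in classes:
        if (y == c).sum() < 6:
            raise ValueError(f"class {c} has fewer than 6 genes; cannot form "
                             "a 2/3 train / 1/3 holdout split")

    rng = np.random.default_rng(cfg.seed)
    mtry = cfg.resolve_mtry(len(features.motifs))

    def one_split(split_rng):
        train, hold = _balanced_split(y, classes, cfg.train_fraction, split_rng)
        forests = {}
        for c in classes:
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees, max_features=mtry,
                random_state=int(split_rng.integers(2**31 - 1)), n_jobs=1)
            rf.fit(X[train], (y[train] == c).astype(int))
            forests[c] = rf
        return train, hold, forests

    train, hold, forests = one_split(rng)
    model = PhaseForestModel(forests, list(features.motifs), classes, train,
                             hold, X, y, gene_ids, cfg)

    report = ClassifierReport(vimp={}, roc={}, auc={})
    roc_auc = roc_and_auc(model)
    report.roc = {c: r for c, (r, _) in roc_auc.items()}
    report.auc = {c: a for c, (_, a) in roc_auc.items()}
    for c in classes:
        report.vimp[c] = variable_importance(model, c, n_repeats=cfg.vimp_repeats)
    report.confusion = _confusion(model)

    if cfg.n_splits > 1:
        aucs = {c: [report.auc[c]] for c in classes}
        for _ in range(cfg.n_splits - 1):
            tr, ho, fo = one_split(rng)
            m2 = PhaseForestModel(fo, list(features.motifs), classes, tr, ho,
                                  X, y, gene_ids, cfg)
            for c, (_, a) in roc_and_auc(m2).items():
                aucs[c].append(a)
        report.auc = {c: float(np.mean(v)) for c, v in aucs.items()}
        report.auc_sd = {c: float(np.std(v)) for c, v in aucs.items()}
    return model, report


def _confusion(model: PhaseForestModel) -> pd.DataFrame:
    """Held-out confusion table; predicted class = highest vote fraction."""
    votes = np.column_stack([model.vote_fractions(c) for c in model.classes])
    pred = np.array(model.classes)[np.argmax(votes, axis=1)]
    true = model.y[model.holdout_idx]
    table = pd.crosstab(pd.Series(true, name="true"),
                        pd.Series(pred, name="predicted"))
    return table.reindex(index=model.classes, columns=model.classes, fill_value=0)


def variable_importance(model: PhaseForestModel, cls: int,
                        n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Held-out permutation VIMP for one class, ranked descending.

    VIMP of a motif = mean decrease in held-out one-vs-rest vote accuracy
    over ``n_repeats`` shuffles of that feature column; ties break
    lexicographically by motif.
    """
    if cls not in model.forests:
        raise KeyError(f"unknown class {cls}")
    rng = np.random.default_rng(seed + cls)
    rf = model.forests[cls]
    Xh = model.X[model.holdout_idx]
    yh = (model.y[model.holdout_idx] == cls).astype(int)
    base = float((rf.predict(Xh) == yh).mean())
    drops = np.zeros(len(model.motifs))
    for j in range(len(model.motifs)):
        accs = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = Xh.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            accs[r] = (rf.predict(Xp) == yh).mean()
        drops[j] = base - accs.mean()
    df = pd.DataFrame({"motif": model.motifs, "vimp": drops})
    return (df.sort_values(["vimp", "motif"], ascending=[False, True], kind="stable")
              .reset_index(drop=True))


def roc_and_auc(model: PhaseForestModel,
                ) -> dict[int, tuple[pd.DataFrame, float]]:
    """Per-class ROC (threshold sweep over vote fractions) and trapezoid AUC."""
    if model.holdout_idx.size == 0:
        raise ValueError("empty holdout set")
    out = {}
    yh = model.y[model.holdout_idx]
    for c in model.classes:
        pos = (yh == c)
        if pos.all() or not pos.any():
            raise ValueError(f"holdout lacks positive or negative examples "
                             f"for class {c}")
        scores = model.vote_fractions(c)
        fpr, tpr, thr = roc_curve(pos.astype(int), scores)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        out[c] = (roc, float(_trapezoid_auc(fpr, tpr)))
    return out


def progressive_table(report: ClassifierReport, top_k: int = 10,
                      extra_motifs=(), noise_floor: float = 0.0,
                      model: PhaseForestModel | None = None) -> pd.DataFrame:
    """Class x motif presence table across the circadian day, double plotted.

    A motif is marked present for a class when it sits in that class's
    ``top_k`` by VIMP, or is an ``extra_motifs`` entry whose VIMP exceeds the
    noise floor.  Because permutation importance is sign-blind — the
    *absence* of a neighbouring phase's element is just as discriminative as
    the presence of the class's own — a ``model`` should be supplied so that
    only motifs positively associated with the class (higher mean presence
    in-class than out-of-class) are marked; this makes the table a genuine
    presence table.  Rows run dawn, noon, dusk, midnight and repeat once to
    make the cyclic progression visible; motifs absent from every class are
    dropped.
    """
    if not report.vimp:
        raise ValueError("VIMP not computed")

    def positively_associated(c: int, motif: str) -> bool:
        if model is None:
            return True
        j = model.motifs.index(motif)
        in_cls = model.X[model.y == c, j].mean()
        out_cls = model.X[model.y != c, j].mean()
        return bool(in_cls > out_cls)

    presence: dict[int, set[str]] = {}
    for c, table in report.vimp.items():
        k = min(top_k, len(table))
        top = set(table.head(k)["motif"])
        for m in extra_motifs:
            row = table[table["motif"] == m]
            if not row.empty and float(row["vimp"].iloc[0]) > noise_floor:
                top.add(m)
        presence[c] = {m for m in top if positively_associated(c, m)}
    motifs = sorted(set().union(*presence.values()))
    order = [c for c in DAY_ORDER if c in presence]
    rows = []
    for c in order * 2:
        rows.append({"class": c, "phase": MODULE_NAMES[c],
                     **{m: m in presence[c] for m in motifs}})
    return pd.DataFrame(rows)


def mean_phase_of_combination(proj: ProjectionResult,
                              features: MotifFeatureMatrix,
                              combination, exclude=()) -> tuple[float, float]:
    """Mean (q1, q2) over circadian genes carrying every motif in
    ``combination`` (binary presence).

    ``exclude`` lists motifs that must be *absent*, which sharpens the group
    to genes with the distinct combination of one phase class: progressive
    overlap means a neighbouring class's genes carry most of a combination
    already, and without the exclusion they drag the mean vector toward
    their own axis.
    """
    combination = list(combination)
    exclude = list(exclude)
    if not combination:
        raise ValueError("combination must be nonempty")
    if proj.is_circadian is None:
        raise ValueError("circadian calls not yet made")
    col = {m: j for j, m in enumerate(features.motifs)}
    missing = [m for m in combination + exclude if m not in col]
    if missing:
        raise KeyError(f"motifs not in feature matrix: {missing}")
    row = {g: i for i, g in enumerate(features.gene_ids)}
    q1s, q2s = [], []
    for i, g in enumerate(proj.gene_ids):
        if not proj.is_circadian[i] or g not in row:
            continue
        feat = features.values[row[g]]
        if (all(feat[col[m]] >= 1 for m in combination)
                and all(feat[col[m]] == 0 for m in exclude)):
            q1s.append(proj.q1[i])
            q2s.append(proj.q2[i])
    if not q1s:
        raise ValueError("no circadian gene carries the full combination")
    return float(np.mean(q1s)), float(np.mean(q2s))
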