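"""Supervised evaluation of a longitudinal gene signature.

The longitudinal profiles are first collapsed to *pseudo-genes* — one
covariate per gene, the subject's average expression over the early lesional
time points.  Predictive value is then measured by leave-one-out (LOO)
support-vector-machine accuracy.  Two protocols are provided:

* ``loo_svm_accuracy`` — a fixed gene list, LOO over subjects;
* ``nested_loo_ensemble`` — the honest protocol: inside every fold the whole
  random-subspace ensemble is retrained on the remaining subjects and its
  top-k genes are selected before the SVM sees the held-out subject.

``random_gene_baseline`` estimates the accuracy a random k-gene list would
achieve, the reference point a useful signature must beat.  Trajectory
summaries (group means per time point against the non-lesional reference)
quantify the recovery pattern that makes the signature interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .ensemble import _as_binary, run_ensemble, select_top_k
from .io import (
    NONRESPONDER,
    RESPONDER,
    LongitudinalExpressionSet,
    build_views,
)

DEFAULT_PSEUDO_TIMEPOINTS = ("LS0", "W1", "W2", "W4")


@dataclass
class EvaluationResult:
    """Per-fold LOO predictions, the 2x2 confusion table and the accuracy."""

    subject_ids: list
    fold_predictions: np.ndarray
    true_labels: np.ndarray
    confusion: np.ndarray            # rows true (N, R), cols predicted (N, R)
    accuracy: float
    svm_params: dict
    seed: int
    per_fold_selected: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "subject_ids": list(self.subject_ids),
            "fold_predictions": [str(v) for v in self.fold_predictions],
            "true_labels": [str(v) for v in self.true_labels],
            "confusion": np.asarray(self.confusion).tolist(),
            "accuracy": float(self.accuracy),
            "svm_params": dict(self.svm_params),
            "seed": self.seed,
        }
        if self.per_fold_selected:
            d["per_fold_selected"] = [list(g) for g in self.per_fold_selected]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationResult":
        return cls(
            subject_ids=list(d["subject_ids"]),
            fold_predictions=np.array(d["fold_predictions"]),
            true_labels=np.array(d["true_labels"]),
            confusion=np.array(d["confusion"]),
            accuracy=d["accuracy"],
            svm_params=d["svm_params"],
            seed=d["seed"],
            per_fold_selected=[list(g) for g in d.get("per_fold_selected", [])],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject_ids,
            "true": self.true_labels,
            "predicted": self.fold_predictions,
            "correct": self.fold_predictions == self.true_labels,
        })


def make_pseudo_genes(
    data: LongitudinalExpressionSet,
    use_timepoints=DEFAULT_PSEUDO_TIMEPOINTS,
) -> pd.DataFrame:
    """Average each gene over the requested time points per subject.

    Cells missing at some requested time points are averaged over the
    available ones; subjects missing *all* requested values for any gene are
    dropped with a warning.  Returns a genes x subjects DataFrame.
    """
    use_timepoints = list(use_timepoints)
    if not use_timepoints:
        raise ValueError("use_timepoints must be non-empty")
    t_idx = [data.timepoint_index(t) for t in use_timepoints]
    vals = np.where(data.missing_mask, np.nan, data.values)[:, :, t_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        pseudo = np.nanmean(vals, axis=2)
    all_missing = np.isnan(pseudo).any(axis=0)
    keep = [s for s, m in zip(data.subject_ids, all_missing) if not m]
    if len(keep) < len(data.subject_ids):
        dropped = sorted(set(data.subject_ids) - set(keep))
        warnings.warn(f"dropping subjects with no observed value at the "
                      f"requested timepoints: {dropped}")
    cols = [data.subject_ids.index(s) for s in keep]
    return pd.DataFrame(pseudo[:, cols], index=data.gene_ids, columns=keep)


def _default_svm_params() -> dict:
    # RBF kernel, cost 1, width 1/(n_features * var): the common library default
    return {"kernel": "rbf", "C": 1.0, "gamma": "scale"}


def _fold_standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loo_svm_accuracy(
    features: pd.DataFrame,
    labels,
    svm_params: dict | None = None,
    gene_subset=None,
    standardize: bool = True,
    seed: int = 0,
) -> EvaluationResult:
    """Leave-one-out SVM accuracy for a fixed gene list.

    ``features`` is genes x subjects (e.g. pseudo-genes).  Features are
    standardized with the training fold's mean and sd only; the held-out
    subject is transformed with those same parameters, so no information
    leaks across the fold boundary.
    """
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        if not gene_subset:
            raise ValueError("gene_subset must be non-empty")
        features = features.loc[gene_subset]
    subjects = list(features.columns)
    X = features.to_numpy().T                        # subjects x genes
    y = _as_binary(labels)
    if y.size != len(subjects):
        raise ValueError("label length does not match subject count")
    if min(np.count_nonzero(y == 1), np.count_nonzero(y == 0)) < 2:
        raise ValueError("need at least 2 subjects per class for LOO")

    params = _default_svm_params()
    params.update(svm_params or {})
    n = len(subjects)
    pred = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.arange(n) != i
        y_tr = y[tr]
        if np.unique(y_tr).size < 2:
            raise ValueError(
                "a LOO training fold contains a single class; more subjects "
                "per class are required")
        X_tr, X_te = X[tr], X[i:i + 1]
        if standardize:
            X_tr, X_te = _fold_standardize(X_tr, X_te)
        clf = SVC(random_state=seed, **params)
        clf.fit(X_tr, y_tr)
        pred[i] = int(clf.predict(X_te)[0])

    return _assemble_result(subjects, pred, y, params, seed)


def _assemble_result(subjects, pred, y, params, seed, per_fold_selected=()):
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    names = np.array([NONRESPONDER, RESPONDER])
    return EvaluationResult(
        subject_ids=list(subjects),
        fold_predictions=names[pred],
        true_labels=names[y],
        confusion=confusion,
        accuracy=float(np.mean(pred == y)),
        svm_params=dict(params),
        seed=seed,
        per_fold_selected=list(per_fold_selected),
    )


def nested_loo_ensemble(
    data: LongitudinalExpressionSet,
    labels=None,
    ensemble_config: dict | None = None,
    k: int = 20,
    svm_params: dict | None = None,
    seed: int = 0,
    use_timepoints=DEFAULT_PSEUDO_TIMEPOINTS,
    n_replicates: int = 2000,
) -> EvaluationResult:
    """Honest LOO: retrain the whole ensemble inside every fold.

    Per fold the views are rebuilt (and re-standardized) on the n-1 training
    subjects, the ensemble is rerun with a fold-specific seeded substream,
    the top-k genes are selected, and an SVM on the training subjects'
    pseudo-genes predicts the held-out subject.  The default 2,000 replicates
    per fold keeps a full run fast; 10,000 matches a production-scale run.
    """
    use_timepoints = list(use_timepoints)
    views_all = build_views(data, use_timepoints, standardize=True)
    subjects = views_all.subject_ids
    y = _as_binary(data.response_labels(subjects) if labels is None else labels)
    params = _default_svm_params()
    params.update(svm_params or {})
    cfg = {"subset_size": 20, "accuracy_cutoff": 0.75}
    cfg.update(ensemble_config or {})
    cfg.setdefault("n_replicates", n_replicates)

    pseudo = make_pseudo_genes(data, use_timepoints)[subjects]
    n = len(subjects)
    pred = np.empty(n, dtype=int)
    per_fold_selected = []
    label_by_subject = dict(zip(subjects, y))
    for i, held_out in enumerate(subjects):
        train_subjects = [s for s in subjects if s != held_out]
        y_tr = np.array([label_by_subject[s] for s in train_subjects])
        if np.unique(y_tr).size < 2:
            raise ValueError(
                f"fold {i} ({held_out}): training fold contains a single class")
        train_data = data.subset_subjects(train_subjects)
        train_views = build_views(train_data, use_timepoints, standardize=True)
        try:
            ens = run_ensemble(
                train_views, y_tr,
                seed=int(np.random.SeedSequence(seed, spawn_key=(i,))
                         .generate_state(1)[0] % (2**31)),
                **cfg)
        except Exception as exc:
            raise RuntimeError(
                f"ensemble failed in fold {i} (held out {held_out})") from exc
        selected = ens.top_genes(k)
        per_fold_selected.append(selected)

        X_tr = pseudo.loc[selected, train_subjects].to_numpy().T
        X_te = pseudo.loc[selected, [held_out]].to_numpy().T
        X_tr, X_te = _fold_standardize(X_tr, X_te)
        clf = SVC(random_state=seed, **params)
        clf.fit(X_tr, y_tr)
        pred[i] = int(clf.predict(X_te)[0])

    return _assemble_result(subjects, pred, y, params, seed, per_fold_selected)


class BaselineAccuracy(NamedTuple):
    mean_accuracy: float
    accuracies: np.ndarray
    k: int
    n_sets: int
    seed: int


def random_gene_baseline(
    data: LongitudinalExpressionSet,
    labels=None,
    k: int = 20,
    n_sets: int = 1000,
    svm_params: dict | None = None,
    seed: int = 0,
    use_timepoints=DEFAULT_PSEUDO_TIMEPOINTS,
) -> BaselineAccuracy:
    """LOO accuracy of random k-gene lists, averaged over ``n_sets`` draws."""
    pseudo = make_pseudo_genes(data, use_timepoints)
    subjects = list(pseudo.columns)
    y = data.response_labels(subjects) if labels is None else labels
    p = len(pseudo.index)
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    accs = np.empty(n_sets)
    genes = np.asarray(pseudo.index)
    for j in range(n_sets):
        subset = genes[np.sort(rng.choice(p, size=k, replace=False))]
        accs[j] = loo_svm_accuracy(
            pseudo, y, svm_params=svm_params, gene_subset=list(subset),
            seed=seed).accuracy
    return BaselineAccuracy(float(accs.mean()), accs, k, n_sets, seed)


# -- trajectory summaries ------------------------------------------------------

@dataclass
class TrajectorySummary:
    """Group-mean expression per gene and time point, plus the healthy
    (non-lesional) reference mean per gene."""

    table: pd.DataFrame              # gene, group, timepoint, mean, n, sem
    reference_means: dict            # gene -> non-lesional mean
    reference_label: str

    def mean_at(self, gene: str, group: str, timepoint: str) -> float:
        t = self.table
        row = t[(t["gene"] == gene) & (t["group"] == group)
                & (t["timepoint"] == timepoint)]
        if row.empty:
            raise KeyError(f"no trajectory row for ({gene}, {group}, {timepoint})")
        return float(row["mean"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def group_mean_trajectories(
    data: LongitudinalExpressionSet,
    labels=None,
    gene_subset=None,
    reference_timepoint: str | None = None,
) -> TrajectorySummary:
    """Mean expression per (gene, response group, time point).

    The reference time point (default: the first label, the non-lesional
    sample) supplies each gene's healthy mean, averaged over all subjects.
    """
    genes = list(gene_subset) if gene_subset is not None else list(data.gene_ids)
    unknown = [g for g in genes if g not in data.gene_ids]
    if unknown:
        raise KeyError(f"unknown genes: {unknown[:5]}")
    subjects = data.subject_ids
    y = np.asarray(data.response_labels(subjects) if labels is None else labels)
    ref_tp = reference_timepoint or data.timepoint_labels[0]
    g_idx = np.array([data.gene_ids.index(g) for g in genes])
    vals = np.where(data.missing_mask, np.nan, data.values)[g_idx]

    rows = []
    for group in (RESPONDER, NONRESPONDER):
        members = y == group
        if not members.any():
            raise ValueError(f"empty response group {group!r}")
        sub = vals[:, members, :]                    # (g, members, T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=1)
            n_obs = np.sum(~np.isnan(sub), axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
        sem = np.where(n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), np.nan)
        for gi, g in enumerate(genes):
            for ti, tp in enumerate(data.timepoint_labels):
                rows.append((g, group, tp, mean[gi, ti],
                             int(n_obs[gi, ti]), sem[gi, ti]))
    table = pd.DataFrame(
        rows, columns=["gene", "group", "timepoint", "mean", "n", "sem"])

    ref_idx = data.timepoint_index(ref_tp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_means = np.nanmean(vals[:, :, ref_idx], axis=1)
    return TrajectorySummary(
        table=table,
        reference_means={g: float(m) for g, m in zip(genes, ref_means)},
        reference_label=ref_tp,
    )


class GapClosure(NamedTuple):
    ratio: float
    defined: bool


def gap_closure(traj: TrajectorySummary, gene: str, group: str,
                from_tp: str, to_tp: str) -> GapClosure:
    """How far the lesional-vs-healthy gap has closed between two time points.

    ``|mean(to) - reference| / |mean(from) - reference|``; below 1 means the
    group's expression moved toward the healthy reference.  A starting gap
    below 1e-8 makes the ratio undefined.
    """
    if gene not in traj.reference_means:
        raise KeyError(f"unknown gene {gene!r}")
    ref = traj.reference_means[gene]
    start = abs(traj.mean_at(gene, group, from_tp) - ref)
    end = abs(traj.mean_at(gene, group, to_tp) - ref)
    if start < 1e-8:
        return GapClosure(float("nan"), False)
    return GapClosure(end / start, True)
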