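"""Random-subspace ensemble of joint latent-variable clusterings.

Each weak learner fits the multi-view latent-variable model (shrinkage off,
K = 2) on a small random gene subset, maps its two clusters onto the binary
response labels by whichever of the two possible mappings agrees better, and
is kept only if that agreement exceeds an accuracy cutoff.  Kept learners
vote on each subject's class, and every gene accumulates an importance score:
the sum of its absolute per-view loadings over all kept learners that sampled
it.  Genes that always shrink to zero or never enter a kept learner score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RESPONDER, NONRESPONDER, ViewStack
from .model import IClusterFit, fit_icluster


def _as_binary(true_labels) -> np.ndarray:
    y = np.asarray(true_labels)
    out = np.empty(y.shape, dtype=int)
    for i, v in enumerate(y):
        if v in (RESPONDER, 1, True):
            out[i] = 1
        elif v in (NONRESPONDER, 0, False):
            out[i] = 0
        else:
            raise ValueError(f"unrecognized response label {v!r}")
    return out


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Counter-based substream: replicate r is reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def sample_gene_subset(p: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m distinct gene indices uniformly without replacement."""
    if not 1 <= m <= p:
        raise ValueError(f"subset size {m} must be in [1, {p}]")
    return np.sort(rng.choice(p, size=m, replace=False))


def map_clusters_to_labels(cluster_labels, true_labels):
    """Best-of-two mapping from 2 cluster ids onto the binary outcome.

    Both possible cluster-to-class mappings are evaluated; the more accurate
    one wins.  On an exact accuracy tie the cluster holding more responders
    maps to the responder class, and if that also ties the lower cluster id
    does.  Returns ``(mapping, accuracy)`` with mapping a dict
    ``{cluster_id: class_label}``.
    """
    cl = np.asarray(cluster_labels, dtype=int)
    y = _as_binary(true_labels)
    if cl.shape != y.shape:
        raise ValueError("cluster and true label lengths differ")
    ids = np.unique(cl)
    if ids.size > 2:
        raise ValueError(f"expected at most 2 clusters, got {ids.size}")
    if ids.size == 2:
        a, b = int(ids[0]), int(ids[1])
    else:  # degenerate single-cluster fit: the absent id predicts nobody
        a, b = int(ids[0]), int(ids[0]) + 1
    in_a = cl == a
    # mapping a -> responder predicts 1 on cluster a, 0 elsewhere; the
    # opposite mapping is its exact complement on a binary outcome
    acc_a_resp = (np.count_nonzero(y[in_a] == 1)
                  + np.count_nonzero(y[~in_a] == 0)) / y.size
    acc_b_resp = 1.0 - acc_a_resp
    if acc_a_resp > acc_b_resp:
        resp_cluster = a
    elif acc_b_resp > acc_a_resp:
        resp_cluster = b
    else:
        n_resp_a = int(np.count_nonzero(y[in_a] == 1))
        n_resp_b = int(np.count_nonzero(y[~in_a] == 1))
        if n_resp_a > n_resp_b:
            resp_cluster = a
        elif n_resp_b > n_resp_a:
            resp_cluster = b
        else:
            resp_cluster = min(a, b)
    other = b if resp_cluster == a else a
    mapping = {resp_cluster: RESPONDER, other: NONRESPONDER}
    accuracy = float(np.mean(
        np.where(cl == resp_cluster, 1, 0) == y))
    return mapping, accuracy


@dataclass
class WeakLearnerResult:
    """One gene subset's fit, label mapping and agreement accuracy."""

    gene_indices: np.ndarray
    fit: IClusterFit
    label_mapping: dict
    accuracy: float
    predicted: np.ndarray       # per-subject class labels


def run_weak_learner(views: ViewStack, gene_indices, true_labels,
                     icluster_params: dict | None = None) -> WeakLearnerResult:
    """Fit one weak learner on the given gene subset.

    Defaults follow the ensemble design: shrinkage disabled (lam = 0, the
    subsets are already small) and K = 2 clusters matching the binary
    outcome.
    """
    params = {"K": 2, "lam": 0.0, "seed": 0}
    params.update(icluster_params or {})
    gene_indices = np.asarray(gene_indices, dtype=int)
    sub = views.restrict_genes(gene_indices)
    fit = fit_icluster(sub, **params)
    mapping, accuracy = map_clusters_to_labels(fit.cluster_labels, true_labels)
    predicted = np.array([mapping[int(c)] for c in fit.cluster_labels])
    return WeakLearnerResult(
        gene_indices=gene_indices, fit=fit, label_mapping=mapping,
        accuracy=accuracy, predicted=predicted)


def aggregate_scores(kept, p: int, normalize_by_sampled: bool = False,
                     use_max: bool = False,
                     times_sampled: np.ndarray | None = None) -> np.ndarray:
    """Per-gene importance from kept weak learners.

    Default score of gene g: sum over kept learners containing g of the sum
    over views (and latent dimensions) of |loading|.  ``use_max`` swaps the
    inner sum for the max over views — more prone to missing genes whose
    per-view loadings are individually subtle but jointly large, hence not
    the default.  ``normalize_by_sampled`` divides by how often the gene was
    sampled (requires ``times_sampled``).
    """
    scores = np.zeros(p)
    for wl in kept:
        per_view = np.stack(
            [np.abs(Wt).sum(axis=1) for Wt in wl.fit.W])  # (T, m)
        contrib = per_view.max(axis=0) if use_max else per_view.sum(axis=0)
        scores[wl.gene_indices] += contrib
    if normalize_by_sampled:
        if times_sampled is None:
            raise ValueError("normalize_by_sampled requires times_sampled")
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(times_sampled > 0, scores / times_sampled, 0.0)
    return scores


def majority_vote(kept, n_subjects: int, tie_label: str = NONRESPONDER):
    """Vote subject classes over kept learners; strict majority wins.

    The published rule covers only strict majorities; an exact tie defaults
    to the non-responder class (conservative clinical default, overridable).
    Returns ``(voted_labels, vote_counts)`` with counts as an
    ``(n_subjects, 2)`` array ordered (non-responder, responder).
    """
    if not kept:
        raise ValueError("no kept learners to vote with")
    counts = np.zeros((n_subjects, 2), dtype=int)
    for wl in kept:
        is_resp = wl.predicted == RESPONDER
        counts[:, 1] += is_resp
        counts[:, 0] += ~is_resp
    voted = np.where(
        counts[:, 1] > counts[:, 0], RESPONDER,
        np.where(counts[:, 0] > counts[:, 1], NONRESPONDER, tie_label))
    return voted, counts


def select_top_k(scores, k: int, gene_ids=None):
    """Top-k genes by score descending; ties break lexicographically by id."""
    if isinstance(scores, dict):
        items = list(scores.items())
    else:
        scores = np.asarray(scores, float)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(scores.size)]
        items = list(zip(gene_ids, scores))
    if k > len(items):
        raise ValueError(f"k={k} exceeds the {len(items)} scored genes")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in items[:k]]


@dataclass
class EnsembleResult:
    """Aggregate of one ensemble run."""

    n_replicates: int
    subset_size: int
    accuracy_cutoff: float
    kept_count: int
    gene_ids: list
    gene_scores: np.ndarray
    times_sampled: np.ndarray
    times_kept: np.ndarray
    vote_counts: np.ndarray          # (n_subjects, 2): non-responder, responder
    voted_labels: np.ndarray
    vote_accuracy: float
    subject_ids: list
    seed: int
    config: dict = field(default_factory=dict)
    replicate_accuracies: np.ndarray | None = None

    def top_genes(self, k: int):
        return select_top_k(self.gene_scores, k, gene_ids=self.gene_ids)

    def scores_by_gene(self) -> dict:
        return {g: float(s) for g, s in zip(self.gene_ids, self.gene_scores)}

    def to_dict(self) -> dict:
        order = np.lexsort((np.asarray(self.gene_ids, dtype=object),
                            -self.gene_scores))
        return {
            "n_replicates": self.n_replicates,
            "subset_size": self.subset_size,
            "accuracy_cutoff": self.accuracy_cutoff,
            "kept_count": self.kept_count,
            "gene_scores": [
                {"gene": self.gene_ids[i],
                 "score": float(self.gene_scores[i]),
                 "times_sampled": int(self.times_sampled[i]),
                 "times_kept": int(self.times_kept[i])}
                for i in order
            ],
            "vote_counts": {
                s: {"non-responder": int(c0), "responder": int(c1)}
                for s, (c0, c1) in zip(self.subject_ids, self.vote_counts)
            },
            "voted_labels": {s: str(v) for s, v in
                             zip(self.subject_ids, self.voted_labels)},
            "vote_accuracy": float(self.vote_accuracy),
            "seed": self.seed,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleResult":
        genes = [row["gene"] for row in d["gene_scores"]]
        subject_ids = list(d["vote_counts"])
        return cls(
            n_replicates=d["n_replicates"],
            subset_size=d["subset_size"],
            accuracy_cutoff=d["accuracy_cutoff"],
            kept_count=d["kept_count"],
            gene_ids=genes,
            gene_scores=np.array([row["score"] for row in d["gene_scores"]]),
            times_sampled=np.array(
                [row["times_sampled"] for row in d["gene_scores"]]),
            times_kept=np.array([row["times_kept"] for row in d["gene_scores"]]),
            vote_counts=np.array(
                [[d["vote_counts"][s]["non-responder"],
                  d["vote_counts"][s]["responder"]] for s in subject_ids]),
            voted_labels=np.array([d["voted_labels"][s] for s in subject_ids]),
            vote_accuracy=d["vote_accuracy"],
            subject_ids=subject_ids,
            seed=d["seed"],
            config=d.get("config", {}),
        )

    def to_frame(self):
        import pandas as pd
        order = np.lexsort((np.asarray(self.gene_ids, dtype=object),
                            -self.gene_scores))
        return pd.DataFrame({
            "gene": [self.gene_ids[i] for i in order],
            "score": self.gene_scores[order],
            "times_sampled": self.times_sampled[order],
            "times_kept": self.times_kept[order],
        })


def run_ensemble(
    views: ViewStack,
    true_labels,
    n_replicates: int = 10_000,
    subset_size: int = 20,
    accuracy_cutoff: float = 0.75,
    seed: int = 0,
    icluster_params: dict | None = None,
    vote_over_all: bool = False,
    tie_label: str = NONRESPONDER,
    score_use_max: bool = False,
    normalize_by_sampled: bool = False,
) -> EnsembleResult:
    """Run the full random-subspace ensemble.

    ``n_replicates`` weak learners are fitted on independent seeded
    substreams; those whose label agreement is *strictly* greater than
    ``accuracy_cutoff`` are kept for scoring and (by default) voting.
    ``vote_over_all`` lets every replicate vote regardless of the cutoff.
    Raises if no learner passes the cutoff — that outcome must fail loudly
    rather than return an empty signature.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0.0 <= accuracy_cutoff < 1.0:
        raise ValueError("accuracy_cutoff must be in [0, 1)")
    y = _as_binary(true_labels)
    n = views.n_subjects
    if y.size != n:
        raise ValueError("label length does not match subject count")
    p = views.n_genes

    scores = np.zeros(p)
    times_sampled = np.zeros(p, dtype=int)
    times_kept = np.zeros(p, dtype=int)
    vote_counts = np.zeros((n, 2), dtype=int)
    kept_count = 0
    accuracies = np.empty(n_replicates)

    for r in range(n_replicates):
        rng = replicate_rng(seed, r)
        subset = sample_gene_subset(p, subset_size, rng)
        wl = run_weak_learner(views, subset, y, icluster_params)
        accuracies[r] = wl.accuracy
        times_sampled[subset] += 1
        keep = wl.accuracy > accuracy_cutoff
        if keep:
            kept_count += 1
            times_kept[subset] += 1
            per_view = np.stack([np.abs(Wt).sum(axis=1) for Wt in wl.fit.W])
            contrib = per_view.max(axis=0) if score_use_max else per_view.sum(axis=0)
            scores[subset] += contrib
        if keep or vote_over_all:
            is_resp = wl.predicted == RESPONDER
            vote_counts[:, 1] += is_resp
            vote_counts[:, 0] += ~is_resp

    if kept_count == 0:
        raise RuntimeError(
            f"no weak learner exceeded the accuracy cutoff {accuracy_cutoff}; "
            "lower the cutoff or check the data for signal")
    if normalize_by_sampled:
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(times_sampled > 0, scores / times_sampled, 0.0)

    voted = np.where(
        vote_counts[:, 1] > vote_counts[:, 0], RESPONDER,
        np.where(vote_counts[:, 0] > vote_counts[:, 1], NONRESPONDER, tie_label))
    truth = np.where(y == 1, RESPONDER, NONRESPONDER)
    vote_accuracy = float(np.mean(voted == truth))

    return EnsembleResult(
        n_replicates=n_replicates,
        subset_size=subset_size,
        accuracy_cutoff=accuracy_cutoff,
        kept_count=kept_count,
        gene_ids=list(views.gene_ids),
        gene_scores=scores,
        times_sampled=times_sampled,
        times_kept=times_kept,
        vote_counts=vote_counts,
        voted_labels=voted,
        vote_accuracy=vote_accuracy,
        subject_ids=list(views.subject_ids),
        seed=seed,
        replicate_accuracies=accuracies,
        config={
            "icluster_params": icluster_params or {},
            "vote_over_all": vote_over_all,
            "tie_label": tie_label,
            "score_use_max": score_use_max,
            "normalize_by_sampled": normalize_by_sampled,
        },
    )
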