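"""Comparator selectors: a LASSO-logistic ensemble and a single joint fit.

Both rank genes for the same downstream LOO-SVM evaluation as the main
ensemble, so the comparison isolates the selection strategy.  The LASSO
ensemble mirrors the random-subspace design but swaps the weak learner for an
L1-penalized logistic regression on time-averaged pseudo-gene covariates
(longitudinal profiles collapsed to cross-sectional ones); the single-fit
selector runs the latent-variable model once on all genes and ranks by summed
absolute loadings, quantifying what the ensemble adds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .ensemble import (
    _as_binary,
    map_clusters_to_labels,
    replicate_rng,
    sample_gene_subset,
    select_top_k,
)
from .model import fit_icluster


@dataclass
class BaselineSelection:
    """Gene ranking produced by a comparator method."""

    method: str
    gene_ids: list
    gene_scores: np.ndarray
    top_genes: list
    extra: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        order = np.lexsort((np.asarray(self.gene_ids, dtype=object),
                            -self.gene_scores))
        return {
            "method": self.method,
            "gene_scores": [
                {"gene": self.gene_ids[i], "score": float(self.gene_scores[i])}
                for i in order
            ],
            "top_genes": list(self.top_genes),
            "extra": self.extra,
            "seed": self.seed,
        }


def lasso_ensemble(
    pseudo: pd.DataFrame,
    labels,
    subset_size: int = 100,
    n_replicates: int = 10_000,
    k: int = 20,
    seed: int = 0,
    C: float | None = None,
    use_abs: bool = True,
) -> BaselineSelection:
    """Random-subspace ensemble with an L1 logistic weak learner.

    Per replicate, ``subset_size`` genes are drawn and an L1-penalized
    logistic model is fitted on their pseudo-gene covariates (standardized);
    each gene accumulates the absolute value of its fitted coefficient (raw
    coefficients with ``use_abs=False``).  The penalty is chosen per
    replicate by 3-fold cross-validated deviance unless a fixed inverse
    penalty ``C`` is given.  The top-k genes by total score are returned;
    ties break lexicographically.
    """
    genes = list(pseudo.index)
    p = len(genes)
    if subset_size > p:
        raise ValueError(f"subset_size {subset_size} exceeds {p} genes")
    y = _as_binary(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate: a single class")
    X_all = pseudo.to_numpy().T                       # subjects x genes
    mu = X_all.mean(axis=0)
    sd = X_all.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    X_all = (X_all - mu) / sd

    scores = np.zeros(p)
    for r in range(n_replicates):
        rng = replicate_rng(seed, r)
        subset = sample_gene_subset(p, subset_size, rng)
        X = X_all[:, subset]
        state = int(rng.integers(2**31))
        if C is None:
            clf = LogisticRegressionCV(
                l1_ratios=(1.0,), solver="liblinear",
                Cs=np.logspace(-2, 2, 10), cv=3, scoring="neg_log_loss",
                random_state=state, max_iter=500,
                use_legacy_attributes=False)
        else:
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, random_state=state,
                max_iter=500)
        clf.fit(X, y)
        coefs = clf.coef_[0]
        scores[subset] += np.abs(coefs) if use_abs else coefs

    if np.all(scores == 0):
        warnings.warn("all coefficients shrank to zero; the top-k ordering is "
                      "purely lexicographic")
    top = select_top_k(scores, k, gene_ids=genes)
    return BaselineSelection(
        method="lasso-ensemble", gene_ids=genes, gene_scores=scores,
        top_genes=top, seed=seed,
        extra={"subset_size": subset_size, "n_replicates": n_replicates,
               "k": k, "C": C, "use_abs": use_abs},
    )


def single_icluster_selector(
    views,
    labels,
    k: int = 20,
    seed: int = 0,
    lam: float = 0.0,
) -> BaselineSelection:
    """One latent-variable fit on all genes; rank by summed |loading|.

    Equivalent to a one-replicate ensemble whose subset is every gene with
    the accuracy filter disabled.  Also reports the fit's cluster-to-label
    agreement, the 'single run' accuracy the ensemble is compared against.
    """
    y = _as_binary(labels)
    fit = fit_icluster(views, K=2, lam=lam, seed=seed)
    mapping, accuracy = map_clusters_to_labels(fit.cluster_labels, y)
    scores = fit.abs_loading_sums()
    genes = list(views.gene_ids)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes")
    top = select_top_k(scores, k, gene_ids=genes)
    return BaselineSelection(
        method="single-icluster", gene_ids=genes, gene_scores=scores,
        top_genes=top, seed=seed,
        extra={"cluster_accuracy": float(accuracy), "k": k,
               "lambda": lam},
    )
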