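"""Synthetic longitudinal expression data with planted treatment-response signal.

The generator emulates a two-tissue treatment time-course: every subject has a
non-lesional (healthy) reference sample and a series of lesional samples at
increasing times after treatment start.  For an *informative* gene ``g`` with
healthy mean ``mu_g`` and lesional displacement ``delta_g``, responders decay
geometrically back toward the healthy mean,

    lesional mean at step t = mu_g + delta_g * r**t        (responders)
    lesional mean at step t = mu_g + delta_g + drift * t   (non-responders)

with ``t = 0`` at the first lesional time point and recovery rate
``0 < r < 1``.  Non-informative genes follow one common law for both groups
(a displacement drawn once, no recovery).  Noise is a per-(gene, subject)
random intercept, shared across time points, plus i.i.d. residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import RESPONDER, NONRESPONDER, LongitudinalExpressionSet

DEFAULT_TIMEPOINTS = ("NL", "LS0", "W1", "W2", "W4")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    ``timepoint_labels[0]`` is the non-lesional reference; the remaining
    labels are lesional steps t = 0, 1, 2, ...  ``delta_range`` bounds the
    displacement magnitude; each informative gene's sign is drawn uniformly.
    Units are log2 expression throughout.
    """

    n_subjects: int = 30
    prop_responders: float = 0.5
    p_genes: int = 300
    n_informative: int = 20
    nl_mean_range: tuple = (5.0, 10.0)
    delta_range: tuple = (1.5, 2.5)
    recovery_rate: float = 0.5
    nonresponder_drift: float = 0.0
    sigma_subject: float = 0.3
    sigma_noise: float = 0.5
    timepoint_labels: tuple = DEFAULT_TIMEPOINTS
    linear_recovery: bool = False
    per_gene_recovery_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 4:
            problems.append("n_subjects must be >= 4")
        if not 0.0 < self.prop_responders < 1.0:
            problems.append("prop_responders must be in (0, 1)")
        n_resp = int(round(self.prop_responders * self.n_subjects))
        if min(n_resp, self.n_subjects - n_resp) < 2:
            problems.append("each response group needs >= 2 subjects")
        if self.p_genes < 1:
            problems.append("p_genes must be >= 1")
        if not 0 <= self.n_informative <= self.p_genes:
            problems.append("n_informative must be in [0, p_genes]")
        if not 0.0 < self.recovery_rate < 1.0:
            problems.append("recovery_rate must be in (0, 1)")
        if self.sigma_subject < 0:
            problems.append("sigma_subject must be >= 0")
        if self.sigma_noise < 0:
            problems.append("sigma_noise must be >= 0")
        if len(self.timepoint_labels) < 2:
            problems.append("need the reference plus >= 1 lesional timepoint")
        if len(set(self.timepoint_labels)) != len(self.timepoint_labels):
            problems.append("timepoint_labels must be unique")
        lo, hi = self.nl_mean_range
        if not lo <= hi:
            problems.append("nl_mean_range must be a (low, high) interval")
        lo, hi = self.delta_range
        if not 0 <= lo <= hi:
            problems.append("delta_range must be a non-negative (low, high) interval")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for recovery testing."""

    informative_gene_ids: tuple
    gene_means: dict            # gene id -> healthy mean mu_g
    gene_deltas: dict           # gene id -> lesional displacement delta_g
    group_labels: dict          # subject id -> responder / non-responder
    recovery_rates: dict = field(default_factory=dict)


def simulate_longitudinal(config: SimulationConfig):
    """Draw one dataset; deterministic given ``config.seed``.

    Returns ``(LongitudinalExpressionSet, SimulationTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    G, S = config.p_genes, config.n_subjects
    tps = list(config.timepoint_labels)
    T = len(tps)

    gene_ids = [f"G{i + 1:04d}" for i in range(G)]
    subject_ids = [f"S{i + 1:02d}" for i in range(S)]

    n_resp = int(round(config.prop_responders * S))
    is_resp = np.zeros(S, dtype=bool)
    is_resp[rng.permutation(S)[:n_resp]] = True

    informative = np.zeros(G, dtype=bool)
    informative[rng.permutation(G)[:config.n_informative]] = True

    mu = rng.uniform(*config.nl_mean_range, size=G)
    sign = rng.choice([-1.0, 1.0], size=G)
    delta = sign * rng.uniform(*config.delta_range, size=G)
    if config.per_gene_recovery_sd > 0:
        r_gene = np.clip(
            rng.normal(config.recovery_rate, config.per_gene_recovery_sd, size=G),
            0.01, 0.99)
    else:
        r_gene = np.full(G, config.recovery_rate)

    # mean surface (G, S, T)
    mean = np.empty((G, S, T))
    mean[:, :, 0] = mu[:, None]                       # non-lesional reference
    steps = np.arange(T - 1)                          # t = 0 at first lesional tp
    if config.linear_recovery:
        frac = np.clip(1.0 - steps[None, :] * (1.0 - r_gene[:, None]), 0.0, 1.0)
    else:
        frac = r_gene[:, None] ** steps[None, :]      # (G, T-1)
    les_resp = mu[:, None] + delta[:, None] * frac                      # (G, T-1)
    les_nonresp = (mu[:, None] + delta[:, None]
                   + config.nonresponder_drift * steps[None, :])
    les_flat = mu[:, None] + delta[:, None]           # non-informative, both groups
    for j, flag in enumerate(informative):
        if flag:
            mean[j, is_resp, 1:] = les_resp[j]
            mean[j, ~is_resp, 1:] = les_nonresp[j]
        else:
            mean[j, :, 1:] = les_flat[j]

    intercept = rng.normal(0.0, config.sigma_subject, size=(G, S))
    noise = rng.normal(0.0, config.sigma_noise, size=(G, S, T))
    values = mean + intercept[:, :, None] + noise

    meta = pd.DataFrame(
        {
            "subject": subject_ids,
            "response": np.where(is_resp, RESPONDER, NONRESPONDER),
        }
    ).set_index("subject")

    data = LongitudinalExpressionSet(
        gene_ids=gene_ids,
        subject_ids=subject_ids,
        timepoint_labels=tps,
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        sample_meta=meta,
    )
    truth = SimulationTruth(
        informative_gene_ids=tuple(g for g, f in zip(gene_ids, informative) if f),
        gene_means={g: float(m) for g, m in zip(gene_ids, mu)},
        gene_deltas={g: float(d) for g, d in zip(gene_ids, delta)},
        group_labels={s: (RESPONDER if f else NONRESPONDER)
                      for s, f in zip(subject_ids, is_resp)},
        recovery_rates={g: float(r) for g, r in zip(gene_ids, r_gene)},
    )
    return data, truth


REFERENCE_SEED = 20210420


def reference_config(seed: int = REFERENCE_SEED) -> SimulationConfig:
    """The fixed study-shaped scenario: 30 subjects split evenly between
    responders and non-responders, 300 genes of which 20 are informative,
    displacement magnitude 1.5-2.5 with random sign, recovery rate 0.5 per
    step, subject-intercept sd 0.3, residual sd 0.5, time points
    NL, LS0, W1, W2, W4."""
    return SimulationConfig(seed=seed)


def reference_simulation(seed: int = REFERENCE_SEED):
    """Generate the reference scenario (see :func:`reference_config`)."""
    return simulate_longitudinal(reference_config(seed))
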