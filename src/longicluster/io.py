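"""Reading, writing and reshaping longitudinal expression data.

Expression matrices are tab-delimited text, either *wide* (one row per gene,
one column per sample keyed ``subject<sep>timepoint``) or *long* (columns
``gene, subject, timepoint, value``).  Sample metadata is a TSV with columns
``subject``, ``response`` and optionally ``treatment``.  The in-memory object
is a dense (genes, subjects, timepoints) array with an explicit missing mask;
the model consumes a :class:`ViewStack` of per-time-point standardized
matrices sharing gene and subject order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONDER = "responder"
NONRESPONDER = "non-responder"

STANDARDIZE_TOL = 1e-8


@dataclass
class LongitudinalExpressionSet:
    """Genes x subjects x time points of log-scale expression plus metadata.

    ``values[g, s, t]`` is finite where ``missing_mask[g, s, t]`` is False and
    NaN where it is True.  ``sample_meta`` is indexed by subject and must give
    every subject a binary ``response`` label.
    """

    gene_ids: list
    subject_ids: list
    timepoint_labels: list
    values: np.ndarray
    missing_mask: np.ndarray
    sample_meta: pd.DataFrame
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        G, S, T = len(self.gene_ids), len(self.subject_ids), len(self.timepoint_labels)
        if self.values.shape != (G, S, T):
            raise ValueError(
                f"values shape {self.values.shape} != ({G}, {S}, {T})")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        for name, ids in (("gene", self.gene_ids), ("subject", self.subject_ids),
                          ("timepoint", self.timepoint_labels)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isfinite(observed).all():
            raise ValueError("non-finite values outside the missing mask")
        missing_meta = [s for s in self.subject_ids
                        if s not in self.sample_meta.index]
        if missing_meta:
            raise ValueError(f"subjects without metadata: {missing_meta[:5]}")
        bad = set(self.sample_meta.loc[self.subject_ids, "response"]) - {
            RESPONDER, NONRESPONDER}
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self):
        return self.values.shape

    def response_labels(self, subjects=None) -> np.ndarray:
        subjects = self.subject_ids if subjects is None else subjects
        return self.sample_meta.loc[subjects, "response"].to_numpy()

    def timepoint_index(self, label: str) -> int:
        try:
            return self.timepoint_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown timepoint {label!r}; have {self.timepoint_labels}")

    def subset_subjects(self, subjects) -> "LongitudinalExpressionSet":
        idx = [self.subject_ids.index(s) for s in subjects]
        return LongitudinalExpressionSet(
            gene_ids=list(self.gene_ids),
            subject_ids=list(subjects),
            timepoint_labels=list(self.timepoint_labels),
            values=self.values[:, idx, :],
            missing_mask=self.missing_mask[:, idx, :],
            sample_meta=self.sample_meta.loc[list(subjects)],
        )

    def equals(self, other: "LongitudinalExpressionSet") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.subject_ids == other.subject_ids
            and self.timepoint_labels == other.timepoint_labels
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
                atol=1e-9, rtol=0,
            )
            and list(self.sample_meta.columns) == list(other.sample_meta.columns)
            and self.sample_meta.loc[self.subject_ids].equals(
                other.sample_meta.loc[other.subject_ids])
        )


@dataclass
class ViewStack:
    """Per-time-point matrices sharing gene and subject order.

    When ``standardization`` is present each gene row of each view has been
    z-scored over that view's subjects; zero-variance rows are centered only
    and listed in ``standardization['zero_variance']`` as (view, gene) pairs.
    """

    views: list
    view_labels: list
    gene_ids: list
    subject_ids: list
    standardization: dict | None = None

    def __post_init__(self):
        self.views = [np.asarray(v, float) for v in self.views]
        if not self.views:
            raise ValueError("need at least one view")
        shape = (len(self.gene_ids), len(self.subject_ids))
        for label, v in zip(self.view_labels, self.views):
            if v.shape != shape:
                raise ValueError(f"view {label!r} has shape {v.shape}, want {shape}")
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite values in view {label!r}")

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def restrict_genes(self, gene_indices) -> "ViewStack":
        idx = np.asarray(gene_indices, dtype=int)
        return ViewStack(
            views=[v[idx] for v in self.views],
            view_labels=list(self.view_labels),
            gene_ids=[self.gene_ids[i] for i in idx],
            subject_ids=list(self.subject_ids),
            standardization=self.standardization,
        )


def build_views(
    data: LongitudinalExpressionSet,
    use_timepoints,
    standardize: bool = True,
) -> ViewStack:
    """Reshape the longitudinal set into per-time-point views.

    Subjects missing any cell at a *used* time point are dropped so all views
    stay aligned; missingness at unused time points is ignored.  With
    ``standardize`` each gene row is z-scored (sample sd, ddof=1) within each
    view; constant rows are centered and left at zero.
    """
    use_timepoints = list(use_timepoints)
    if not use_timepoints:
        raise ValueError("use_timepoints must be non-empty")
    t_idx = [data.timepoint_index(t) for t in use_timepoints]

    miss_any = data.missing_mask[:, :, t_idx].any(axis=(0, 2))   # per subject
    keep = [s for s, m in zip(data.subject_ids, miss_any) if not m]
    if not keep:
        raise ValueError("all subjects dropped: every subject is missing a cell "
                         "at a requested timepoint")
    if len(keep) < 2:
        raise ValueError(f"only {len(keep)} subject(s) remain after dropping "
                         "incomplete subjects")
    s_idx = [data.subject_ids.index(s) for s in keep]

    views = []
    zero_variance = []
    means, sds = [], []
    for t in t_idx:
        V = data.values[:, s_idx, t].copy()
        if standardize:
            mu = V.mean(axis=1, keepdims=True)
            sd = V.std(axis=1, ddof=1, keepdims=True)
            flat = sd[:, 0] < STANDARDIZE_TOL
            sd_safe = np.where(flat[:, None], 1.0, sd)
            V = (V - mu) / sd_safe
            V[flat] = 0.0
            zero_variance.extend(
                (data.timepoint_labels[t], data.gene_ids[g])
                for g in np.flatnonzero(flat))
            means.append(mu[:, 0])
            sds.append(sd[:, 0])
        views.append(V)

    standardization = None
    if standardize:
        standardization = {
            "means": means,
            "sds": sds,
            "zero_variance": zero_variance,
            "ddof": 1,
        }
    return ViewStack(
        views=views,
        view_labels=use_timepoints,
        gene_ids=list(data.gene_ids),
        subject_ids=keep,
        standardization=standardization,
    )


# -- expression TSV round trip -------------------------------------------------

def read_expression(
    path,
    meta_path,
    layout: str = "wide",
    key_sep: str = "__",
) -> LongitudinalExpressionSet:
    """Read an expression TSV plus a sample-metadata TSV.

    Wide layout: first column holds gene ids, remaining columns are named
    ``subject<key_sep>timepoint``.  Long layout: columns ``gene, subject,
    timepoint, value``.  Unparseable numeric cells become missing and are
    counted in ``load_report``; duplicate (gene, subject, timepoint) triples
    are an error.  Subjects absent from the metadata are dropped (counted in
    the report); no overlap at all is an error.
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "subject" not in meta.columns or "response" not in meta.columns:
        raise ValueError("metadata needs 'subject' and 'response' columns")
    if meta["subject"].duplicated().any():
        dup = meta.loc[meta["subject"].duplicated(), "subject"].iloc[0]
        raise ValueError(f"duplicate metadata row for subject {dup!r}")
    meta = meta.set_index("subject")

    if layout == "wide":
        long = _wide_to_long(path, key_sep)
    elif layout == "long":
        long = pd.read_csv(
            path, sep="\t", dtype={"gene": str, "subject": str, "timepoint": str})
        missing_cols = {"gene", "subject", "timepoint", "value"} - set(long.columns)
        if missing_cols:
            raise ValueError(f"long layout is missing columns {sorted(missing_cols)}")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    dup = long.duplicated(subset=["gene", "subject", "timepoint"])
    if dup.any():
        row = long.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (gene, subject, timepoint) triple: "
            f"({row['gene']}, {row['subject']}, {row['timepoint']})")

    numeric = pd.to_numeric(long["value"], errors="coerce")
    was_blank = long["value"].isna() | (long["value"].astype(str).str.strip() == "")
    n_unparseable = int((numeric.isna() & ~was_blank).sum())

    gene_ids = list(dict.fromkeys(long["gene"]))
    subject_ids = list(dict.fromkeys(long["subject"]))
    timepoints = list(dict.fromkeys(long["timepoint"]))

    in_meta = [s for s in subject_ids if s in meta.index]
    if not in_meta:
        raise ValueError("no overlap between expression subjects and metadata")
    dropped = [s for s in subject_ids if s not in meta.index]
    subject_ids = in_meta

    g_pos = {g: i for i, g in enumerate(gene_ids)}
    s_pos = {s: i for i, s in enumerate(subject_ids)}
    t_pos = {t: i for i, t in enumerate(timepoints)}
    values = np.full((len(gene_ids), len(subject_ids), len(timepoints)), np.nan)
    mask = np.ones_like(values, dtype=bool)
    rows = long["gene"].map(g_pos).to_numpy()
    cols = long["subject"].map(s_pos).to_numpy()
    deps = long["timepoint"].map(t_pos).to_numpy()
    ok = ~pd.isna(cols) & ~numeric.isna().to_numpy()
    rows, cols, deps = rows[ok], cols[ok].astype(int), deps[ok]
    values[rows, cols, deps] = numeric.to_numpy()[ok]
    mask[rows, cols, deps] = False

    return LongitudinalExpressionSet(
        gene_ids=gene_ids,
        subject_ids=subject_ids,
        timepoint_labels=timepoints,
        values=values,
        missing_mask=mask,
        sample_meta=meta,
        load_report={
            "n_unparseable_cells": n_unparseable,
            "n_missing_cells": int(mask.sum()),
            "dropped_subjects_without_metadata": dropped,
        },
    )


def _wide_to_long(path, key_sep: str) -> pd.DataFrame:
    wide = pd.read_csv(path, sep="\t", dtype=str)
    gene_col = wide.columns[0]
    bad = [c for c in wide.columns[1:] if key_sep not in c]
    if bad:
        raise ValueError(
            f"wide columns must be named subject{key_sep}timepoint; bad: {bad[:5]}")
    long = wide.melt(id_vars=[gene_col], var_name="key", value_name="value")
    parts = long["key"].str.split(key_sep, n=1, expand=True)
    long["subject"], long["timepoint"] = parts[0], parts[1]
    long = long.rename(columns={gene_col: "gene"})
    return long[["gene", "subject", "timepoint", "value"]]


def write_expression(data: LongitudinalExpressionSet, path, meta_path,
                     layout: str = "long", key_sep: str = "__") -> None:
    """Write the set back to TSV (missing cells become blank values)."""
    G, S, T = data.shape
    if layout == "long":
        g, s, t = np.meshgrid(range(G), range(S), range(T), indexing="ij")
        df = pd.DataFrame({
            "gene": np.asarray(data.gene_ids)[g.ravel()],
            "subject": np.asarray(data.subject_ids)[s.ravel()],
            "timepoint": np.asarray(data.timepoint_labels)[t.ravel()],
            "value": [
                "" if m else repr(float(v))
                for v, m in zip(data.values.ravel(), data.missing_mask.ravel())
            ],
        })
        df.to_csv(path, sep="\t", index=False)
    elif layout == "wide":
        cols = {}
        for j, s in enumerate(data.subject_ids):
            for k, t in enumerate(data.timepoint_labels):
                col = [
                    "" if data.missing_mask[i, j, k]
                    else repr(float(data.values[i, j, k]))
                    for i in range(G)
                ]
                cols[f"{s}{key_sep}{t}"] = col
        pd.DataFrame({"gene": data.gene_ids, **cols}).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    meta = data.sample_meta.loc[data.subject_ids].reset_index()
    meta = meta.rename(columns={meta.columns[0]: "subject"})
    meta.to_csv(meta_path, sep="\t", index=False)


# -- result report serialization ----------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_report(obj, path) -> None:
    """Serialize a result object deterministically.

    ``.json`` paths get the full object (via its ``to_dict`` when it has one)
    with sorted keys; ``.tsv`` paths get the object's tabular summary
    (``to_frame``) — per-fold predictions for evaluation results, the score
    table for ensemble results.
    """
    path = str(path)
    if path.endswith(".tsv"):
        if not hasattr(obj, "to_frame"):
            raise TypeError(f"{type(obj).__name__} has no tabular form")
        obj.to_frame().to_csv(path, sep="\t", index=False)
        return
    payload = obj.to_dict() if hasattr(obj, "to_dict") else _jsonable(obj)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_report(path, cls=None):
    """Read a JSON report back; ``cls.from_dict`` rebuilds the object."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if cls is not None:
        return cls.from_dict(payload)
    return payload
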