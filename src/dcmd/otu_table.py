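"""OTU count tables: reading, validation, filtering, screening, resolutions.

The universal input is a table of non-negative integer counts ``n_ij`` for
``I`` samples by ``J`` OTUs, with per-sample total aligned reads ``N_i`` and
optional class labels.  Per-sample *resolutions* ``t_i = N_i / mean(N)``
normalize sequencing depth to the cohort average and scale all Poisson rates
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests


class ValidationError(ValueError):
    """Raised when an input table violates the count-table contract."""


@dataclass
class OTUTable:
    """Integer count matrix (samples x OTUs) with totals and optional labels."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: Optional[np.ndarray] = None
    metadata: Optional[pd.DataFrame] = None  # per-sample extras (e.g. pair ids)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flt = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.round(flt)):
                raise ValidationError("counts must be integers")
            self.counts = flt.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        I, J = self.counts.shape
        if I < 2 or J < 1:
            raise ValidationError("need at least 2 samples and 1 OTU")
        if len(self.sample_ids) != I or len(self.otu_ids) != J:
            raise ValidationError("ID lists do not match the count matrix shape")
        if len(set(self.sample_ids)) != I:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.otu_ids)) != J:
            raise ValidationError("duplicate OTU IDs")
        if self.totals is None:
            self.totals = self.counts.sum(axis=1)
        self.totals = np.asarray(self.totals)
        if self.totals.shape != (I,):
            raise ValidationError("totals must have one entry per sample")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (I,):
                raise ValidationError("labels must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, idx) -> "OTUTable":
        idx = np.asarray(idx)
        return OTUTable(
            counts=self.counts[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            otu_ids=list(self.otu_ids),
            totals=self.totals[idx],
            labels=None if self.labels is None else self.labels[idx],
            metadata=None if self.metadata is None else self.metadata.iloc[idx],
        )

    def select_otus(self, idx) -> "OTUTable":
        idx = np.asarray(idx)
        return OTUTable(
            counts=self.counts[:, idx],
            sample_ids=list(self.sample_ids),
            otu_ids=[self.otu_ids[j] for j in idx],
            totals=self.totals,
            labels=self.labels,
            metadata=self.metadata,
        )

    def relative_abundances(self) -> np.ndarray:
        """q_ij = n_ij / N_i."""
        if np.any(self.totals <= 0):
            raise ValidationError("relative abundances need positive totals")
        return self.counts / self.totals[:, None].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class Resolutions:
    """Per-sample resolution t_i = N_i / mean(N); mean(t) == 1."""

    t: np.ndarray
    nbar: float


def read_otu_table(
    path,
    orientation: str = "samples-in-rows",
    label_column: Optional[str] = None,
    totals_column: Optional[str] = "auto",
    metadata_columns: Sequence[str] = (),
    sep: Optional[str] = None,
) -> OTUTable:
    """Read a delimited count table (TSV/CSV, header row of IDs).

    ``orientation`` is ``samples-in-rows`` or ``otus-in-rows``; the first
    column holds row IDs.  ``label_column``/``totals_column`` name optional
    per-sample metadata columns (interpreted after orientation is applied).
    The default ``totals_column='auto'`` uses a ``total_reads`` column when
    present (as written by :func:`write_otu_table`) and row sums otherwise.
    """
    if orientation not in ("samples-in-rows", "otus-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    header = pd.read_csv(path, sep=sep, header=None, nrows=1, engine="python")
    raw_names = [str(v) for v in header.iloc[0, 1:]]
    if len(set(raw_names)) != len(raw_names):
        raise ValidationError("duplicate column IDs in header")
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    if totals_column == "auto":
        totals_column = "total_reads" if "total_reads" in df.columns or (
            orientation == "otus-in-rows" and "total_reads" in df.index
        ) else None
    if orientation == "otus-in-rows":
        meta_rows = [c for c in (label_column, totals_column, *metadata_columns)
                     if c and c in df.index]
        meta = df.loc[meta_rows].T if meta_rows else None
        df = df.drop(index=meta_rows).T
        if meta is not None:
            df = pd.concat([df, meta], axis=1)
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValidationError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    metadata = None
    if metadata_columns:
        missing = [c for c in metadata_columns if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata columns not found: {missing}")
        metadata = df[list(metadata_columns)].copy()
        df = df.drop(columns=list(metadata_columns))
    totals = None
    if totals_column is not None:
        if totals_column not in df.columns:
            raise ValidationError(f"totals column {totals_column!r} not found")
        totals = pd.to_numeric(df[totals_column]).to_numpy()
        df = df.drop(columns=[totals_column])
    values = df.to_numpy()
    numeric = pd.DataFrame(df).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-numeric entry {values[i, j]!r} at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )
    if np.any(numeric != np.round(numeric)):
        i, j = np.argwhere(numeric != np.round(numeric))[0]
        raise ValidationError(
            f"non-integer count {values[i, j]!r} at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )
    if np.any(numeric < 0):
        i, j = np.argwhere(numeric < 0)[0]
        raise ValidationError(
            f"negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )
    return OTUTable(
        counts=numeric.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(o) for o in df.columns],
        totals=totals,
        labels=labels,
        metadata=metadata,
    )


def write_otu_table(table: OTUTable, path, sep: str = "\t") -> None:
    df = table.to_frame()
    df.insert(0, "total_reads", table.totals)
    if table.labels is not None:
        df.insert(0, "label", table.labels)
    df.to_csv(path, sep=sep, index_label="sample_id")


def read_labels(path, sep: Optional[str] = None) -> pd.Series:
    """Read a two-column (sample_id, label) file."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def filter_samples_by_depth(table: OTUTable, min_reads: int) -> OTUTable:
    """Drop samples whose total reads fall below ``min_reads`` (kept if equal)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = np.flatnonzero(table.totals >= min_reads)
    if keep.size == 0:
        raise ValidationError(f"depth filter at {min_reads} removed every sample")
    return table.select_samples(keep)


def filter_otus(
    table: OTUTable,
    min_mean_rel_abundance: float = 0.0,
    max_zero_proportion: float = 1.0,
) -> OTUTable:
    """Keep OTUs with mean relative abundance >= threshold and zero
    proportion strictly below ``max_zero_proportion``."""
    if not (0 <= min_mean_rel_abundance <= 1 and 0 <= max_zero_proportion <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    rel = table.relative_abundances()
    mean_rel = rel.mean(axis=0)
    zero_prop = (table.counts == 0).mean(axis=0)
    keep = np.flatnonzero(
        (mean_rel >= min_mean_rel_abundance)
        & ((zero_prop < max_zero_proportion) | (max_zero_proportion >= 1.0))
    )
    if keep.size == 0:
        raise ValidationError("abundance/zero filters removed every OTU")
    return table.select_otus(keep)


def compute_resolutions(table: OTUTable) -> Resolutions:
    """t_i = N_i / mean(N).  Requires every total positive."""
    totals = np.asarray(table.totals, dtype=float)
    if np.any(totals <= 0):
        i = int(np.argmax(totals <= 0))
        raise ValidationError(f"sample {table.sample_ids[i]!r} has non-positive total reads")
    nbar = float(totals.mean())
    return Resolutions(t=totals / nbar, nbar=nbar)


def screen_otus(
    train: OTUTable,
    alpha_q: float = 0.05,
    exact_below: int = 30,
) -> list[str]:
    """Univariate screen: two-sided Mann-Whitney U on relative abundances
    per OTU, Benjamini-Hochberg q-values, retain q < ``alpha_q``.

    Defined for binary labels only, and intended to run on the training
    split so the screen never sees test labels.
    """
    if train.labels is None:
        raise ValidationError("screening requires labels")
    if not 0 < alpha_q <= 1:
        raise ValueError("alpha_q must be in (0, 1]")
    classes = np.unique(train.labels)
    if classes.size != 2:
        raise ValidationError("screening is defined for exactly two classes")
    rel = train.relative_abundances()
    a = rel[train.labels == classes[0]]
    b = rel[train.labels == classes[1]]
    method = "exact" if min(len(a), len(b)) < exact_below and not _has_ties(rel) else "asymptotic"
    pvals = np.ones(train.n_otus)
    for j in range(train.n_otus):
        if np.all(a[:, j] == a[0, j]) and np.all(b[:, j] == b[0, j]) and a[0, j] == b[0, j]:
            pvals[j] = 1.0  # constant OTU: no evidence
            continue
        try:
            res = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method=method)
        except ValueError:
            res = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method="asymptotic")
        pvals[j] = res.pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    if alpha_q >= 1.0:
        keep = np.arange(train.n_otus)
    else:
        keep = np.flatnonzero(qvals < alpha_q)
    return [train.otu_ids[j] for j in keep]


def screening_report(train: OTUTable, alpha_q: float = 0.05) -> pd.DataFrame:
    """Per-OTU screening table: U statistic, p, BH q, retained flag."""
    if train.labels is None:
        raise ValidationError("screening requires labels")
    classes = np.unique(train.labels)
    if classes.size != 2:
        raise ValidationError("screening is defined for exactly two classes")
    rel = train.relative_abundances()
    a = rel[train.labels == classes[0]]
    b = rel[train.labels == classes[1]]
    U = np.empty(train.n_otus)
    p = np.empty(train.n_otus)
    for j in range(train.n_otus):
        res = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method="asymptotic")
        U[j], p[j] = res.statistic, res.pvalue
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"otu_id": train.otu_ids, "U": U, "p": p, "q": q, "retained": q < alpha_q}
    )


def _has_ties(rel: np.ndarray) -> bool:
    for j in range(rel.shape[1]):
        col = rel[:, j]
        if np.unique(col).size < col.size:
            return True
    return False
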