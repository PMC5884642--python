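"""Ingest, filtering and normalization of kinase quantification tables.

The unit of data is a kinase-by-sample table of label-free MS intensities
(multiplexed-inhibitor-bead capture), with per-entry unique-peptide counts.
Missingness is explicit: a kinase not detected in a sample carries NaN, never
zero.  Downstream modelling operates on log2, per-sample autoscaled values
(within-sample Z-scores), the convention used throughout kinome MIB/MS work.

Filters implemented here follow the field's standard identification rules:
a kinase must reach >= 3 unique peptides somewhere in the dataset, and must be
observed in at least 30% of samples to enter quantitative analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .exceptions import (
    DegenerateDataError,
    FormatError,
    LookupMissingError,
    ParameterError,
)

PEPTIDE_SUFFIX = "|peptides"

#: Canonical subtype vocabulary (extra labels are permitted in metadata).
SUBTYPES = (
    "basal-like",
    "claudin-low",
    "HER2-enriched",
    "luminal",
    "basal-like/HER2amp",
    "tumor-unknown",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class QuantTable:
    """Raw kinase-by-sample intensities plus unique-peptide counts.

    ``intensity``: DataFrame indexed by kinase id, one column per sample;
    NaN marks a non-detected entry.  ``unique_peptides``: same shape, integer
    counts (may be None for intensity-only tables).
    """

    intensity: pd.DataFrame
    unique_peptides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.intensity.index.duplicated().any():
            dup = self.intensity.index[self.intensity.index.duplicated()][0]
            raise FormatError(f"duplicate kinase id {dup!r}")
        if self.intensity.columns.duplicated().any():
            dup = self.intensity.columns[self.intensity.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.unique_peptides is not None:
            if not self.unique_peptides.index.equals(self.intensity.index) or (
                not self.unique_peptides.columns.equals(self.intensity.columns)
            ):
                raise FormatError("unique_peptides shape does not match intensity")

    @property
    def kinases(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean detection mask."""
        return self.intensity.notna()

    def subset_kinases(self, keep: Iterable[str]) -> "QuantTable":
        keep = [k for k in self.kinases if k in set(keep)]  # preserve order
        pep = None if self.unique_peptides is None else self.unique_peptides.loc[keep]
        return QuantTable(self.intensity.loc[keep], pep)

    def subset_samples(self, keep: Iterable[str]) -> "QuantTable":
        keep = [s for s in self.samples if s in set(keep)]
        pep = None if self.unique_peptides is None else self.unique_peptides[keep]
        return QuantTable(self.intensity[keep], pep)


@dataclass
class NormalizedMatrix:
    """Log2, per-sample autoscaled kinase profiles.

    ``values``: DataFrame (kinase x sample); NaN marks a masked (unobserved)
    entry.  For every sample the observed values have mean 0 and unit SD
    (n-1 denominator) whenever >= 2 values are observed.
    """

    values: pd.DataFrame

    @property
    def kinases(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Observed flag per entry."""
        return self.values.notna()


# SampleMeta is a plain DataFrame indexed by sample_id with columns
# cell_line, subtype, treatment, replicate; `read_sample_meta` builds it.
SampleMeta = pd.DataFrame


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated text)
# ---------------------------------------------------------------------------


def read_quant_table(
    path,
    dialect: Literal["wide-intensity", "wide-with-peptides"] = "wide-intensity",
    zeros_as_missing: bool = False,
) -> QuantTable:
    """Read a wide TSV quantification table.

    ``wide-intensity``: first column = kinase id, remaining columns = samples.
    ``wide-with-peptides``: each sample contributes two columns, ``<s>`` for
    intensity and ``<s>|peptides`` for its unique-peptide count.  Empty cells
    are missing entries, never zeros; explicit zeros are kept unless
    ``zeros_as_missing`` is set.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate kinase row id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column header {dup!r}")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    stripped = raw.apply(lambda col: col.astype("string").str.strip())
    bad = numeric.isna() & stripped.notna() & (stripped != "")
    if bad.any().any():
        k = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[k]][0]
        raise FormatError(f"{path}: non-numeric cell at row {k!r}, column {s!r}")

    if dialect == "wide-intensity":
        intensity, peptides = numeric, None
    elif dialect == "wide-with-peptides":
        pep_cols = [c for c in numeric.columns if c.endswith(PEPTIDE_SUFFIX)]
        int_cols = [c for c in numeric.columns if not c.endswith(PEPTIDE_SUFFIX)]
        expected = [s + PEPTIDE_SUFFIX for s in int_cols]
        if sorted(pep_cols) != sorted(expected):
            raise FormatError(
                f"{path}: peptide columns do not pair with sample columns"
            )
        intensity = numeric[int_cols]
        peptides = numeric[expected].fillna(0).astype(int)
        peptides.columns = int_cols
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    if zeros_as_missing:
        intensity = intensity.mask(intensity == 0)
    return QuantTable(intensity, peptides)


def write_quant_table(q: QuantTable, path) -> None:
    """Write a QuantTable in the dialect matching its contents."""
    if q.unique_peptides is None:
        out = q.intensity.copy()
    else:
        out = pd.concat(
            [q.intensity, q.unique_peptides.add_suffix(PEPTIDE_SUFFIX)], axis=1
        )
    out.index.name = "kinase"
    out.to_csv(path, sep="\t")


def read_sample_meta(path) -> SampleMeta:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "subtype", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id in metadata")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def check_meta(q: QuantTable, meta: SampleMeta) -> None:
    """Every quantified sample must carry exactly one metadata row."""
    missing = [s for s in q.samples if s not in meta.index]
    if missing:
        raise LookupMissingError(f"samples without metadata: {missing[:5]}")


def read_normalized_matrix(path) -> NormalizedMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedMatrix(values)


def write_normalized_matrix(n: NormalizedMatrix, path) -> None:
    out = n.values.copy()
    out.index.name = "kinase"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_by_peptides(q: QuantTable, min_unique: int = 3) -> QuantTable:
    """Keep kinases whose maximum unique-peptide count over samples reaches
    ``min_unique`` (inclusive); identification is a per-dataset property.
    """
    if q.unique_peptides is None:
        raise ParameterError("QuantTable carries no unique-peptide counts")
    keep = q.unique_peptides.max(axis=1) >= min_unique
    return q.subset_kinases(q.unique_peptides.index[keep])


def filter_by_presence(q: QuantTable, min_frac: float = 0.30) -> QuantTable:
    """Keep kinases observed in at least ceil(min_frac * n_samples) samples."""
    if not 0.0 <= min_frac <= 1.0:
        raise ParameterError(f"min_frac must be in [0, 1], got {min_frac}")
    if len(q.samples) < 1:
        raise ParameterError("table has no samples")
    need = math.ceil(min_frac * len(q.samples))
    counts = q.observed.sum(axis=1)
    return q.subset_kinases(counts.index[counts >= need])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def log2_autoscale(q: QuantTable, ddof: int = 1) -> NormalizedMatrix:
    """Log2-transform and autoscale each sample over its observed entries.

    Per sample: x -> (log2 x - mean) / SD, mean and SD taken over observed
    entries only (SD with ``ddof`` in the denominator; n-1 by default).
    Missing entries stay masked.  Samples with fewer than two observed values
    or zero variance cannot be autoscaled and raise.
    """
    if (q.intensity <= 0).any().any():
        bad = q.intensity.columns[(q.intensity <= 0).any(axis=0)][0]
        raise ParameterError(f"non-positive intensity in sample {bad!r}")
    logged = np.log2(q.intensity)
    n_obs = logged.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = n_obs.index[n_obs < 2][0]
        raise DegenerateDataError(f"sample {bad!r} has < 2 observed values")
    sd = logged.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise DegenerateDataError(f"sample {bad!r} has zero variance")
    values = (logged - logged.mean(axis=0)) / sd
    return NormalizedMatrix(values)


def average_replicates(n: NormalizedMatrix, meta: SampleMeta) -> NormalizedMatrix:
    """Collapse replicate samples into one column per cell line.

    The averaged entry is the mean over observed replicate values; it is
    missing only when every replicate is missing.  Cell-line column order
    follows first appearance in the sample order.
    """
    missing = [s for s in n.samples if s not in meta.index]
    if missing:
        raise LookupMissingError(f"samples absent from metadata: {missing[:5]}")
    lines: list[str] = []
    cols = {}
    for s in n.samples:
        line = meta.loc[s, "cell_line"]
        if line not in cols:
            lines.append(line)
            cols[line] = []
        cols[line].append(s)
    avg = pd.DataFrame(
        {line: n.values[cols[line]].mean(axis=1) for line in lines},
        index=n.values.index,
    )
    return NormalizedMatrix(avg)


# ---------------------------------------------------------------------------
# Sample similarity
# ---------------------------------------------------------------------------


def sample_similarity(
    n: NormalizedMatrix,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Pairwise sample correlation and a hierarchical-clustering leaf order.

    Pearson correlation is computed per sample pair over the kinases observed
    in both.  Samples are then agglomerated on Euclidean distance between
    profiles (average linkage) and the dendrogram leaf order returned.  Pairs
    sharing fewer than 3 kinases are flagged unreliable (third return value).
    """
    samples = n.samples
    if len(samples) < 2:
        raise ParameterError("need >= 2 samples")
    V = n.values
    corr = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    unreliable = pd.DataFrame(False, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            both = V[a].notna() & V[b].notna()
            if both.sum() < 3:
                unreliable.loc[a, b] = unreliable.loc[b, a] = True
                r = np.nan
            else:
                x, y = V.loc[both, a], V.loc[both, b]
                r = float(np.corrcoef(x, y)[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r

    # Euclidean distance over shared-kinase profiles; missing filled with the
    # per-kinase mean so the linkage is defined on complete vectors.
    filled = V.apply(lambda row: row.fillna(row.mean()), axis=1).fillna(0.0)
    dist = ssd.pdist(filled.T.to_numpy(), metric="euclidean")
    link = sch.linkage(dist, method="average")
    order = [samples[i] for i in sch.leaves_list(link)]
    return corr, order, unreliable


# ---------------------------------------------------------------------------
# Subtype-unique detection
# ---------------------------------------------------------------------------


def subtype_unique_kinases(q: QuantTable, meta: SampleMeta) -> dict[str, set[str]]:
    """Kinases captured in exactly one subtype.

    A kinase belongs to subtype S iff it is observed in at least one sample
    labelled S and in zero samples of every other subtype.
    """
    check_meta(q, meta)
    subtype_of = meta.loc[q.samples, "subtype"]
    det = q.observed
    out: dict[str, set[str]] = {s: set() for s in subtype_of.unique()}
    per_subtype = det.T.groupby(subtype_of).any().T  # kinase x subtype
    n_subtypes_detected = per_subtype.sum(axis=1)
    for subtype in per_subtype.columns:
        only = per_subtype[subtype] & (n_subtypes_detected == 1)
        out[subtype] = set(per_subtype.index[only])
    return out
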