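"""Agreement between MIB-binding and transcript abundance.

Per-kinase Pearson correlation between cell-line-averaged MIB log2 profiles
and RNA abundance (log2(count + 1) of RSEM-style counts) across cell lines,
plus RNA detection calls at the 50-count threshold, MIB/RNA detection-overlap
sets per cell line, and a jointly autoscaled MIB+RNA matrix for data-type
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ParameterError
from .io_filter import NormalizedMatrix

#: RSEM count threshold treated as a positive RNA identification (inclusive).
RNA_DETECTION_THRESHOLD = 50.0

# ExpressionTable: a plain DataFrame, kinase rows x cell-line columns of
# non-negative RSEM-style counts.
ExpressionTable = pd.DataFrame


def read_expression_table(path) -> ExpressionTable:
    e = pd.read_csv(path, sep="\t", index_col=0)
    if (e < 0).any().any():
        raise ParameterError(f"{path}: negative counts")
    return e


def write_expression_table(e: ExpressionTable, path) -> None:
    out = e.copy()
    out.index.name = "kinase"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Detection calls and overlap
# ---------------------------------------------------------------------------


def rna_detection_calls(
    e: ExpressionTable, threshold: float = RNA_DETECTION_THRESHOLD
) -> pd.DataFrame:
    """Boolean kinase-by-line table: detected iff count >= threshold."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    return e >= threshold


def detection_overlap(
    mib_detected: dict[str, set[str]], rna_detected: dict[str, set[str]]
) -> dict[str, dict[str, set[str]]]:
    """Per-line split of detected kinases into MIB-only / RNA-only / both."""
    out = {}
    for line in sorted(set(mib_detected) | set(rna_detected)):
        m = mib_detected.get(line, set())
        r = rna_detected.get(line, set())
        out[line] = {"MIB-only": m - r, "RNA-only": r - m, "both": m & r}
    return out


# ---------------------------------------------------------------------------
# Per-kinase correlation
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Per-kinase MIB/RNA Pearson correlation across cell lines.

    ``table`` columns: r, n_lines, flagged (fewer than 3 shared lines or a
    zero-variance vector — r undefined but the kinase is kept).  ``mean_r``
    averages the defined r values only; ``n_defined`` says over how many.
    """

    table: pd.DataFrame

    @property
    def mean_r(self) -> float:
        return float(self.table["r"].mean())

    @property
    def n_defined(self) -> int:
        return int(self.table["r"].notna().sum())

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        r = self.table["r"].dropna()
        return np.histogram(r, bins=bins, range=(-1.0, 1.0))

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "kinase"
        out.to_csv(path, sep="\t")


def per_kinase_correlation(
    mib_profiles: NormalizedMatrix, e: ExpressionTable
) -> ConcordanceResult:
    """Pearson r per kinase between MIB profiles and log2(count+1) RNA.

    ``mib_profiles`` must already be cell-line averaged (replicates
    collapsed); columns are matched to RNA columns by cell-line id.  Kinases
    with < 3 shared observed lines or a constant vector in either modality
    get r = NaN and a flag rather than being dropped.
    """
    shared_lines = [l for l in mib_profiles.samples if l in e.columns]
    if len(shared_lines) < 3:
        raise ParameterError("need >= 3 shared cell lines between MIB and RNA")
    shared_k = [k for k in mib_profiles.kinases if k in e.index]
    M = mib_profiles.values.loc[shared_k, shared_lines]
    R = np.log2(e.loc[shared_k, shared_lines].astype(float) + 1.0)

    r = pd.Series(np.nan, index=pd.Index(shared_k, name="kinase"))
    n_lines = pd.Series(0, index=r.index)
    for k in shared_k:
        both = M.loc[k].notna() & R.loc[k].notna()
        n = int(both.sum())
        n_lines[k] = n
        if n < 3:
            continue
        x = M.loc[k, both].to_numpy(dtype=float)
        y = R.loc[k, both].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r[k] = float(np.corrcoef(x, y)[0, 1])
    table = pd.DataFrame({"r": r, "n_lines": n_lines, "flagged": r.isna()})
    return ConcordanceResult(table)


# ---------------------------------------------------------------------------
# Joint autoscaled matrix
# ---------------------------------------------------------------------------


def joint_autoscaled_matrix(
    mib: NormalizedMatrix, e: ExpressionTable
) -> tuple[NormalizedMatrix, pd.Series]:
    """Concatenate MIB columns with per-sample autoscaled log2(count+1) RNA.

    Every joint column is a within-sample Z-score over its observed entries,
    so the two data types live on one scale and can be clustered together.
    Returns the joint matrix and a per-column data-type tag ("MIB" / "RNA");
    RNA columns are suffixed ``|RNA`` to keep ids unique.
    """
    shared_k = [k for k in mib.kinases if k in e.index]
    if not shared_k:
        raise ParameterError("no shared kinases between MIB and RNA tables")
    logged = np.log2(e.loc[shared_k].astype(float) + 1.0)
    n_obs = logged.notna().sum(axis=0)
    sd = logged.std(axis=0, ddof=1)
    bad = n_obs.index[(n_obs < 2) | (sd == 0)]
    if len(bad):
        raise DegenerateDataError(f"degenerate RNA column {bad[0]!r}")
    scaled = (logged - logged.mean(axis=0)) / sd
    scaled.columns = [f"{c}|RNA" for c in scaled.columns]
    joint = pd.concat([mib.values.loc[shared_k], scaled], axis=1)
    tags = pd.Series(
        ["MIB"] * len(mib.samples) + ["RNA"] * scaled.shape[1],
        index=joint.columns, name="data_type",
    )
    return NormalizedMatrix(joint), tags
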