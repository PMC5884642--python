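"""Drug-perturbation response: log2 fold changes and subnetwork summaries.

Fold change is computed on raw replicate-averaged intensities (autoscaling
would destroy ratio semantics): FC = log2(treated / untreated) per kinase per
cell line, defined only where both conditions observed the kinase.  Fold
changes are then summarized per subnetwork (community) as mean and SD across
cell lines, and as per-line distributions (median, IQR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_filter import QuantTable, SampleMeta
from .kinome_network import NetworkPartition


@dataclass
class ResponseProfile:
    """Per-kinase log2 fold change for one cell line under one treatment."""

    cell_line: str
    treatment: str
    fc: pd.Series  # NaN where undefined (kinase unobserved in a condition)

    @property
    def observed(self) -> pd.Series:
        return self.fc.notna()


def _condition_means(q: QuantTable, samples: list[str]) -> pd.Series:
    """Replicate-averaged raw intensity (observed values only)."""
    return q.intensity[samples].mean(axis=1)


def log2_fold_change(
    treated: QuantTable,
    untreated: QuantTable,
    meta: SampleMeta | None = None,
    treatment: str = "treated",
) -> list[ResponseProfile]:
    """Log2 fold change of treated over untreated intensities.

    Replicates are averaged per condition first.  With ``meta`` supplied,
    columns are grouped by cell line and one profile per line is returned;
    without it, each table's columns are treated as replicates of a single
    condition and a single profile results.  A kinase observed in only one
    condition gets NaN (flagged undefined), never +/-inf.
    """
    if list(treated.kinases) != list(untreated.kinases):
        raise ParameterError("treated and untreated tables must share kinases")
    if (treated.intensity <= 0).any().any() or (untreated.intensity <= 0).any().any():
        raise ParameterError("intensities must be positive where observed")

    def line_groups(q: QuantTable) -> dict[str, list[str]]:
        if meta is None:
            return {"all": q.samples}
        out: dict[str, list[str]] = {}
        for s in q.samples:
            out.setdefault(meta.loc[s, "cell_line"], []).append(s)
        return out

    t_groups, u_groups = line_groups(treated), line_groups(untreated)
    shared = [l for l in t_groups if l in u_groups]
    if not shared:
        raise ParameterError("no cell line present in both conditions")
    profiles = []
    for line in shared:
        t_mean = _condition_means(treated, t_groups[line])
        u_mean = _condition_means(untreated, u_groups[line])
        fc = np.log2(t_mean / u_mean)
        profiles.append(ResponseProfile(line, treatment, fc))
    return profiles


@dataclass
class SubnetworkResponse:
    """Mean/SD of per-kinase fold change across cell lines, by subnetwork.

    ``table``: per kinase — community, mean_fc, sd_fc (n-1; 0 and flagged
    when a single line contributes), n_lines; kinases absent from the
    partition carry community -1 (unassigned).
    """

    table: pd.DataFrame

    def community_summary(self) -> pd.DataFrame:
        grp = self.table[self.table["community"] >= 0].groupby("community")
        return pd.DataFrame(
            {
                "n_kinases": grp.size(),
                "mean_fc": grp["mean_fc"].mean(),
                "mean_abs_fc": grp["mean_fc"].apply(lambda s: s.abs().mean()),
            }
        )

    def top_subnetworks(self, m: int) -> list[int]:
        """Subnetwork ids ranked by member count (descending)."""
        sizes = (
            self.table[self.table["community"] >= 0]
            .groupby("community").size().sort_values(ascending=False, kind="mergesort")
        )
        return list(sizes.index[:m])


def subnetwork_response(
    profiles: list[ResponseProfile], partition: NetworkPartition
) -> SubnetworkResponse:
    """Per-kinase fold-change mean and SD across cell lines, grouped by
    subnetwork.  SD uses the n-1 denominator; a kinase contributing from a
    single line gets SD 0 with ``single_line`` flagged."""
    if not profiles:
        raise ParameterError("need >= 1 response profile")
    fc = pd.DataFrame({p.cell_line: p.fc for p in profiles})
    n_lines = fc.notna().sum(axis=1)
    mean_fc = fc.mean(axis=1)
    sd_fc = fc.std(axis=1, ddof=1).where(n_lines > 1, 0.0)
    community = pd.Series(
        [partition.community_of.get(k, -1) for k in fc.index], index=fc.index
    )
    table = pd.DataFrame(
        {
            "community": community,
            "mean_fc": mean_fc,
            "sd_fc": sd_fc,
            "n_lines": n_lines,
            "single_line": n_lines == 1,
        }
    )
    return SubnetworkResponse(table[n_lines > 0])


def response_distribution(
    profile: ResponseProfile,
    partition: NetworkPartition,
    subnetworks: set[int],
) -> pd.DataFrame:
    """Fold-change distribution per requested subnetwork for one cell line.

    Returns per subnetwork: n, median, q1, q3, IQR.  Empty subnetworks yield
    an all-NaN row (warned via n = 0) rather than being dropped.
    """
    known = set(partition.community_of.values())
    bad = set(subnetworks) - known
    if bad:
        raise ParameterError(f"unknown subnetwork ids: {sorted(bad)}")
    rows = []
    for c in sorted(subnetworks):
        members = partition.members(c)
        vals = profile.fc.reindex(sorted(members)).dropna()
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((c, len(vals), med, q1, q3, q3 - q1))
        else:
            rows.append((c, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["subnetwork", "n", "median", "q1", "q3", "iqr"]
    ).set_index("subnetwork")
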