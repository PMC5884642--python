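"""Subtype-distinguishing kinase selection.

Two complementary feature-selection routes over the autoscaled MIB-binding
matrix:

* *pan-subtype* kinases — those driving overall variance, taken as the top
  10% of absolute PCA loadings on each of the first three principal
  components;
* *subtype-specific* kinases — those separating one subtype from all others,
  ranked per subtype by the Gaussian Bhattacharyya distance between the
  one-vs-rest group distributions.

The two lists are composed into a single distinguishing set capped at 50
kinases: the top 5% of each subtype's ranking first, then pan-subtype
kinases in PC order until the cap.  A Welch t-test utility provides the
two-group volcano statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, ParameterError
from .io_filter import NormalizedMatrix, SampleMeta

#: Composition order for the canonical breast-cancer subtypes; rankings for
#: labels outside this list are appended in sorted order.
CANONICAL_SUBTYPE_ORDER = ("basal-like", "claudin-low", "HER2-enriched", "luminal")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # kinase x component weights
    scores: pd.DataFrame  # sample x component
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def impute_kinase_mean(n: NormalizedMatrix) -> NormalizedMatrix:
    """Fill each kinase's missing entries with its observed mean.

    In autoscaled space this is the kinase's mean deviation; kinases with no
    observed value at all are filled with 0.  Used to complete the matrix
    ahead of PCA only — ranking operations work on observed values.
    """
    filled = n.values.apply(lambda row: row.fillna(row.mean()), axis=1).fillna(0.0)
    return NormalizedMatrix(filled)


def run_pca(n: NormalizedMatrix) -> PCAResult:
    """Principal components of the kinase-feature covariance.

    The sample-by-kinase matrix is column-centred and decomposed by SVD;
    loadings are the right singular vectors (one weight per kinase per
    component), scores the projections of the samples, and
    ``variance_fraction[c] = lambda_c / sum(lambda)``.
    """
    if n.values.isna().any().any():
        raise ParameterError("matrix contains missing values; impute or drop first")
    X = n.values.T.to_numpy(dtype=float)  # samples x kinases
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    total = lam.sum()
    var_frac = lam / total if total > 0 else np.zeros_like(lam)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=n.values.index, columns=comps)
    scores = pd.DataFrame(U * s, index=n.values.columns, columns=comps)
    return PCAResult(loadings, scores, var_frac)


def pan_subtype_features(
    p: PCAResult, n_pcs: int = 3, percentile: float = 90.0
) -> pd.DataFrame:
    """Kinases with top-decile absolute loadings on the first ``n_pcs`` PCs.

    Per component, the ceil((1 - percentile/100) * K) kinases of largest
    |weight| are taken, ordered by descending |weight|; the PC1 block comes
    first, then PC2, then PC3, with duplicates removed keeping the first
    occurrence.  Returns a DataFrame (kinase, component, weight) in that
    order.
    """
    if not 0 <= percentile < 100:
        raise ParameterError(f"percentile must be in [0, 100), got {percentile}")
    if n_pcs > p.n_components:
        raise ParameterError(
            f"n_pcs={n_pcs} exceeds available components ({p.n_components})"
        )
    K = p.loadings.shape[0]
    take = math.ceil((1.0 - percentile / 100.0) * K)
    rows, seen = [], set()
    for c in p.loadings.columns[:n_pcs]:
        w = p.loadings[c].abs().sort_values(ascending=False, kind="mergesort")
        for k in w.index[:take]:
            if k not in seen:
                seen.add(k)
                rows.append((k, c, float(p.loadings.loc[k, c])))
    return pd.DataFrame(rows, columns=["kinase", "component", "weight"])


# ---------------------------------------------------------------------------
# Bhattacharyya ranking
# ---------------------------------------------------------------------------


def bhattacharyya_distance(
    mu1: float, var1: float, mu2: float, var2: float
) -> float:
    """Bhattacharyya distance between two univariate Gaussians.

    D_B = 1/4 ln(1/4 (s1/s2 + s2/s1 + 2)) + 1/4 (m1 - m2)^2 / (s1 + s2),
    with s = variance.  Zero iff the distributions coincide.
    """
    if var1 <= 0 or var2 <= 0:
        raise ParameterError("variances must be positive")
    ratio = 0.25 * (var1 / var2 + var2 / var1 + 2.0)
    return 0.25 * math.log(ratio) + 0.25 * (mu1 - mu2) ** 2 / (var1 + var2)


@dataclass
class FeatureRanking:
    """Per-kinase one-vs-rest separability for one subtype.

    ``table`` columns: mu_in, mu_out, var_in, var_out, score (Bhattacharyya
    distance; NaN when a group has < 2 observed values or zero variance),
    rank (1 = most separating; NaN-scored kinases rank last, ties broken
    lexicographically by kinase id).
    """

    subtype: str
    table: pd.DataFrame

    def top(self, m: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:m])


def rank_subtype_features(
    n: NormalizedMatrix, meta: SampleMeta, subtype: str
) -> FeatureRanking:
    """Rank kinases by one-vs-rest Bhattacharyya distance for ``subtype``."""
    labels = meta.loc[n.samples, "subtype"]
    in_samples = list(labels.index[labels == subtype])
    out_samples = list(labels.index[labels != subtype])
    if len(in_samples) < 2 or len(out_samples) < 2:
        raise ParameterError(
            f"subtype {subtype!r} needs >= 2 samples on both sides of the split"
        )
    V_in, V_out = n.values[in_samples], n.values[out_samples]
    mu_in, mu_out = V_in.mean(axis=1), V_out.mean(axis=1)
    var_in = V_in.var(axis=1, ddof=1)
    var_out = V_out.var(axis=1, ddof=1)
    n_in, n_out = V_in.notna().sum(axis=1), V_out.notna().sum(axis=1)

    ok = (n_in >= 2) & (n_out >= 2) & (var_in > 0) & (var_out > 0)
    score = pd.Series(np.nan, index=n.values.index)
    score[ok] = [
        bhattacharyya_distance(mu_in[k], var_in[k], mu_out[k], var_out[k])
        for k in score.index[ok]
    ]
    order = sorted(
        score.index, key=lambda k: (-(score[k]) if ok[k] else math.inf, k)
    )
    rank = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="kinase")
    ).reindex(score.index)
    table = pd.DataFrame(
        {
            "mu_in": mu_in,
            "mu_out": mu_out,
            "var_in": var_in,
            "var_out": var_out,
            "score": score,
            "rank": rank,
        }
    )
    return FeatureRanking(subtype, table)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


@dataclass
class DistinguishingSet:
    """Ordered <= ``cap`` kinase feature list with per-kinase provenance.

    ``table`` columns: provenance (``subtype-specific:<name>`` or
    ``pan-subtype:PC<i>``), order (position in the composed list), score.
    Subtype-specific entries always precede pan-subtype entries.
    """

    table: pd.DataFrame
    cap: int = 50

    @property
    def kinases(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "kinase"
        out.to_csv(path, sep="\t")


def _subtype_order(rankings: dict[str, FeatureRanking]) -> list[str]:
    known = [s for s in CANONICAL_SUBTYPE_ORDER if s in rankings]
    extra = sorted(s for s in rankings if s not in CANONICAL_SUBTYPE_ORDER)
    return known + extra


def compose_distinguishing_set(
    rankings: dict[str, FeatureRanking],
    pan: pd.DataFrame,
    cap: int = 50,
    top_frac: float = 0.05,
) -> DistinguishingSet:
    """Compose the distinguishing kinase list.

    Takes the top ceil(top_frac * K) of each subtype ranking (canonical
    subtype order), deduplicates keeping the first occurrence, then appends
    pan-subtype kinases in their PC order, skipping duplicates, until ``cap``
    entries.  If the subtype-specific entries alone already exceed the cap
    they are truncated by round-robin interleaving over subtypes by rank.
    """
    if not rankings:
        raise ParameterError("no subtype rankings supplied")
    if cap < 0:
        raise ParameterError("cap must be >= 0")
    order = _subtype_order(rankings)
    K = len(next(iter(rankings.values())).table)
    m = math.ceil(top_frac * K)

    per_subtype = {s: rankings[s].top(m) for s in order}

    chosen: list[tuple[str, str, float]] = []  # (kinase, provenance, score)
    seen: set[str] = set()

    def add(kinase: str, provenance: str, score: float) -> None:
        if kinase not in seen:
            seen.add(kinase)
            chosen.append((kinase, provenance, score))

    n_unique_specific = len({k for s in order for k in per_subtype[s]})
    if n_unique_specific > cap:
        # interleave by rank across subtypes so every subtype keeps its best
        for i in range(m):
            for s in order:
                if len(chosen) >= cap:
                    break
                if i < len(per_subtype[s]):
                    k = per_subtype[s][i]
                    add(k, f"subtype-specific:{s}",
                        float(rankings[s].table.loc[k, "score"]))
            if len(chosen) >= cap:
                break
    else:
        for s in order:
            for k in per_subtype[s]:
                add(k, f"subtype-specific:{s}",
                    float(rankings[s].table.loc[k, "score"]))

    for _, row in pan.iterrows():
        if len(chosen) >= cap:
            break
        add(row["kinase"], f"pan-subtype:{row['component']}", float(row["weight"]))

    chosen = chosen[:cap]
    table = pd.DataFrame(
        {
            "provenance": [p for _, p, _ in chosen],
            "order": np.arange(1, len(chosen) + 1),
            "score": [sc for _, _, sc in chosen],
        },
        index=pd.Index([k for k, _, _ in chosen], name="kinase"),
    )
    return DistinguishingSet(table, cap=cap)


# ---------------------------------------------------------------------------
# Two-group differential statistics
# ---------------------------------------------------------------------------


def differential_groups(
    n: NormalizedMatrix,
    group_a: list[str],
    group_b: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch two-sample t-test per kinase between two sample groups.

    Returns a DataFrame (effect = mean_a - mean_b, p, testable flag; and
    p_adj when ``adjust``).  Raw p-values are the default readout; Benjamini-
    Hochberg adjustment is a switch.  Kinases with fewer than two observed
    values in either group are flagged untestable (NaN statistics).
    """
    if set(group_a) & set(group_b):
        raise ParameterError("groups must be disjoint")
    A, B = n.values[list(group_a)], n.values[list(group_b)]
    n_a, n_b = A.notna().sum(axis=1), B.notna().sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    effect = A.mean(axis=1) - B.mean(axis=1)
    pvals = pd.Series(np.nan, index=n.values.index)
    for k in n.values.index[testable]:
        a = A.loc[k].dropna().to_numpy()
        b = B.loc[k].dropna().to_numpy()
        pvals[k] = stats.ttest_ind(a, b, equal_var=False).pvalue
    out = pd.DataFrame(
        {"effect": effect.where(testable), "p": pvals, "testable": testable}
    )
    if adjust:
        adj = pd.Series(np.nan, index=out.index)
        mask = out["p"].notna()
        if mask.any():
            adj[mask] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out
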