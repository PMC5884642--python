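"""Synthetic MIB/MS cohorts with planted, recoverable structure.

Generates kinase-by-sample intensity tables that mimic the statistical shape
of multiplexed-inhibitor-bead mass-spectrometry data: log-normal intensities,
four breast-cancer subtype groups over replicated cell lines, a handful of
kinases with planted pan-subtype variance or one-vs-rest subtype shifts,
detection dropout, unique-peptide counts, an RNA table with tunable per-kinase
coupling to MIB binding, a planted-partition interaction network with
community-aligned annotation terms, and treated/untreated pairs with planted
subnetwork fold changes.  Every generator is deterministic under a fixed seed
and returns the planted ground truth for recovery testing.

Intensities are drawn as Gaussians in log2 space and exponentiated, so planted
effects are exact in the space the analysis works in.  The default cohort is
4 subtypes x 4 cell lines x 2 replicates = 32 samples over 254 kinases,
matching the scale of the cell-line panel this pipeline targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_filter import QuantTable, SampleMeta

DEFAULT_SUBTYPES: tuple[tuple[str, int, int], ...] = (
    ("basal-like", 4, 2),
    ("claudin-low", 4, 2),
    ("HER2-enriched", 4, 2),
    ("luminal", 4, 2),
)

# rng stream ids, one per generator, so the stages draw independent streams
# from the same user-facing seed
_STREAM_MIB = 1
_STREAM_RNA = 2
_STREAM_NET = 3
_STREAM_PERT = 4
_STREAM_QUERY = 5


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the planted one-vs-rest group-mean shift in units of
    the within-subtype SD (sqrt(line_sd^2 + noise_sd^2), log2 scale).
    ``rna_coupling`` is either a single target Pearson correlation applied to
    every kinase or a (mean, sd) pair sampled per kinase (clipped to
    [-0.99, 0.99]).
    """

    n_kinases: int = 254
    subtypes: tuple[tuple[str, int, int], ...] = DEFAULT_SUBTYPES
    n_pan_kinases: int = 10
    n_specific_per_subtype: int = 5
    effect_size: float = 3.0
    baseline_log2_mean: float = 20.0
    kinase_spread_sd: float = 2.0  # between-kinase baseline spread, log2
    line_sd: float = 0.5  # between-cell-line biological variation, log2
    noise_sd: float = 0.3  # replicate noise, log2
    dropout_rate: float = 0.10
    dropout_mode: Literal["mcar", "intensity"] = "mcar"
    frac_low_peptides: float = 0.05  # kinases kept below the 3-peptide rule
    frac_understudied: float = 0.35
    rna_coupling: float | tuple[float, float] = (0.2, 0.15)
    rna_base_log2: float = 9.0  # median RNA abundance ~ 2^9 counts
    rna_spread: float = 1.5
    frac_rna_undetected: float = 0.05  # kinases under 50 counts in all lines
    network_k: int = 16
    p_within: float = 0.5
    p_between: float = 0.02
    n_terms: int = 40
    term_size: int = 15
    fc_communities: int = 2  # communities given a planted drug response
    fc_magnitude: float = 1.0  # |log2 fold change| of the planted response
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_kinases, self.n_pan_kinases, self.n_specific_per_subtype,
                  self.network_k, self.n_terms, self.term_size]
        if any(c < 0 for c in counts) or self.n_kinases <= 0:
            raise ParameterError("counts must be positive")
        if not self.subtypes:
            raise ParameterError("at least one subtype required")
        for name, n_lines, n_reps in self.subtypes:
            if n_lines < 1 or n_reps < 1:
                raise ParameterError(f"subtype {name!r} needs >=1 line and replicate")
        n_planted = self.n_pan_kinases + len(self.subtypes) * self.n_specific_per_subtype
        if n_planted > self.n_kinases:
            raise ParameterError("planted kinases exceed n_kinases")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.p_within <= self.p_between:
            raise ParameterError("p_within must exceed p_between")
        for frac in (self.frac_low_peptides, self.frac_understudied,
                     self.frac_rna_undetected):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("fractions must be in [0, 1]")
        if self.effect_size < 0 or self.noise_sd < 0 or self.line_sd < 0:
            raise ParameterError("effect_size and SDs must be non-negative")

    @property
    def within_sd(self) -> float:
        """Marginal within-subtype SD across samples (log2 units)."""
        return float(np.sqrt(self.line_sd**2 + self.noise_sd**2))

    @property
    def n_samples(self) -> int:
        return sum(nl * nr for _, nl, nr in self.subtypes)


@dataclass
class CohortTruth:
    """Planted ground truth of one synthetic cohort."""

    kinases: list[str]
    labels: dict[str, str]  # sample -> subtype
    cell_line_of: dict[str, str]  # sample -> cell line
    planted_pan: set[str]
    planted_specific: dict[str, set[str]]  # subtype -> kinases
    understudied: set[str]
    subtype_shift: pd.DataFrame  # kinase x subtype planted mean shift (log2)
    baseline_log2: pd.Series | None = None  # per-kinase characteristic abundance
    community_of: dict[str, int] = field(default_factory=dict)
    enriched_terms: dict[int, str] = field(default_factory=dict)
    planted_fc: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def line_subtype(self) -> dict[str, str]:
        """Cell line -> subtype map derived from the sample labels."""
        return {self.cell_line_of[s]: self.labels[s] for s in self.labels}

    def to_json(self, path) -> None:
        blob = {
            "kinases": self.kinases,
            "labels": self.labels,
            "cell_line_of": self.cell_line_of,
            "planted_pan": sorted(self.planted_pan),
            "planted_specific": {k: sorted(v) for k, v in self.planted_specific.items()},
            "understudied": sorted(self.understudied),
            "subtype_shift": self.subtype_shift.to_dict(),
            "baseline_log2": (
                None if self.baseline_log2 is None else self.baseline_log2.to_dict()
            ),
            "community_of": self.community_of,
            "enriched_terms": {str(k): v for k, v in self.enriched_terms.items()},
            "planted_fc": {f"{l}\t{k}": v for (l, k), v in self.planted_fc.items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            kinases=blob["kinases"],
            labels=blob["labels"],
            cell_line_of=blob["cell_line_of"],
            planted_pan=set(blob["planted_pan"]),
            planted_specific={k: set(v) for k, v in blob["planted_specific"].items()},
            understudied=set(blob["understudied"]),
            subtype_shift=pd.DataFrame(blob["subtype_shift"]),
            baseline_log2=(
                None if blob.get("baseline_log2") is None
                else pd.Series(blob["baseline_log2"])
            ),
            community_of=blob["community_of"],
            enriched_terms={int(k): v for k, v in blob["enriched_terms"].items()},
            planted_fc={
                tuple(k.split("\t")): v for k, v in blob["planted_fc"].items()
            },
        )


# ---------------------------------------------------------------------------
# MIB/MS cohort
# ---------------------------------------------------------------------------


def _sample_layout(spec: CohortSpec) -> tuple[list[str], list[str], dict, dict]:
    """Sample/cell-line naming: one block per subtype."""
    samples, lines = [], []
    labels, line_of = {}, {}
    for name, n_lines, n_reps in spec.subtypes:
        for i in range(1, n_lines + 1):
            line = f"{name}_c{i}"
            lines.append(line)
            for r in range(1, n_reps + 1):
                s = f"{line}_r{r}"
                samples.append(s)
                labels[s] = name
                line_of[s] = line
    return samples, lines, labels, line_of


def _draw_log2_matrix(
    spec: CohortSpec,
    truth_base: np.ndarray,
    shift: pd.DataFrame,
    samples: list[str],
    labels: dict[str, str],
    line_of: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Log2 intensities = kinase baseline + subtype shift + line effect + noise."""
    kinases = list(shift.index)
    lines = sorted({line_of[s] for s in samples})
    line_eff = pd.DataFrame(
        rng.normal(0.0, spec.line_sd, size=(len(kinases), len(lines))),
        index=kinases, columns=lines,
    )
    X = np.empty((len(kinases), len(samples)))
    for j, s in enumerate(samples):
        X[:, j] = (
            truth_base
            + shift[labels[s]].to_numpy()
            + line_eff[line_of[s]].to_numpy()
            + rng.normal(0.0, spec.noise_sd, size=len(kinases))
        )
    return pd.DataFrame(X, index=kinases, columns=samples)


def _apply_dropout(
    log2: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Return an intensity matrix (2^log2) with missing entries as NaN."""
    if spec.dropout_rate == 0:
        mask = np.zeros(log2.shape, dtype=bool)
    elif spec.dropout_mode == "mcar":
        mask = rng.random(log2.shape) < spec.dropout_rate
    else:  # intensity-dependent: logistic in log2 intensity, centred so the
        # overall rate is approximately dropout_rate
        x = log2.to_numpy()
        x0 = np.quantile(x, spec.dropout_rate)
        p = 1.0 / (1.0 + np.exp((x - x0) / 1.0))
        # rescale so the mean probability matches the requested rate
        p *= spec.dropout_rate / max(p.mean(), 1e-12)
        mask = rng.random(log2.shape) < np.clip(p, 0, 1)
    intensity = np.power(2.0, log2.to_numpy())
    intensity[mask] = np.nan
    return pd.DataFrame(intensity, index=log2.index, columns=log2.columns)


def generate_mib_cohort(spec: CohortSpec) -> tuple[QuantTable, SampleMeta, CohortTruth]:
    """Generate one MIB/MS cohort with planted pan- and subtype-specific kinases.

    Planted subtype-specific kinases carry a one-vs-rest mean shift of
    ``effect_size * within_sd`` (random sign) in log2 space; planted
    pan-subtype kinases carry independent per-subtype shifts of the same
    scale, inflating their cross-subtype variance.  Dropout and shifted-
    Poisson unique-peptide counts are applied afterwards.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_MIB])
    kinases = [f"KIN{i:04d}" for i in range(1, spec.n_kinases + 1)]
    samples, lines, labels, line_of = _sample_layout(spec)
    subtype_names = [s[0] for s in spec.subtypes]

    # planted sets: disjoint draws from the kinase universe
    n_spec_total = spec.n_specific_per_subtype * len(subtype_names)
    picked = rng.choice(kinases, size=spec.n_pan_kinases + n_spec_total, replace=False)
    planted_pan = set(picked[: spec.n_pan_kinases])
    planted_specific: dict[str, set[str]] = {}
    off = spec.n_pan_kinases
    for name in subtype_names:
        planted_specific[name] = set(picked[off : off + spec.n_specific_per_subtype])
        off += spec.n_specific_per_subtype

    delta = spec.effect_size * spec.within_sd
    shift = pd.DataFrame(0.0, index=kinases, columns=subtype_names)
    for k in sorted(planted_pan):
        shift.loc[k, :] = rng.normal(0.0, delta, size=len(subtype_names))
    for name in subtype_names:
        for k in sorted(planted_specific[name]):
            shift.loc[k, name] = delta * rng.choice([-1.0, 1.0])

    base = rng.normal(spec.baseline_log2_mean, spec.kinase_spread_sd, len(kinases))
    log2 = _draw_log2_matrix(spec, base, shift, samples, labels, line_of, rng)
    intensity = _apply_dropout(log2, spec, rng)

    # unique-peptide counts: shifted Poisson, with a spec-controlled fraction
    # of kinases held under the 3-peptide identification rule
    n_low = int(round(spec.frac_low_peptides * spec.n_kinases))
    low = set(rng.choice(kinases, size=n_low, replace=False)) if n_low else set()
    pep = 3 + rng.poisson(4.0, size=intensity.shape)
    pep_df = pd.DataFrame(pep, index=kinases, columns=samples)
    for k in sorted(low):
        pep_df.loc[k] = rng.integers(1, 3, size=len(samples))

    n_under = int(round(spec.frac_understudied * spec.n_kinases))
    understudied = set(rng.choice(kinases, size=n_under, replace=False)) if n_under else set()

    meta = pd.DataFrame(
        {
            "cell_line": [line_of[s] for s in samples],
            "subtype": [labels[s] for s in samples],
            "treatment": "untreated",
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = CohortTruth(
        kinases=kinases,
        labels=labels,
        cell_line_of=line_of,
        planted_pan=planted_pan,
        planted_specific=planted_specific,
        understudied=understudied,
        subtype_shift=shift,
        baseline_log2=pd.Series(base, index=kinases),
    )
    return QuantTable(intensity, pep_df), meta, truth


def generate_tumor_queries(
    spec: CohortSpec,
    truth: CohortTruth,
    n_per_subtype: int = 2,
    seed: int | None = None,
) -> tuple[QuantTable, SampleMeta]:
    """Draw fresh samples from the same planted model, as unseen "tumors".

    One new cell line per query; no dropout is applied here (feature deletion
    is the caller's concern when emulating sparse biopsies).
    """
    rng = np.random.default_rng(
        [spec.seed if seed is None else seed, _STREAM_QUERY]
    )
    subtype_names = [s[0] for s in spec.subtypes]
    samples, labels, line_of = [], {}, {}
    for name in subtype_names:
        for i in range(1, n_per_subtype + 1):
            s = f"query_{name}_t{i}_r1"
            samples.append(s)
            labels[s] = name
            line_of[s] = f"query_{name}_t{i}"
    # a kinase's characteristic abundance is a property of the kinase, not of
    # the cohort: queries share the training baselines
    if truth.baseline_log2 is not None:
        base = truth.baseline_log2.reindex(truth.kinases).to_numpy()
    else:
        base = rng.normal(
            spec.baseline_log2_mean, spec.kinase_spread_sd, len(truth.kinases)
        )
    log2 = _draw_log2_matrix(
        spec, base, truth.subtype_shift, samples, labels, line_of, rng
    )
    intensity = pd.DataFrame(
        np.power(2.0, log2.to_numpy()), index=log2.index, columns=log2.columns
    )
    meta = pd.DataFrame(
        {
            "cell_line": [line_of[s] for s in samples],
            "subtype": [labels[s] for s in samples],
            "treatment": "untreated",
            "replicate": 1,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return QuantTable(intensity), meta


# ---------------------------------------------------------------------------
# RNA table
# ---------------------------------------------------------------------------


def generate_rna_table(
    spec: CohortSpec, truth: CohortTruth, mib: QuantTable
) -> pd.DataFrame:
    """RNA abundance (RSEM-style, real-valued counts) per kinase per cell line.

    For each kinase the log2 RNA profile across cell lines is a mixture
    ``rho * z_mib + sqrt(1 - rho^2) * eps`` of the standardized cell-line-
    averaged MIB log2 profile and independent noise, so the per-kinase Pearson
    correlation between log2(count + 1) and MIB binding targets ``rho``.
    Counts are 2^(base + spread * y) - 1, making the coupling exact on the
    log2(count + 1) scale.  A spec-controlled fraction of kinases is forced
    below 50 counts in every line (undetected by the RNA threshold rule).
    """
    spec.validate()
    if list(mib.kinases) != list(truth.kinases):
        raise ParameterError("MIB table kinases do not match cohort truth")
    unknown = [s for s in mib.samples if s not in truth.cell_line_of]
    if unknown:
        raise ParameterError(f"MIB samples unknown to cohort truth: {unknown[:5]}")
    rng = np.random.default_rng([spec.seed, _STREAM_RNA])

    log2_mib = np.log2(mib.intensity)
    line_of = pd.Series({s: truth.cell_line_of[s] for s in mib.samples})
    avg = log2_mib.T.groupby(line_of).mean().T  # kinase x cell line
    lines = list(avg.columns)

    if isinstance(spec.rna_coupling, tuple):
        mu, sd = spec.rna_coupling
        rho = np.clip(rng.normal(mu, sd, size=len(truth.kinases)), -0.99, 0.99)
    else:
        rho = np.full(len(truth.kinases), float(spec.rna_coupling))

    A = avg.to_numpy()
    # standardize each kinase's MIB profile across lines; constant or
    # all-missing rows get a zero profile (coupling undefined there)
    A = np.where(np.isnan(A), np.nanmean(A, axis=1, keepdims=True), A)
    A = np.where(np.isnan(A), 0.0, A)
    mean = A.mean(axis=1, keepdims=True)
    sdv = A.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(A - mean, sdv, out=np.zeros_like(A), where=sdv > 0)

    eps = rng.standard_normal(size=z.shape)
    y = rho[:, None] * z + np.sqrt(1.0 - rho[:, None] ** 2) * eps
    counts = np.maximum(
        np.power(2.0, spec.rna_base_log2 + spec.rna_spread * y) - 1.0, 0.0
    )
    rna = pd.DataFrame(counts, index=truth.kinases, columns=lines)

    n_under = int(round(spec.frac_rna_undetected * spec.n_kinases))
    if n_under:
        under = rng.choice(truth.kinases, size=n_under, replace=False)
        rna.loc[sorted(under)] = rng.uniform(0.0, 49.0, size=(n_under, len(lines)))
    return rna


# ---------------------------------------------------------------------------
# Network + annotations
# ---------------------------------------------------------------------------


def generate_network_and_annotations(
    spec: CohortSpec, truth: CohortTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted-partition interaction graph and community-aligned annotations.

    Kinases are split into ``network_k`` near-equal communities; edges appear
    with probability ``p_within`` inside and ``p_between`` across communities.
    One annotation term per community covers exactly that community (the
    planted enrichment signal); ``n_terms`` additional random terms of
    ``term_size`` members provide the null background.  Updates
    ``truth.community_of`` and ``truth.enriched_terms`` in place.

    Returns (edge list DataFrame [kinase_a, kinase_b, sources], annotation
    DataFrame [kinase, term] in long format).
    """
    spec.validate()
    if spec.network_k < 2:
        raise ParameterError("network_k must be >= 2")
    rng = np.random.default_rng([spec.seed, _STREAM_NET])
    kinases = np.array(truth.kinases)
    perm = rng.permutation(len(kinases))
    community_of = {
        str(kinases[idx]): int(i % spec.network_k) for i, idx in enumerate(perm)
    }

    comm = np.array([community_of[k] for k in kinases])
    edges_a, edges_b = [], []
    n = len(kinases)
    u = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_within if comm[i] == comm[j] else spec.p_between
            if u[i, j] < p:
                edges_a.append(kinases[i])
                edges_b.append(kinases[j])
    edges = pd.DataFrame(
        {"kinase_a": edges_a, "kinase_b": edges_b, "sources": "synthetic"}
    )

    rows = []
    enriched_terms: dict[int, str] = {}
    for c in range(spec.network_k):
        term = f"TERM_COMM{c:02d}"
        enriched_terms[c] = term
        for k in kinases[comm == c]:
            rows.append((k, term))
    for t in range(spec.n_terms):
        members = rng.choice(kinases, size=min(spec.term_size, n), replace=False)
        for k in members:
            rows.append((k, f"TERM_RAND{t:02d}"))
    annotations = pd.DataFrame(rows, columns=["kinase", "term"])

    truth.community_of = community_of
    truth.enriched_terms = enriched_terms
    return edges, annotations


# ---------------------------------------------------------------------------
# Perturbation pair
# ---------------------------------------------------------------------------


def generate_perturbation_pair(
    spec: CohortSpec, truth: CohortTruth
) -> tuple[QuantTable, QuantTable, SampleMeta]:
    """Treated/untreated tables for one representative cell line per subtype.

    ``fc_communities`` communities receive a planted log2 fold change of
    alternating sign and magnitude ``fc_magnitude`` (recorded per (line,
    kinase) in ``truth.planted_fc``); treated intensities are untreated times
    2^(planted_fc + replicate noise).  Requires the network stage to have
    assigned communities first.
    """
    spec.validate()
    if not truth.community_of:
        raise ParameterError(
            "community assignments missing: run generate_network_and_annotations first"
        )
    rng = np.random.default_rng([spec.seed, _STREAM_PERT])
    subtype_names = [s[0] for s in spec.subtypes]
    reps = max(nr for _, _, nr in spec.subtypes)

    samples, labels, line_of = [], {}, {}
    rep_lines = []
    for name in subtype_names:
        line = f"{name}_c1"
        rep_lines.append(line)
        for r in range(1, reps + 1):
            s = f"{line}_r{r}"
            samples.append(s)
            labels[s] = name
            line_of[s] = line

    if truth.baseline_log2 is not None:
        base = truth.baseline_log2.reindex(truth.kinases).to_numpy()
    else:
        base = rng.normal(
            spec.baseline_log2_mean, spec.kinase_spread_sd, len(truth.kinases)
        )
    log2_u = _draw_log2_matrix(
        spec, base, truth.subtype_shift, samples, labels, line_of, rng
    )

    hit = sorted(set(truth.community_of.values()))[: spec.fc_communities]
    fc_of_comm = {
        c: spec.fc_magnitude * (1.0 if i % 2 == 0 else -1.0)
        for i, c in enumerate(hit)
    }
    fc_kinase = np.array(
        [fc_of_comm.get(truth.community_of[k], 0.0) for k in truth.kinases]
    )
    truth.planted_fc = {
        (line, k): float(fc)
        for line in rep_lines
        for k, fc in zip(truth.kinases, fc_kinase)
        if fc != 0.0
    }

    noise = rng.normal(0.0, spec.noise_sd, size=log2_u.shape)
    log2_t = log2_u.add(fc_kinase, axis=0) + noise

    untreated = QuantTable(_apply_dropout(log2_u, spec, rng))
    treated = QuantTable(_apply_dropout(log2_t, spec, rng))
    meta = pd.DataFrame(
        {
            "cell_line": [line_of[s] for s in samples],
            "subtype": [labels[s] for s in samples],
            "treatment": "untreated",
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return untreated, treated, meta
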