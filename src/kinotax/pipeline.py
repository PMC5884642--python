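"""End-to-end orchestration: simulate-or-ingest through every analysis stage.

``run_full`` executes the stages an input set allows — cohort simulation or
ingest, peptide/presence filtering and autoscaling, distinguishing-set
selection, leave-one-out subtype classification, MIB/RNA concordance,
network partitioning with understudied-kinase annotation, and perturbation
response — writing each stage's tables under the output directory and a
manifest (parameters, seeds, per-stage status, output checksums) at the end.
Stages whose inputs are absent are marked skipped, not failed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io_filter, kinome_network, perturbation_response, subtype_classifier, synthetic_cohort, taxonomy, transcript_concordance
from .exceptions import KinotaxError, ParameterError

log = logging.getLogger("kinotax")


@dataclass
class RunConfig:
    """Flat run configuration; every default is the pipeline's documented
    threshold (3 peptides, 30% presence, 50-kinase cap, top 5%, 3 PCs at the
    90th percentile, k = 16 subnetworks, 50-count RNA detection)."""

    out_dir: str = "kinotax_out"
    seed: int = 0
    # inputs; when quant_path is None a synthetic cohort is generated
    quant_path: str | None = None
    meta_path: str | None = None
    rna_path: str | None = None
    edges_paths: list[str] = field(default_factory=list)
    annotations_path: str | None = None
    treated_path: str | None = None
    untreated_path: str | None = None
    # filters
    min_peptides: int = 3
    min_presence: float = 0.30
    # selection
    cap: int = 50
    top_frac: float = 0.05
    n_pcs: int = 3
    percentile: float = 90.0
    # classifier
    svm_c: float = 1.0
    tau: float = 0.0
    # concordance / network
    rna_threshold: float = 50.0
    network_k: int = 16
    n_linkage_centers: int = 8  # understudied centers annotated per run

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 <= self.min_presence <= 1:
            raise ParameterError("min_presence must be in [0, 1]")
        if self.cap < 0 or self.min_peptides < 0 or self.network_k < 1:
            raise ParameterError("thresholds outside documented domains")
        for p in [self.quant_path, self.meta_path, self.rna_path,
                  self.annotations_path, self.treated_path, self.untreated_path,
                  *self.edges_paths]:
            if p is not None and not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: RunConfig) -> dict:
    """Run every stage the inputs allow; return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, t0: float | None = None, **extra) -> None:
        entry = {"status": status, **extra}
        if t0 is not None:
            entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
        log.info("stage %s: %s", stage, status)

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    truth = None
    rna = None
    edges_df = None
    annotations = None

    # -- simulate or ingest -------------------------------------------------
    t0 = time.perf_counter()
    if config.quant_path is None:
        spec = synthetic_cohort.CohortSpec(seed=config.seed)
        quant, meta, truth = synthetic_cohort.generate_mib_cohort(spec)
        rna = synthetic_cohort.generate_rna_table(spec, truth, quant)
        edges_df, annotations = synthetic_cohort.generate_network_and_annotations(spec, truth)
        untreated, treated, pert_meta = synthetic_cohort.generate_perturbation_pair(spec, truth)
        save("quant.tsv", lambda p: io_filter.write_quant_table(quant, p))
        save("meta.tsv", lambda p: io_filter.write_sample_meta(meta, p))
        save("rna.tsv", lambda p: transcript_concordance.write_expression_table(rna, p))
        save("edges.tsv", lambda p: edges_df.to_csv(p, sep="\t", index=False))
        save("annotations.tsv", lambda p: annotations.to_csv(p, sep="\t", index=False))
        save("truth.json", truth.to_json)
        record("simulate", "completed", t0)
    else:
        if config.meta_path is None:
            raise ParameterError("meta_path required alongside quant_path")
        quant = io_filter.read_quant_table(config.quant_path, dialect="wide-with-peptides")
        meta = io_filter.read_sample_meta(config.meta_path)
        if config.rna_path:
            rna = transcript_concordance.read_expression_table(config.rna_path)
        if config.edges_paths:
            edges_df = pd.concat(
                [kinome_network.read_edge_list(p) for p in config.edges_paths],
                ignore_index=True,
            )
        if config.annotations_path:
            annotations = pd.read_csv(config.annotations_path, sep="\t")
        treated = untreated = pert_meta = None
        if config.treated_path and config.untreated_path:
            treated = io_filter.read_quant_table(config.treated_path)
            untreated = io_filter.read_quant_table(config.untreated_path)
        record("ingest", "completed", t0)

    # -- filter + normalize -------------------------------------------------
    t0 = time.perf_counter()
    filtered = io_filter.filter_by_peptides(quant, config.min_peptides)
    filtered = io_filter.filter_by_presence(filtered, config.min_presence)
    norm = io_filter.log2_autoscale(filtered)
    averaged = io_filter.average_replicates(norm, meta)
    save("normalized.tsv", lambda p: io_filter.write_normalized_matrix(norm, p))
    save("cell_line_profiles.tsv",
         lambda p: io_filter.write_normalized_matrix(averaged, p))
    record("normalize", "completed", t0,
           n_kinases=len(filtered.kinases), n_samples=len(filtered.samples))

    # -- taxonomy -----------------------------------------------------------
    t0 = time.perf_counter()
    complete = taxonomy.impute_kinase_mean(norm)
    pca = taxonomy.run_pca(complete)
    pan = taxonomy.pan_subtype_features(pca, config.n_pcs, config.percentile)
    subtypes = sorted(meta.loc[norm.samples, "subtype"].unique())
    rankings = {
        s: taxonomy.rank_subtype_features(norm, meta, s) for s in subtypes
    }
    dset = taxonomy.compose_distinguishing_set(
        rankings, pan, cap=config.cap, top_frac=config.top_frac
    )
    save("distinguishing_set.tsv", dset.to_tsv)
    record("taxonomy", "completed", t0, n_features=len(dset))

    # -- classifier ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        model = subtype_classifier.train_svm(
            norm, meta, dset, C=config.svm_c, tau=config.tau
        )
        conf = subtype_classifier.loo_evaluate(norm, meta, dset, C=config.svm_c)
        save("classifier_model.json", model.to_json)
        save("loo_confusion.tsv", lambda p: conf.to_csv(p, sep="\t"))
        record("classifier", "completed", t0,
               loo_accuracy=subtype_classifier.loo_accuracy(conf))
    except KinotaxError as exc:
        record("classifier", "skipped", t0, reason=str(exc))

    # -- concordance ----------------------------------------------------------
    t0 = time.perf_counter()
    if rna is not None:
        conc = transcript_concordance.per_kinase_correlation(averaged, rna)
        save("concordance.tsv", conc.to_tsv)
        record("concordance", "completed", t0,
               mean_r=conc.mean_r, n_defined=conc.n_defined)
    else:
        record("concordance", "skipped", reason="no RNA table")

    # -- network ----------------------------------------------------------
    t0 = time.perf_counter()
    if edges_df is not None:
        universe = set(filtered.kinases)
        net = kinome_network.compile_union_network([edges_df], universe)
        partition = kinome_network.spectral_partition(
            net, k=config.network_k, seed=config.seed
        )
        save("partition.json", lambda p: Path(p).write_text(
            json.dumps({"k": partition.k, "community_of": partition.community_of},
                       indent=1)))
        extra = {"n_isolated": len(net.isolated)}
        if annotations is not None and truth is not None:
            centers = sorted(truth.understudied & set(averaged.kinases))
            centers = centers[: config.n_linkage_centers]
            linkages = {
                c: kinome_network.lasso_linkages(averaged, c, seed=config.seed)
                for c in centers
            }
            enrich_rows = []
            for c in centers:
                subnet = kinome_network.build_functional_subnetwork(c, linkages, net)
                res = kinome_network.hypergeometric_enrichment(
                    subnet.members & universe, annotations, universe
                )
                res.insert(0, "center", c)
                enrich_rows.append(res.head(5))
            if enrich_rows:
                save("ego_enrichment.tsv", lambda p: pd.concat(enrich_rows)
                     .to_csv(p, sep="\t", index=False))
            extra["n_centers_annotated"] = len(centers)
        record("network", "completed", t0, **extra)
    else:
        partition = None
        record("network", "skipped", reason="no edge lists")

    # -- perturbation -------------------------------------------------------
    t0 = time.perf_counter()
    if treated is not None and untreated is not None and partition is not None:
        profiles = perturbation_response.log2_fold_change(
            treated, untreated, meta=pert_meta
        )
        resp = perturbation_response.subnetwork_response(profiles, partition)
        save("subnetwork_response.tsv", lambda p: resp.table.to_csv(p, sep="\t"))
        record("perturbation", "completed", t0, n_profiles=len(profiles))
    else:
        record("perturbation", "skipped", reason="no treated/untreated pair")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
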