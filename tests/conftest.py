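import numpy as np
import pandas as pd
import pytest

from kinotax import io_filter, taxonomy
from kinotax.synthetic_cohort import CohortSpec, generate_mib_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (254 kinases, 32 samples, effect size 3)."""
    spec = CohortSpec(seed=1)
    quant, meta, truth = generate_mib_cohort(spec)
    return spec, quant, meta, truth


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    """Filtered + autoscaled matrix and cell-line averages of the default cohort."""
    spec, quant, meta, truth = default_cohort
    q = io_filter.filter_by_peptides(quant)
    q = io_filter.filter_by_presence(q)
    norm = io_filter.log2_autoscale(q)
    averaged = io_filter.average_replicates(norm, meta)
    return norm, averaged, meta, truth


@pytest.fixture(scope="session")
def distinguishing_set(normalized_cohort):
    norm, _, meta, _ = normalized_cohort
    pca = taxonomy.run_pca(taxonomy.impute_kinase_mean(norm))
    pan = taxonomy.pan_subtype_features(pca)
    subtypes = sorted(meta.loc[norm.samples, "subtype"].unique())
    rankings = {s: taxonomy.rank_subtype_features(norm, meta, s) for s in subtypes}
    return taxonomy.compose_distinguishing_set(rankings, pan)


@pytest.fixture()
def toy_quant():
    """3 kinases x 4 samples with one missing entry and peptide counts."""
    intensity = pd.DataFrame(
        {
            "s1": [2.0, 16.0, 4.0],
            "s2": [8.0, 32.0, 4.0],
            "s3": [4.0, 8.0, np.nan],
            "s4": [16.0, 64.0, 2.0],
        },
        index=["KA", "KB", "KC"],
    )
    peptides = pd.DataFrame(
        {
            "s1": [3, 5, 2],
            "s2": [2, 6, 1],
            "s3": [3, 4, 2],
            "s4": [1, 8, 2],
        },
        index=["KA", "KB", "KC"],
    )
    return io_filter.QuantTable(intensity, peptides)


@pytest.fixture()
def toy_meta():
    return pd.DataFrame(
        {
            "cell_line": ["L1", "L1", "L2", "L2"],
            "subtype": ["basal-like", "basal-like", "luminal", "luminal"],
            "treatment": "untreated",
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
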