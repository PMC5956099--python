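import pytest

from somalex.allele_metrics import build_allele_table
from somalex.associations import log2_fold_change_frame
from somalex.synthetic_cohort import CohortConfig, generate_cohort, write_bundle


@pytest.fixture(scope="session")
def small_cohort():
    """~400-variant cohort for structural tests."""
    cfg = CohortConfig(
        n_samples=24,
        cancer_types=("BLCA", "BRCA"),
        mean_variants_per_sample=20.0,
        n_genes=150,
    )
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions (~2000 variants, depth ~100x)."""
    return generate_cohort(seed=2025)


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Allele table joined to expression change and generator truth."""
    c = default_cohort
    variants = c.variants.assign(is_cgc=c.variants.gene.isin(c.cgc_genes))
    calls = build_allele_table(variants, c.counts, c.purity)
    expr = log2_fold_change_frame(c.expression)
    calls = calls.merge(
        expr[["gene", "sample_id", "log2fc"]], on=["gene", "sample_id"], how="left"
    )
    return calls.merge(
        c.truth[
            [
                "sample_id", "chrom", "pos", "selection", "log_selection",
                "beta_log2fc", "nmd_verdict", "planned_filter", "allelic_event",
            ]
        ],
        on=["sample_id", "chrom", "pos"],
    )


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_cohort, outdir)
    return paths


@pytest.fixture(scope="session")
def default_bundle(default_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle_default")
    return write_bundle(default_cohort, outdir)
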