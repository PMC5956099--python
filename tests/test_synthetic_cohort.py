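"""Generator determinism, closed-form expectations and truth round-trips."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from somalex import data_io
from somalex.synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    write_bundle,
)


def calibration_config(**overrides):
    """No selection, no NMD, no allelic events, fixed purity/depth."""
    base = dict(
        n_samples=20,
        mean_variants_per_sample=50.0,
        n_genes=100,
        sigma_log_selection=0.0,
        ptv_log_selection_shift=0.0,
        nmd_degradation=0.0,
        p_variant_allele_silenced=0.0,
        p_reference_allele_silenced=0.0,
        p_planned_germline=0.0,
        p_planned_low_depth=0.0,
        p_planned_chrx=0.0,
        p_planned_imprinted=0.0,
        n_hypermutators=0,
        frac_tfbs_gain=0.0,
        frac_tfbs_loss=0.0,
        depth_fixed=True,
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_all_frames(self):
        cfg = CohortConfig(n_samples=8, mean_variants_per_sample=10, n_genes=60)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=5)
        for attr in ("variants", "counts", "purity", "expression", "truth"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
        assert a.genome == b.genome

    def test_different_seeds_differ(self):
        cfg = CohortConfig(n_samples=8, mean_variants_per_sample=10, n_genes=60)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=6)
        assert not a.counts.equals(b.counts)

    def test_bundle_bytes_identical_across_runs(self, tmp_path):
        cfg = CohortConfig(n_samples=6, mean_variants_per_sample=8, n_genes=60)

        def digest(d):
            write_bundle(generate_cohort(cfg, seed=3), d)
            h = hashlib.sha256()
            for p in sorted(Path(d).iterdir()):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            return h.hexdigest()

        assert digest(tmp_path / "a") == digest(tmp_path / "b")


class TestClosedFormExpectations:
    def test_neutral_deep_cohort_has_unit_mean_vrd(self):
        # s=1, d=0, depth 1000, purity 1 -> V_R:D concentrates at 1
        cfg = calibration_config(
            purity_fixed=1.0, depth_tumor_dna=1000, depth_tumor_rna=1000
        )
        c = generate_cohort(cfg, seed=13)
        merged = c.counts
        vaf_d = merged["tex_var"] / (merged["tex_ref"] + merged["tex_var"])
        vaf_r = merged["ttr_var"] / (merged["ttr_ref"] + merged["ttr_var"])
        v_rd = (vaf_r / vaf_d).to_numpy()
        assert len(v_rd) >= 900
        assert 0.97 <= float(np.mean(v_rd)) <= 1.03

    def test_mean_dna_vaf_is_half_purity(self):
        # admixture of a diploid heterozygous tumor: E[VAF_tDNA] = pi/2
        cfg = calibration_config(purity_fixed=0.5)
        c = generate_cohort(cfg, seed=13)
        vaf_d = c.counts["tex_var"] / (c.counts["tex_ref"] + c.counts["tex_var"])
        assert float(vaf_d.mean()) == pytest.approx(0.25, abs=0.01)
        assert c.truth["expected_vaf_tdna"].unique() == pytest.approx([0.25])


class TestBundleRoundTrip:
    def test_reading_back_reproduces_record_counts(self, small_cohort, small_bundle):
        variants = data_io.read_variants(small_bundle["variants"], "maf")
        assert len(variants) == len(small_cohort.variants)
        counts = data_io.read_counts_table(small_bundle["counts"])
        pd.testing.assert_frame_equal(
            counts, small_cohort.counts.reset_index(drop=True)
        )
        models = data_io.read_gene_models(small_bundle["gene_models"])
        assert set(models) == set(small_cohort.models)
        t_mem = small_cohort.models[next(iter(models))]
        t_disk = models[t_mem.transcript_id]
        assert t_disk.exons == t_mem.exons
        assert (t_disk.cds_start, t_disk.cds_end) == (t_mem.cds_start, t_mem.cds_end)

    def test_genome_fasta_round_trip(self, small_cohort, small_bundle):
        genome = data_io.open_fasta(small_bundle["genome"])
        for chrom, seq in small_cohort.genome.items():
            assert str(genome[chrom][:]) == seq

    def test_imprinted_bed_round_trip(self, small_cohort, small_bundle):
        assert data_io.read_bed(small_bundle["imprinted_bed"]) == small_cohort.imprinted


class TestTruthStructure:
    def test_planned_filters_present(self, default_cohort):
        planned = default_cohort.truth["planned_filter"].value_counts()
        for kind in ("chrx", "imprinted", "germline", "low_depth"):
            assert planned.get(kind, 0) > 0

    def test_every_escape_rule_represented(self, default_cohort):
        rules = set(default_cohort.truth["nmd_rule"]) - {""}
        assert rules == {
            "last_eej_proximal",
            "start_proximal_alt_aug",
            "long_exon_boundary",
            "short_half_life",
            "single_exon",
            "nmd_insensitive",
        }

    def test_invalid_config_rejected_before_output(self):
        with pytest.raises(Exception):
            CohortConfig(frac_ptv=0.5, frac_missense=0.5, frac_silent=0.5)
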