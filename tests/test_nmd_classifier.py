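"""PTC localization and the six-rule NMD escape engine."""

import pytest

from somalex.nmd_classifier import (
    NMDConfig,
    classify_nmd,
    has_downstream_inframe_aug,
    locate_ptc,
)
from somalex.types import SomalexError, TranscriptModel

from helpers import (
    LONG_EXONS,
    SINGLE_EXON,
    STD_EXONS,
    cds_seq_with_aug,
    make_transcript,
    mirror,
)


@pytest.fixture
def two_exon_plus():
    # exons [100,200] and [300,400], CDS genomic 150..350
    return TranscriptModel(
        transcript_id="T2",
        gene="G2",
        chrom="chr1",
        strand="+",
        exons=((100, 200), (300, 400)),
        cds_start=150,
        cds_end=350,
    )


class TestLocatePtc:
    def test_plus_strand_coordinates(self, two_exon_plus):
        loc = locate_ptc(180, two_exon_plus)
        assert loc.ptc_cds_offset == 30
        assert loc.exon_index == 1
        assert loc.dist_last_eej == 20

    def test_last_exon_gives_negative_junction_distance(self, two_exon_plus):
        loc = locate_ptc(320, two_exon_plus)
        assert loc.exon_index == 2
        assert loc.dist_last_eej < 0

    def test_minus_strand_mirror_gives_identical_spliced_answers(self, two_exon_plus):
        t_minus, pos = mirror(two_exon_plus, 180, axis=500)
        assert t_minus.strand == "-"
        assert locate_ptc(pos, t_minus) == locate_ptc(180, two_exon_plus)

    def test_position_outside_cds_is_an_error(self, two_exon_plus):
        with pytest.raises(SomalexError):
            locate_ptc(120, two_exon_plus)

    def test_noncoding_transcript_is_an_error(self):
        t = TranscriptModel("T", "G", "chr1", "+", ((100, 200),))
        with pytest.raises(SomalexError):
            locate_ptc(150, t)


class TestAugSearch:
    def test_inframe_aug_downstream_found(self):
        assert has_downstream_inframe_aug(cds_seq_with_aug(aug_at=300), 80)

    def test_aug_upstream_of_ptc_ignored(self):
        assert not has_downstream_inframe_aug(cds_seq_with_aug(aug_at=30), 80)

    def test_out_of_frame_aug_ignored(self):
        seq = list("C" * 720)
        seq[301:304] = "ATG"  # codon-offset 301 is out of frame
        assert not has_downstream_inframe_aug("".join(seq), 80)


# Escape-rule grid: every geometrically realizable combination of intended
# flags on hand-built transcripts. Each entry: (transcript kwargs, mRNA
# offset of the PTC, cds sequence or None, expected true flags).
GRID = [
    # all rules false -> elicit
    (dict(exons=STD_EXONS, cds_m=(20, 739)), 500, None, set()),
    # rule 1: PTC in the last exon
    (dict(exons=STD_EXONS, cds_m=(20, 739)), 700, None, {"last_eej_proximal"}),
    # rule 1: within 50 nt upstream of the last junction (dist = 39)
    (dict(exons=STD_EXONS, cds_m=(20, 739)), 560, None, {"last_eej_proximal"}),
    # rule 2: start-proximal with a downstream in-frame AUG
    (
        dict(exons=STD_EXONS, cds_m=(20, 739)),
        100,
        cds_seq_with_aug(aug_at=300),
        {"start_proximal_alt_aug"},
    ),
    # start-proximal but no alternative AUG -> elicit
    (dict(exons=STD_EXONS, cds_m=(20, 739)), 100, cds_seq_with_aug(aug_at=None), set()),
    # rule 3: long exon, close to its 5' boundary
    (dict(exons=LONG_EXONS, cds_m=(20, 979)), 300, None, {"long_exon_boundary"}),
    # long exon but far from both boundaries -> not rule 3
    (dict(exons=LONG_EXONS, cds_m=(20, 979)), 550, None, set()),
    # rule 4: short-lived transcript
    (dict(exons=STD_EXONS, cds_m=(20, 739), half_life=0.5), 500, None, {"short_half_life"}),
    # rule 5: single-exon transcript (rule 1 stays false)
    (dict(exons=SINGLE_EXON, cds_m=(20, 739)), 400, None, {"single_exon"}),
    # rule 6: NMD-insensitive gene
    (dict(exons=STD_EXONS, cds_m=(20, 739), insensitive=True), 500, None, {"nmd_insensitive"}),
    # combinations
    (
        dict(exons=STD_EXONS, cds_m=(20, 739), half_life=0.5),
        700,
        None,
        {"last_eej_proximal", "short_half_life"},
    ),
    (
        dict(exons=SINGLE_EXON, cds_m=(20, 739), insensitive=True, half_life=0.2),
        400,
        None,
        {"single_exon", "nmd_insensitive", "short_half_life"},
    ),
    (
        dict(exons=LONG_EXONS, cds_m=(20, 979), insensitive=True),
        210,  # CDS offset 190: start-proximal AND just inside the long exon
        cds_seq_with_aug(length=960, aug_at=600),
        {"long_exon_boundary", "nmd_insensitive", "start_proximal_alt_aug"},
    ),
    # rule 2 geometry with rule 1: short upstream exons put a start-proximal
    # PTC into the last exon (400 nt, so rule 3 stays quiet)
    (
        dict(exons=((1000, 1059), (1100, 1159), (1200, 1599)), cds_m=(10, 509)),
        150,
        cds_seq_with_aug(length=500, aug_at=300),
        {"last_eej_proximal", "start_proximal_alt_aug"},
    ),
]


@pytest.mark.parametrize("kwargs,m,cds_seq,expected", GRID)
def test_escape_flag_grid(kwargs, m, cds_seq, expected):
    t = make_transcript(**kwargs)
    ann = classify_nmd(t.genomic_pos(m), t, cds_sequence=cds_seq)
    true_flags = {k for k, v in ann.flags.items() if v}
    assert true_flags == expected
    assert ann.verdict == ("escape" if expected else "elicit")


@pytest.mark.parametrize("kwargs,m,cds_seq,expected", GRID)
def test_strand_mirror_invariance(kwargs, m, cds_seq, expected):
    t = make_transcript(**kwargs)
    pos = t.genomic_pos(m)
    t2, pos2 = mirror(t, pos)
    a1 = classify_nmd(pos, t, cds_sequence=cds_seq)
    a2 = classify_nmd(pos2, t2, cds_sequence=cds_seq)
    assert a1.flags == a2.flags
    assert a1.location == a2.location
    assert a1.verdict == a2.verdict


def test_literal_rule1_direction_is_configurable():
    t = make_transcript(exons=STD_EXONS, cds_m=(20, 739))
    pos = t.genomic_pos(500)  # 99 nt upstream of the last junction
    canonical = classify_nmd(pos, t)
    literal = classify_nmd(pos, t, config=NMDConfig(rule1_literal=True))
    assert not canonical.flags["last_eej_proximal"]
    assert literal.flags["last_eej_proximal"]


def test_verdict_is_or_of_flags_on_cohort_ptvs(small_cohort):
    """On generator PTVs, the classifier reproduces the designed verdicts."""
    from somalex.nmd_classifier import annotate_ptvs

    c = small_cohort
    ann = annotate_ptvs(
        c.variants, c.models, c.genome, c.half_life, c.insensitive_genes
    )
    merged = ann.merge(
        c.truth[c.truth.consequence == "PTV"][
            ["sample_id", "chrom", "pos", "nmd_verdict"]
        ],
        on=["sample_id", "chrom", "pos"],
    )
    assert len(merged) > 20
    assert (merged["verdict"] == merged["nmd_verdict"]).all()
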