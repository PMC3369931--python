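import random

import pytest

from antarscan.classify import (ClassifiedHit, GenomeSummary, classify_hits,
                                correlate_with_antar_genes,
                                detect_rbs_overlap, extract_scan_regions,
                                group_regulons, link_terminator)
from antarscan.io import GeneFeature, SequenceRecord, revcomp
from antarscan.motif import MotifHit
from antarscan.terminator import TerminatorHit


def motif_hit(start, strand="+", seqid="g", score=20.0):
    s = start
    return MotifHit(seqid=seqid, strand=strand,
                    p1_left=(s, s + 3), l1=(s + 3, s + 9),
                    p1_right=(s + 9, s + 12), linker=(s + 12, s + 18),
                    p2_left=(s + 18, s + 21), l2=(s + 21, s + 27),
                    p2_right=(s + 27, s + 30), score=score,
                    subsequence="", l1_seq="AUCGGU", l2_seq="AUCGGC")


def term_hit(left, right, strand="+", seqid="g", hp=18.0, tail=4.0):
    return TerminatorHit(seqid=seqid, strand=strand, left_arm=left,
                         right_arm=right, loop=(left[1], right[0]),
                         utract=(right[1], right[1] + 12),
                         hairpin_score=hp, tail_score=tail)


def cds(start, end, strand="+", tag="LT0001", seqid="g"):
    return GeneFeature(seqid=seqid, start=start, end=end, strand=strand,
                       kind="CDS", attributes={"locus_tag": tag})


# ---------------------------------------------------------------------------
# intergenic regions

def test_extract_scan_regions_complement():
    genome = SequenceRecord(id="g", residues="C" * 100)
    feats = [cds(10, 40), cds(60, 90)]
    assert extract_scan_regions(genome, feats) == [(0, 10), (40, 60), (90, 100)]


def test_extract_scan_regions_overlapping_cds_merge():
    genome = SequenceRecord(id="g", residues="C" * 100)
    feats = [cds(10, 40), cds(30, 70)]
    assert extract_scan_regions(genome, feats) == [(0, 10), (70, 100)]


def test_extract_scan_regions_no_cds_and_non_cds_ignored():
    genome = SequenceRecord(id="g", residues="C" * 50)
    assert extract_scan_regions(genome, []) == [(0, 50)]
    gene = GeneFeature(seqid="g", start=5, end=20, strand="+", kind="gene")
    assert extract_scan_regions(genome, [gene]) == [(0, 50)]


# ---------------------------------------------------------------------------
# terminator linkage

def test_link_terminator_requires_overlap_and_geometry():
    hit = motif_hit(10)  # p2 footprint (28, 40), l1 ends at 19
    linked = link_terminator(hit, [term_hit((38, 44), (50, 56))])
    assert linked is not None
    term, shared = linked
    assert shared == 2
    # no overlap with the second hairpin
    assert link_terminator(hit, [term_hit((41, 47), (53, 59))]) is None
    # antisense terminator never links
    assert link_terminator(hit, [term_hit((38, 44), (50, 56), strand="-")]) is None
    # hairpin beginning upstream of L1 never links
    assert link_terminator(hit, [term_hit((5, 11), (17, 23))]) is None
    # other replicon
    assert link_terminator(hit, [term_hit((38, 44), (50, 56), seqid="x")]) is None


def test_link_terminator_prefers_larger_overlap_then_score():
    hit = motif_hit(10)
    small = term_hit((39, 45), (51, 57), hp=30.0)   # shares 1 nt
    big = term_hit((36, 42), (48, 54), hp=12.0)     # shares 4 nt
    assert link_terminator(hit, [small, big])[0] is big
    big2 = term_hit((36, 42), (48, 54), hp=25.0)
    assert link_terminator(hit, [small, big, big2])[0] is big2


def minus_term(left, right, seqid="g", hp=18.0, tail=4.0):
    # minus-strand spans stay in forward coordinates: the transcript-5'
    # (left) arm is the rightmost arm and the U-tract lies further left
    return TerminatorHit(seqid=seqid, strand="-", left_arm=left,
                         right_arm=right, loop=(right[1], left[0]),
                         utract=(right[0] - 12, right[0]),
                         hairpin_score=hp, tail_score=tail)


def test_link_terminator_minus_strand_geometry():
    # on the minus strand P2 is transcript-downstream, i.e. at lower
    # forward coordinates
    hit = MotifHit(seqid="g", strand="-",
                   p1_left=(87, 90), l1=(81, 87), p1_right=(78, 81),
                   linker=(72, 78), p2_left=(69, 72), l2=(63, 69),
                   p2_right=(60, 63), score=20.0, subsequence="")
    term = minus_term((50, 56), (38, 44))
    linked = link_terminator(hit, [term], overlap_min=1)
    assert linked is None  # no overlap with p2 footprint (60, 72)
    term2 = minus_term((62, 68), (44, 50))
    linked = link_terminator(hit, [term2], overlap_min=1)
    assert linked is not None and linked[1] == 6


# ---------------------------------------------------------------------------
# Shine-Dalgarno detection

def _plus_genome(sd_at=38, gene_start=50):
    residues = ["C"] * 100
    residues[sd_at:sd_at + 6] = list("AGGAGG")
    residues[gene_start:gene_start + 3] = list("ATG")
    return SequenceRecord(id="g", residues="".join(residues))


def test_rbs_plus_strand_detected():
    genome = _plus_genome()  # SD at [38,44), spacing 6 before ATG at 50
    gene = cds(50, 80)
    hit = motif_hit(12)  # span (12, 42) overlaps SD
    assert detect_rbs_overlap(hit, [gene], genome) is True


def test_rbs_plus_strand_requires_hit_overlap():
    genome = _plus_genome()
    gene = cds(50, 80)
    far = motif_hit(2)  # span (2, 32): ends before the SD at 38
    assert detect_rbs_overlap(far, [gene], genome) is False


def test_rbs_spacing_window_enforced():
    # SD directly abutting the start codon (spacing 0) is not accepted
    genome = _plus_genome(sd_at=44)
    gene = cds(50, 80)
    hit = motif_hit(16)
    assert detect_rbs_overlap(hit, [gene], genome) is False


def test_rbs_partial_match_minimum():
    residues = ["C"] * 100
    residues[39:43] = list("GGAG")  # 4 consecutive SD-core nt
    residues[50:53] = list("ATG")
    genome = SequenceRecord(id="g", residues="".join(residues))
    hit = motif_hit(12)
    assert detect_rbs_overlap(hit, [cds(50, 80)], genome) is True
    assert detect_rbs_overlap(hit, [cds(50, 80)], genome, min_match=5) is False


def test_rbs_minus_strand_detected():
    # gene on the minus strand occupying [20, 50); start codon at [47, 50);
    # the SD sits downstream on the forward strand, as revcomp(AGGAGG)
    residues = ["C"] * 100
    residues[47:50] = list(revcomp("ATG"))
    residues[56:62] = list(revcomp("AGGAGG"))
    genome = SequenceRecord(id="g", residues="".join(residues))
    gene = cds(20, 50, strand="-")
    hit = motif_hit(52, strand="-")  # span (52, 82) covers SD interval
    assert detect_rbs_overlap(hit, [gene], genome) is True
    far = motif_hit(65, strand="-")  # span (65, 95): misses (44, 62)
    assert detect_rbs_overlap(far, [gene], genome) is False


# ---------------------------------------------------------------------------
# end-to-end classification

def _classification_fixture():
    residues = ["C"] * 200
    residues[138:144] = list("AGGAGG")
    residues[150:153] = list("ATG")
    genome = SequenceRecord(id="g", residues="".join(residues))
    gene = cds(150, 180)
    hits = [
        motif_hit(10),    # will link a terminator -> attenuator
        motif_hit(60),    # nothing nearby -> orphan
        motif_hit(112),   # covers the SD at 138 -> translational candidate
        motif_hit(155),   # inside the CDS -> discarded
    ]
    terms = [term_hit((36, 42), (48, 54))]
    return genome, [gene], hits, terms


def test_classification_partition():
    genome, feats, hits, terms = _classification_fixture()
    out = classify_hits(hits, terms, feats, genome)
    cats = {c.motif.start: c.category for c in out}
    assert cats == {10: "attenuator", 60: "orphan",
                    112: "translational_candidate", 155: "discarded"}
    att = next(c for c in out if c.category == "attenuator")
    assert att.shared_nt == 4 and att.linked_terminator is not None
    disc = next(c for c in out if c.category == "discarded")
    assert disc.discard_reason == "in_coding_region"


def test_classification_order_invariance():
    genome, feats, hits, terms = _classification_fixture()
    ref = classify_hits(hits, terms, feats, genome)
    shuffled = hits[:]
    random.Random(5).shuffle(shuffled)
    assert classify_hits(shuffled, terms, feats, genome) == ref


def test_classified_hit_validation():
    with pytest.raises(ValueError):
        ClassifiedHit(motif=motif_hit(0), category="discarded")
    with pytest.raises(ValueError):
        ClassifiedHit(motif=motif_hit(0), category="attenuator")
    with pytest.raises(ValueError):
        ClassifiedHit(motif=motif_hit(0, strand="+"), category="attenuator",
                      linked_terminator=term_hit((1, 4), (8, 11), strand="-"))


# ---------------------------------------------------------------------------
# summaries

def test_correlation_table_fractions():
    def summary(gid, present, scores, n_att=0):
        return GenomeSummary(genome_id=gid, antar_present=present,
                             n_hits=len(scores), n_attenuators=n_att,
                             n_translational=0,
                             n_orphans=len(scores) - n_att, scores=scores)
    summaries = [
        summary("g1", True, [12.0, 14.0, 16.0], n_att=2),
        summary("g2", True, [11.0, 13.0], n_att=1),
        summary("g3", False, [10.0]),
    ]
    df = correlate_with_antar_genes(summaries)
    assert df.loc["antar_plus", "n_hits"] == 5
    assert df.loc["antar_plus", "fraction_of_all_hits"] == pytest.approx(5 / 6)
    assert df.loc["antar_plus", "attenuator_fraction"] == pytest.approx(3 / 5)
    assert df.loc["antar_minus", "n_genomes"] == 1
    assert df.loc["antar_plus", "mean_score"] == pytest.approx(13.2)


def test_group_regulons_counts_distinct_units():
    genes = [cds(1000 + 200 * k, 1100 + 200 * k, tag=f"LT{k:04d}")
             for k in range(6)]
    classified = []
    for i in range(13):
        gene = genes[i % 6]
        cat = "discarded" if i == 12 else "orphan"
        classified.append(ClassifiedHit(
            motif=motif_hit(10 * i), category=cat,
            discard_reason="in_coding_region" if cat == "discarded" else None,
            downstream_gene=gene))
    summary = group_regulons(classified, genes, genome_id="g")
    assert summary.n_hits == 13
    assert summary.n_transcriptional_units == 6
    assert summary.n_orphans == 12
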