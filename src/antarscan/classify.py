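"""Join motif hits to genomic context and terminator predictions.

A motif hit becomes a transcription-attenuation candidate when the second
hairpin (P2) overlaps the 5' arm of a same-strand intrinsic terminator —
the two structures then compete for the shared residues, which is the
mutual-exclusivity switch the regulator exploits.  Hits lacking a linked
terminator may still act at the level of translation initiation when they
cover a Shine-Dalgarno sequence, and are otherwise reported as orphans.
Hits inside coding regions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneFeature, SequenceRecord, revcomp
from .motif import MotifHit
from .terminator import TerminatorHit

__all__ = [
    "ClassifiedHit",
    "GenomeSummary",
    "extract_scan_regions",
    "link_terminator",
    "detect_rbs_overlap",
    "classify_hits",
    "correlate_with_antar_genes",
    "group_regulons",
]

SD_CORE = "AGGAGG"
SD_MIN_MATCH = 4
SD_SPACING = (4, 16)  # nt between the SD match and the start codon


@dataclass(frozen=True)
class ClassifiedHit:
    motif: MotifHit
    category: str  # attenuator | translational_candidate | orphan | discarded
    discard_reason: str | None = None
    linked_terminator: TerminatorHit | None = None
    shared_nt: int = 0
    downstream_gene: GeneFeature | None = None
    distance_to_start: int | None = None
    rbs_overlap: bool = False

    def __post_init__(self) -> None:
        if self.category == "discarded" and not self.discard_reason:
            raise ValueError("discarded hits must carry a discard_reason")
        if self.category == "attenuator":
            if self.linked_terminator is None:
                raise ValueError("attenuators must carry a linked terminator")
            if self.linked_terminator.strand != self.motif.strand:
                raise ValueError("linked terminator must share the motif's strand")


@dataclass
class GenomeSummary:
    genome_id: str
    antar_present: bool
    n_hits: int
    n_attenuators: int
    n_translational: int
    n_orphans: int
    scores: list[float] = field(default_factory=list)
    n_transcriptional_units: int = 0


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------

def extract_scan_regions(genome: SequenceRecord,
                         features: list[GeneFeature]) -> list[tuple[int, int]]:
    """Maximal intervals of the genome not covered by any CDS feature.

    Restricting the scan to these intergenic intervals is equivalent to
    discarding in-coding hits after the fact, but cheaper.
    """
    n = len(genome)
    cds = sorted((f.start, f.end) for f in features if f.kind == "CDS")
    regions = []
    cursor = 0
    for start, end in cds:
        start, end = max(0, start), min(n, end)
        if start > cursor:
            regions.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < n:
        regions.append((cursor, n))
    return regions


def link_terminator(hit: MotifHit, terminators: list[TerminatorHit],
                    overlap_min: int = 1) -> tuple[TerminatorHit, int] | None:
    """Best same-strand terminator whose 5' arm overlaps the hit's P2.

    The terminator must be oriented with the motif (same strand), its
    hairpin must begin downstream of L1 in transcript orientation, and its
    transcript-5' arm must share at least ``overlap_min`` nt with the P2
    footprint.  Ties on shared length break by terminator total score.
    """
    best: tuple[int, float, TerminatorHit] | None = None
    p2 = hit.p2_footprint
    for term in terminators:
        if term.seqid != hit.seqid or term.strand != hit.strand:
            continue
        # transcript-orientation: hairpin must start downstream of L1
        if hit.strand == "+":
            if term.hairpin_span[0] < hit.l1[1]:
                continue
        else:
            if term.hairpin_span[1] > hit.l1[0]:
                continue
        shared = _overlap(term.left_arm, p2)
        if shared >= overlap_min:
            key = (shared, term.total_score)
            if best is None or key > (best[0], best[1]):
                best = (shared, term.total_score, term)
    if best is None:
        return None
    return best[2], best[0]


# ---------------------------------------------------------------------------

def _downstream_gene(hit: MotifHit,
                     features: list[GeneFeature]) -> tuple[GeneFeature, int] | None:
    """Nearest same-strand gene/CDS whose start lies downstream of the hit."""
    genes = [f for f in features
             if f.kind in ("gene", "CDS") and f.strand == hit.strand
             and f.seqid == hit.seqid]
    if hit.strand == "+":
        ahead = [f for f in genes if f.start >= hit.end]
        if not ahead:
            return None
        g = min(ahead, key=lambda f: f.start)
        return g, g.start - hit.end
    ahead = [f for f in genes if f.end <= hit.start]
    if not ahead:
        return None
    g = max(ahead, key=lambda f: f.end)
    return g, hit.start - g.end


def _sd_matches(region: str, min_match: int = SD_MIN_MATCH) -> list[tuple[int, int]]:
    """Spans within *region* matching >=min_match consecutive SD-core nt."""
    spans = []
    for k in range(len(SD_CORE), min_match - 1, -1):
        for off in range(len(SD_CORE) - k + 1):
            sub = SD_CORE[off:off + k]
            i = region.find(sub)
            while i != -1:
                spans.append((i, i + k))
                i = region.find(sub, i + 1)
    return spans


def detect_rbs_overlap(hit: MotifHit, features: list[GeneFeature],
                       genome: SequenceRecord,
                       min_match: int = SD_MIN_MATCH,
                       spacing: tuple[int, int] = SD_SPACING) -> bool:
    """True when the hit covers a Shine-Dalgarno site of the next gene.

    Requires a purine-rich SD-like match (>=min_match consecutive nt of
    AGGAGG) within the spacing window upstream of the downstream
    same-strand gene start, with the hit footprint intersecting the
    SD-through-start-codon interval.
    """
    res = _downstream_gene(hit, features)
    if res is None:
        return False
    gene, _ = res
    lo_sp, hi_sp = spacing
    if hit.strand == "+":
        start = gene.start  # first base of the start codon (forward)
        win_lo = max(0, start - hi_sp - len(SD_CORE))
        window = genome.residues[win_lo:start]
        for a, b in _sd_matches(window, min_match):
            spacing = start - (win_lo + b)
            if lo_sp <= spacing <= hi_sp:
                sd_start = win_lo + a
                if _overlap((hit.start, hit.end), (sd_start, start + 3)) > 0:
                    return True
        return False
    # minus strand: the start codon occupies forward [gene.end - 3, gene.end)
    start = gene.end
    win_hi = min(len(genome), start + hi_sp + len(SD_CORE))
    # transcript-oriented upstream window, right edge abutting the start codon
    window = revcomp(genome.residues[start:win_hi])
    for a, b in _sd_matches(window, min_match):
        spacing = len(window) - b
        if lo_sp <= spacing <= hi_sp:
            sd_end_fwd = win_hi - a  # forward coordinate just past the SD 5' end
            if _overlap((hit.start, hit.end), (start - 3, sd_end_fwd)) > 0:
                return True
    return False


# ---------------------------------------------------------------------------

def classify_hits(hits: list[MotifHit], terminators: list[TerminatorHit],
                  features: list[GeneFeature], genome: SequenceRecord,
                  overlap_min: int = 1,
                  rbs_min_match: int = SD_MIN_MATCH,
                  rbs_spacing: tuple[int, int] = SD_SPACING) -> list[ClassifiedHit]:
    """Assign each motif hit to exactly one category.

    Order of tests: in-coding discard, then terminator linkage
    (attenuator), then Shine-Dalgarno overlap (translational candidate),
    else orphan.  Deterministic and independent of input hit order.
    """
    cds = [(f.start, f.end) for f in features if f.kind == "CDS"
           and f.seqid == genome.id]
    out = []
    for hit in sorted(hits, key=lambda h: (h.seqid, h.start, h.strand)):
        ds = _downstream_gene(hit, features)
        gene, dist = ds if ds else (None, None)
        if any(_overlap((hit.start, hit.end), span) > 0 for span in cds):
            out.append(ClassifiedHit(motif=hit, category="discarded",
                                     discard_reason="in_coding_region",
                                     downstream_gene=gene,
                                     distance_to_start=dist))
            continue
        linked = link_terminator(hit, terminators, overlap_min)
        if linked is not None:
            term, shared = linked
            out.append(ClassifiedHit(motif=hit, category="attenuator",
                                     linked_terminator=term, shared_nt=shared,
                                     downstream_gene=gene,
                                     distance_to_start=dist))
            continue
        rbs = detect_rbs_overlap(hit, features, genome,
                                 min_match=rbs_min_match, spacing=rbs_spacing)
        category = "translational_candidate" if rbs else "orphan"
        out.append(ClassifiedHit(motif=hit, category=category,
                                 rbs_overlap=rbs, downstream_gene=gene,
                                 distance_to_start=dist))
    return out


def correlate_with_antar_genes(summaries: list[GenomeSummary]) -> pd.DataFrame:
    """Per-group statistics comparing genomes with and without ANTAR genes.

    ANTAR-protein presence is an input flag per genome, never computed.
    """
    rows = {}
    all_hits = sum(s.n_hits for s in summaries)
    for flag, label in ((True, "antar_plus"), (False, "antar_minus")):
        group = [s for s in summaries if s.antar_present == flag]
        scores = [x for s in group for x in s.scores]
        n_hits = sum(s.n_hits for s in group)
        n_att = sum(s.n_attenuators for s in group)
        rows[label] = {
            "n_genomes": len(group),
            "n_hits": n_hits,
            "mean_score": float(pd.Series(scores).mean()) if scores else float("nan"),
            "median_score": float(pd.Series(scores).median()) if scores else float("nan"),
            "attenuator_fraction": n_att / n_hits if n_hits else float("nan"),
            "fraction_of_all_hits": n_hits / all_hits if all_hits else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_regulons(classified: list[ClassifiedHit],
                   features: list[GeneFeature],
                   genome_id: str = "",
                   antar_present: bool = True) -> GenomeSummary:
    """Summarise a genome's classified hits into a regulon overview.

    A transcriptional unit is a distinct downstream gene (by locus tag)
    with at least one non-discarded hit in its upstream intergenic region;
    hits without a downstream gene do not count toward units.
    """
    kept = [c for c in classified if c.category != "discarded"]
    units = {c.downstream_gene.locus_tag or
             f"{c.downstream_gene.seqid}:{c.downstream_gene.start}"
             for c in kept if c.downstream_gene is not None}
    return GenomeSummary(
        genome_id=genome_id,
        antar_present=antar_present,
        n_hits=len(classified),
        n_attenuators=sum(c.category == "attenuator" for c in classified),
        n_translational=sum(c.category == "translational_candidate"
                            for c in classified),
        n_orphans=sum(c.category == "orphan" for c in classified),
        scores=[c.motif.score for c in classified],
        n_transcriptional_units=len(units),
    )
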