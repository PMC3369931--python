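"""Deterministic synthetic fixtures: genomes with embedded motifs and
terminators, a seed alignment, a leader construct with its mutant series,
and simulated binding titrations.

Everything here is synthetic, built to the published constraints of the
natural elements (3-bp minimum stems, hexanucleotide loops with A at
position 1 and G at position 4, conserved C-G/A-U closing pairs, linkers
of 5-12 nt, intrinsic terminators with up to 26-nt loops).  The leader
construct reproduces the coordinate frame of the characterised eutP
5' leader (P1 arm at 25-28, L1 at 29-34 with A29/G32, P2 stem containing
G51, L2 at 53-58 with A53/G56, numbering from the transcription start as
+1) so that the classic loss-of-function mutants land on the published
positions; the inter-element sequence is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingCurve, fraction_bound
from .io import SequenceRecord, GeneFeature, StructuredAlignment, revcomp, to_dna
from .motif import NT, WATSON_CRICK, WOBBLE, Candidate

__all__ = [
    "EmbedSpec",
    "EUTP_LEADER",
    "EUTP_TRUTH",
    "CONSENSUS_LOOP1",
    "CONSENSUS_LOOP2",
    "DECOY_CLASSES",
    "MUTANT_EXPECTATIONS",
    "build_motif",
    "eutp_leader_record",
    "synthetic_seed_alignment",
    "packaged_seed_alignment",
    "embed_dual_hairpin",
    "generate_genome",
    "mutant_series",
    "simulate_isotherm",
]

# loop consensus used throughout the synthetic elements: A at position 1,
# G at position 4 (1-based), as conserved in the natural substrates
CONSENSUS_LOOP1 = "ATCGGT"
CONSENSUS_LOOP2 = "ATCGGC"

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# Synthetic leader construct (eutP coordinate frame), 0-based internally.
# 1-based layout: 1-24 upstream (A/G only: cannot base-pair internally),
# 25-28 P1 left arm ACAC, 29-34 L1 AUCGGU (A29, G32), 35-38 P1 right arm
# GUGU, 39-49 11-nt linker, 50-52 P2 left arm GGC (G51 in the stem),
# 53-58 L2 AUCGGC (A53, G56), 59-61 P2 right arm GCC, 62-79 terminator
# hairpin whose 5' arm shares the P2 3' arm (mutual exclusivity; the 5-nt
# terminator loop cannot reach the motif's 6-nt loop by unpairing stem
# pairs, which change loop length in steps of 2), 80-87 U-tract, 88-91 tail.
EUTP_LEADER = to_dna(
    "GAAGAAAGAAGGAAAGAAAGAAGA"    # 1-24
    "ACAC" "ATCGGT" "GTGT"        # P1 / L1 / P1'
    "AAAAAAAAAAA"                 # linker (11 nt)
    "GGC" "ATCGGC" "GCC"          # P2 / L2 / P2'
    "AATAT" "TTCGA" "ATATTGGC"    # terminator: arm extension, loop, 3' arm
    "TTTTTTTT"                    # U-tract
    "AAGA"
)

EUTP_TRUTH = Candidate(start=24, s1=4, linker_len=11, s2=3, loop_len=6)


def eutp_leader_record(name: str = "eutP_leader_synthetic") -> SequenceRecord:
    return SequenceRecord(id=name, residues=EUTP_LEADER)


# ---------------------------------------------------------------------------
# Seed alignment

def synthetic_seed_alignment(n_rows: int = 17, seed: int = 2012) -> StructuredAlignment:
    """A 17-row seed alignment of dual-hairpin substrate RNAs (synthetic).

    Columns: 3-bp stem 1, 6-nt loop 1, stem 1', a 12-column gapped linker
    (realised lengths 5-12 nt), 3-bp stem 2, 6-nt loop 2, stem 2'.
    Conserved features mirror the natural substrate family: A1/G4 in both
    loops; stem-1 closing pair C-G with A-U beneath it; stem-2 closing
    pair C-G.  Non-conserved positions vary across rows.
    """
    rng = np.random.default_rng(seed)
    structure = "<<<......>>>" + "." * 12 + "(((......)))"
    pair_pool = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T")]

    def pick_pair(consensus, p=0.7):
        if rng.random() < p:
            return consensus
        return pair_pool[rng.integers(len(pair_pool))]

    def pick_base(consensus, p=0.75):
        if rng.random() < p:
            return consensus
        return NT[rng.integers(4)]

    rows = []
    linker_lengths = [5, 6, 7, 8, 9, 10, 11, 12]
    for r in range(n_rows):
        # stem 1: outer pair varies, middle A-U and closing C-G conserved
        s1 = [pick_pair(("C", "G")), ("A", "T"), ("C", "G")]
        s2 = [pick_pair(("G", "C")), pick_pair(("G", "C")), ("C", "G")]
        l1 = "A" + pick_base("T") + pick_base("C") + "G" + pick_base("G") + pick_base("T")
        l2 = "A" + pick_base("T") + pick_base("C") + "G" + pick_base("G") + pick_base("C")
        d = linker_lengths[r % len(linker_lengths)]
        linker = "".join(NT[rng.integers(4)] for _ in range(d)) + "-" * (12 - d)
        row = ("".join(p[0] for p in s1) + l1 + "".join(p[1] for p in reversed(s1))
               + linker
               + "".join(p[0] for p in s2) + l2 + "".join(p[1] for p in reversed(s2)))
        rows.append((f"seed{r + 1:02d}", row))
    return StructuredAlignment(rows=rows, structure_line=structure)


def packaged_seed_alignment() -> StructuredAlignment:
    """The synthetic seed alignment shipped with the package (17 rows)."""
    from importlib.resources import files

    from .io import read_structured_alignment
    return read_structured_alignment(
        str(files("antarscan").joinpath("data/seed_synthetic.sto")))


# ---------------------------------------------------------------------------
# Embedding

@dataclass(frozen=True)
class EmbedSpec:
    stem1_len: int = 4
    stem2_len: int = 4
    loop1: str = CONSENSUS_LOOP1
    loop2: str = CONSENSUS_LOOP2
    linker_len: int = 8
    with_terminator: bool = False
    # odd loop length: unpairing terminator stem pairs changes the loop in
    # steps of 2, so a 5-nt loop can never present a 6-nt pseudo motif loop
    terminator_loop_len: int = 5
    terminator_arm_extra: int = 4
    utract_len: int = 8
    position: int | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        assert len(self.loop1) == len(self.loop2)
        assert min(self.stem1_len, self.stem2_len, self.linker_len,
                   self.utract_len) >= 0


def _random_background(n: int, gc: float, rng) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(list(NT), size=n, p=p))


def build_motif(spec: EmbedSpec, rng=None) -> tuple[str, Candidate]:
    """The motif sequence described by *spec* plus its local placement."""
    rng = rng or np.random.default_rng(spec.seed)

    def stem(n, closing=("C", "G"), under=("A", "T")):
        pairs = []
        for i in range(n):  # outer -> inner
            if i == n - 1:
                pairs.append(closing)
            elif i == n - 2:
                pairs.append(under)
            else:
                pairs.append([("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
                             [rng.integers(4)])
        left = "".join(p[0] for p in pairs)
        right = "".join(p[1] for p in reversed(pairs))
        return left, right

    l1, r1 = stem(spec.stem1_len)
    l2, r2 = stem(spec.stem2_len, closing=("C", "G"), under=("G", "C"))
    linker = "A" * spec.linker_len
    motif = l1 + to_dna(spec.loop1) + r1 + linker + l2 + to_dna(spec.loop2) + r2
    cand = Candidate(start=0, s1=spec.stem1_len, linker_len=spec.linker_len,
                     s2=spec.stem2_len, loop_len=len(spec.loop1))
    return motif, cand


def _terminator_block(p2_right: str, spec: EmbedSpec, rng) -> str:
    """Terminator continuation: the hairpin 5' arm reuses the P2 3' arm."""
    # A/T-rich extension: the shared GC-rich motif arm already carries the
    # hairpin over threshold, and A/T extension bases cannot cross-pair with
    # the G/C-rich motif elements to create spurious motif registrations
    extra = "".join(["A", "T"][rng.integers(2)] for _ in range(spec.terminator_arm_extra))
    left = p2_right + extra
    loop = "".join("TTCGA"[i % 5] for i in range(spec.terminator_loop_len))
    return extra + loop + revcomp(left) + "T" * spec.utract_len


def embed_dual_hairpin(spec: EmbedSpec, background_len: int = 400,
                       gc: float = 0.5, seed: int | None = None,
                       seqid: str = "synthetic") -> tuple[SequenceRecord, dict]:
    """Embed exactly one compliant motif in an i.i.d. background.

    Returns the sequence and a truth record with the motif placement (and
    terminator coordinates when requested).  Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    motif, local = build_motif(spec, rng)
    tail = ""
    if spec.with_terminator:
        p2_right = motif[len(motif) - spec.stem2_len:]
        tail = _terminator_block(p2_right, spec, rng)
    footprint = len(motif) + len(tail)
    if footprint + 2 > background_len:
        raise ValueError(
            f"motif footprint {footprint} does not fit in background of "
            f"{background_len} nt"
        )
    if spec.position == "random":
        offset = int(rng.integers(1, background_len - footprint - 1))
    else:
        offset = int(spec.position)
        if not 1 <= offset <= background_len - footprint - 1:
            raise ValueError("explicit position leaves no room for the element")
    bg = _random_background(background_len, gc, rng)
    bg[offset:offset + footprint] = list(motif + tail)
    # non-pairing guards so the embedded stems cannot extend into background
    bg[offset - 1] = "A"
    if not spec.with_terminator and offset + footprint < background_len:
        bg[offset + footprint] = "A"
    seq = SequenceRecord(id=seqid, residues="".join(bg))
    cand = Candidate(start=offset + local.start, s1=local.s1,
                     linker_len=local.linker_len, s2=local.s2,
                     loop_len=local.loop_len)
    truth = {"placement": cand, "spans": cand.spans, "start": cand.start,
             "end": cand.end, "with_terminator": spec.with_terminator}
    if spec.with_terminator:
        hp_left_start = cand.end - spec.stem2_len
        arm = spec.stem2_len + spec.terminator_arm_extra
        truth["terminator"] = {
            "left_arm": (hp_left_start, hp_left_start + arm),
            "loop": (hp_left_start + arm,
                     hp_left_start + arm + spec.terminator_loop_len),
            "right_arm": (hp_left_start + arm + spec.terminator_loop_len,
                          hp_left_start + 2 * arm + spec.terminator_loop_len),
            "utract": (hp_left_start + 2 * arm + spec.terminator_loop_len,
                       hp_left_start + 2 * arm + spec.terminator_loop_len
                       + spec.utract_len),
        }
    return seq, truth


# ---------------------------------------------------------------------------
# Whole-genome fixtures

DECOY_CLASSES = ("single_hairpin", "shuffled_loops", "two_bp_stem",
                 "linker_out_of_range")


def _decoy(kind: str, rng) -> str:
    """A decoy element of the named class (designed to be rejected)."""
    base = EmbedSpec()
    if kind == "single_hairpin":
        motif, _ = build_motif(base, rng)
        p1 = base.stem1_len * 2 + len(base.loop1)
        return motif[:p1]
    if kind == "shuffled_loops":
        # loops violating the A1/G4 consensus at both conserved positions
        def bad_loop():
            l = [NT[rng.integers(4)] for _ in range(6)]
            l[0] = "CGT"[rng.integers(3)]   # not A
            l[3] = "ACT"[rng.integers(3)]   # not G
            return "".join(l)
        spec = EmbedSpec(loop1=bad_loop(), loop2=bad_loop())
        return build_motif(spec, rng)[0]
    if kind == "two_bp_stem":
        spec = EmbedSpec(stem1_len=2, stem2_len=2)
        return build_motif(spec, rng)[0]
    if kind == "linker_out_of_range":
        # 3-bp stems so the out-of-range linker cannot be absorbed by a
        # stem re-registering as its inner sub-stem
        spec = EmbedSpec(stem1_len=3, stem2_len=3,
                         linker_len=(3, 14)[rng.integers(2)])
        return build_motif(spec, rng)[0]
    raise ValueError(f"unknown decoy class {kind!r}")


_ELEMENT_GAP = 15  # > widest linker window, so elements cannot couple
_SCREEN_MARGIN = 1.0  # bits of slack around the 10-bit reporting cutoff


def _element_is_clean(element: str, motif_len: int | None, model,
                      threshold: float) -> bool:
    """True if the isolated element produces only the expected hit.

    The element is padded with non-pairing A runs; an element whose
    expectation is "no hit" must produce none, and a true motif must
    produce hits only over its motif part (the terminator tail may not
    spawn extra placements).
    """
    from .motif import scan_sequence as _scan

    pad = "A" * (_ELEMENT_GAP + 2)
    rec = SequenceRecord(id="element", residues=pad + element + pad)
    hits = _scan(model, rec, threshold=threshold, background="uniform")
    lo = len(pad)
    hi = lo + (motif_len if motif_len is not None else 0)
    return all(h.strand == "+" and h.start < hi and lo < h.end for h in hits)


def generate_genome(n_motifs: int = 3, n_decoys: int = 10, n_genes: int = 4,
                    length: int = 8000, gc: float = 0.5, seed: int = 0,
                    with_terminator: bool = True, n_in_cds: int = 0,
                    genome_id: str = "synthetic_genome",
                    gene_len: int = 150, max_rounds: int = 40,
                    ) -> tuple[SequenceRecord, list[GeneFeature], pd.DataFrame]:
    """A screened synthetic genome with embedded motifs, decoys and CDS.

    True motifs land in intergenic space (each optionally coupled to a
    downstream intrinsic terminator); decoys cycle through the four decoy
    classes; ``n_in_cds`` extra motifs sit inside coding regions to
    exercise the in-coding discard rule.  Returns the sequence, the gene
    features, and a truth table listing every embedded element.

    The generator guarantees its own truth table: every background region
    is rejection-resampled (deterministically, from seeds derived from
    ``seed``) until a reference scan of the assembled genome yields a hit
    over every embedded motif, no hit anywhere else at a threshold one bit
    below the reporting cutoff, and a linkable terminator for every
    motif-terminator couple.  It raises ``RuntimeError`` if no clean
    assembly is found within ``max_rounds`` resampling rounds.
    """
    from .classify import link_terminator
    from .motif import scan_sequence, train_model
    from .terminator import find_terminators

    rng = np.random.default_rng(seed)
    total_cds = n_genes * gene_len
    if total_cds >= length:
        raise ValueError("genes do not fit in the requested genome length")
    seg_len = (length - total_cds) // (n_genes + 1)
    if seg_len < 60:
        raise ValueError("intergenic segments too short for element packing")

    # region skeleton: [intergenic][CDS] ... [intergenic]; the division
    # remainder extends the final intergenic region
    regions: list[dict] = []
    features: list[GeneFeature] = []
    cursor = 0
    for g in range(n_genes + 1):
        regions.append({"kind": "intergenic", "start": cursor,
                        "end": cursor + seg_len, "elements": []})
        cursor += seg_len
        if g < n_genes:
            features.append(GeneFeature(
                seqid=genome_id, start=cursor, end=cursor + gene_len,
                strand="+", kind="CDS",
                attributes={"locus_tag": f"LT{g + 1:04d}",
                            "product": "hypothetical protein"},
            ))
            regions.append({"kind": "cds", "start": cursor,
                            "end": cursor + gene_len, "elements": []})
            cursor += gene_len
    regions[-1]["end"] = length

    screen_model = train_model(synthetic_seed_alignment())
    screen_threshold = 10.0 - _SCREEN_MARGIN
    segments = [r for r in regions if r["kind"] == "intergenic"]
    genes = [r for r in regions if r["kind"] == "cds"]

    def build_clean(maker, motif_len_of, retries: int = 20):
        """Draw elements from the master rng until one is self-clean."""
        for _ in range(retries):
            element, motif_len = maker()
            if _element_is_clean(element, motif_len_of(element, motif_len),
                                 screen_model, screen_threshold):
                return element, motif_len
        raise RuntimeError("could not draw a self-clean synthetic element")

    for m in range(n_motifs):
        def make_motif():
            spec = EmbedSpec(with_terminator=with_terminator,
                             linker_len=int(rng.integers(5, 13)))
            motif, _ = build_motif(spec, rng)
            tail = _terminator_block(motif[-spec.stem2_len:], spec, rng) \
                if with_terminator else ""
            return motif + tail, len(motif)
        element, motif_len = build_clean(make_motif, lambda e, ml: ml)
        seg = m % len(segments)
        if seg == len(segments) - 1 and n_genes > 0:
            seg = 0  # keep true motifs upstream of a gene where possible
        segments[seg]["elements"].append({
            "element_id": f"motif{m + 1}", "kind": "motif", "seq": element,
            "motif_len": motif_len, "with_terminator": with_terminator,
            "expected": "hit"})
    for d in range(n_decoys):
        kind = DECOY_CLASSES[d % len(DECOY_CLASSES)]
        element, _ = build_clean(lambda: (_decoy(kind, rng), None),
                                 lambda e, ml: None)
        seg = (d + n_motifs) % len(segments)
        segments[seg]["elements"].append({
            "element_id": f"decoy{d + 1}", "kind": kind, "seq": element,
            "motif_len": None, "with_terminator": False, "expected": "no_hit"})
    for c in range(n_in_cds):
        if n_genes == 0:
            raise ValueError("n_in_cds requires at least one gene")
        def make_plain():
            return build_motif(EmbedSpec(), rng)[0], None
        element, _ = build_clean(make_plain, lambda e, ml: len(e))
        if len(element) + 2 * _ELEMENT_GAP > gene_len:
            raise ValueError("gene too short to host an in-CDS motif")
        genes[c % n_genes]["elements"].append({
            "element_id": f"in_cds{c + 1}", "kind": "motif_in_cds",
            "seq": element, "motif_len": len(element),
            "with_terminator": False, "expected": "discarded"})

    for r in regions:
        need = 5 + sum(len(e["seq"]) + 7 + _ELEMENT_GAP for e in r["elements"])
        if need + 2 > r["end"] - r["start"]:
            raise ValueError("infeasible packing: region overflow")

    def realize(region: dict, idx: int, attempt: int):
        """Background + element placement for one region (local coords)."""
        rng_r = np.random.default_rng([seed, idx, attempt])
        rlen = region["end"] - region["start"]
        content = _random_background(rlen, gc, rng_r)
        offsets = []
        cursor_l = 5
        for e in region["elements"]:
            offset = cursor_l + int(rng_r.integers(0, 8))
            end = offset + len(e["seq"])
            content[offset:end] = list(e["seq"])
            # non-pairing guards so embedded stems cannot extend outwards
            content[offset - 1] = "A"
            if end < rlen:
                content[end] = "A"
            offsets.append(offset)
            cursor_l = end + _ELEMENT_GAP
        return content, offsets

    contents = [None] * len(regions)
    offsets = [None] * len(regions)
    attempts = [0] * len(regions)
    for i, r in enumerate(regions):
        contents[i], offsets[i] = realize(r, i, 0)

    def region_at(pos: int) -> int:
        for i, r in enumerate(regions):
            if r["start"] <= pos < r["end"]:
                return i
        return len(regions) - 1

    for _round in range(max_rounds):
        genome = SequenceRecord(
            id=genome_id, residues="".join("".join(c) for c in contents))
        placed = []  # (region_idx, element, genome_start, motif_end)
        for i, r in enumerate(regions):
            for e, off in zip(r["elements"], offsets[i]):
                g0 = r["start"] + off
                ml = e["motif_len"] if e["motif_len"] is not None else 0
                placed.append((i, e, g0, g0 + ml))
        motif_spans = [(g0, gm) for (_i, e, g0, gm) in placed
                       if e["kind"] in ("motif", "motif_in_cds")]

        hits = scan_sequence(screen_model, genome, threshold=screen_threshold)
        bad: set[int] = set()
        for h in hits:
            if not any(h.start < gm and g0 < h.end for g0, gm in motif_spans):
                bad.add(region_at(h.start))
                bad.add(region_at(max(h.start, h.end - 1)))
        for i, e, g0, gm in placed:
            if e["kind"] in ("motif", "motif_in_cds"):
                if not any(h.strand == "+" and h.score >= 10.0
                           and h.start < gm and g0 < h.end for h in hits):
                    bad.add(i)
        if not bad and with_terminator:
            terms = find_terminators(genome)
            for i, e, g0, gm in placed:
                if e["kind"] == "motif" and e["with_terminator"]:
                    best = max((h for h in hits
                                if h.strand == "+" and h.start < gm and g0 < h.end),
                               key=lambda h: h.score)
                    if link_terminator(best, terms) is None:
                        bad.add(i)
        if not bad:
            break
        for i in bad:
            attempts[i] += 1
            contents[i], offsets[i] = realize(regions[i], i, attempts[i])
    else:
        raise RuntimeError(
            f"no clean synthetic genome within {max_rounds} resampling rounds")

    truth_rows = []
    order = {"motif": 0, "motif_in_cds": 2}
    def _num(eid: str) -> int:
        return int("".join(c for c in eid if c.isdigit()) or 0)
    for i, e, g0, gm in sorted(
            placed, key=lambda t: (order.get(t[1]["kind"], 1),
                                   _num(t[1]["element_id"]))):
        truth_rows.append({
            "element_id": e["element_id"], "kind": e["kind"],
            "start": g0,
            "end": gm if e["kind"] in ("motif", "motif_in_cds")
            else g0 + len(e["seq"]),
            "with_terminator": e["with_terminator"],
            "expected": e["expected"],
        })
    return genome, features, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Mutant series

def mutant_series(wild_type: SequenceRecord | None = None,
                  truth: Candidate | None = None) -> list[tuple[str, SequenceRecord]]:
    """Named loss/gain-of-function variants of a dual-hairpin leader.

    Defaults to the synthetic eutP-frame leader.  The series mirrors the
    classic reporter-fusion panel: P1 deletion, a single P2 stem break,
    each conserved loop residue (positions 1 and 4 of L1 and L2), a P1
    stem disruption with and without compensatory restoration, a
    closing-pair sequence swap that preserves pairing, too-short and
    too-long linkers, and oligo-U loops.
    """
    if wild_type is None:
        wild_type = eutp_leader_record()
        truth = EUTP_TRUTH
    if truth is None:
        raise ValueError("truth placement required for a custom wild type")
    s = wild_type.residues
    spans = truth.spans

    def edit(positions_bases: dict[int, str]) -> str:
        out = list(s)
        for pos, b in positions_bases.items():
            out[pos] = b
        return "".join(out)

    def rec(name: str, residues: str) -> tuple[str, SequenceRecord]:
        return name, SequenceRecord(id=f"{wild_type.id}|{name}", residues=residues)

    p1l, l1 = spans["p1_left"], spans["l1"]
    p1r, link = spans["p1_right"], spans["linker"]
    p2l, l2 = spans["p2_left"], spans["l2"]
    p2r = spans["p2_right"]
    out = [("wild_type", wild_type)]

    out.append(rec("delta_P1", s[:p1l[0]] + s[p1r[1]:]))

    # single P2 stem break: left-arm base two in from the closing pair is
    # replaced by its partner base (self-pairs are never legal)
    pos = p2l[1] - 2
    partner = s[p2r[0] + 1]
    out.append(rec("p2_stem_break", edit({pos: partner})))

    out.append(rec("l1_pos1_A_to_U", edit({l1[0]: "T"})))
    out.append(rec("l1_pos4_G_to_A", edit({l1[0] + 3: "A"})))
    out.append(rec("l2_pos1_A_to_U", edit({l2[0]: "T"})))
    out.append(rec("l2_pos4_G_to_A", edit({l2[0] + 3: "A"})))

    # disrupt the two outermost P1 left-arm bases; restore re-pairs them
    d_edit = {p1l[0]: _WC[s[p1l[0]]], p1l[0] + 1: _WC[s[p1l[0] + 1]]}
    out.append(rec("stem_disrupt", edit(d_edit)))
    r_edit = dict(d_edit)
    r_edit[p1r[1] - 1] = _WC[d_edit[p1l[0]]]
    r_edit[p1r[1] - 2] = _WC[d_edit[p1l[0] + 1]]
    out.append(rec("stem_restore", edit(r_edit)))

    # swap the bases of the two closing P1 pairs: sequence changes, pairing kept
    swap = {
        p1l[1] - 1: s[p1r[0]], p1r[0]: s[p1l[1] - 1],
        p1l[1] - 2: s[p1r[0] + 1], p1r[0] + 1: s[p1l[1] - 2],
    }
    out.append(rec("closing_pair_swap", edit(swap)))

    d = link[1] - link[0]
    out.append(rec("linker_3nt", s[:link[0] + 3] + s[link[1]:]))
    out.append(rec("linker_14nt", s[:link[1]] + "A" * (14 - d) + s[link[1]:]))

    oligo_u = {p: "T" for p in range(l1[0], l1[1])}
    oligo_u.update({p: "T" for p in range(l2[0], l2[1])})
    out.append(rec("loops_to_oligoU", edit(oligo_u)))
    return out


# expected outcome of each variant under default scan settings:
#   no_placement - the element admits no structurally legal placement
#   below_cutoff - a (possibly shifted) placement survives but scores < 10 bits
#   hit_lower    - still a hit, strictly outscored by the wild type
MUTANT_EXPECTATIONS = {
    "wild_type": "hit",
    "delta_P1": "no_placement",
    "p2_stem_break": "no_placement",
    "l1_pos1_A_to_U": "hit_lower",
    "l1_pos4_G_to_A": "hit_lower",
    "l2_pos1_A_to_U": "hit_lower",
    "l2_pos4_G_to_A": "hit_lower",
    # the conserved closing pairs plus loop A1 always admit a one-shifted
    # registration untouched by the outer-pair disruption, so a (heavily
    # penalised) placement survives
    "stem_disrupt": "hit_lower",
    "stem_restore": "hit_lower",
    "closing_pair_swap": "hit_lower",
    "linker_3nt": "below_cutoff",
    "linker_14nt": "no_placement",
    "loops_to_oligoU": "below_cutoff",
}


# ---------------------------------------------------------------------------
# Binding titrations

def simulate_isotherm(kd: float, concentrations, noise_sd: float = 0.05,
                      seed: int = 0, label: str = "") -> BindingCurve:
    """Single-site titration with multiplicative Gaussian noise.

    Bound fractions are ``f(c) * (1 + e)``, e ~ N(0, noise_sd), clipped to
    [0, 1]; reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    f = fraction_bound(kd, conc)
    if noise_sd > 0:
        f = f * (1.0 + rng.normal(0.0, noise_sd, size=conc.shape))
    f = np.clip(f, 0.0, 1.0)
    return BindingCurve(concentrations=conc, fraction_bound=f, label=label)
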