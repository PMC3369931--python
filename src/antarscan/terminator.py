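"""De novo prediction of rho-independent (intrinsic) transcription terminators.

An intrinsic terminator is a GC-rich hairpin followed by a run of uridines.
The screen here is a deterministic additive one: stem pairs score by a
small table (G-C strongest, then A-U, then G-U wobble; mismatches penalised)
and the downstream U-tract scores by geometrically weighted U-richness so
that uridines closest to the hairpin matter most.  Both scores must clear
their thresholds for a placement to be reported.  The terminal loop may be
unusually large (up to 26 nt by default) because antiterminator-coupled
terminators can carry the upstream element's arm inside the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import SequenceRecord, revcomp, to_dna

__all__ = [
    "TerminatorParams",
    "TerminatorHit",
    "score_hairpin",
    "score_utract",
    "find_terminators",
]

_DEFAULT_PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}


@dataclass(frozen=True)
class TerminatorParams:
    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 26
    max_mismatches: int = 1
    mismatch_score: float = -2.0
    pair_scores: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_SCORES))
    tail_window: int = 12
    tail_decay: float = 0.9
    hairpin_min_score: float = 8.0
    tail_min_score: float = 3.0

    def __post_init__(self) -> None:
        assert self.loop_max >= self.loop_min and self.stem_max >= self.stem_min
        assert 0.0 < self.tail_decay <= 1.0


@dataclass(frozen=True)
class TerminatorHit:
    """A predicted intrinsic terminator on the forward strand.

    ``left_arm`` is the hairpin arm that is 5' in transcript orientation
    (for minus-strand hits the spans are still forward-strand coordinates,
    with ``left_arm`` the rightmost arm on the forward strand).
    """

    seqid: str
    strand: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop: tuple[int, int]
    utract: tuple[int, int]
    hairpin_score: float
    tail_score: float

    @property
    def total_score(self) -> float:
        return self.hairpin_score + self.tail_score

    @property
    def start(self) -> int:
        return min(self.left_arm[0], self.right_arm[0], self.utract[0])

    @property
    def end(self) -> int:
        return max(self.left_arm[1], self.right_arm[1], self.utract[1])

    @property
    def loop_len(self) -> int:
        return self.loop[1] - self.loop[0]

    @property
    def hairpin_span(self) -> tuple[int, int]:
        return (min(self.left_arm[0], self.right_arm[0]),
                max(self.left_arm[1], self.right_arm[1]))


def score_hairpin(left: str, right: str,
                  params: TerminatorParams | None = None) -> float:
    """Additive pair score of two equal-length arms (right arm read reversed)."""
    params = params or TerminatorParams()
    left, right = to_dna(left), to_dna(right)
    if len(left) != len(right):
        raise ValueError(f"arm lengths differ: {len(left)} vs {len(right)}")
    total = 0.0
    for a, b in zip(left, reversed(right)):
        total += params.pair_scores.get((a, b), params.mismatch_score)
    return total


def _count_mismatches(left: str, right: str, params: TerminatorParams) -> int:
    return sum(1 for a, b in zip(left, reversed(right))
               if (a, b) not in params.pair_scores)


def score_utract(downstream: str, tail_window: int = 12,
                 tail_decay: float = 0.9) -> float:
    """Geometrically weighted U-richness of the residues 3' of the hairpin."""
    s = to_dna(downstream)
    return sum(tail_decay ** i
               for i in range(min(tail_window, len(s)))
               if s[i] == "T")


def _enumerate_strand(s: str, params: TerminatorParams) -> list[dict]:
    """All above-threshold placements on one strand (local coordinates).

    Hairpin end positions are pre-filtered by the U-tract score, which is
    by far the sparsest of the three filters; only qualifying ends are
    expanded into (start, stem, loop) combinations.
    """
    n = len(s)
    tail_at = [score_utract(s[p:p + params.tail_window], params.tail_window,
                            params.tail_decay) for p in range(n + 1)]
    good_ends = [p for p in range(n + 1) if tail_at[p] >= params.tail_min_score]
    out = []
    for end in good_ends:
        for stem in range(params.stem_min, params.stem_max + 1):
            for loop in range(params.loop_min, params.loop_max + 1):
                i = end - 2 * stem - loop
                if i < 0:
                    continue
                left = s[i:i + stem]
                right = s[end - stem:end]
                if any(c not in "ACGT" for c in s[i:end]):
                    continue
                if _count_mismatches(left, right, params) > params.max_mismatches:
                    continue
                hp = score_hairpin(left, right, params)
                if hp < params.hairpin_min_score:
                    continue
                out.append({
                    "left_arm": (i, i + stem),
                    "loop": (i + stem, end - stem),
                    "right_arm": (end - stem, end),
                    "utract": (end, min(end + params.tail_window, n)),
                    "hairpin_score": hp,
                    "tail_score": tail_at[end],
                })
    out.sort(key=lambda r: (r["left_arm"], r["right_arm"]))
    return out


def _deduplicate(hits: list[TerminatorHit]) -> list[TerminatorHit]:
    """Per-strand overlap resolution by total score; ties leftmost, then
    smaller loop.  Strands are resolved independently: downstream linkage
    is same-strand, so an antisense structure must never displace the
    sense-strand terminator of a locus."""
    kept: list[TerminatorHit] = []
    for strand in ("+", "-"):
        ranked = sorted((h for h in hits if h.strand == strand),
                        key=lambda h: (-h.total_score, h.start, h.loop_len))
        for h in ranked:
            span = h.hairpin_span
            if all(span[1] <= k.hairpin_span[0] or span[0] >= k.hairpin_span[1]
                   for k in kept if k.strand == strand):
                kept.append(h)
    return kept


def find_terminators(seq: SequenceRecord, params: TerminatorParams | None = None,
                     both_strands: bool = True,
                     deduplicate: bool = True) -> list[TerminatorHit]:
    """Predict intrinsic terminators on a sequence.

    Returns every placement whose hairpin and tail scores clear their
    thresholds; overlapping placements are resolved by total score.
    Coordinates are forward-strand with a strand flag.
    """
    params = params or TerminatorParams()
    s = seq.residues
    n = len(s)
    hits: list[TerminatorHit] = []
    strands = [("+", s)]
    if both_strands:
        strands.append(("-", revcomp(s)))
    for strand, strand_seq in strands:
        for raw in _enumerate_strand(strand_seq, params):
            if strand == "-":
                raw = {k: ((n - v[1], n - v[0]) if isinstance(v, tuple) else v)
                       for k, v in raw.items()}
            hits.append(TerminatorHit(seqid=seq.id, strand=strand, **raw))
    if deduplicate:
        hits = _deduplicate(hits)
    hits.sort(key=lambda h: (h.seqid, h.start))
    return hits
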