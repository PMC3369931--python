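"""Probabilistic dual stem-loop (antiterminator) motif model and scanner.

The ANTAR substrate element is a fixed-topology RNA motif: two short
hairpins (P1, P2) with hexanucleotide terminal loops (L1, L2), joined by a
variable-length single-stranded linker.  Because the topology never varies,
a full stochastic context-free grammar is unnecessary: the model is a
position-specific log-odds scorer over loop residues, stem base pairs
(joint 16-state distributions, so covariation in the stems is captured) and
linker length, and the scanner enumerates every structurally legal
placement directly.

Scores are in bits: log2 of the probability of the candidate under the
motif model over its probability under a mononucleotide background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import SequenceRecord, StructuredAlignment, revcomp, to_dna, to_rna

__all__ = [
    "DualHairpinModel",
    "MotifHit",
    "Candidate",
    "TrainingError",
    "train_model",
    "enumerate_candidates",
    "score_candidate",
    "scan_sequence",
    "match_consensus_pattern",
    "WATSON_CRICK",
    "WOBBLE",
]

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}

WATSON_CRICK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "T"), ("T", "G")}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a seed alignment cannot support model training."""


def _legal_pairs(allow_gu: bool) -> frozenset[tuple[str, str]]:
    return frozenset(WATSON_CRICK | WOBBLE) if allow_gu else frozenset(WATSON_CRICK)


@dataclass
class DualHairpinModel:
    """Trained emission and length model for the two-hairpin motif.

    ``stem1_pairs``/``stem2_pairs`` hold one 4x4 joint distribution per
    trained pair column, ordered outermost to innermost (the last entry is
    the conserved closing pair).  ``generic_pair`` is the pooled pair
    distribution used for candidate stems longer than the trained columns.

    ``linker_min``/``linker_max`` bound the linker lengths the scanner
    enumerates (default: the observed seed range).  ``linker_probs`` is the
    smoothed length distribution over the slightly wider support starting
    at ``linker_support_min``, so small excursions beyond the observed
    range can still be scored when the bounds are widened by hand.
    """

    loop1_em: np.ndarray
    loop2_em: np.ndarray
    stem1_pairs: np.ndarray
    stem2_pairs: np.ndarray
    generic_pair: np.ndarray
    linker_probs: np.ndarray
    linker_min: int
    linker_max: int
    linker_support_min: int
    background: np.ndarray
    pseudocount: float = 0.5
    min_stem: int = 3
    stem_max: int = 8
    loop_len: int = 6
    allow_gu: bool = True

    def __post_init__(self) -> None:
        for arr in ("loop1_em", "loop2_em", "stem1_pairs", "stem2_pairs",
                    "generic_pair", "linker_probs", "background"):
            object.__setattr__(self, arr, np.asarray(getattr(self, arr), dtype=float))
        assert self.min_stem >= 1 and self.loop_len >= 3
        for em in (self.loop1_em, self.loop2_em):
            assert em.shape == (self.loop_len, 4)
            assert np.allclose(em.sum(axis=1), 1.0, atol=1e-9)
        for pm in (self.stem1_pairs, self.stem2_pairs):
            assert pm.ndim == 3 and pm.shape[1:] == (4, 4)
            assert np.allclose(pm.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert abs(self.linker_probs.sum() - 1.0) < 1e-9

    # -- convenience -------------------------------------------------------
    @property
    def legal_pairs(self) -> frozenset[tuple[str, str]]:
        return _legal_pairs(self.allow_gu)

    def consensus_motif(self) -> str:
        """Highest-emission sequence of the motif (RNA), with the most
        probable linker length filled with the most common background base."""
        def stem_arms(pm):
            lefts, rights = [], []
            for dist in pm:  # outer -> inner
                a, b = np.unravel_index(np.argmax(dist), (4, 4))
                lefts.append(NT[a])
                rights.append(NT[b])
            return "".join(lefts), "".join(reversed(rights))
        s1l, s1r = stem_arms(self.stem1_pairs)
        s2l, s2r = stem_arms(self.stem2_pairs)
        l1 = "".join(NT[j] for j in np.argmax(self.loop1_em, axis=1))
        l2 = "".join(NT[j] for j in np.argmax(self.loop2_em, axis=1))
        d = self.linker_support_min + int(np.argmax(self.linker_probs))
        d = min(max(d, self.linker_min), self.linker_max)
        filler = NT[int(np.argmax(self.background))] * d
        return to_rna(s1l + l1 + s1r + filler + s2l + l2 + s2r)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "loop1_em": self.loop1_em.tolist(),
            "loop2_em": self.loop2_em.tolist(),
            "stem1_pairs": self.stem1_pairs.tolist(),
            "stem2_pairs": self.stem2_pairs.tolist(),
            "generic_pair": self.generic_pair.tolist(),
            "linker_probs": self.linker_probs.tolist(),
            "linker_min": self.linker_min,
            "linker_max": self.linker_max,
            "linker_support_min": self.linker_support_min,
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
            "min_stem": self.min_stem,
            "stem_max": self.stem_max,
            "loop_len": self.loop_len,
            "allow_gu": self.allow_gu,
        }
        return json.dumps(payload, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "DualHairpinModel":
        d = json.loads(text)
        version = d.pop("format_version", None)
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "DualHairpinModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class Candidate:
    """One structurally legal placement, before scoring (forward coords)."""

    start: int
    s1: int
    linker_len: int
    s2: int
    loop_len: int = 6

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        i, s1, d, s2, L = self.start, self.s1, self.linker_len, self.s2, self.loop_len
        a = i + 2 * s1 + L + d
        return {
            "p1_left": (i, i + s1),
            "l1": (i + s1, i + s1 + L),
            "p1_right": (i + s1 + L, i + 2 * s1 + L),
            "linker": (i + 2 * s1 + L, a),
            "p2_left": (a, a + s2),
            "l2": (a + s2, a + s2 + L),
            "p2_right": (a + s2 + L, a + 2 * s2 + L),
        }

    @property
    def end(self) -> int:
        return self.start + 2 * self.s1 + 2 * self.s2 + 2 * self.loop_len + self.linker_len


@dataclass(frozen=True)
class MotifHit:
    """A scored motif placement, with forward-strand coordinates."""

    seqid: str
    strand: str
    p1_left: tuple[int, int]
    l1: tuple[int, int]
    p1_right: tuple[int, int]
    linker: tuple[int, int]
    p2_left: tuple[int, int]
    l2: tuple[int, int]
    p2_right: tuple[int, int]
    score: float
    subsequence: str
    l1_seq: str = ""
    l2_seq: str = ""

    @property
    def start(self) -> int:
        return min(self.p1_left[0], self.p2_right[0])

    @property
    def end(self) -> int:
        return max(self.p1_left[1], self.p2_right[1])

    @property
    def p2_footprint(self) -> tuple[int, int]:
        """Span from the start of P2's first arm to the end of its last."""
        return (min(self.p2_left[0], self.p2_right[0]),
                max(self.p2_left[1], self.p2_right[1]))


# ---------------------------------------------------------------------------
# Training

def _column_counts(rows: list[str], col: int) -> np.ndarray:
    counts = np.zeros(4)
    for seq in rows:
        c = seq[col]
        if c in NT_INDEX:
            counts[NT_INDEX[c]] += 1
    return counts


def train_model(
    aln: StructuredAlignment,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    min_stem: int = 3,
    stem_max: int = 8,
    allow_gu: bool = True,
    linker_bounds: tuple[int, int] | None = None,
) -> DualHairpinModel:
    """Estimate the dual-hairpin model from a structured seed alignment.

    Loop emissions are Laplace-smoothed per-column frequencies,
    ``(count + pc) / (total + 4 pc)``; stem pair columns use the joint
    16-state analogue.  The linker-length distribution is the empirical
    distribution of ungapped linker lengths, add-one smoothed over
    ``[observed_min - 1, observed_max + 1]`` (clipped to >= 1).  The
    scanner's enumeration bounds default to the observed range itself
    (override with ``linker_bounds``): a wider window would let a long
    stem re-register as its inner sub-stem and absorb out-of-range linkers.
    """
    if aln.n_rows < 2:
        raise TrainingError(f"need at least 2 alignment rows, got {aln.n_rows}")
    if len(aln.stem1_pairs) < min_stem or len(aln.stem2_pairs) < min_stem:
        raise TrainingError(
            f"each stem block needs >= {min_stem} paired columns "
            f"(got {len(aln.stem1_pairs)} and {len(aln.stem2_pairs)})"
        )
    loop_len = len(aln.loop1_cols)
    if len(aln.loop2_cols) != loop_len:
        raise TrainingError("the two loop blocks have different widths")

    rows = [to_dna(seq) for _, seq in aln.rows]
    pc = float(pseudocount)

    def loop_em(cols):
        em = np.empty((len(cols), 4))
        for k, col in enumerate(cols):
            counts = _column_counts(rows, col)
            em[k] = (counts + pc) / (counts.sum() + 4 * pc)
        return em

    def pair_counts(i, j):
        counts = np.zeros((4, 4))
        for seq in rows:
            a, b = seq[i], seq[j]
            if a in NT_INDEX and b in NT_INDEX:
                counts[NT_INDEX[a], NT_INDEX[b]] += 1
        return counts

    def stem_em(pairs):
        em = np.empty((len(pairs), 4, 4))
        for k, (i, j) in enumerate(pairs):  # outermost first
            counts = pair_counts(i, j)
            em[k] = (counts + pc) / (counts.sum() + 16 * pc)
        return em

    pooled = np.zeros((4, 4))
    for i, j in aln.stem1_pairs + aln.stem2_pairs:
        pooled += pair_counts(i, j)
    generic = (pooled + pc) / (pooled.sum() + 16 * pc)

    lengths = [sum(1 for c in aln.linker_cols if seq[c] in NT_INDEX) for seq in rows]
    support_lo = max(1, min(lengths) - 1)
    support_hi = max(lengths) + 1
    scan_lo, scan_hi = (max(1, min(lengths)), max(lengths))
    if linker_bounds is not None:
        scan_lo, scan_hi = linker_bounds
        support_lo = min(support_lo, scan_lo)
        support_hi = max(support_hi, scan_hi)
    counts = np.array([lengths.count(d) for d in range(support_lo, support_hi + 1)],
                      dtype=float)
    linker_probs = (counts + 1.0) / (counts.sum() + len(counts))

    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be a positive length-4 distribution")

    return DualHairpinModel(
        loop1_em=loop_em(aln.loop1_cols),
        loop2_em=loop_em(aln.loop2_cols),
        stem1_pairs=stem_em(aln.stem1_pairs),
        stem2_pairs=stem_em(aln.stem2_pairs),
        generic_pair=generic,
        linker_probs=linker_probs,
        linker_min=scan_lo,
        linker_max=scan_hi,
        linker_support_min=support_lo,
        background=bg,
        pseudocount=pc,
        min_stem=min_stem,
        stem_max=stem_max,
        loop_len=loop_len,
        allow_gu=allow_gu,
    )


# ---------------------------------------------------------------------------
# Enumeration

def _stem_run_ok(seq: str, left_start: int, right_end: int, s: int,
                 legal: frozenset) -> bool:
    """True if all s pairs (left_start+m, right_end-1-m) are legal."""
    for m in range(s):
        a, b = seq[left_start + m], seq[right_end - 1 - m]
        if (a, b) not in legal:
            return False
    return True


def enumerate_candidates(seq: SequenceRecord | str,
                         model: DualHairpinModel) -> list[Candidate]:
    """Every structurally legal placement of the motif on the given strand.

    A placement is legal when both stems have ``min_stem``..``stem_max``
    contiguous legal pairs, both loops are exactly ``loop_len`` nt, the
    linker length lies within the model's bounds, and no residue is reused.
    Windows containing a non-ACGT residue are skipped.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else to_dna(seq)
    n = len(s)
    L = model.loop_len
    legal = model.legal_pairs
    out: list[Candidate] = []
    min_s, max_s = model.min_stem, model.stem_max
    for i in range(n):
        for s1 in range(min_s, max_s + 1):
            p1_end = i + 2 * s1 + L
            if p1_end > n:
                break
            if not _stem_run_ok(s, i, p1_end, s1, legal):
                continue
            if any(c not in NT_INDEX for c in s[i + s1:i + s1 + L]):
                continue
            for d in range(model.linker_min, model.linker_max + 1):
                a = p1_end + d
                for s2 in range(min_s, max_s + 1):
                    end = a + 2 * s2 + L
                    if end > n:
                        break
                    if not _stem_run_ok(s, a, end, s2, legal):
                        continue
                    if any(c not in NT_INDEX for c in s[a + s2:a + s2 + L]):
                        continue
                    if any(c not in NT_INDEX for c in s[p1_end:a]):
                        continue
                    out.append(Candidate(start=i, s1=s1, linker_len=d, s2=s2,
                                         loop_len=L))
    return out


# ---------------------------------------------------------------------------
# Scoring

def score_candidate(model: DualHairpinModel, cand: Candidate,
                    seq: SequenceRecord | str,
                    background: np.ndarray | None = None) -> float:
    """Log-odds bit score of a placement: loops + stem pairs + linker length.

    Stem pairs are aligned to trained columns innermost-first (the closing
    pair always meets the trained closing-pair distribution); pairs beyond
    the trained depth score against the pooled generic-pair distribution.
    The linker term is ``log2(P(len) * W)`` where W is the width of the
    scanning window, so a flat trained length distribution contributes 0.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else to_dna(seq)
    if cand.loop_len != model.loop_len:
        raise ValueError("candidate loop length does not match the model")
    bg = model.background if background is None else np.asarray(background, float)
    log_bg = np.log2(bg)
    spans = cand.spans
    total = 0.0

    for em, key in ((model.loop1_em, "l1"), (model.loop2_em, "l2")):
        lo, hi = spans[key]
        for k in range(model.loop_len):
            b = NT_INDEX[s[lo + k]]
            total += np.log2(em[k, b]) - log_bg[b]

    for pm, left_key, right_key in (
        (model.stem1_pairs, "p1_left", "p1_right"),
        (model.stem2_pairs, "p2_left", "p2_right"),
    ):
        (ls, le) = spans[left_key]
        (rs, re_) = spans[right_key]
        slen = le - ls
        k = pm.shape[0]
        for m in range(slen):  # m = 0 is outermost
            a = NT_INDEX[s[ls + m]]
            b = NT_INDEX[s[re_ - 1 - m]]
            t = k - slen + m  # trained column, inner-aligned
            dist = pm[t] if t >= 0 else model.generic_pair
            total += np.log2(dist[a, b]) - (log_bg[a] + log_bg[b])

    d = cand.linker_len
    idx = d - model.linker_support_min
    if not (0 <= idx < len(model.linker_probs)):
        raise ValueError(f"linker length {d} outside the model's support")
    W = model.linker_max - model.linker_min + 1
    total += np.log2(model.linker_probs[idx] * W)
    return float(total)


# ---------------------------------------------------------------------------
# Scanning

def _candidate_to_hit(cand: Candidate, seqid: str, strand: str, s: str,
                      score: float, seq_len: int) -> MotifHit:
    spans = cand.spans
    sub = s[cand.start:cand.end]
    if strand == "-":
        # map reverse-complement coordinates back to the forward strand
        spans = {k: (seq_len - b, seq_len - a) for k, (a, b) in spans.items()}
    l1 = s[cand.spans["l1"][0]:cand.spans["l1"][1]]
    l2 = s[cand.spans["l2"][0]:cand.spans["l2"][1]]
    return MotifHit(
        seqid=seqid, strand=strand, score=score, subsequence=to_rna(sub),
        l1_seq=l1, l2_seq=l2, **spans,
    )


def _deduplicate(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy resolution of overlaps: best score, then leftmost, then longest."""
    ranked = sorted(hits, key=lambda h: (-h.score, h.start, -(h.end - h.start)))
    kept: list[MotifHit] = []
    for h in ranked:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    return kept


def scan_sequence(model: DualHairpinModel, seq: SequenceRecord,
                  threshold: float = 10.0, both_strands: bool = True,
                  background: str | np.ndarray = "sequence",
                  deduplicate: bool = True) -> list[MotifHit]:
    """Scan a sequence for motif hits with bit score >= threshold.

    ``background`` is either an explicit distribution, ``"sequence"`` (the
    scanned sequence's own mononucleotide frequencies), ``"model"`` or
    ``"uniform"``.  With ``both_strands`` the reverse complement is scanned
    too and coordinates are mapped back to the forward strand.
    """
    s = seq.residues
    if isinstance(background, str):
        if background == "sequence":
            counts = np.array([s.count(c) for c in NT], dtype=float)
            bg = (counts + 1.0) / (counts.sum() + 4.0)
        elif background == "model":
            bg = model.background
        elif background == "uniform":
            bg = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown background mode {background!r}")
    else:
        bg = np.asarray(background, dtype=float)

    hits: list[MotifHit] = []
    strands = [("+", s)]
    if both_strands:
        strands.append(("-", revcomp(s)))
    for strand, strand_seq in strands:
        for cand in enumerate_candidates(strand_seq, model):
            score = score_candidate(model, cand, strand_seq, background=bg)
            if score >= threshold:
                hits.append(_candidate_to_hit(cand, seq.id, strand, strand_seq,
                                              score, len(s)))
    if deduplicate:
        hits = _deduplicate(hits)
    hits.sort(key=lambda h: (h.seqid, h.start))
    return hits


# ---------------------------------------------------------------------------
# Degenerate consensus matching

def match_consensus_pattern(seq: SequenceRecord | str,
                            pattern: str = "AGCAANGRRGCUY") -> list[tuple[int, int]]:
    """All (possibly overlapping) spans matching an IUPAC degenerate pattern.

    The default is the 13-nt sequence shared by the eut leader attenuation
    sites.  U and T are equivalent on both sides.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else to_dna(seq)
    sets = []
    for c in pattern.upper():
        if c not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC code {c!r} in pattern")
        sets.append(IUPAC_SETS[c])
    m = len(sets)
    return [
        (i, i + m)
        for i in range(len(s) - m + 1)
        if all(s[i + j] in sets[j] for j in range(m))
    ]
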