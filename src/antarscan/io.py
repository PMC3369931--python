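"""Readers and writers for the formats the pipeline consumes and emits.

All coordinates are 0-based half-open on the forward strand internally;
GFF3's 1-based inclusive convention is converted exactly at the I/O edge.
Genomic sequences are stored as DNA (T); RNA input (U) is accepted and
mapped to T, and motif subsequences are printed back as RNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneFeature",
    "StructuredAlignment",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_structured_alignment",
    "write_structured_alignment",
    "write_hits",
    "read_hits_tsv",
    "to_rna",
    "to_dna",
    "revcomp",
]

IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

HIT_TSV_COLUMNS = [
    "seqid", "strand", "category", "discard_reason", "score",
    "start", "end",
    "p1_left_start", "p1_left_end", "l1_start", "l1_end",
    "p1_right_start", "p1_right_end", "linker_start", "linker_end",
    "p2_left_start", "p2_left_end", "l2_start", "l2_end",
    "p2_right_start", "p2_right_end",
    "l1_seq", "l2_seq", "subsequence",
    "terminator_start", "terminator_end", "terminator_score", "shared_nt",
    "downstream_gene", "distance_to_start", "rbs_overlap",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def to_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA alphabet internally)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        object.__setattr__(self, "residues", to_dna(self.residues))
        for i, c in enumerate(self.residues):
            if c not in IUPAC_NT:
                raise FormatError(
                    f"illegal residue {c!r} at position {i + 1} in record {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """A gene/CDS annotation with internal 0-based half-open coordinates."""

    seqid: str
    start: int
    end: int
    strand: str
    kind: str = "other"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature on {self.seqid} has start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand symbol {self.strand!r}")

    @property
    def locus_tag(self) -> str | None:
        v = self.attributes.get("locus_tag")
        return v if v else None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file; U is mapped to T, order preserved."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty body")
        records.append(SequenceRecord(id=rec.id, residues=seq, description=rec.description))
    if not records:
        raise FormatError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    ``gene`` and ``CDS`` keep their kind; every other feature type is
    tagged ``other``.
    """
    from gffutils.iterators import DataIterator

    features = []
    for f in DataIterator(str(path)):
        if f.start is None or f.end is None or f.start > f.end:
            raise FormatError(
                f"feature on line for {f.seqid!r} has start > end ({f.start} > {f.end})"
            )
        if f.strand not in ("+", "-"):
            raise FormatError(f"unknown strand symbol {f.strand!r} on {f.seqid!r}")
        kind = f.featuretype if f.featuretype in ("gene", "CDS") else "other"
        attrs = {k: v[0] if len(v) == 1 else ";".join(v) for k, v in f.attributes.items()}
        features.append(GeneFeature(
            seqid=f.seqid, start=f.start - 1, end=f.end, strand=f.strand,
            kind=kind, attributes=attrs,
        ))
    return features


def write_gff3_features(rows: Iterable[dict], path: str | Path) -> None:
    """Write generic GFF3 rows (internal coordinates) to *path*."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = ";".join(f"{k}={v}" for k, v in r.get("attributes", {}).items())
            fh.write("\t".join([
                r["seqid"], r.get("source", "antarscan"), r["type"],
                str(r["start"] + 1), str(r["end"]),
                f"{r['score']:.3f}" if r.get("score") is not None else ".",
                r.get("strand", "."), ".", attrs or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Structured (Stockholm-dialect) seed alignments

_PAIR_BRACKETS = {"<": ">", "(": ")"}


def _match_brackets(structure: str, open_ch: str, close_ch: str) -> list[tuple[int, int]]:
    """Pair columns for one bracket class, outermost first (stack matching)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == open_ch:
            stack.append(i)
        elif c == close_ch:
            if not stack:
                raise FormatError(
                    f"unbalanced {close_ch!r} at structure column {i}"
                )
            pairs.append((stack.pop(), i))
        elif c not in "<>()." :
            raise FormatError(f"illegal structure character {c!r} at column {i}")
    if stack:
        raise FormatError(f"unbalanced {open_ch!r} in structure line")
    # outermost pair has the smallest left index
    return sorted(pairs, key=lambda p: p[0])


def _contiguous(block: Sequence[int]) -> bool:
    return all(b - a == 1 for a, b in zip(block, block[1:]))


@dataclass
class StructuredAlignment:
    """A seed alignment plus a consensus-structure line.

    The structure line uses ``<``/``>`` for stem-1 pairs, ``(``/``)`` for
    stem-2 pairs and ``.`` for unpaired columns; the two hairpins must be
    non-crossing and appear in 5'-to-3' order.
    """

    rows: list[tuple[str, str]]
    structure_line: str

    # derived column sets, filled by __post_init__
    stem1_pairs: list[tuple[int, int]] = field(init=False)
    stem2_pairs: list[tuple[int, int]] = field(init=False)
    loop1_cols: list[int] = field(init=False)
    loop2_cols: list[int] = field(init=False)
    linker_cols: list[int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.structure_line)
        for name, seq in self.rows:
            if len(seq) != n:
                raise FormatError(
                    f"row {name!r} has length {len(seq)}, structure line has {n}"
                )
        s1 = _match_brackets(self.structure_line, "<", ">")
        s2 = _match_brackets(self.structure_line, "(", ")")
        if not s1 or not s2:
            raise FormatError("structure line must contain two stem blocks")
        # arms of each stem must be contiguous column runs (one block per arm)
        for pairs, label in ((s1, "stem 1"), (s2, "stem 2")):
            left = [p[0] for p in pairs]
            right = sorted(p[1] for p in pairs)
            if not (_contiguous(left) and _contiguous(right)):
                raise FormatError(f"{label} arms are not contiguous column blocks")
        if not s1[-1][1] < s2[0][0]:
            raise FormatError("stem blocks must appear in 5'-to-3' order without crossing")
        self.stem1_pairs = s1
        self.stem2_pairs = s2
        self.loop1_cols = list(range(s1[-1][0] + 1, s1[-1][1]))
        self.loop2_cols = list(range(s2[-1][0] + 1, s2[-1][1]))
        self.linker_cols = list(range(s1[0][1] + 1, s2[0][0]))

    @property
    def n_columns(self) -> int:
        return len(self.structure_line)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, index: int) -> str:
        """Row *index* with gaps removed, in DNA alphabet."""
        return to_dna(re.sub(r"[-.]", "", self.rows[index][1]))


def read_structured_alignment(path: str | Path) -> StructuredAlignment:
    """Read a Stockholm-dialect seed alignment with one consensus line."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as Stockholm: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise FormatError(f"{path} is missing the consensus structure (#=GC SS_cons) line")
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    return StructuredAlignment(rows=rows, structure_line=ss)


def write_structured_alignment(aln: StructuredAlignment, path: str | Path) -> None:
    width = max(len("#=GC SS_cons"),
                max(len(name) for name, _ in aln.rows)) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, seq in aln.rows:
            fh.write(f"{name:<{width}}{seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{aln.structure_line}\n//\n")


# ---------------------------------------------------------------------------
# Hit reports

def _hit_row(ch) -> dict:
    """Flatten a ClassifiedHit (or bare MotifHit) to one TSV row."""
    from .classify import ClassifiedHit  # local import avoids a cycle

    if not isinstance(ch, ClassifiedHit):
        ch = ClassifiedHit(motif=ch, category="orphan")
    m = ch.motif
    term = ch.linked_terminator
    row = {
        "seqid": m.seqid, "strand": m.strand,
        "category": ch.category, "discard_reason": ch.discard_reason or "",
        "score": m.score, "start": m.start, "end": m.end,
        "l1_seq": to_rna(m.l1_seq), "l2_seq": to_rna(m.l2_seq),
        "subsequence": m.subsequence,
        "terminator_start": term.start if term else "",
        "terminator_end": term.end if term else "",
        "terminator_score": term.total_score if term else "",
        "shared_nt": ch.shared_nt if term else "",
        "downstream_gene": (ch.downstream_gene.locus_tag or "") if ch.downstream_gene else "",
        "distance_to_start": ch.distance_to_start if ch.distance_to_start is not None else "",
        "rbs_overlap": int(ch.rbs_overlap),
    }
    for name in ("p1_left", "l1", "p1_right", "linker", "p2_left", "l2", "p2_right"):
        span = getattr(m, name)
        row[f"{name}_start"], row[f"{name}_end"] = span
    return row


def write_hits(hits, path: str | Path, format: str = "tsv") -> None:
    """Write classified (or bare motif) hits as TSV or GFF3.

    The GFF3 output is 1-based inclusive with the bit score in the score
    column; the TSV carries the full fixed column set and round-trips
    coordinates and scores exactly.
    """
    if format == "tsv":
        df = pd.DataFrame([_hit_row(h) for h in hits], columns=HIT_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "gff3":
        rows = []
        for h in hits:
            r = _hit_row(h)
            attrs = {
                "ID": f"{r['seqid']}:{r['start']}-{r['end']}",
                "category": r["category"],
                "loop1": r["l1_seq"], "loop2": r["l2_seq"],
            }
            if r["discard_reason"]:
                attrs["discard_reason"] = r["discard_reason"]
            if r["terminator_start"] != "":
                attrs["terminator"] = f"{r['terminator_start'] + 1}-{r['terminator_end']}"
            rows.append({
                "seqid": r["seqid"], "type": "ncRNA_motif",
                "start": r["start"], "end": r["end"],
                "score": r["score"], "strand": r["strand"], "attributes": attrs,
            })
        write_gff3_features(rows, path)
    else:
        raise ValueError(f"unknown hit format {format!r}")


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    """Read a hit TSV back into a DataFrame (coordinates as integers)."""
    return pd.read_csv(path, sep="\t", keep_default_na=False)
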