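import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antarscan.io import SequenceRecord, StructuredAlignment, revcomp
from antarscan.motif import (Candidate, DualHairpinModel, TrainingError,
                             WATSON_CRICK, WOBBLE, enumerate_candidates,
                             match_consensus_pattern, scan_sequence,
                             score_candidate, train_model)

# ---------------------------------------------------------------------------
# toy alignment with hand-countable statistics

TOY_STRUCTURE = "<<<......>>>" + "..." + "(((......)))"
TOY_ROWS = [
    ("r1", "CAC" "AACGGT" "GTG" "AAA" "GGC" "ATCGGC" "GCC"),
    ("r2", "CAC" "ATCGGT" "GTG" "AA-" "GGC" "ATCGGC" "GCC"),
    ("r3", "GAC" "CACGGT" "GTC" "AAA" "GCC" "ATCGGC" "GGC"),
]


@pytest.fixture(scope="module")
def toy_alignment():
    return StructuredAlignment(rows=list(TOY_ROWS), structure_line=TOY_STRUCTURE)


@pytest.fixture(scope="module")
def toy_model(toy_alignment):
    return train_model(toy_alignment)


def test_training_loop_emissions_hand_count(toy_model):
    # loop1 column 1 (alignment col 3): residues A, A, C over 3 rows;
    # Laplace smoothing with pseudocount 0.5: (count + 0.5) / (3 + 2)
    em = toy_model.loop1_em[0]
    assert em == pytest.approx([2.5 / 5, 1.5 / 5, 0.5 / 5, 0.5 / 5])
    # loop1 column 4 (alignment col 6): G, G, G
    assert toy_model.loop1_em[3] == pytest.approx(
        [0.5 / 5, 0.5 / 5, 3.5 / 5, 0.5 / 5])


def test_training_stem_pair_emissions_hand_count(toy_model):
    # outermost stem-1 pair (cols 0, 11): (C,G), (C,G), (G,C);
    # joint smoothing: (count + 0.5) / (3 + 16 * 0.5)
    dist = toy_model.stem1_pairs[0]
    A, C, G, T = 0, 1, 2, 3
    assert dist[C, G] == pytest.approx(2.5 / 11)
    assert dist[G, C] == pytest.approx(1.5 / 11)
    assert dist[A, T] == pytest.approx(0.5 / 11)
    assert dist.sum() == pytest.approx(1.0)


def test_training_linker_distribution_hand_count(toy_model):
    # ungapped linker lengths 3, 2, 3 -> scan bounds = observed [2, 3],
    # smoothed support [1, 4] with add-one counts [1, 2, 3, 1] / 7
    assert (toy_model.linker_min, toy_model.linker_max) == (2, 3)
    assert toy_model.linker_support_min == 1
    assert toy_model.linker_probs == pytest.approx(np.array([1, 2, 3, 1]) / 7)


def test_training_pseudocount_zero_limit(toy_alignment):
    m = train_model(toy_alignment, pseudocount=1e-12)
    # loop1 col 1 frequencies approach the exact 2/3, 1/3
    assert m.loop1_em[0][0] == pytest.approx(2 / 3, rel=1e-9)
    assert m.loop1_em[0][1] == pytest.approx(1 / 3, rel=1e-9)


def test_training_rejects_degenerate_input(toy_alignment):
    with pytest.raises(TrainingError):
        train_model(StructuredAlignment(rows=[TOY_ROWS[0]],
                                        structure_line=TOY_STRUCTURE))
    with pytest.raises(TrainingError):
        train_model(toy_alignment, min_stem=4)  # only 3 trained pair columns


# ---------------------------------------------------------------------------
# scoring properties

def _uniform_model(linker_min=2, linker_max=3):
    W = linker_max - linker_min + 1
    return DualHairpinModel(
        loop1_em=np.full((6, 4), 0.25), loop2_em=np.full((6, 4), 0.25),
        stem1_pairs=np.full((3, 4, 4), 1 / 16),
        stem2_pairs=np.full((3, 4, 4), 1 / 16),
        generic_pair=np.full((4, 4), 1 / 16),
        linker_probs=np.full(W, 1 / W),
        linker_min=linker_min, linker_max=linker_max,
        linker_support_min=linker_min,
        background=np.full(4, 0.25))


def test_uniform_model_scores_zero():
    """Log-odds of a model identical to the background is exactly 0."""
    model = _uniform_model()
    seq = "CAC" "ATCGGT" "GTG" "AA" "GGC" "ATCGGC" "GCC"
    cand = Candidate(start=0, s1=3, linker_len=2, s2=3)
    assert score_candidate(model, cand, seq) == pytest.approx(0.0, abs=1e-12)


def test_one_bit_per_probability_doubling():
    """Doubling one emission relative to background adds exactly 1 bit."""
    base = _uniform_model()
    boosted = _uniform_model()
    boosted.loop1_em = boosted.loop1_em.copy()
    boosted.loop1_em[0] = [0.5, 1 / 6, 1 / 6, 1 / 6]  # P(A) = 2 * background
    seq = "CAC" "ATCGGT" "GTG" "AA" "GGC" "ATCGGC" "GCC"
    cand = Candidate(start=0, s1=3, linker_len=2, s2=3)
    delta = score_candidate(boosted, cand, seq) - score_candidate(base, cand, seq)
    assert delta == pytest.approx(1.0, abs=1e-12)


def test_score_hand_computed(toy_model):
    """Bit score equals the explicit sum of log-odds terms."""
    seq = "CAC" "ATCGGT" "GTG" "AAA" "GGC" "ATCGGC" "GCC"
    cand = Candidate(start=0, s1=3, linker_len=3, s2=3)
    m = toy_model
    NT = "ACGT"
    expected = 0.0
    for k, base in enumerate("ATCGGT"):
        expected += np.log2(m.loop1_em[k][NT.index(base)] / 0.25)
    for k, base in enumerate("ATCGGC"):
        expected += np.log2(m.loop2_em[k][NT.index(base)] / 0.25)
    for t, (a, b) in enumerate([("C", "G"), ("A", "T"), ("C", "G")]):
        expected += np.log2(m.stem1_pairs[t][NT.index(a), NT.index(b)] / (0.25 * 0.25))
    for t, (a, b) in enumerate([("G", "C"), ("G", "C"), ("C", "G")]):
        expected += np.log2(m.stem2_pairs[t][NT.index(a), NT.index(b)] / (0.25 * 0.25))
    expected += np.log2(m.linker_probs[3 - m.linker_support_min] * 2)  # W = 2
    assert score_candidate(m, cand, seq) == pytest.approx(expected, abs=1e-12)


def test_consensus_is_loopwise_maximal(toy_model):
    """No single loop substitution can raise the consensus score."""
    consensus = toy_model.consensus_motif().replace("U", "T")
    cand = Candidate(start=0, s1=3, linker_len=len(consensus) - 24, s2=3)
    best = score_candidate(toy_model, cand, consensus)
    spans = cand.spans
    for key in ("l1", "l2"):
        lo, hi = spans[key]
        for pos in range(lo, hi):
            for b in "ACGT":
                if b == consensus[pos]:
                    continue
                mutated = consensus[:pos] + b + consensus[pos + 1:]
                assert score_candidate(toy_model, cand, mutated) <= best + 1e-9


def test_linker_outside_support_rejected(toy_model):
    seq = "CAC" "ATCGGT" "GTG" + "A" * 20 + "GGC" "ATCGGC" "GCC"
    cand = Candidate(start=0, s1=3, linker_len=20, s2=3)
    with pytest.raises(ValueError):
        score_candidate(toy_model, cand, seq)


# ---------------------------------------------------------------------------
# enumeration vs brute force

def _brute_force(seq: str, model) -> set:
    """Independent enumeration by direct checking of every span tuple."""
    legal = set(WATSON_CRICK) | (set(WOBBLE) if model.allow_gu else set())
    n, L = len(seq), model.loop_len
    found = set()
    for i in range(n):
        for s1 in range(model.min_stem, model.stem_max + 1):
            for d in range(model.linker_min, model.linker_max + 1):
                for s2 in range(model.min_stem, model.stem_max + 1):
                    end = i + 2 * s1 + 2 * s2 + 2 * L + d
                    if end > n:
                        continue
                    window = seq[i:end]
                    if any(c not in "ACGT" for c in window):
                        continue
                    ok = all(
                        (seq[i + m], seq[i + 2 * s1 + L - 1 - m]) in legal
                        for m in range(s1))
                    a = i + 2 * s1 + L + d
                    ok = ok and all(
                        (seq[a + m], seq[a + 2 * s2 + L - 1 - m]) in legal
                        for m in range(s2))
                    if ok:
                        found.add((i, s1, d, s2))
    return found


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=40, max_size=120))
def test_enumeration_matches_brute_force(model, s):
    got = {(c.start, c.s1, c.linker_len, c.s2)
           for c in enumerate_candidates(s, model)}
    assert got == _brute_force(s, model)


def test_enumeration_skips_ambiguous_windows(model):
    clean = "CAC" "ATCGGT" "GTG" + "A" * 8 + "GGC" "ATCGGC" "GCC"
    assert enumerate_candidates(clean, model)
    dirty = clean[:15] + "N" + clean[16:]
    assert not any(c.start < 16 < c.end for c in enumerate_candidates(dirty, model))


# ---------------------------------------------------------------------------
# scanning

def test_scan_finds_embedded_motif(model):
    from antarscan.simulate import EmbedSpec, embed_dual_hairpin
    rec, truth = embed_dual_hairpin(EmbedSpec(seed=5), background_len=300)
    hits = scan_sequence(model, rec)
    assert any(h.strand == "+" and h.start < truth["end"]
               and truth["start"] < h.end for h in hits)


def test_scan_strand_symmetry(model):
    from antarscan.simulate import EmbedSpec, embed_dual_hairpin
    rec, _ = embed_dual_hairpin(EmbedSpec(seed=9), background_len=250)
    flipped = SequenceRecord(id=rec.id, residues=revcomp(rec.residues))
    fwd = scan_sequence(model, rec, background="uniform", deduplicate=False)
    rev = scan_sequence(model, flipped, background="uniform", deduplicate=False)
    n = len(rec)
    mapped = {(n - h.end, n - h.start, "-" if h.strand == "+" else "+",
               round(h.score, 9)) for h in rev}
    assert {(h.start, h.end, h.strand, round(h.score, 9)) for h in fwd} == mapped


def test_leader_hit_positions(model, leader):
    """The leader's single hit places the conserved loops at the published
    coordinate frame (1-based 29-34 and 53-58, A at 29/53, G at 32/56)."""
    hits = scan_sequence(model, leader)
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "+"
    assert h.l1 == (28, 34) and h.l2 == (52, 58)
    assert h.l1_seq == "ATCGGT" and h.l2_seq == "ATCGGC"
    assert leader.residues[28] == "A" and leader.residues[31] == "G"
    assert leader.residues[52] == "A" and leader.residues[55] == "G"
    assert h.score >= 10.0


def test_scan_threshold_filters(model, leader):
    strong = scan_sequence(model, leader, threshold=10.0)
    assert strong
    assert not scan_sequence(model, leader, threshold=strong[0].score + 1.0)


# ---------------------------------------------------------------------------
# serialization

def test_model_json_round_trip(model, tmp_path):
    path = tmp_path / "model.json"
    model.save(path)
    back = DualHairpinModel.load(path)
    np.testing.assert_allclose(back.loop1_em, model.loop1_em)
    np.testing.assert_allclose(back.stem2_pairs, model.stem2_pairs)
    np.testing.assert_allclose(back.linker_probs, model.linker_probs)
    assert (back.linker_min, back.linker_max) == (model.linker_min, model.linker_max)
    assert back.allow_gu == model.allow_gu


def test_model_version_rejected(model):
    import json
    payload = json.loads(model.to_json())
    payload["format_version"] = 999
    with pytest.raises(ValueError):
        DualHairpinModel.from_json(json.dumps(payload))


# ---------------------------------------------------------------------------
# degenerate consensus matching

def test_consensus_pattern_match():
    # the 13-nt attenuation-site consensus: AGCAANGRRGCUY
    assert match_consensus_pattern("AGCAATGAAGCTT") == [(0, 13)]
    assert match_consensus_pattern("AGCAATGAAGCTG") == []
    assert match_consensus_pattern("AAGCAACGGGGCUCAA") == [(1, 14)]


def test_consensus_pattern_u_t_equivalence():
    assert match_consensus_pattern("ACGT", pattern="ACGU") == [(0, 4)]
    assert match_consensus_pattern(SequenceRecord(id="x", residues="AUGU"),
                                   pattern="ATGT") == [(0, 4)]


def test_consensus_pattern_bad_code():
    with pytest.raises(ValueError):
        match_consensus_pattern("ACGT", pattern="AXGT")
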