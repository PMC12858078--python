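"""Structure parsing, layer decomposition, loops and sections."""

import itertools

import numpy as np
import pytest

from pkscan import (
    BasePair,
    FixtureSpec,
    Implant,
    PseudoknottedStructure,
    StructureError,
    assign_loops,
    decompose_layers,
    generate_structure,
    identify_sections,
    parse_bpseq,
    parse_ct,
    parse_dotbracket,
    write_bpseq,
    write_ct,
    write_dotbracket,
)


def test_parse_dotbracket_hairpin(hairpin):
    assert hairpin.secondary_pairs == {BasePair(0, 8), BasePair(1, 7), BasePair(2, 6)}
    assert hairpin.pseudoknot_pairs == frozenset()


def test_parse_dotbracket_layers_split_pseudoknots():
    s = parse_dotbracket("GGGGGCCCAACCCCCAGGA\n((((([[[...)))))]]]")
    assert len(s.secondary_pairs) == 5
    assert s.pseudoknot_pairs == {BasePair(5, 18), BasePair(6, 17), BasePair(7, 16)}


def test_parse_dotbracket_normalizes_t_and_case():
    s = parse_dotbracket("ggta\n....")
    assert s.sequence == "GGUA"


@pytest.mark.parametrize("text", [
    "GG\n((",                       # unbalanced open
    "GG\n))",                       # unbalanced close
    "GGG\n((",                      # length mismatch
    "GG\n(x",                       # unknown character
])
def test_parse_dotbracket_errors(text):
    with pytest.raises(StructureError):
        parse_dotbracket(text)


def test_non_crossing_extra_layer_rejected():
    # a bracket-layer pair that crosses nothing belongs in the secondary layer
    with pytest.raises(StructureError):
        parse_dotbracket("GAAC\n.[].")


def test_structure_rejects_double_pairing():
    with pytest.raises(StructureError):
        PseudoknottedStructure("GGCC", {BasePair(0, 3), BasePair(0, 2)}, frozenset())


def test_dotbracket_roundtrip_on_generated_fixtures(params):
    for seed in range(5):
        fix = generate_structure(FixtureSpec(seed=seed, implants=(
            Implant("2cluster", 4, "perfect"), Implant("type1-3cluster", 3, "perfect"))))
        text = write_dotbracket(fix.structure, header=">x")
        back = parse_dotbracket(text)
        assert back.sequence == fix.structure.sequence
        assert back.secondary_pairs == fix.structure.secondary_pairs
        assert back.pseudoknot_pairs == fix.structure.pseudoknot_pairs


def test_ct_bpseq_roundtrip_identity():
    # stems larger than the pseudoknot helix, so the maximum non-crossing
    # decomposition recovers the original layering
    fix = generate_structure(FixtureSpec(
        seed=3, stem_len=(7, 8), implants=(Implant("2cluster", 3, "perfect"),)))
    s = fix.structure
    for writer, reader in [(write_ct, parse_ct), (write_bpseq, parse_bpseq)]:
        back = reader(writer(s))
        assert back.sequence == s.sequence
        assert back.secondary_pairs == s.secondary_pairs
        assert back.pseudoknot_pairs == s.pseudoknot_pairs
        # parse -> write -> parse is identity on the parsed form
        again = reader(writer(back))
        assert again.all_pairs == back.all_pairs
        assert again.secondary_pairs == back.secondary_pairs


def test_ct_non_reciprocal_partners_rejected():
    text = "3 t\n1 G 0 2 3 1\n2 A 1 3 0 2\n3 C 2 0 2 3\n"
    with pytest.raises(StructureError):
        parse_ct(text)


def test_bpseq_hairpin_matches_dotbracket(hairpin):
    assert parse_bpseq(write_bpseq(hairpin)).all_pairs == hairpin.all_pairs


def _brute_max_noncrossing(pairs):
    def ok(subset):
        return all(
            not (a.pos5 < b.pos5 < a.pos3 < b.pos3 or b.pos5 < a.pos5 < b.pos3 < a.pos3)
            for a, b in itertools.combinations(subset, 2))
    return max(
        (len(sub) for r in range(len(pairs) + 1)
         for sub in itertools.combinations(pairs, r) if ok(sub)),
        default=0)


def test_decompose_layers_matches_exhaustive_maximum():
    rng = np.random.default_rng(11)
    for _ in range(30):
        m = int(rng.integers(0, 13))
        positions = rng.choice(60, size=2 * m, replace=False)
        rng.shuffle(positions)
        pairs = [BasePair(min(a, b), max(a, b))
                 for a, b in zip(positions[::2], positions[1::2])]
        secondary, pk = decompose_layers(pairs)
        assert len(secondary) == _brute_max_noncrossing(pairs)
        assert sorted(secondary + pk) == sorted(pairs)
        assert _brute_max_noncrossing(secondary) == len(secondary)  # non-crossing


def test_decompose_layers_prefers_larger_helix():
    big = [BasePair(i, 20 - i) for i in range(5)]       # 5-pair helix
    small = [BasePair(10 + i, 30 - i) for i in range(3)]  # crossing 3-pair helix
    secondary, pk = decompose_layers(big + small)
    assert sorted(secondary) == sorted(big)
    assert sorted(pk) == sorted(small)


def test_decompose_layers_nested_only():
    pairs = [BasePair(0, 9), BasePair(1, 8), BasePair(3, 5)]
    secondary, pk = decompose_layers(pairs)
    assert sorted(secondary) == sorted(pairs) and pk == []


def test_assign_loops_kinds():
    s = parse_dotbracket("A" * 24 + "\n((..((...))..((...))..))")
    loops = assign_loops(s)
    # three unpaired runs of the central multiloop share one id
    multi_ids = {loops[p].id for p in (2, 3, 11, 12, 20, 21)}
    assert len(multi_ids) == 1
    assert loops[2].kind == "multi"
    assert loops[6].kind == "hairpin" and loops[15].kind == "hairpin"
    assert loops[6].id != loops[15].id


def test_exterior_tails_share_one_loop():
    s = parse_dotbracket("AAGGGAAACCCAA\n..(((...)))..")
    loops = assign_loops(s)
    assert loops[0].kind == "exterior" and loops[0].id == 0
    assert loops[12].id == loops[0].id


def test_identify_sections_basic(hairpin):
    secs = identify_sections(hairpin)
    assert len(secs) == 1 and (secs[0].start, secs[0].end) == (3, 6)


def test_identify_sections_fully_paired_is_empty():
    assert identify_sections(parse_dotbracket("GGCCGGCC\n(((())))")) == []


def test_sections_cover_unpaired_exactly():
    s = parse_dotbracket("AAGGGAAACCCAAAGGGAAACCCAA\n..(((...)))...(((...)))..")
    secs = identify_sections(s)
    covered = sorted(p for sec in secs for p in sec.positions)
    paired = {p for bp in s.secondary_pairs for p in bp}
    assert covered == [p for p in range(len(s)) if p not in paired]
    starts = [sec.start for sec in secs]
    assert starts == sorted(starts)
    assert [sec.index for sec in secs] == list(range(len(secs)))
    # maximality: flanks of every section are paired or sequence ends
    for sec in secs:
        assert sec.start == 0 or sec.start - 1 in paired
        assert sec.end == len(s) or sec.end in paired


def test_sections_ignore_pseudoknot_pairs():
    # pseudoknot-paired bases still belong to sections
    fix = generate_structure(FixtureSpec(seed=1))
    pk_positions = {p for bp in fix.structure.pseudoknot_pairs for p in bp}
    section_positions = {p for sec in fix.sections for p in sec.positions}
    assert pk_positions <= section_positions
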