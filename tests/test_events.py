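"""Event enumeration against a brute-force oracle, AST assembly, and the
mode-string grammar."""

from collections import Counter
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasd.events import (
    DEFAULT_FLANK,
    JunctionEvent,
    SpliceEventType,
    assemble_ast,
    enumerate_events,
    mode_string,
    parse_mode,
)
from sasd.gene_models import ExonRecord, TranscriptModel, load_annotation


def _chain_model(n_exons, exon_len=200, intron_len=200, tid="T1"):
    exons = []
    pos = 0
    for k in range(1, n_exons + 1):
        exons.append(ExonRecord(tid, k, "c", pos, pos + exon_len, "+"))
        pos += exon_len + intron_len
    return TranscriptModel(tid, "G1", "G1", exons)


def brute_force_event_counts(n_exons):
    """Independent enumeration over all ordered feature pairs and singles."""
    E, I = n_exons, n_exons - 1
    counts = Counter()
    counts["EXON_NM"] = sum(1 for _ in range(1, E + 1))
    counts["INTRON_AS"] = sum(1 for _ in range(1, I + 1))
    for j in range(1, E + 1):
        for k in range(1, E + 1):
            if k == j + 1:
                counts["E_E_NM"] += 1
            elif k >= j + 2:
                counts["E_E_AS"] += 1
    for j in range(1, E + 1):
        for k in range(1, I + 1):
            if k == j:
                counts["E_I_AS"] += 1
    for j in range(1, I + 1):
        for k in range(1, E + 1):
            if k == j + 1:
                counts["I_E_AS"] += 1
    return counts


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_exons,expected",
        [
            (4, {"EXON_NM": 4, "INTRON_AS": 3, "E_E_NM": 3, "E_I_AS": 3,
                 "I_E_AS": 3, "E_E_AS": 3}),
            (2, {"EXON_NM": 2, "INTRON_AS": 1, "E_E_NM": 1, "E_I_AS": 1,
                 "I_E_AS": 1, "E_E_AS": 0}),
        ],
    )
    def test_per_type_counts(self, n_exons, expected):
        counts = Counter(e.type.value for e in enumerate_events(_chain_model(n_exons)))
        assert {t: counts.get(t, 0) for t in expected} == expected
        assert counts == {k: v for k, v in brute_force_event_counts(n_exons).items() if v}

    def test_single_exon_yields_one_event(self):
        events = enumerate_events(_chain_model(1))
        assert len(events) == 1
        assert events[0].type is SpliceEventType.EXON_NM

    def test_no_duplicates_and_closed_form_total(self):
        for E in range(1, 10):
            events = enumerate_events(_chain_model(E))
            assert len(set((e.type, e.left, e.right) for e in events)) == len(events)
            I = E - 1
            expected = E + 4 * I + (E * (E - 1)) // 2 - I
            assert len(events) == expected

    def test_random_transcripts_match_brute_force(self):
        import numpy as np

        rng = np.random.default_rng(123)
        for _ in range(200):
            E = int(rng.integers(1, 13))
            counts = Counter(e.type.value for e in enumerate_events(_chain_model(E)))
            brute = brute_force_event_counts(E)
            assert counts == {k: v for k, v in brute.items() if v}


class TestEventValidation:
    def test_event_class_mapping_is_total(self):
        classes = {t.splice_class for t in SpliceEventType}
        assert classes == {"Normal Splicing", "Exon Skipping", "Intron Retention"}

    def test_inconsistent_events_rejected(self):
        with pytest.raises(ValueError):
            JunctionEvent("T", "G", SpliceEventType.E_E_NM, ("E", 1), ("E", 3))
        with pytest.raises(ValueError):
            JunctionEvent("T", "G", SpliceEventType.E_I_AS, ("E", 1), ("i", 2))
        with pytest.raises(ValueError):
            JunctionEvent("T", "G", SpliceEventType.EXON_NM, ("E", 1), ("E", 2))


@pytest.fixture()
def built(small_models):
    models, genome = small_models
    return models[0], genome


class TestAssembly:

    def test_default_flank_gives_240nt_ast(self, built):
        model, genome = built
        for event in enumerate_events(model):
            if not event.type.is_junction:
                continue
            (ast,) = assemble_ast(event, genome, model)
            assert len(ast.sequence) == 240
            assert ast.junction_offset == 120
            assert not ast.left_truncated and not ast.right_truncated

    def test_flank_substrings_come_from_joined_features(self, built):
        model, genome = built
        truthy = {("E", e.ordinal): e.sequence(genome) for e in model.exons}
        truthy |= {("i", i.ordinal): i.sequence(genome) for i in model.introns}
        for event in enumerate_events(model):
            if not event.type.is_junction:
                continue
            (ast,) = assemble_ast(event, genome, model)
            left, right = truthy[event.left], truthy[event.right]
            j = ast.junction_offset
            assert ast.sequence[:j] == left[-j:]
            assert ast.sequence[j:] == right[: len(ast.sequence) - j]
            assert ast.sequence in left + right

    def test_short_feature_truncates_flank(self):
        m = _chain_model(2, exon_len=50, intron_len=300)
        from sasd.gene_models import Genome

        genome = Genome({"c": "ACGT" * 200})
        event = next(e for e in enumerate_events(m)
                     if e.type is SpliceEventType.E_I_AS)
        (ast,) = assemble_ast(event, genome, m)
        assert len(ast.sequence) == 50 + 120
        assert ast.junction_offset == 50
        assert ast.left_truncated and not ast.right_truncated

    def test_single_feature_fits_in_one_window(self, built):
        model, genome = built
        event = enumerate_events(model)[0]  # EXON_NM of exon 1 (200 nt)
        asts = assemble_ast(event, genome, model)
        assert len(asts) == 1
        assert asts[0].sequence == model.exons[0].sequence(genome)
        assert asts[0].junction_offset is None

    def test_long_feature_tiles_cover_everything(self):
        from sasd.gene_models import Genome
        import numpy as np

        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        genome = Genome({"c": seq})
        m = TranscriptModel("T1", "G1", "G1",
                            [ExonRecord("T1", 1, "c", 0, 1000, "+")])
        (event,) = enumerate_events(m)
        asts = assemble_ast(event, genome, m)
        assert all(len(a.sequence) == 240 for a in asts)
        assert [a.window_index for a in asts] == list(range(1, len(asts) + 1))
        covered = set()
        for a in asts:
            _, s, e, _ = a.genomic_intervals[0]
            covered |= set(range(s, e))
            assert seq[s:e] == a.sequence
        assert covered == set(range(1000))

    def test_flank_monotonicity_and_saturation(self, built):
        model, genome = built
        for event in enumerate_events(model):
            lengths = []
            for flank in (40, 120, 200, 500):
                asts = assemble_ast(event, genome, model, flank=flank)
                lengths.append(max(len(a.sequence) for a in asts))
            assert lengths == sorted(lengths)
            # flags mark exactly the flanks cut short at a feature boundary
            if event.type.is_junction:
                truthy = {("E", e.ordinal): len(e) for e in model.exons}
                truthy |= {("i", i.ordinal): len(i) for i in model.introns}
                for flank in (40, 120, 500):
                    (a,) = assemble_ast(event, genome, model, flank=flank)
                    assert a.left_truncated == (truthy[event.left] < flank)
                    assert a.right_truncated == (truthy[event.right] < flank)

    def test_mirrored_minus_strand_gives_identical_ast(self, tmp_path, two_gene_fixture):
        from sasd.fixtures import mirror_fixture_files

        mirror_fixture_files(two_gene_fixture.genome_path, two_gene_fixture.gtf_path,
                             tmp_path / "g.fa", tmp_path / "a.gtf")
        orig, go = load_annotation(two_gene_fixture.gtf_path,
                                   two_gene_fixture.genome_path)
        mirr, gm = load_annotation(tmp_path / "a.gtf", tmp_path / "g.fa")
        for mo, mm in zip(orig, mirr):
            for eo, em in zip(enumerate_events(mo), enumerate_events(mm)):
                ao = assemble_ast(eo, go, mo)
                am = assemble_ast(em, gm, mm)
                assert [a.sequence for a in ao] == [a.sequence for a in am]


class TestModeStrings:
    @pytest.mark.parametrize(
        "event_args,expected",
        [
            ((SpliceEventType.I_E_AS, ("i", 3), ("E", 4)), "i3E4"),
            ((SpliceEventType.E_I_AS, ("E", 1), ("i", 1)), "E1i1"),
            ((SpliceEventType.INTRON_AS, ("i", 6), None), "i6"),
            ((SpliceEventType.EXON_NM, ("E", 2), None), "E2"),
            ((SpliceEventType.E_E_AS, ("E", 102), ("E", 182)), "E102E182"),
            ((SpliceEventType.E_E_NM, ("E", 1), ("E", 2)), "E1E2"),
        ],
    )
    def test_canonical_emission(self, event_args, expected):
        t, left, right = event_args
        assert mode_string(JunctionEvent("T", "G", t, left, right)) == expected

    @pytest.mark.parametrize(
        "mode,etype,left,right",
        [
            ("i3E4", SpliceEventType.I_E_AS, ("i", 3), ("E", 4)),
            ("E7_E11", SpliceEventType.E_E_AS, ("E", 7), ("E", 11)),
            ("E7E11", SpliceEventType.E_E_AS, ("E", 7), ("E", 11)),
            ("i2_E3", SpliceEventType.I_E_AS, ("i", 2), ("E", 3)),
            ("E102E182", SpliceEventType.E_E_AS, ("E", 102), ("E", 182)),
            ("i6", SpliceEventType.INTRON_AS, ("i", 6), None),
            ("E1i1", SpliceEventType.E_I_AS, ("E", 1), ("i", 1)),
        ],
    )
    def test_parse(self, mode, etype, left, right):
        assert parse_mode(mode) == (etype, left, right)

    @pytest.mark.parametrize("bad", ["", "X1", "E0", "i1i2", "E3E3", "E5E2",
                                     "E1i3", "i3E9", "E1_", "1E2"])
    def test_unparseable_strings_raise(self, bad):
        with pytest.raises(ValueError):
            parse_mode(bad)

    @given(st.sampled_from(list(SpliceEventType)), st.integers(1, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_parse_of_emit(self, etype, lo):
        if etype is SpliceEventType.E_E_NM:
            right = ("E", lo + 1)
        elif etype is SpliceEventType.E_E_AS:
            right = ("E", lo + 2)
        elif etype is SpliceEventType.E_I_AS:
            right = ("i", lo)
        elif etype is SpliceEventType.I_E_AS:
            right = ("E", lo + 1)
        else:
            right = None
        left = ("i", lo) if etype in (SpliceEventType.INTRON_AS,
                                      SpliceEventType.I_E_AS) else ("E", lo)
        event = JunctionEvent("T", "G", etype, left, right)
        assert parse_mode(mode_string(event)) == (etype, left, right)
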