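import pytest

from trftarget.chimera import (
    Decomposition,
    Rejection,
    build_interaction_pairs,
    collapse_duplicates,
    decompose_read,
    map_target_fragment,
)
from trftarget.seq import NucleotideSequence, TranscriptRecord, reverse_complement

from conftest import make_trf


@pytest.fixture
def catalog():
    return [
        make_trf("tRF-3001a", "UGGUUCGAGCCCAUAGCA", "tRF-3"),
        make_trf("tRF-5002a", "GCAUUGGUGGUUCAG", "tRF-5"),
    ]


def read(seq, rid="r1"):
    return NucleotideSequence(rid, seq)


class TestDecomposeRead:
    def test_trf_prefix(self, catalog):
        r = read(catalog[0].sequence.residues + "CGAACCAAAGG")
        dec = decompose_read(r, catalog)
        assert isinstance(dec, Decomposition)
        assert dec.trf_id == "tRF-3001a"
        assert dec.orientation == "trf_first"
        assert dec.target_fragment == "CGAACCAAAGG"

    def test_trf_suffix(self, catalog):
        r = read("CGAACCAAAGG" + catalog[1].sequence.residues)
        dec = decompose_read(r, catalog)
        assert dec.orientation == "trf_last"
        assert dec.trf_id == "tRF-5002a"

    def test_internal_substitution_rejected(self, catalog):
        t = catalog[0].sequence.residues
        mutated = t[:9] + ("A" if t[9] != "A" else "C") + t[10:]
        r = read(mutated + "CGAACCAAAGG")
        rej = decompose_read(r, catalog)
        assert isinstance(rej, Rejection) and rej.reason == "no_trf_match"

    def test_read_shorter_than_any_trf(self, catalog):
        rej = decompose_read(read("ACGUACGUACGU"), catalog)
        assert rej.reason == "no_trf_match"

    def test_fragment_too_short(self, catalog):
        r = read(catalog[0].sequence.residues + "CGAAC")
        assert decompose_read(r, catalog).reason == "fragment_too_short"

    def test_two_trfs_at_both_ends_ambiguous(self):
        a = make_trf("tRF-3001a", "GGGGCCCCGGGGCCCCGG", "tRF-3")
        b = make_trf("tRF-3002a", "AAAAUUUUAAAAUUUUAA", "tRF-3")
        r = read(a.sequence.residues + "CGAACC" + b.sequence.residues)
        assert decompose_read(r, [a, b]).reason == "ambiguous"

    def test_longest_match_wins(self):
        short = make_trf("tRF-5003a", "GCAUUGGUGGUUCAG", "tRF-5")  # 15 nt
        longer = make_trf("tRF-5004a", "GCAUUGGUGGUUCAGUGGUAGA", "tRF-5")  # 22 nt
        r = read(longer.sequence.residues + "CGAACCAAA")
        dec = decompose_read(r, [short, longer])
        assert dec.trf_id == "tRF-5004a"


class TestMapTargetFragment:
    def _tx(self, tid, utr3):
        return TranscriptRecord(tid, tid, "", "", utr3)

    def test_unique_hit(self):
        hits = map_target_fragment("CGAACC", [self._tx("NM_1", "AAACGAACCAAA")])
        assert len(hits) == 1
        tid, iv = hits[0]
        assert tid == "NM_1" and (iv.start, iv.end) == (3, 9)

    def test_absent_fragment(self):
        assert map_target_fragment("GGGGGG", [self._tx("NM_1", "AAAAAAA")]) == []

    def test_multi_mapping_returns_all(self):
        txs = [self._tx("NM_1", "AACGAACCAA"), self._tx("NM_2", "UUCGAACCUU")]
        hits = map_target_fragment("CGAACC", txs)
        assert {t for t, _ in hits} == {"NM_1", "NM_2"}


class TestBuildInteractionPairs:
    def _setup(self, catalog):
        motif = reverse_complement(catalog[0].seed)  # CGAACC
        utr = "GCGUAGGCA" + motif + "AGCAUGGCAUAAGGC"
        tx = TranscriptRecord("NM_1", "G1", "", "", utr)
        return tx, motif

    def test_seed_containing_fragment_yields_positive(self, catalog):
        tx, motif = self._setup(catalog)
        frag = tx.utr3[6:18]  # contains the full motif
        r = read(catalog[0].sequence.residues + frag)
        pairs, rej = build_interaction_pairs([r], catalog, [tx])
        assert len(pairs) == 1
        assert pairs[0].label == "positive"
        assert (pairs[0].site.site.start, pairs[0].site.site.end) == (9, 15)

    def test_partial_seed_complementarity_dropped(self, catalog):
        utr = "GCGUAGGCACGAACAAGCAUGGCAU"  # CGAACA: 5/6 match only
        tx = TranscriptRecord("NM_1", "G1", "", "", utr)
        r = read(catalog[0].sequence.residues + utr[6:18])
        pairs, rej = build_interaction_pairs([r], catalog, [tx])
        assert pairs == []
        assert any(x.reason == "no_seed_match" for x in rej)

    def test_duplicate_reads_deduplicate(self, catalog):
        tx, _ = self._setup(catalog)
        frag = tx.utr3[6:18]
        reads = [
            read(catalog[0].sequence.residues + frag, "r1"),
            read(frag + catalog[0].sequence.residues, "r2"),
        ]
        pairs, _ = build_interaction_pairs(reads, catalog, [tx])
        assert len(pairs) == 1

    def test_decoy_only_input_yields_nothing(self, catalog):
        pairs, rej = build_interaction_pairs(
            [read("ACGU" * 10)], catalog, [TranscriptRecord("NM_1", "G", "", "", "A" * 40)]
        )
        assert pairs == [] and rej[0].reason == "no_trf_match"


class TestCollapseDuplicates:
    def test_exact_duplicates_removed(self):
        reads = [read("ACGUACGU", "a"), read("ACGUACGU", "b"), read("GGGGCCCC", "c")]
        kept = collapse_duplicates(reads)
        assert [r.id for r in kept] == ["a", "c"]


class TestSyntheticRoundTrip:
    def test_every_implanted_pair_recovered_exactly_once(self):
        from trftarget import chimera, simulate

        cfg = simulate.SyntheticConfig(n_transcripts=60, n_positive_pairs=25, rng_seed=11)
        transcripts, trfs, truth, _ = simulate.generate_reference(cfg)
        reads = simulate.generate_chimeric_reads(truth, trfs, cfg)
        pairs, _ = chimera.build_interaction_pairs(reads, trfs, transcripts)
        assert {p.key for p in pairs} == set(truth.positives)

    def test_no_decomposition_deviates_from_catalog(self):
        from trftarget import simulate

        cfg = simulate.SyntheticConfig(n_transcripts=40, n_positive_pairs=10, rng_seed=3)
        transcripts, trfs, truth, _ = simulate.generate_reference(cfg)
        reads = simulate.generate_chimeric_reads(truth, trfs, cfg)
        seqs = {t.trf_id: t.sequence.residues for t in trfs}
        for r in reads:
            dec = decompose_read(r, trfs)
            if isinstance(dec, Decomposition):
                span = r.residues[dec.trf_span.start : dec.trf_span.end]
                assert span == seqs[dec.trf_id]
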