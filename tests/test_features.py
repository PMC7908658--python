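import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trftarget.chimera import InteractionPair
from trftarget.features import (
    BASES,
    DINUCS,
    assemble_feature_matrix,
    default_registry,
    flank_au_score,
    seed_match_frequency,
    site_features,
    transcript_features,
    trf_features,
    window_composition,
)
from trftarget.seq import TranscriptRecord
from trftarget.sites import scan_seed_matches

from conftest import make_trf

H35 = sum(1.0 / d for d in range(1, 36))


class TestFlankAuScore:
    @pytest.mark.parametrize(
        "window,exclude,expected",
        [
            ("GGGG", 0, 0.0),
            ("AU", 0, 1.5),
            ("A" * 35, 0, H35),
            ("A" * 35, 10, sum(1.0 / d for d in range(11, 36))),
            ("", 0, 0.0),
        ],
    )
    def test_examples(self, window, exclude, expected):
        assert flank_au_score(window, exclude) == pytest.approx(expected, abs=1e-12)

    @given(st.text(alphabet="ACGU", min_size=1, max_size=35), st.data())
    def test_monotone_under_gc_to_au_substitution(self, w, data):
        pos = data.draw(st.integers(0, len(w) - 1))
        replaced = w[:pos] + "A" + w[pos + 1 :]
        assert flank_au_score(replaced) >= flank_au_score(w)


class TestWindowComposition:
    def test_homopolymer(self):
        c = window_composition("AAAA")
        assert c["comp_A"] == 1.0 and c["dinuc_AA"] == 1.0 and c["gc"] == 0.0

    def test_uniform(self):
        c = window_composition("ACGU")
        assert all(c[f"comp_{b}"] == 0.25 for b in BASES)
        assert c["gc"] == 50.0

    @given(st.text(alphabet="ACGU", min_size=2, max_size=50))
    def test_families_sum_to_one(self, w):
        c = window_composition(w)
        assert math.isclose(sum(c[f"comp_{b}"] for b in BASES), 1.0, abs_tol=1e-9)
        assert math.isclose(sum(c[f"dinuc_{d}"] for d in DINUCS), 1.0, abs_tol=1e-9)


class TestSeedMatchFrequency:
    def test_one_match_per_kb(self):
        utr = "CGAACC" + "A" * 994  # exactly 1000 nt, one motif
        assert seed_match_frequency(utr, "GGUUCG") == pytest.approx(1.0)

    def test_empty_region_missing(self):
        assert math.isnan(seed_match_frequency("", "GGUUCG"))


class TestSiteFeatures:
    def _site(self, trf, utr):
        return scan_seed_matches(trf, utr, "tx")[0]

    def test_all_gc_flanks(self):
        trf = make_trf()
        utr = "G" * 40 + "CGAACC" + "C" * 20
        s = self._site(trf, utr)
        vals = site_features(trf, utr, s)
        assert vals["s_au_up35"] == 0.0 and vals["s_au_down15"] == 0.0
        assert vals["gc_up35"] == 100.0 and vals["gc_down15"] == 100.0

    def test_truncated_edge_window_used_as_is(self):
        trf = make_trf()
        utr = "CGAACC" + "A" * 30
        vals = site_features(trf, utr, self._site(trf, utr))
        assert math.isnan(vals["gc_up35"])  # empty upstream window
        assert vals["s_au_up35"] == 0.0
        assert vals["dist5"] == 0.0

    def test_vector_covers_site_family(self):
        trf = make_trf()
        utr = "A" * 40 + "CGAACC" + "U" * 20
        vals = site_features(trf, utr, self._site(trf, utr))
        registry = default_registry()
        site_names = [n for n, fam in registry.entries if fam == "site_sequence"]
        assert set(vals) == set(site_names)

    def test_flank_identity_indicators_one_hot(self):
        trf = make_trf()
        utr = "A" * 40 + "CGAACC" + "U" * 20
        vals = site_features(trf, utr, self._site(trf, utr))
        for pos in ("up1", "up2", "down1", "down2"):
            assert sum(vals[f"flank_{pos}_{b}"] for b in BASES) == 1.0


class TestTranscriptFeatures:
    def test_missing_utr5_flagged(self):
        trf = make_trf()
        tx = TranscriptRecord("NM_1", "G", "", "AUGUAA", "A" * 50)
        vals = transcript_features(tx, trf)
        assert math.isnan(vals["utr5_len"]) and math.isnan(vals["utr5_gc"])

    def test_gc_of_au_only_utr(self):
        trf = make_trf()
        tx = TranscriptRecord("NM_1", "G", "", "", "AU" * 30)
        assert transcript_features(tx, trf)["utr3_gc"] == 0.0


class TestTrfFeatures:
    def test_gc_rich_trf(self):
        trf = make_trf(seq="G" * 9 + "C" * 9)
        vals = trf_features(trf, [])
        assert vals["trf_len"] == 18.0
        assert vals["trf_gc"] == 100.0 and vals["seed_gc"] == 100.0
        assert vals["ta_3utr"] == 0.0

    def test_ta_is_sum_over_utrs(self):
        trf = make_trf()
        txs = [
            TranscriptRecord("NM_1", "G", "", "", "CGAACC" + "A" * 10 + "CGAACC"),
            TranscriptRecord("NM_2", "G", "", "", "CGAACC" + "U" * 10),
        ]
        assert trf_features(trf, txs)["ta_3utr"] == 3.0

    def test_ta_genome_missing_without_genome(self):
        assert math.isnan(trf_features(make_trf(), [])["ta_genome"])


class TestAssembleFeatureMatrix:
    @pytest.fixture
    def setting(self):
        trf = make_trf()
        utr = "A" * 40 + "CGAACC" + "UGCAUGGC" * 6
        tx = TranscriptRecord("NM_1", "G1", "A" * 20, "AUG" * 30, utr)
        site = scan_seed_matches(trf, utr, "NM_1")[0]
        pair = InteractionPair(trf.trf_id, "NM_1", site, "positive", "CLASH")
        return trf, tx, pair

    def test_shape_and_column_order(self, setting):
        trf, tx, pair = setting
        X = assemble_feature_matrix([pair, pair, pair], [trf], [tx])
        registry = default_registry()
        assert X.shape == (3, len(registry.names))
        assert list(X.columns) == registry.names
        # identical pairs produce identical rows
        assert np.allclose(X.iloc[0], X.iloc[2], equal_nan=True)

    def test_deterministic(self, setting):
        trf, tx, pair = setting
        a = assemble_feature_matrix([pair], [trf], [tx])
        b = assemble_feature_matrix([pair], [trf], [tx])
        assert a.equals(b)

    def test_registry_version_stable(self):
        assert default_registry().version == default_registry().version
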