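"""Pair enumeration, hypergeometric scoring, ranking, and indicators."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from metalsite import (
    ProteinRecord,
    enumerate_pairs,
    encode_saap_indicators,
    extract_sites,
    extract_window,
    hypergeom_pmf,
    mine_saaps,
    rank_saaps,
    saap_pvalue,
    windows_for_sites,
)
from metalsite.saap import (
    SaapCatalog,
    SaapFeature,
    compute_pvalues,
    read_catalog,
    window_pairs,
    write_catalog,
)
from metalsite.synthetic import PlantedPair, SyntheticConfig, generate


def make_window(context, binding=False, rec_id="p1"):
    """A standalone labeled window: context placed mid-sequence."""
    seq = "A" * 7 + context.replace("X", "A") + "A" * 7
    rec = ProteinRecord(rec_id, seq, {14: "Fe"} if binding else {})
    win = extract_window(rec, 14)
    assert win.context == context.replace("X", "A")
    return win


def padded_window(binding=False):
    """A window at the sequence start, so offset -6..-1 are padding."""
    rec = ProteinRecord("p1", "CPDEFGH", {1: "Fe"} if binding else {})
    return extract_window(rec, 1)


class TestEnumeratePairs:
    def test_single_positive_window_counts(self):
        # C at offset -4 and P at offset +1 around a binding center
        win = make_window("AACAAACPAAAAA", binding=True)
        catalog = enumerate_pairs([win])
        by_key = {f.key: f for f in catalog.features}
        assert catalog.N == 1 and catalog.M == 1
        assert by_key[(-4, "C", 1, "P")].n == 1
        assert by_key[(-4, "C", 1, "P")].x == 1

    def test_identical_negative_windows(self):
        wins = [make_window("AACAAACPAAAAA") for _ in range(2)]
        catalog = enumerate_pairs(wins)
        f = {f.key: f for f in catalog.features}[(-4, "C", 1, "P")]
        assert (f.n, f.x) == (2, 0)

    def test_padding_never_matches(self):
        win = padded_window()
        catalog = enumerate_pairs([win])
        assert all(f.offset1 >= 1 for f in catalog.features)

    def test_center_offset_excluded(self):
        win = make_window("AACAAACPAAAAA")
        assert all(0 not in (o1, o2) for (o1, _, o2, _) in window_pairs(win))

    def test_mixed_center_types_rejected(self):
        c = make_window("AAAAAACAAAAAA")
        h = make_window("AAAAAAHAAAAAA")
        with pytest.raises(ValueError, match="[Mm]ixed"):
            enumerate_pairs([c, h])

    def test_recount_is_identical(self, small_planted):
        dataset, sites = small_planted
        wins = windows_for_sites(sites, dataset.records)
        a = enumerate_pairs(wins)
        b = enumerate_pairs(wins)
        assert [(f.key, f.n, f.x) for f in a.features] == [
            (f.key, f.n, f.x) for f in b.features
        ]
        assert all(f.x <= min(f.n, a.M) for f in a.features)


class TestHypergeometric:
    @pytest.mark.parametrize(
        "N,M,n,x,expected",
        [
            (5, 2, 2, 1, 0.6),      # C(2,1)C(3,1)/C(5,2)
            (10, 10, 3, 3, 1.0),    # all items positive
            (4, 2, 2, 0, 1 / 6),    # C(2,0)C(2,2)/C(4,2)
        ],
    )
    def test_pmf_values(self, N, M, n, x, expected):
        assert hypergeom_pmf(N, M, n, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "N,M,n,x,expected",
        [
            (5, 2, 2, 2, 0.1),   # single tail term
            (7, 3, 4, 0, 1.0),   # full tail
            (5, 2, 2, 1, 0.7),   # 0.6 + 0.1
        ],
    )
    def test_tail_values(self, N, M, n, x, expected):
        assert saap_pvalue(N, M, n, x) == pytest.approx(expected, abs=1e-12)

    def test_point_mode_matches_pmf(self):
        assert saap_pvalue(5, 2, 2, 1, mode="point") == pytest.approx(0.6)

    def test_bounds_rejected(self):
        for bad in [(5, 6, 2, 1), (5, 2, 6, 1), (5, 2, 2, 3), (5, 2, 4, 0)]:
            with pytest.raises(ValueError):
                hypergeom_pmf(*bad)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_and_tail_monotone(self, data):
        """Cross-check against scipy's hypergeometric survival function and
        verify the tail is non-increasing in x."""
        N = data.draw(st.integers(1, 60))
        M = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        lo, hi = max(0, n + M - N), min(n, M)
        x = data.draw(st.integers(lo, hi))
        p = saap_pvalue(N, M, n, x)
        assert 0.0 < p <= 1.0
        ref = float(scipy.stats.hypergeom.sf(x - 1, N, M, n))
        assert p == pytest.approx(ref, abs=1e-10)
        if x < hi:
            assert saap_pvalue(N, M, n, x + 1) <= p + 1e-12


class TestRanking:
    def test_order_retained_below_alpha(self):
        feats = [
            SaapFeature(-4, "C", 1, "P", n=5, x=5, p_value=2.70e-04),
            SaapFeature(-6, "C", 4, "C", n=5, x=4, p_value=6.90e-04),
            SaapFeature(-3, "C", 3, "C", n=5, x=3, p_value=1.80e-03),
        ]
        ranked = rank_saaps(SaapCatalog(N=10, M=5, features=feats), alpha=0.05)
        assert [f.key for f in ranked.features] == [f.key for f in feats]

    def test_all_insignificant_dropped(self):
        feats = [SaapFeature(-1, "A", 1, "A", n=3, x=1, p_value=1.0)]
        ranked = rank_saaps(SaapCatalog(N=10, M=5, features=feats), alpha=0.05)
        assert ranked.features == []

    def test_deterministic_tie_break(self):
        a = SaapFeature(-2, "G", 3, "S", n=4, x=4, p_value=1e-3)
        b = SaapFeature(-4, "C", 1, "P", n=4, x=4, p_value=1e-3)
        for order in ([a, b], [b, a]):
            ranked = rank_saaps(SaapCatalog(N=10, M=5, features=order), 0.05)
            assert [f.key for f in ranked.features] == [b.key, a.key]

    def test_planted_pair_ranks_high(self):
        """A strongly planted pair lands in the top 3 of the mined catalog."""
        top3 = 0
        for seed in range(5):
            cfg = SyntheticConfig(
                n_proteins=12,
                length_range=(100, 160),
                n_positive_sites=25,
                n_negative_sites=75,
                planted_pairs=[PlantedPair(-4, "C", 1, "P", 0.8, 0.05)],
                pssm_signal=0.0,
                seed=seed,
            )
            ds = generate(cfg)
            sites = [
                s for r in ds.records for s in extract_sites(r) if s.residue == "C"
            ]
            catalog = mine_saaps(windows_for_sites(sites, ds.records))
            keys = [f.key for f in catalog.features[:3]]
            top3 += (-4, "C", 1, "P") in keys
        assert top3 >= 4


class TestIndicators:
    def test_present_pair(self):
        win = make_window("AACAAACPAAAAA")
        feats = [SaapFeature(-4, "C", 1, "P")]
        np.testing.assert_array_equal(encode_saap_indicators(win, feats), [1.0])

    def test_absent_pair(self):
        win = make_window("AAAAAACPAAAAA")  # P at +1 but no C at -4
        feats = [SaapFeature(-4, "C", 1, "P")]
        np.testing.assert_array_equal(encode_saap_indicators(win, feats), [0.0])

    def test_empty_feature_list(self):
        win = make_window("AACAAACPAAAAA")
        assert encode_saap_indicators(win, []).size == 0


class TestCatalogIO:
    def test_round_trip(self, tmp_path):
        catalog = SaapCatalog(
            N=100,
            M=25,
            features=[
                SaapFeature(-4, "C", 1, "P", n=12, x=9, p_value=2.7e-4),
                SaapFeature(-6, "L", 3, "C", n=8, x=4, p_value=1.8e-3),
            ],
        )
        path = tmp_path / "catalog.tsv"
        write_catalog(catalog, path)
        back = read_catalog(path)
        assert (back.N, back.M) == (100, 25)
        assert [(f.key, f.n, f.x) for f in back.features] == [
            (f.key, f.n, f.x) for f in catalog.features
        ]
        for a, b in zip(back.features, catalog.features):
            assert a.p_value == pytest.approx(b.p_value, rel=1e-5)
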