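"""Pair stability, outcome accumulation, and the SSt table."""

import dataclasses

import numpy as np
import pytest

import phonostab as ps
from phonostab.align import Alignment, GAP
from phonostab.stability import OutcomeAccumulator, accumulate_outcomes

from conftest import make_wordlist


def aln(cells, weights, langs=("A", "B")):
    return Alignment(
        cells=tuple(cells),
        score=0.0,
        weights=np.asarray(weights, dtype=float),
        left_language=langs[0],
        right_language=langs[1],
    )


class TestPairStability:
    def test_all_identical(self):
        a = aln([("k", "k"), ("a", "a")], [1.0, 0.5])
        assert ps.pair_stability([a]).s == 1.0

    def test_none_identical(self):
        a = aln([("k", "t"), ("a", "u")], [1.0, 0.5])
        assert ps.pair_stability([a]).s == 0.0

    def test_weighted_arithmetic(self):
        """Weights (1, 1, 0.5) with identity (yes, no, yes) give 1.5/2.5."""
        a1 = aln([("k", "k"), ("a", "u")], [1.0, 1.0])
        a2 = aln([("s", "s")], [0.5])
        res = ps.pair_stability([a1, a2])
        assert res.s == pytest.approx(0.6)
        assert res.n_word_pairs == 2
        assert res.n_segment_pairs == 3
        assert res.n_identical == 2

    def test_gap_cells_excluded_from_denominator(self):
        a = aln([("k", "k"), ("a", GAP)], [1.0, 1.0])
        assert ps.pair_stability([a]).s == 1.0

    def test_no_segment_cells_raises(self):
        a = aln([("k", GAP)], [1.0])
        with pytest.raises(ValueError):
            ps.pair_stability([a])


class TestReplacementRate:
    @pytest.mark.parametrize(
        "s,expected",
        [(0.791, 0.209), (1.0, 0.0), (0.254, 0.746)],
    )
    def test_one_minus_s(self, s, expected):
        assert ps.replacement_rate(s) == pytest.approx(expected)

    def test_accepts_pair_stability(self):
        a = aln([("k", "k")], [1.0])
        assert ps.replacement_rate(ps.pair_stability([a])) == 0.0


class TestAccumulateOutcomes:
    def make_acc(self):
        return OutcomeAccumulator(ps.default_registry())

    def test_identical_cell_counts_stable_per_side(self):
        acc = self.make_acc()
        accumulate_outcomes(aln([("p", "p")], [1.0]), 0.5, acc.registry, acc)
        for name in ("voiceless", "stop", "labial", "voiceless stop", "voiceless labial"):
            np.testing.assert_allclose(acc.weights[name], [1.0, 0, 0, 0])

    def test_in_group_and_out_group_shift(self):
        acc = self.make_acc()
        accumulate_outcomes(aln([("p", "b")], [1.0]), 1.0, acc.registry, acc)
        # both p and b are stops -> two shift_in instances for "stop"
        np.testing.assert_allclose(acc.weights["stop"], [0, 2.0, 0, 0])
        # only the p side is voiceless, and b is not -> one shift_out
        np.testing.assert_allclose(acc.weights["voiceless"], [0, 0, 1.0, 0])

    def test_gap_side_counts_indel_only(self):
        acc = self.make_acc()
        accumulate_outcomes(aln([("p", GAP)], [1.0]), 1.0, acc.registry, acc)
        np.testing.assert_allclose(acc.weights["stop"], [0, 0, 0, 1.0])
        assert all(w.sum() == 0 for n, w in acc.weights.items() if "vowel" in n)

    def test_rate_out_of_range_rejected(self):
        acc = self.make_acc()
        with pytest.raises(ValueError):
            accumulate_outcomes(aln([("p", "p")], [1.0]), 1.5, acc.registry, acc)


class TestComputeSst:
    def test_hand_computed_micro_example(self):
        """Two languages, three aligned forms with weights checked by hand."""
        wl = make_wordlist(
            [
                ("A", "c1", "pata"),
                ("B", "c1", "pata"),
                ("A", "c2", "kaki"),
                ("B", "c2", "kati"),
                ("A", "c3", "mana"),
                ("B", "c3", "mana"),
            ]
        )
        sets = [
            ps.HomologueSet("c1", frozenset({("A", 0), ("B", 1)})),
            ps.HomologueSet("c2", frozenset({("A", 2), ("B", 3)})),
            ps.HomologueSet("c3", frozenset({("A", 4), ("B", 5)})),
        ]
        sim = ps.initial_scores()
        # constant info weights make the hand computation tractable
        class Flat:
            def profile(self, segments):
                return np.ones(len(segments))

        info = {"A": Flat(), "B": Flat()}
        sst, pairs = ps.compute_sst(wl, sets, sim, info_models=info)
        # s = 11 identical of 12 aligned cells; rate = 1/12
        assert pairs.iloc[0]["s"] == pytest.approx(11 / 12)
        # group "voiceless velar": k-k stable (2 sides), k-t out (1 side);
        # sst = 2/3 exactly
        assert sst.loc["voiceless velar", "sst"] == pytest.approx(2 / 3, abs=1e-12)
        # nasal: all m/n cells identical -> sst 1
        assert sst.loc["nasal", "sst"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_change_degenerate_all_na(self):
        """Identical languages have rate 0 everywhere, so no counts accrue."""
        wl = make_wordlist([("A", "c1", "pata"), ("B", "c1", "pata")])
        sets = [ps.HomologueSet("c1", frozenset({("A", 0), ("B", 1)}))]
        sst, _ = ps.compute_sst(wl, sets, ps.initial_scores())
        assert sst["sst"].isna().all()

    def test_empty_homologues_rejected(self, toy_wordlist):
        with pytest.raises(ValueError):
            ps.compute_sst(toy_wordlist, [], ps.initial_scores())

    def test_sparse_groups_na(self, recovery_run):
        sst = recovery_run["sst"]
        for name in ps.default_registry().sparse_excluded:
            assert np.isnan(sst.loc[name, "sst"])

    def test_proportions_and_bounds(self, recovery_run):
        """For every observed group the four proportions sum to one."""
        sst = recovery_run["sst"]
        observed = sst[sst["total"] > 0]
        props = observed[["p_stable", "p_shift_in", "p_shift_out", "p_indel"]]
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-9)
        defined = sst["sst"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()

    def test_scale_free_in_info_weights(self):
        """Multiplying all info weights by c > 0 leaves every sst unchanged."""
        wl, truth = ps.simulate(ps.SimConfig(n_leaves=4, concept_count=15, seed=21))
        sim = ps.estimate_pmi(wl, iterations=1)

        class Scaled:
            def __init__(self, inner, c):
                self.inner, self.c = inner, c

            def profile(self, segments):
                return self.c * self.inner.profile(segments)

        from phonostab.infoweight import fit_info_model

        base = {l: fit_info_model(wl, l) for l in sorted(wl.languages)}
        scaled = {l: Scaled(m, 0.37) for l, m in base.items()}
        sst1, _ = ps.compute_sst(wl, truth.true_homologues, sim, info_models=base)
        sst2, _ = ps.compute_sst(wl, truth.true_homologues, sim, info_models=scaled)
        np.testing.assert_allclose(
            sst1["sst"].to_numpy(), sst2["sst"].to_numpy(), atol=1e-9, equal_nan=True
        )

    def test_graded_preset_consonants_more_stable_than_vowels(self):
        """With vowel intensities above consonant ones, consonant groups come
        out more stable on average — the coarse empirical ordering."""
        wl, _ = ps.simulate(ps.default_presets()["graded"])
        sim = ps.estimate_pmi(wl)
        sets = ps.cluster_homologues(wl, sim)
        sst, _ = ps.compute_sst(wl, sets, sim)
        d = sst.dropna(subset=["sst"])
        assert (
            d[d["major"] == "consonant"]["sst"].mean()
            > d[d["major"] == "vowel"]["sst"].mean()
        )
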