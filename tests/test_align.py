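"""Alignment, PMI learning and homologue clustering."""

import itertools

import numpy as np
import pytest

import phonostab as ps
from phonostab.align import GAP, SimilarityModel

from conftest import make_wordlist


def brute_force_best(left, right, sim, gap):
    """Independent oracle: exhaustive recursion over all global alignments."""
    if not left and not right:
        return 0.0
    best = -np.inf
    if left and right:
        best = max(
            best, sim.score(left[0], right[0]) + brute_force_best(left[1:], right[1:], sim, gap)
        )
    if left:
        best = max(best, gap + brute_force_best(left[1:], right, sim, gap))
    if right:
        best = max(best, gap + brute_force_best(left, right[1:], sim, gap))
    return best


@pytest.fixture(scope="module")
def random_sim():
    """A fixed random symmetric score table over four IPA segments."""
    rng = np.random.default_rng(42)
    alphabet = ("p", "t", "a", "u")
    scores = {}
    for x, y in itertools.combinations_with_replacement(alphabet, 2):
        v = float(np.round(rng.uniform(-3, 3), 3))
        scores[(x, y)] = scores[(y, x)] = v
    return SimilarityModel(scores=scores, gap_penalty=-1.0), alphabet


class TestInitialScores:
    @pytest.mark.parametrize("pair,expected", [(("p", "p"), 2), (("p", "b"), 1), (("p", "a"), -2)])
    def test_stated_rules(self, pair, expected):
        sim = ps.initial_scores()
        assert sim.score(*pair) == expected

    def test_symmetry_and_self_dominance(self):
        sim = ps.initial_scores()
        for a, b in itertools.product("ptkmsau", repeat=2):
            assert sim.score(a, b) == sim.score(b, a)
            assert sim.score(a, a) >= sim.score(a, b)


class TestNWAlign:
    def test_identity_alignment(self):
        sim = ps.initial_scores()
        aln = ps.nw_align(tuple("kaksi"), tuple("kaksi"), sim)
        assert aln.score == 10
        assert all(a == b and a is not GAP for a, b in aln.cells)

    def test_forced_gap(self):
        sim = ps.initial_scores()
        aln = ps.nw_align(("a",), ("a", "b"), sim)
        assert aln.cells == (("a", "a"), (GAP, "b"))
        assert aln.score == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ps.nw_align((), ("a",), ps.initial_scores())

    def test_matches_brute_force_on_short_pairs(self, random_sim):
        sim, alphabet = random_sim
        seqs = [
            s
            for n in (1, 2, 3)
            for s in itertools.product(alphabet, repeat=n)
        ]
        rng = np.random.default_rng(0)
        sample = rng.choice(len(seqs), size=40, replace=False)
        for i in sample:
            for j in sample[:10]:
                left, right = seqs[i], seqs[j]
                aln = ps.nw_align(left, right, sim)
                assert aln.score == pytest.approx(
                    brute_force_best(left, right, sim, sim.gap_penalty)
                )

    def test_score_symmetric_under_swap(self, random_sim):
        sim, alphabet = random_sim
        rng = np.random.default_rng(1)
        for _ in range(50):
            left = tuple(rng.choice(alphabet, size=rng.integers(1, 6)))
            right = tuple(rng.choice(alphabet, size=rng.integers(1, 6)))
            a = ps.nw_align(left, right, sim)
            b = ps.nw_align(right, left, sim)
            assert a.score == pytest.approx(b.score)

    def test_gap_cells_never_both_sides(self, random_sim):
        sim, alphabet = random_sim
        rng = np.random.default_rng(2)
        for _ in range(30):
            left = tuple(rng.choice(alphabet, size=rng.integers(1, 6)))
            right = tuple(rng.choice(alphabet, size=rng.integers(1, 6)))
            aln = ps.nw_align(left, right, sim)
            assert all(a is not GAP or b is not GAP for a, b in aln.cells)
            assert tuple(a for a, _ in aln.cells if a is not GAP) == left
            assert tuple(b for _, b in aln.cells if b is not GAP) == right


class TestEstimatePMI:
    def test_regular_correspondence_reaches_clip(self):
        """A rare segment that always corresponds to itself hits the PMI
        ceiling on a 20-concept wordlist."""
        rng = np.random.default_rng(5)
        cons, vows = list("ptmnsl"), list("aeiou")
        rows = []
        for i in range(20):
            first = "k" if i < 3 else str(rng.choice(cons))  # k is rare but regular
            base = [first, str(rng.choice(vows)), str(rng.choice(cons)), str(rng.choice(vows))]
            for lang, shift in (("A", 0), ("B", 1)):
                w = [
                    c if c not in vows else vows[(vows.index(c) + shift) % 5]
                    for c in base
                ]
                rows.append((lang, f"c{i}", "".join(w)))
        sim = ps.estimate_pmi(make_wordlist(rows), iterations=2)
        assert sim.score("k", "k") == pytest.approx(3.0)

    def test_scores_symmetric(self, toy_wordlist):
        sim = ps.estimate_pmi(toy_wordlist, iterations=1)
        inv = sorted(toy_wordlist.segment_inventory())
        for a, b in itertools.product(inv, repeat=2):
            assert sim.scores[(a, b)] == sim.scores[(b, a)]

    def test_keep_fraction_one_single_concept(self):
        wl = make_wordlist([("A", "eye", "kala"), ("B", "eye", "kola")])
        sim = ps.estimate_pmi(wl, keep_fraction=1.0, iterations=1)
        assert sim.iterations_run == 1

    def test_too_few_languages(self):
        wl = make_wordlist([("A", "eye", "kala"), ("A", "sun", "mi")])
        with pytest.raises(ValueError):
            ps.estimate_pmi(wl)

    def test_converges_to_fixed_point(self):
        """The score table stops changing between late iterations."""
        wl, _ = ps.simulate(ps.SimConfig(n_leaves=4, concept_count=25, seed=17))
        s9 = ps.estimate_pmi(wl, iterations=9)
        s10 = ps.estimate_pmi(wl, iterations=10)
        diff = max(abs(s9.scores[k] - s10.scores[k]) for k in s9.scores)
        assert diff < 1e-6


class TestClusterHomologues:
    def test_identical_forms_one_set(self):
        wl = make_wordlist([(lang, "eye", "kala") for lang in "ABC"])
        sim = ps.initial_scores()
        sets = ps.cluster_homologues(wl, sim, threshold=0.1)
        assert len(sets) == 1
        assert len(sets[0].members) == 3

    def test_nonpositive_score_separates(self):
        wl = make_wordlist([("A", "eye", "papa"), ("B", "eye", "iui")])
        sim = ps.initial_scores()
        sets = ps.cluster_homologues(wl, sim, threshold=0.9)
        assert len(sets) == 2

    def test_threshold_validated(self, toy_wordlist):
        with pytest.raises(ValueError):
            ps.cluster_homologues(toy_wordlist, ps.initial_scores(), threshold=1.5)

    def test_partition_covers_all_forms(self, recovery_run):
        covered = sorted(
            idx for hs in recovery_run["sets"] for _, idx in hs.members
        )
        assert covered == list(range(len(recovery_run["wordlist"])))


class TestBCubed:
    def test_perfect_match(self):
        sets = [ps.HomologueSet("c", frozenset({("A", 0), ("B", 1)}))]
        assert ps.bcubed_f(sets, sets) == 1.0

    def test_oversplit_penalized(self):
        truth = [ps.HomologueSet("c", frozenset({("A", 0), ("B", 1)}))]
        pred = [
            ps.HomologueSet("c", frozenset({("A", 0)})),
            ps.HomologueSet("c", frozenset({("B", 1)})),
        ]
        assert ps.bcubed_f(pred, truth) == pytest.approx(2 * 1 * 0.5 / 1.5)
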