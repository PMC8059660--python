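"""Synthetic lexical evolution over a language-family tree.

Proto-words (CV-alternating strings over a configurable IPA inventory) evolve
down a balanced binary tree.  Each segment carries an exponential replacement
clock whose intensity λ depends on its manner class (consonants) or height
class (vowels); on an edge of length t it is replaced with probability
1 − exp(−λ t), the replacement drawn from a kernel splitting mass between a
different segment of the same class, a segment of another class, and outright
deletion.  Insertions arrive as a Poisson process.  Optional extras emulate
two nuisances of real wordlists: shared inflection-like suffixes appended per
language (to exercise information weighting) and horizontal borrowing.
Iconicity is seeded by forcing chosen groups into chosen concepts'
proto-words with a given probability.

Ground truth (per-group expected retention, true homologue sets, the seeded
pairs) is returned alongside the wordlist so every pipeline stage can be
validated by parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .align import HomologueSet
from .sound_classes import Segment, default_segment_table
from .wordlist import WordForm, Wordlist

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate",
    "expected_retention",
    "default_presets",
    "DEFAULT_INVENTORY",
]

#: default segment inventory: a mid-sized, typologically plausible system
#: covering every non-sparse group of the default registry
DEFAULT_INVENTORY = (
    "p b t d k g ʔ t͡ʃ d͡ʒ m n ɲ ŋ f v s z ʃ ʒ x ɣ h j w r ɾ l ʎ "
    "i y ɨ u ɯ e ø ə o ɛ ɔ æ a ɐ ɑ"
).split()

#: shared suffix pool emulating recurring inflectional endings
DEFAULT_SUFFIXES = (("t", "a"), ("n", "a"), ("k", "o"), ("m", "i"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run; defaults give a moderate scenario."""

    n_leaves: int = 10
    branch_length: float = 0.1
    inventory: tuple[str, ...] = tuple(DEFAULT_INVENTORY)
    concept_count: int = 50
    word_length: tuple[int, int] = (3, 6)
    suffix_mode: bool = False
    suffixes: tuple[tuple[str, ...], ...] = DEFAULT_SUFFIXES
    intensities: dict = field(
        default_factory=lambda: {
            c: 0.7
            for c in ("nasal", "stop", "continuant", "vibrant", "lateral", "high", "mid", "low")
        }
    )
    replacement_kernel: tuple[float, float, float] = (0.15, 0.70, 0.15)
    insertion_rate: float = 0.05
    iconic_seeds: tuple[tuple[str, str, float], ...] = ()  # (concept, group, boost)
    borrowing_rate: float = 0.0
    lineage_mode: str = "tree"  # "tree": common descent; "independent": one language per family
    seed: int = 0

    def __post_init__(self):
        a, b, d = self.replacement_kernel
        if not np.isclose(a + b + d, 1.0) or min(a, b, d) < 0:
            raise ValueError("replacement_kernel must be a probability triple")
        if self.insertion_rate < 0 or self.borrowing_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.lineage_mode not in ("tree", "independent"):
            raise ValueError(f"unknown lineage_mode {self.lineage_mode!r}")


@dataclass
class SimTruth:
    """Ground truth emitted with a simulated wordlist."""

    true_retention: dict  # group name -> mean pairwise expected identity
    true_homologues: list  # HomologueSet per concept
    iconic_seeds: tuple


def expected_retention(lam: float, path_length: float) -> float:
    """Probability a segment survives unreplaced over a tree path: exp(−λ·path)."""
    if lam < 0:
        raise ValueError("intensity must be non-negative")
    return float(np.exp(-lam * path_length))


def _segment_class(seg: Segment) -> str:
    return seg.manner if seg.major == "consonant" else seg.height


def _build_tree(n_leaves: int) -> list[tuple[int, ...]]:
    """Leaf addresses (paths of 0/1 edge choices) of a balanced binary tree."""

    def split(prefix: tuple[int, ...], n: int) -> list[tuple[int, ...]]:
        if n == 1:
            return [prefix]
        half = n // 2
        return split(prefix + (0,), n - half) + split(prefix + (1,), half)

    return split((), n_leaves)


def _path_length(a: tuple[int, ...], b: tuple[int, ...], branch_length: float) -> float:
    common = 0
    for x, y in zip(a, b):
        if x != y:
            break
        common += 1
    return branch_length * (len(a) - common + len(b) - common)


def simulate(config: SimConfig) -> tuple[Wordlist, SimTruth]:
    """Run one simulation; fully reproducible from ``config.seed``."""
    table = default_segment_table()
    rng = np.random.default_rng(config.seed)
    classified = {t: table.classify(t) for t in config.inventory}
    by_class: dict[str, list[str]] = {}
    by_major: dict[str, list[str]] = {"consonant": [], "vowel": []}
    for tok, seg in classified.items():
        by_class.setdefault(_segment_class(seg), []).append(tok)
        by_major[seg.major].append(tok)
    for cls, lam in config.intensities.items():
        if lam > 0 and cls not in by_class:
            raise ValueError(f"inventory lacks any segment of class {cls!r}")

    from .sound_classes import default_registry

    registry = default_registry()
    group_members = {
        g.name: [t for t, s in classified.items() if g.contains(s)] for g in registry
    }

    leaves = _build_tree(config.n_leaves)
    languages = [f"L{i:03d}" for i in range(config.n_leaves)]
    concepts = [f"C{i:03d}" for i in range(config.concept_count)]
    seeds_by_concept: dict[str, list[tuple[str, float]]] = {}
    for concept, group, boost in config.iconic_seeds:
        seeds_by_concept.setdefault(concept, []).append((group, boost))

    # --- proto-words -----------------------------------------------------
    lo, hi = config.word_length

    def draw_word(concept: str) -> list[str]:
        """A fresh CV-alternating word, with the concept's iconic seeds applied."""
        length = int(rng.integers(lo, hi + 1))
        start_major = "consonant" if rng.random() < 0.5 else "vowel"
        majors = ["consonant", "vowel"]
        if start_major == "vowel":
            majors = majors[::-1]
        word = [str(rng.choice(by_major[majors[i % 2]])) for i in range(length)]
        for group, boost in seeds_by_concept.get(concept, ()):
            members = group_members.get(group)
            if not members:
                raise ValueError(f"iconic seed group {group!r} has no inventory member")
            if rng.random() < boost:
                gmajor = registry[group].major
                slots = [i for i, t in enumerate(word) if classified[t].major == gmajor]
                tok = str(rng.choice(members))
                if slots:
                    word[int(rng.choice(slots))] = tok
                else:
                    word.append(tok)
        return word

    languages_list = languages
    if config.lineage_mode == "independent":
        # one language per family: every (language, concept) word is an
        # independent draw, so there is no common descent at all
        forms = [
            WordForm(
                language_id=lang,
                concept_id=concept,
                form="".join(w),
                segments=tuple(w),
            )
            for concept in concepts
            for lang in languages_list
            for w in [draw_word(concept)]
        ]
        wordlist = Wordlist(forms)
        true_homologues = [
            HomologueSet(f.concept_id, frozenset({(f.language_id, i)}))
            for i, f in enumerate(wordlist.forms)
        ]
        return wordlist, SimTruth(
            true_retention={},
            true_homologues=true_homologues,
            iconic_seeds=config.iconic_seeds,
        )

    protos: dict[str, list[str]] = {concept: draw_word(concept) for concept in concepts}

    # --- evolution down the tree ----------------------------------------
    alpha, beta, delta = config.replacement_kernel

    def mutate(word: list[str], t: float) -> list[str]:
        out: list[str] = []
        for tok in word:
            lam = config.intensities.get(_segment_class(classified[tok]), 0.0)
            if rng.random() >= 1.0 - np.exp(-lam * t):
                out.append(tok)
                continue
            u = rng.random()
            if u < alpha:
                cls = _segment_class(classified[tok])
                options = [c for c in by_class[cls] if c != tok]
                out.append(str(rng.choice(options)) if options else tok)
            elif u < alpha + beta:
                major = classified[tok].major
                if rng.random() < 0.9:
                    pool_major = major
                else:
                    pool_major = "vowel" if major == "consonant" else "consonant"
                cls = _segment_class(classified[tok])
                options = [
                    c for c in by_major[pool_major] if _segment_class(classified[c]) != cls
                ]
                out.append(str(rng.choice(options)) if options else tok)
            else:
                if len(word) == 1:
                    out.append(tok)  # never delete a word to nothing
                continue
        if not out:
            out = [word[-1]]  # full deletion: retain the final segment
        n_ins = rng.poisson(config.insertion_rate * t)
        for _ in range(n_ins):
            pos = int(rng.integers(0, len(out) + 1))
            out.insert(pos, str(rng.choice(config.inventory)))
        return out

    def evolve(word: list[str], depth_prefix: tuple[int, ...]) -> dict[tuple[int, ...], list[str]]:
        """Evolve a word along the subtree below ``depth_prefix``."""
        children = {}
        subtree = [lf for lf in leaves if lf[: len(depth_prefix)] == depth_prefix]
        if subtree == [depth_prefix]:
            return {depth_prefix: word}
        for branch in (0, 1):
            sub = [lf for lf in subtree if lf[len(depth_prefix)] == branch]
            if not sub:
                continue
            evolved = mutate(list(word), config.branch_length)
            children.update(evolve(evolved, depth_prefix + (branch,)))
        return children

    forms: list[WordForm] = []
    leaf_words: dict[str, dict[str, list[str]]] = {c: {} for c in concepts}
    leaf_index = {leaf: languages[i] for i, leaf in enumerate(leaves)}
    for concept in concepts:
        evolved = evolve(list(protos[concept]), ())
        for leaf, word in evolved.items():
            leaf_words[concept][leaf_index[leaf]] = word

    # --- borrowing -------------------------------------------------------
    if config.borrowing_rate > 0:
        for concept in concepts:
            for lang in languages:
                if rng.random() < config.borrowing_rate:
                    donor = str(rng.choice([l for l in languages if l != lang]))
                    leaf_words[concept][lang] = list(leaf_words[concept][donor])

    # --- suffixes --------------------------------------------------------
    suffix_of: dict[str, tuple[str, ...]] = {}
    if config.suffix_mode:
        for lang in languages:
            suffix_of[lang] = config.suffixes[
                int(rng.integers(0, len(config.suffixes)))
            ]

    for concept in concepts:
        for lang in languages:
            word = list(leaf_words[concept][lang])
            if config.suffix_mode:
                word = word + list(suffix_of[lang])
            forms.append(
                WordForm(
                    language_id=lang,
                    concept_id=concept,
                    form="".join(word),
                    segments=tuple(word),
                )
            )
    # synonyms cannot arise here, but identical independent developments can;
    # disambiguate duplicate (language, concept, form) rows by keeping the first
    seen = set()
    unique_forms = []
    for f in forms:
        key = (f.language_id, f.concept_id, f.form)
        if key not in seen:
            seen.add(key)
            unique_forms.append(f)
    wordlist = Wordlist(unique_forms)

    # --- ground truth ----------------------------------------------------
    pair_paths = [
        _path_length(a, b, config.branch_length)
        for a, b in itertools.combinations(leaves, 2)
    ]
    mean_exp = {
        cls: float(np.mean([expected_retention(lam, p) for p in pair_paths]))
        for cls, lam in config.intensities.items()
    }
    true_retention = {}
    for g in registry:
        members = group_members[g.name]
        if not members:
            continue
        true_retention[g.name] = float(
            np.mean([mean_exp[_segment_class(classified[t])] for t in members])
        )
    idx_of = {
        (f.language_id, f.concept_id): i for i, f in enumerate(wordlist.forms)
    }
    true_homologues = [
        HomologueSet(
            concept,
            frozenset(
                (lang, idx_of[(lang, concept)])
                for lang in languages
                if (lang, concept) in idx_of
            ),
        )
        for concept in concepts
    ]
    return wordlist, SimTruth(
        true_retention=true_retention,
        true_homologues=true_homologues,
        iconic_seeds=config.iconic_seeds,
    )


def iconicity_counterpart(config: SimConfig, seed_offset: int = 1) -> SimConfig:
    """The independent-lineage companion of a tree-mode configuration.

    Stability and iconicity are measured on different samples in this
    design — stability on a family tree of related languages, iconicity on a
    one-language-per-family global sample.  This returns a configuration with
    the same concepts, inventory and iconic seeds but unrelated languages,
    for building the iconicity table that is joined against the tree
    sample's stability estimates.
    """
    import dataclasses

    return dataclasses.replace(
        config, lineage_mode="independent", seed=config.seed + seed_offset
    )


# ---------------------------------------------------------------------------
# presets


def _graded_intensities() -> dict:
    # coarse stability ordering: nasals/stops/laterals most stable,
    # continuants and vibrants intermediate, vowels least, low vowels worst
    return {
        "nasal": 0.3,
        "stop": 0.45,
        "lateral": 0.6,
        "continuant": 0.9,
        "vibrant": 1.2,
        "high": 1.4,
        "mid": 1.7,
        "low": 2.0,
    }


def _coupled_seeds() -> tuple[tuple[str, str, float], ...]:
    """Iconicity seeded preferentially into high-stability groups."""
    # seeds go to the lowest-intensity groups; globally these are mostly
    # consonantal (nasals, stops, laterals), with the highest vowels as the
    # most stable vocalic groups
    consonant_groups = ["nasal", "voiced nasal", "stop", "voiceless stop", "labial"]
    vowel_groups = ["high vowel", "high front vowel", "high back vowel"]
    seeds = []
    for i in range(60):
        concept = f"C{i:03d}"
        if i % 4 == 3:
            group = vowel_groups[(i // 4) % len(vowel_groups)]
        else:
            group = consonant_groups[i % len(consonant_groups)]
        seeds.append((concept, group, 0.9))
    return tuple(seeds)


def default_presets() -> dict[str, SimConfig]:
    """Named study conditions used throughout the test-bench.

    null
        no iconic seeds, uniform moderate intensities, long branches so the
        leaves are effectively unrelated — emulating the one-language-per-
        family design of a global iconicity sample.
    graded
        intensities increasing nasal/stop/lateral < continuant < vibrant <
        vowels, matching the coarse stability ordering the method should find.
    coupled
        graded intensities with iconicity seeded into high-stability groups.
    recovery
        the parameter-recovery condition: 20 languages, 300 concepts,
        intensities spanning 0.2–2.0, fixed seed.
    """
    return {
        "null": SimConfig(
            n_leaves=100,
            concept_count=50,
            branch_length=0.5,
            lineage_mode="independent",
            intensities={
                c: 0.7
                for c in (
                    "nasal",
                    "stop",
                    "continuant",
                    "vibrant",
                    "lateral",
                    "high",
                    "mid",
                    "low",
                )
            },
            seed=11,
        ),
        "graded": SimConfig(
            n_leaves=16,
            concept_count=100,
            branch_length=0.03,
            intensities=_graded_intensities(),
            seed=12,
        ),
        "coupled": SimConfig(
            n_leaves=32,
            concept_count=150,
            branch_length=0.03,
            intensities=_graded_intensities(),
            iconic_seeds=_coupled_seeds(),
            seed=13,
        ),
        "recovery": SimConfig(
            n_leaves=20,
            concept_count=300,
            branch_length=0.02,
            intensities={
                "nasal": 0.2,
                "stop": 0.4,
                "lateral": 0.65,
                "continuant": 0.9,
                "vibrant": 1.2,
                "high": 1.4,
                "mid": 1.7,
                "low": 2.0,
            },
            seed=20200190,
        ),
    }
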