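"""Pairwise global alignment, data-driven segment similarity, homologue clustering.

Similarity scores are learned by an iterative PMI scheme: align all
cross-language same-concept form pairs under the current scores, keep the
best-scoring fraction, and re-estimate pointwise mutual information from the
aligned non-gap cells.  Homologue (cognate) sets are then found per concept
by average-linkage clustering of score-normalized alignment distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .infoweight import InfoModel, info_profile
from .sound_classes import Segment, SegmentTable, default_segment_table
from .wordlist import Wordlist

__all__ = [
    "GAP",
    "SimilarityModel",
    "Alignment",
    "HomologueSet",
    "initial_scores",
    "nw_align",
    "estimate_pmi",
    "cluster_homologues",
    "bcubed_f",
]

#: gap marker used in alignment cells
GAP = None

PMI_CLIP = 3.0
PMI_SMOOTHING = 0.1


@dataclass
class SimilarityModel:
    """Symmetric segment-pair scores with a linear gap penalty.

    Unseen pairs fall back to a coarse feature-based score so the model is
    total over any segment inventory.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    gap_penalty: float = -1.0
    iterations_run: int = 0
    fallback: Callable[[str, str], float] | None = None

    def score(self, a: str, b: str) -> float:
        s = self.scores.get((a, b))
        if s is not None:
            return s
        if self.fallback is not None:
            s = self.fallback(a, b)
        else:
            s = 2.0 if a == b else -1.0
        self.scores[(a, b)] = s
        self.scores[(b, a)] = s
        return s


def _feature_fallback(table: SegmentTable) -> Callable[[str, str], float]:
    def fallback(a: str, b: str) -> float:
        if a == b:
            return 2.0
        sa: Segment = table.classify(a)
        sb: Segment = table.classify(b)
        if sa.major != sb.major:
            return -2.0
        if (
            sa.major == "consonant"
            and sa.manner == sb.manner
            and sa.place == sb.place
            and sa.voicing != sb.voicing
        ):
            return 1.0
        return 0.0

    return fallback


def initial_scores(registry=None, table: SegmentTable | None = None) -> SimilarityModel:
    """Bootstrap similarity model used to seed PMI estimation.

    Identity +2; same place and manner but different voicing +1; same major
    class 0; consonant against vowel −2; gap penalty −1.  The ``registry``
    argument is accepted for interface symmetry; scoring only needs the
    segment feature table.
    """
    del registry
    table = table or default_segment_table()
    return SimilarityModel(fallback=_feature_fallback(table))


@dataclass
class Alignment:
    """A scored global alignment of two segmented forms with per-cell weights."""

    cells: tuple[tuple[str | None, str | None], ...]
    score: float
    weights: np.ndarray
    left_language: str = ""
    right_language: str = ""

    def __post_init__(self):
        assert all(a is not GAP or b is not GAP for a, b in self.cells)


def nw_align(
    left: Sequence[str],
    right: Sequence[str],
    sim: SimilarityModel,
    info_left: InfoModel | None = None,
    info_right: InfoModel | None = None,
    left_language: str = "",
    right_language: str = "",
) -> Alignment:
    """Needleman–Wunsch global alignment with a linear gap penalty.

    Traceback ties are broken deterministically: substitution is preferred
    over a gap on the left side, which is preferred over a gap on the right.
    Cell weights are the mean of the two sides' information content (the
    non-gap side's alone for gap cells), or 1 when no info models are given.
    """
    left = tuple(left)
    right = tuple(right)
    if not left or not right:
        raise ValueError("nw_align requires non-empty sequences")
    n, m = len(left), len(right)
    g = sim.gap_penalty
    F = np.empty((n + 1, m + 1))
    F[:, 0] = g * np.arange(n + 1)
    F[0, :] = g * np.arange(m + 1)
    for i in range(1, n + 1):
        a = left[i - 1]
        row = F[i]
        prev = F[i - 1]
        for j in range(1, m + 1):
            row[j] = max(
                prev[j - 1] + sim.score(a, right[j - 1]),
                row[j - 1] + g,
                prev[j] + g,
            )
    cells: list[tuple[str | None, str | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and F[i, j] == F[i - 1, j - 1] + sim.score(left[i - 1], right[j - 1])
        ):
            cells.append((left[i - 1], right[j - 1]))
            i -= 1
            j -= 1
        elif j > 0 and F[i, j] == F[i, j - 1] + g:
            cells.append((GAP, right[j - 1]))
            j -= 1
        else:
            cells.append((left[i - 1], GAP))
            i -= 1
    cells.reverse()

    if info_left is not None and info_right is not None:
        wl = info_profile(info_left, left)
        wr = info_profile(info_right, right)
        weights = np.empty(len(cells))
        li = ri = 0
        for c, (a, b) in enumerate(cells):
            if a is not GAP and b is not GAP:
                weights[c] = 0.5 * (wl[li] + wr[ri])
                li += 1
                ri += 1
            elif a is not GAP:
                weights[c] = wl[li]
                li += 1
            else:
                weights[c] = wr[ri]
                ri += 1
    else:
        weights = np.ones(len(cells))

    return Alignment(
        cells=tuple(cells),
        score=float(F[n, m]),
        weights=weights,
        left_language=left_language,
        right_language=right_language,
    )


def _concept_pairs(wordlist: Wordlist, cross_language: bool = True):
    """All (form_i, form_j) index pairs sharing a concept (i < j)."""
    by_concept: dict[str, list[int]] = {}
    for i, f in enumerate(wordlist.forms):
        by_concept.setdefault(f.concept_id, []).append(i)
    for concept, idxs in sorted(by_concept.items()):
        for i, j in itertools.combinations(idxs, 2):
            if cross_language and wordlist.forms[i].language_id == wordlist.forms[j].language_id:
                continue
            yield i, j


def estimate_pmi(
    wordlist: Wordlist,
    sim0: SimilarityModel | None = None,
    iterations: int = 3,
    keep_fraction: float = 0.7,
) -> SimilarityModel:
    """Learn PMI similarity scores from cross-language same-concept pairs.

    Each round aligns all pairs under the current scores, keeps the
    ``keep_fraction`` best by length-normalized score, and recomputes
    scores(a, b) = log2(p(a,b) / (p(a) p(b))) from aligned non-gap cells with
    add-0.1 smoothing, clipped to ±3.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if len(wordlist.languages) < 2:
        raise ValueError("PMI estimation needs at least 2 languages")
    sim = sim0 or initial_scores()
    inventory = sorted(wordlist.segment_inventory())
    V = len(inventory)
    pairs = list(_concept_pairs(wordlist))

    for it in range(iterations):
        scored = []
        for i, j in pairs:
            a = wordlist.forms[i].segments
            b = wordlist.forms[j].segments
            aln = nw_align(a, b, sim)
            norm = aln.score / (0.5 * (len(a) + len(b)))
            scored.append((norm, i, aln))
        scored.sort(key=lambda t: -t[0])
        kept = scored[: max(1, math.ceil(keep_fraction * len(scored)))]

        joint: dict[tuple[str, str], float] = {}
        marg: dict[str, float] = {}
        total = 0.0
        for _, _, aln in kept:
            for a, b in aln.cells:
                if a is GAP or b is GAP:
                    continue
                joint[(a, b)] = joint.get((a, b), 0.0) + 1.0
                joint[(b, a)] = joint.get((b, a), 0.0) + 1.0
                marg[a] = marg.get(a, 0.0) + 1.0
                marg[b] = marg.get(b, 0.0) + 1.0
                total += 2.0
        denom = total + PMI_SMOOTHING * V * V
        scores: dict[tuple[str, str], float] = {}
        for a in inventory:
            pa = (marg.get(a, 0.0) + PMI_SMOOTHING * V) / denom
            for b in inventory:
                pb = (marg.get(b, 0.0) + PMI_SMOOTHING * V) / denom
                pab = (joint.get((a, b), 0.0) + PMI_SMOOTHING) / denom
                pmi = math.log2(pab / (pa * pb))
                scores[(a, b)] = float(np.clip(pmi, -PMI_CLIP, PMI_CLIP))
        sim = SimilarityModel(
            scores=scores,
            gap_penalty=sim.gap_penalty,
            iterations_run=it + 1,
            fallback=sim.fallback,
        )
    return sim


@dataclass(frozen=True)
class HomologueSet:
    """Forms (by wordlist index) judged to descend from one ancestral form."""

    concept_id: str
    members: frozenset[tuple[str, int]]  # (language_id, form index)


def cluster_homologues(
    wordlist: Wordlist, sim: SimilarityModel, threshold: float = 0.45
) -> list[HomologueSet]:
    """Partition each concept's forms into homologue sets.

    Distance between forms f, g is 1 − score(f,g) / mean(score(f,f),
    score(g,g)), clipped to [0, 1]; average-linkage clustering is cut at
    ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out: list[HomologueSet] = []
    by_concept: dict[str, list[int]] = {}
    for i, f in enumerate(wordlist.forms):
        by_concept.setdefault(f.concept_id, []).append(i)
    for concept, idxs in sorted(by_concept.items()):
        if len(idxs) == 1:
            f = wordlist.forms[idxs[0]]
            out.append(
                HomologueSet(concept, frozenset({(f.language_id, idxs[0])}))
            )
            continue
        self_scores = [
            nw_align(wordlist.forms[i].segments, wordlist.forms[i].segments, sim).score
            for i in idxs
        ]
        k = len(idxs)
        dm = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                s_ab = nw_align(
                    wordlist.forms[idxs[a]].segments,
                    wordlist.forms[idxs[b]].segments,
                    sim,
                ).score
                denom = 0.5 * (self_scores[a] + self_scores[b])
                d = 1.0 if denom <= 0 else 1.0 - s_ab / denom
                dm[a, b] = dm[b, a] = float(np.clip(d, 0.0, 1.0))
        labels = fcluster(
            linkage(squareform(dm, checks=False), method="average"),
            t=threshold,
            criterion="distance",
        )
        for lab in sorted(set(labels)):
            members = frozenset(
                (wordlist.forms[idxs[a]].language_id, idxs[a])
                for a in range(k)
                if labels[a] == lab
            )
            out.append(HomologueSet(concept, members))
    return out


def bcubed_f(
    predicted: Iterable[HomologueSet], truth: Iterable[HomologueSet]
) -> float:
    """B-cubed F-score of a predicted homologue partition against truth."""
    pred_of: dict[tuple[str, int], frozenset] = {}
    true_of: dict[tuple[str, int], frozenset] = {}
    for hs in predicted:
        for m in hs.members:
            pred_of[m] = hs.members
    for hs in truth:
        for m in hs.members:
            true_of[m] = hs.members
    items = sorted(set(pred_of) & set(true_of))
    if not items:
        raise ValueError("no overlapping items between partitions")
    precision = recall = 0.0
    for it in items:
        inter = len(pred_of[it] & true_of[it])
        precision += inter / len(pred_of[it])
        recall += inter / len(true_of[it])
    precision /= len(items)
    recall /= len(items)
    return 2 * precision * recall / (precision + recall)
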