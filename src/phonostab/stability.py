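"""Sound-group stability (SSt) estimation from homologue-pair alignments.

For every unordered language pair, all cross-language form pairs inside each
homologue set are aligned.  The pair's stability s is the information-
weighted proportion of aligned both-segment cells whose tokens are identical;
1 − s, the pair's overall rate of phonetic replacement, then down-weights
every instance that pair contributes, so clusters of closely related
languages cannot dominate the group counts.  Each aligned instance of a
segment from a group falls into one of four outcomes — stable (identical
token opposite), shift in group, shift out of group, or loss/gain (gap) —
and SSt is the weighted share of the first two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import GAP, Alignment, HomologueSet, SimilarityModel, nw_align
from .infoweight import InfoModel, fit_info_model
from .sound_classes import (
    GroupRegistry,
    SegmentTable,
    default_registry,
    default_segment_table,
)
from .wordlist import Wordlist

__all__ = [
    "PairStability",
    "OutcomeAccumulator",
    "pair_stability",
    "replacement_rate",
    "accumulate_outcomes",
    "compute_sst",
]

OUTCOMES = ("stable", "shift_in", "shift_out", "indel")


@dataclass(frozen=True)
class PairStability:
    """Weighted identity proportion between one language pair's homologues."""

    language_a: str
    language_b: str
    s: float
    n_word_pairs: int
    n_segment_pairs: int
    n_identical: int


def pair_stability(alignments: list[Alignment]) -> PairStability:
    """Info-weighted average stability across all alignments of one language pair.

    s = Σ w·[identical] / Σ w over cells where both sides are segments;
    the n_* tallies are unweighted.
    """
    if not alignments:
        raise ValueError("pair_stability requires at least one alignment")
    wsum = wid = 0.0
    n_seg = n_id = 0
    for aln in alignments:
        for (a, b), w in zip(aln.cells, aln.weights):
            if a is GAP or b is GAP:
                continue
            wsum += w
            n_seg += 1
            if a == b:
                wid += w
                n_id += 1
    if wsum == 0.0:
        raise ValueError("no aligned segment pairs between this language pair")
    return PairStability(
        language_a=alignments[0].left_language,
        language_b=alignments[0].right_language,
        s=wid / wsum,
        n_word_pairs=len(alignments),
        n_segment_pairs=n_seg,
        n_identical=n_id,
    )


def replacement_rate(pair: PairStability | float) -> float:
    """Overall rate of phonetic replacement for a language pair: 1 − s.

    A pair with s = 0.791 contributes each aligned instance at only 20.9% of
    a full sound pair; identical languages (s = 1) contribute nothing.
    """
    s = pair.s if isinstance(pair, PairStability) else float(pair)
    return 1.0 - s


@dataclass
class OutcomeAccumulator:
    """Per-group weighted counts in the four outcome categories."""

    registry: GroupRegistry
    table: SegmentTable = field(default_factory=default_segment_table)
    weights: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self):
        self.weights = {g.name: np.zeros(4) for g in self.registry}
        self._groups_of: dict[str, tuple] = {}

    def _segment_groups(self, token: str):
        got = self._groups_of.get(token)
        if got is None:
            got = self.registry.groups_for(self.table.classify(token))
            self._groups_of[token] = got
        return got

    def add(self, alignment: Alignment, rate: float) -> None:
        accumulate_outcomes(alignment, rate, self.registry, self)

    def to_table(self) -> pd.DataFrame:
        """SSt table: weighted outcome counts, proportions and stability rate.

        sst = (stable + shift_in) / total; NA for sparse-excluded groups and
        for groups with zero total weight.
        """
        rows = []
        for g in self.registry:
            w = self.weights[g.name]
            total = float(w.sum())
            excluded = g.name in self.registry.sparse_excluded
            if total > 0 and not excluded:
                sst = float((w[0] + w[1]) / total)
                props = w / total
            else:
                sst = np.nan
                props = np.full(4, np.nan) if total == 0 else w / total
            rows.append(
                {
                    "group": g.name,
                    "feature_class": g.feature_class,
                    "major": g.major,
                    "w_stable": w[0],
                    "w_shift_in": w[1],
                    "w_shift_out": w[2],
                    "w_indel": w[3],
                    "total": total,
                    "p_stable": props[0],
                    "p_shift_in": props[1],
                    "p_shift_out": props[2],
                    "p_indel": props[3],
                    "sst": sst,
                }
            )
        return pd.DataFrame(rows).set_index("group")


def accumulate_outcomes(
    alignment: Alignment,
    rate: float,
    registry: GroupRegistry,
    acc: OutcomeAccumulator,
) -> OutcomeAccumulator:
    """Add one alignment's instances to the per-group outcome tallies.

    Every cell is counted once per non-gap side: for each group containing
    that side's segment, weight = info weight × replacement rate goes to
    stable / shift_in / shift_out / indel depending on the opposite side.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return acc
    for (a, b), w in zip(alignment.cells, alignment.weights):
        wr = w * rate
        if wr == 0.0:
            continue
        for focal, other in ((a, b), (b, a)):
            if focal is GAP:
                continue
            other_groups = None if other is GAP else acc._segment_groups(other)
            for g in acc._segment_groups(focal):
                if other is GAP:
                    k = 3
                elif other == focal:
                    k = 0
                elif g in other_groups:
                    k = 1
                else:
                    k = 2
                acc.weights[g.name][k] += wr
    return acc


def compute_sst(
    wordlist: Wordlist,
    homologues: list[HomologueSet],
    sim: SimilarityModel,
    info_models: dict[str, InfoModel] | None = None,
    registry: GroupRegistry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full SSt computation over all language pairs.

    Returns (sst_table, pair_table): the per-group outcome/stability table
    and the per-language-pair stability report (s, word/segment/identity
    tallies).  Language pairs with s = 1 contribute no group counts.
    """
    if not homologues:
        raise ValueError("no homologue sets given")
    registry = registry or default_registry()
    if info_models is None:
        info_models = {
            lang: fit_info_model(wordlist, lang) for lang in sorted(wordlist.languages)
        }

    by_pair: dict[tuple[str, str], list[Alignment]] = {}
    for hs in homologues:
        members = sorted(hs.members)
        for (la, ia), (lb, ib) in itertools.combinations(members, 2):
            if la == lb:
                continue
            (la_, ia_), (lb_, ib_) = sorted(((la, ia), (lb, ib)))
            aln = nw_align(
                wordlist.forms[ia_].segments,
                wordlist.forms[ib_].segments,
                sim,
                info_left=info_models[la_],
                info_right=info_models[lb_],
                left_language=la_,
                right_language=lb_,
            )
            by_pair.setdefault((la_, lb_), []).append(aln)

    acc = OutcomeAccumulator(registry)
    pair_rows = []
    for (la, lb), alns in sorted(by_pair.items()):
        try:
            ps = pair_stability(alns)
        except ValueError:
            continue  # no both-segment cells for this pair
        rate = replacement_rate(ps)
        pair_rows.append(
            {
                "lang_a": la,
                "lang_b": lb,
                "s": ps.s,
                "n_word_pairs": ps.n_word_pairs,
                "n_segment_pairs": ps.n_segment_pairs,
                "n_identical": ps.n_identical,
            }
        )
        for aln in alns:
            accumulate_outcomes(aln, rate, registry, acc)
    return acc.to_table(), pd.DataFrame(pair_rows)
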