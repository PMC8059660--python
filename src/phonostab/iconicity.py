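"""Per-(concept, sound group) iconicity coding via Bayesian odds ratios.

Presence/absence of a group in a language's word for a concept is modelled
Beta-Binomially with flat Beta(1, 1) priors, separately for the focal
concept (k of n languages) and the all-concepts baseline (K of N slots).
Monte-Carlo draws of odds(p)/odds(q) give a posterior for the odds ratio;
the iconic value is the centre of the equal-tailed 95% interval.  A row is
noteworthy-strong when the centre shows at least a 25% increase and the
whole interval clears the region of practical equivalence (ROPE), and
noteworthy-weak when the interval merely excludes the null and the median
clears the ROPE.  Rows with iconic value below 1 (underrepresentations,
largely mirror images of overrepresentations elsewhere) are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sound_classes import GroupRegistry, default_registry, default_segment_table
from .wordlist import Wordlist

__all__ = [
    "OccurrenceCounts",
    "ORPosterior",
    "occurrence_counts",
    "or_posterior",
    "classify_noteworthy",
    "build_iconicity_table",
    "DEFAULT_ROPE",
]

DEFAULT_ROPE = (1.0 / 1.25, 1.25)
CENTER_THRESHOLD = 1.25  # "25% increase" rule on the iconic value


@dataclass(frozen=True)
class OccurrenceCounts:
    """Presence counts of one group for one concept against the global baseline."""

    concept_id: str
    group: str
    k: int  # languages whose word(s) for the concept contain the group
    n: int  # languages attesting the concept
    K: int  # (language, concept) slots containing the group, all concepts
    N: int  # all attested (language, concept) slots

    def __post_init__(self):
        if not (0 <= self.k <= self.n and 0 <= self.K <= self.N and self.n <= self.N):
            raise ValueError(f"inconsistent counts {self}")


@dataclass(frozen=True)
class ORPosterior:
    draws_seed: int
    median: float
    ci_low: float
    ci_high: float

    @property
    def center(self) -> float:
        return 0.5 * (self.ci_low + self.ci_high)


def occurrence_counts(
    wordlist: Wordlist, registry: GroupRegistry | None = None
) -> list[OccurrenceCounts]:
    """Presence/absence tallies for every (concept, group) pair.

    A language counts once per concept regardless of synonymy: any synonym
    containing a segment of the group makes the slot present.  The baseline
    (K, N) runs over all slots, including the focal concept's.
    """
    if len(wordlist.concepts) < 2:
        raise ValueError("occurrence counting needs at least 2 concepts")
    registry = registry or default_registry()
    table = default_segment_table()
    group_names = registry.names

    groups_of_token: dict[str, frozenset[str]] = {}

    def token_groups(token: str) -> frozenset[str]:
        got = groups_of_token.get(token)
        if got is None:
            got = frozenset(
                g.name for g in registry.groups_for(table.classify(token))
            )
            groups_of_token[token] = got
        return got

    # present[(language, concept)] = set of group names
    present: dict[tuple[str, str], set[str]] = {}
    for f in wordlist.forms:
        slot = (f.language_id, f.concept_id)
        bag = present.setdefault(slot, set())
        for tok in f.segments:
            bag |= token_groups(tok)

    N = len(present)
    K = {g: 0 for g in group_names}
    n_by_concept: dict[str, int] = {}
    k_by = {g: {} for g in group_names}
    for (lang, concept), bag in present.items():
        n_by_concept[concept] = n_by_concept.get(concept, 0) + 1
        for g in bag:
            K[g] += 1
            k_by[g][concept] = k_by[g].get(concept, 0) + 1

    out = []
    for concept in sorted(n_by_concept):
        for g in group_names:
            out.append(
                OccurrenceCounts(
                    concept_id=concept,
                    group=g,
                    k=k_by[g].get(concept, 0),
                    n=n_by_concept[concept],
                    K=K[g],
                    N=N,
                )
            )
    return out


def _or_draws(counts: OccurrenceCounts, n_draws: int, rng: np.random.Generator):
    p = rng.beta(counts.k + 1, counts.n - counts.k + 1, size=n_draws)
    q = rng.beta(counts.K + 1, counts.N - counts.K + 1, size=n_draws)
    return (p / (1.0 - p)) / (q / (1.0 - q))


def or_posterior(
    counts: OccurrenceCounts, n_draws: int = 4000, seed: int = 0
) -> ORPosterior:
    """Monte-Carlo posterior summary of the odds ratio for one row.

    Flat Beta priors make the posterior proper even for k = 0 or K = N.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    draws = _or_draws(counts, n_draws, rng)
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return ORPosterior(draws_seed=seed, median=float(med), ci_low=float(lo), ci_high=float(hi))


def classify_noteworthy(
    post: ORPosterior, rope: tuple[float, float] = DEFAULT_ROPE
) -> str:
    """Strong/weak/none noteworthiness of an overrepresentation.

    strong: centre ≥ 1.25 and the whole 95% interval above the ROPE;
    weak: centre ≥ 1.25, the log-OR interval excludes 0 (ci_low > 1) and the
    posterior median is above the ROPE; else none.
    """
    lo, hi = rope
    if not (lo < 1.0 < hi):
        raise ValueError(f"malformed ROPE {rope}: must straddle 1")
    if post.center >= CENTER_THRESHOLD and post.ci_low > hi:
        return "strong"
    if (
        post.center >= CENTER_THRESHOLD
        and post.ci_low > 1.0
        and post.median > hi
    ):
        return "weak"
    return "none"


def build_iconicity_table(
    wordlist: Wordlist,
    registry: GroupRegistry | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    rope: tuple[float, float] = DEFAULT_ROPE,
    prefilter: bool = False,
) -> pd.DataFrame:
    """Full iconicity table: one row per (concept, group), classified and filtered.

    Rows with iconic value (interval centre) below 1 are removed unless
    ``prefilter`` is true; the pre-filter row count is kept in
    ``df.attrs["prefilter_rows"]``.  Reproducible given ``seed``.
    """
    registry = registry or default_registry()
    counts = occurrence_counts(wordlist, registry)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(counts))
    rows = []
    for c, child in zip(counts, children):
        rng = np.random.default_rng(child)
        draws = _or_draws(c, n_draws, rng)
        lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
        post = ORPosterior(draws_seed=seed, median=float(med), ci_low=float(lo), ci_high=float(hi))
        rows.append(
            {
                "concept": c.concept_id,
                "group": c.group,
                "k": c.k,
                "n": c.n,
                "K": c.K,
                "N": c.N,
                "or_median": post.median,
                "ci_low": post.ci_low,
                "ci_high": post.ci_high,
                "center": post.center,
                # a group never seen in the focal concept cannot be
                # overrepresented there; with k = K = 0 the OR posterior is a
                # pure prior artifact (the flat priors have unequal weight
                # against n and N), so zero-occurrence rows are never flagged
                "noteworthy": "none" if c.k == 0 else classify_noteworthy(post, rope),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["prefilter_rows"] = len(df)
    if not prefilter:
        df = df[df["center"] >= 1.0].reset_index(drop=True)
        df.attrs["prefilter_rows"] = len(rows)
    return df
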