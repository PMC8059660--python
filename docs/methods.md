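# Methods

This note documents the models and procedures implemented in `phonostab`,
the choices made where the design was genuinely open, and what the bundled
synthetic-data experiments do and do not establish.

## Sound classification

IPA strings are tokenized by greedy longest match against a shipped segment
table (`data/segments.tsv`); combining diacritics and length marks attach to
the preceding base token, a tie bar merges two bases into one segment, and a
voiceless ring overrides consonant voicing. Space-delimited input is treated
as pre-segmented. Features are deliberately coarse, five-way per axis:

- consonants: place {labial, alveolar, velar, palatal, glottal} (dentals and
  retroflexes → alveolar; uvulars → velar; pharyngeals → glottal), manner
  {nasal, stop, continuant, vibrant, lateral} (affricates are stops;
  fricatives and approximants are continuants; trills and taps are
  vibrants), binary voicing;
- vowels: height {high, mid, low}, backness {front, central, back}, binary
  rounding. Diphthongs are two segments, which keeps the segment→group map
  total.

The default registry (`data/groups.tsv`) holds 54 groups: 32 consonantal
(voicing 2, manner 5, manner×voicing 10, place 5, place×voicing 10) and 22
vocalic (height 3, backness 3, rounding 2, height×backness 9,
backness×rounding over front/back 4, plus low front rounded). Five groups —
voiced glottals, voiceless nasals, voiceless laterals, voiceless vibrants,
low front rounded vowels — are carried in the registry but excluded from
stability estimation as too sparsely attested; their stability is reported
as NA. Every consonant belongs to exactly 5 groups, every vowel to 4–6. The
registry, segment table and L1 matrix are plain TSV and can be overridden.

## Information weighting

Each position of a word receives a weight in [0, 1]:
`min(1, mean(forward surprisal, backward surprisal) / cap)` under
per-language trigram models over segments (two boundary symbols on each
side), with add-0.5 smoothing over `inventory + 1` outcomes and
`cap = log2(inventory + 1)` (the uniform surprisal). Positions that are
predictable from their context — recurring inflectional material above
all — get low weight. The symmetric trigram form was chosen because it is
fully specified, bounded (which makes the stability counts scale-free), and
reproduces the qualitative target behaviour; it is *not* a reimplementation
of any particular published weighting scheme. The suffix-downweighting
property is verified on simulated lexica with shared inflection-like
endings for several seeds.

## Alignment and homologue detection

Global alignment is Needleman–Wunsch with a linear gap penalty (−1) and a
deterministic traceback (substitution preferred over a left-side gap over a
right-side gap). Similarity scores are learned by iterative PMI: starting
from coarse feature-based scores (identity +2, same place and manner but
different voicing +1, same major class 0, consonant–vowel −2), each of 3
rounds aligns all cross-language same-concept pairs, keeps the best 70% by
length-normalized score, and re-estimates
`score(a,b) = log2(p(a,b)/(p(a)p(b)))` from aligned non-gap cells with
add-0.1 smoothing, clipped to ±3. The procedure reaches a fixed point on
the fixtures tested. Homologue sets are found per concept by average-linkage
clustering of `d(f,g) = 1 − score(f,g)/mean(score(f,f), score(g,g))`
(clipped to [0,1]) cut at 0.45. All of iterations, keep fraction and
threshold are exposed in the API and CLI. No affine gaps, no partial
cognacy, no conditioned sound laws.

## Stability estimation

For each unordered language pair, all cross-language form pairs within each
homologue set are aligned with information weights (a cell's weight is the
mean of the two sides' info content; a gap cell takes the non-gap side's).
Pair stability s is the weighted identity proportion over both-segment
cells; raw tallies (word pairs, segment pairs, identical pairs) are reported
alongside. Each aligned instance then contributes
`info weight × (1 − s)` to its groups' outcome tallies, once per non-gap
side, in one of four categories: stable, shift in group, shift out of
group, indel. `SSt = (stable + shift_in)/total`.

Notable consequences, by design: a language pair with s = 1 contributes
nothing (its replacement rate is 0), so a simulation without change yields
an all-NA table — the statistic measures the *fate of sounds under change*,
not the amount of change. Rescaling all info weights by a constant leaves
every SSt unchanged. "Identical" means the full token including diacritics.
Stability is symmetric per unordered pair; no per-language or directional
variant is computed.

## Iconicity coding

Presence/absence of a group in a language's word(s) for a concept (any
synonym counts once) gives k of n languages for the focal concept and K of
N language–concept slots overall (baseline includes the focal concept; with
≥ 50 concepts the difference from leave-one-out is negligible). With flat
Beta(1,1) priors, `n_draws` (default 4000) Monte-Carlo draws of
`odds(p)/odds(q)` give the OR posterior; the iconic value is the centre of
the equal-tailed 95% interval. Classification: *strong* iff centre ≥ 1.25
and the interval lies entirely above the ROPE (default (1/1.25, 1.25),
symmetric on the log scale); *weak* iff centre ≥ 1.25, the interval excludes
the null (ci_low > 1, the non-vacuous reading of "excluding zero" on the
log-OR scale) and the median clears the ROPE. Rows with centre < 1 are
removed after classification (underrepresentations mirror
overrepresentations of complement groups). Rows with k = 0 are never
flagged: with zero occurrences the posterior is a pure prior artifact (the
flat priors weigh differently against n and N), and a group absent from a
concept cannot be overrepresented in it.

## Combined table and regression

The combined table is the full concept × group cross product (344 concepts
× 54 groups = 18 576 rows at the published scale), with SSt joined by group
(NA for sparse or unobserved groups) and the L1 coding joined per axis.
A group is coded on an axis iff its predicate entails a coded value —
"voiced stop" is *earlier* on the manner axis and *later* on the voicing
axis; when one label is demanded and axes conflict, the coding is none.
The L1 matrix codes: place labial/alveolar earlier vs palatal/velar/glottal
later; manner stop vs continuant; voicing voiceless vs voiced; openness low
vs high/mid; backness back vs front/central. Aspiration-based distinctions
are out of scope.

Regression is OLS of **log** iconic value on raw SSt (iconic values are
ratio-scaled and analysed logarithmically; a flag allows the raw response),
over rows with iconic value ≥ 1 and defined SSt, for all rows and for the
consonant and vowel strata. `n(all) = n(consonants) + n(vowels)` holds for
every table since major class partitions the groups.

## The synthetic-data generator

Proto-words are CV-alternating draws (length 3–6) over a 43-segment
inventory covering every non-sparse registry group. They evolve down a
balanced binary tree; each segment is replaced on an edge of length t with
probability 1 − exp(−λt), where λ is set per manner class (consonants) or
height class (vowels). A replacement is, with probability (0.15, 0.70,
0.15): a different segment of the same class; a segment of another class
(same major class with probability 0.9); or a deletion. Insertions are
Poisson(0.05·t) per word. One event per segment per edge is drawn
(edges are short in all presets, so multi-hit corrections are negligible).
Optional features: per-language suffixes from a small shared pool (appended
after evolution, to exercise information weighting), horizontal borrowing,
and iconic seeding — forcing a segment of a chosen group into a concept's
word with probability `presence_boost`.

Two lineage modes exist because the two quantities the pipeline estimates
live on different sampling designs. `tree` mode gives common descent, the
setting for stability estimation. `independent` mode draws every
(language, concept) word independently — one language per family, the
design of global iconicity samples. This distinction matters: under common
descent, word shape and composition are heritable, so concept-level
overrepresentation of whatever the proto-word happened to contain is a
*genuine* signal, not a detector error; calibration of the iconicity coding
is therefore meaningful only on independent samples, and the coupled
experiment below measures SSt on a tree sample but Ico on an independent
counterpart sharing concepts and seeds (`iconicity_counterpart`), exactly
mirroring a two-dataset design.

### Presets (the study conditions)

- **null** — 100 independent languages, 50 concepts, uniform moderate
  intensities (0.7), no seeds. Used to measure the strong-flag rate under
  no iconicity (measured ≈ 0.1%, well under the 2% bound).
- **graded** — 16 languages, 100 concepts, tree mode, intensities
  nasal 0.3 < stop 0.45 < lateral 0.6 < continuant 0.9 < vibrant 1.2 <
  high 1.4 < mid 1.7 < low 2.0: the coarse expected ordering, with vowels
  least stable.
- **coupled** — 32 languages, 150 concepts, graded intensities, 60 iconic
  seeds (boost 0.9) placed in the lowest-intensity groups: 45 in stable
  consonant groups, 15 in high-vowel groups (the most stable vocalic
  classes). Seeding mostly consonantal follows directly from "seeds in
  low-λ groups": the low-λ end of the spectrum is consonantal.
- **recovery** — 20 languages, 300 concepts, intensities spanning 0.2–2.0,
  fixed seed. The parameter-recovery condition: true per-group retention is
  `mean over leaf pairs of exp(−λ_g · path)`.

Branch lengths (0.02 recovery, 0.03 graded/coupled) and the replacement
kernel were calibrated so that the presets lie in the regime they are meant
to represent: divergence deep enough that replacement-rate weighting has
signal, shallow enough that (i) homologue clustering at the 0.45 threshold
recovers the true sets (B³ F ≈ 0.87 on recovery) and (ii) token-survival
retention remains identifiable from SSt — with a large within-class
replacement share, class-aligned groups' SSt decouples from token survival
(in-class shifts count as stable outcomes), which is why the within-class
kernel share is small (0.15).

### What the simulations do and do not show

The generator emulates segment-wise neutral replacement with class-specific
rates, recurrent morphology, and iconic overrepresentation. It does not
model conditioned sound change (metathesis, assimilation, lenition chains),
semantic shift, dialect chains, synonym competition, or realistic
phylogenies, so passing recovery tests demonstrates that the estimators
measure what they claim under the model's assumptions — not that those
assumptions hold of any real language family. The measured numbers quoted
above are produced by the test suite, not asserted by hand.

## Numerical and interface choices

- TSV everywhere, UTF-8, NFC-normalized on read; floats written with 9
  significant digits (round-trips at 1e-9 relative); NA cells as "NA";
  deterministic row order.
- All Monte-Carlo paths take explicit integer seeds (numpy Generator;
  per-row seeds are spawned from a root SeedSequence).
- Degenerate inputs: empty IPA cells are skipped with a warning; a language
  pair with no aligned both-segment cells is dropped from stability; a
  group with zero total weight gets NA stability; regression requires ≥ 3
  usable rows.
- Tie-breaks: alignment traceback prefers substitution, then a gap on the
  left side; clustering uses scipy average linkage on a condensed distance
  matrix; equal stability rates sort alphabetically in summaries.

## Known limitations

Homologue detection is a deliberately simple substitute for full
cognacy-annotation systems and degrades with deep divergence (singleton
over-splitting); the information model is per-language trigram, not gappy
multi-context; the OR model treats languages as exchangeable and carries no
phylogenetic correction — which is precisely why calibration requires the
independent-sample design; and the published regression statistics of
comparable real-data studies depend on specific corpora and homologue
judgements, so they are not reproduction targets for this package.
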