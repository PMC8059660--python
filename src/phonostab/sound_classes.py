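"""IPA segmentation, articulatory feature bundles, sound groups, and L1 acquisition codings.

Segments are classified along a deliberately coarse five-way scheme on each
axis: place in {labial, alveolar, palatal, velar, glottal}, manner in
{nasal, stop, continuant, vibrant, lateral}, binary voicing for consonants;
height, backness and rounding for vowels.  Dentals and retroflexes fold into
"alveolar", uvulars and pharyngeals into "velar"/"glottal", affricates are
stops, fricatives and approximants are continuants, trills and taps are
vibrants.  Sound groups are named conjunctions of these feature values at
several granularity levels (e.g. "stop" vs "voiceless stop"); the default
registry holds 54 of them, 32 consonantal and 22 vocalic.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Segment",
    "SoundGroup",
    "GroupRegistry",
    "L1Matrix",
    "TokenizationError",
    "ClassificationError",
    "segment_ipa",
    "classify",
    "default_registry",
    "default_l1_matrix",
    "l1_coding",
]

#: tie bars joining two bases into a single (affricate-like) segment
TIE_BARS = frozenset('\u0361\u035c')

#: combining marks and modifier letters that attach to the preceding base segment
DIACRITICS = (
    frozenset('\u02d0\u02d1\u02b0\u02b1\u02b2\u02b7\u02e0\u02e4\u02c0\u02bc\u207f\u02e1\u02de')
    | frozenset('\u0325\u032a\u033a\u033b\u031d\u031e\u031f\u0320\u030a\u0303')
    | frozenset('\u0339\u031c\u0330\u0324\u032c\u0329\u032f\u0308\u033d\u0306')
    | TIE_BARS
)

#: diacritics that force voicelessness (ring below / ring above)
VOICELESS_MARKS = frozenset('\u0325\u030a')

L1_AXES = ("place", "manner", "voicing", "openness", "backness")

#: maps an L1 axis name to the Segment attribute it reads
_AXIS_FEATURE = {
    "place": "place",
    "manner": "manner",
    "voicing": "voicing",
    "openness": "height",
    "backness": "backness",
}


class TokenizationError(ValueError):
    """Raised when an IPA string contains material outside the inventory."""


class ClassificationError(KeyError):
    """Raised when a token cannot be mapped to a feature bundle."""


@dataclass(frozen=True)
class Segment:
    """One IPA segment with its articulatory feature bundle.

    Consonants carry ``place``/``manner``/``voicing``; vowels carry
    ``height``/``backness``/``rounding``.  The unused axes are None.
    """

    token: str
    major: str
    place: str | None = None
    manner: str | None = None
    voicing: str | None = None
    height: str | None = None
    backness: str | None = None
    rounding: str | None = None


def _read_tsv(name: str, path: str | Path | None = None) -> list[dict[str, str]]:
    if path is None:
        source = resources.files("phonostab.data").joinpath(name)
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    return rows


class SegmentTable:
    """Token → feature bundle lookup plus greedy longest-match tokenizer."""

    def __init__(self, bundles: Mapping[str, Segment]):
        self.bundles = dict(bundles)
        self._max_len = max(len(t) for t in self.bundles)

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "SegmentTable":
        rows = _read_tsv("segments.tsv", path)
        bundles: dict[str, Segment] = {}
        for row in rows:
            token = unicodedata.normalize("NFC", row["token"])
            bundles[token] = Segment(
                token=token,
                major=row["major"],
                place=row.get("place") or None,
                manner=row.get("manner") or None,
                voicing=row.get("voicing") or None,
                height=row.get("height") or None,
                backness=row.get("backness") or None,
                rounding=row.get("rounding") or None,
            )
        return cls(bundles)

    # -- tokenization -----------------------------------------------------

    def tokenize(self, text: str) -> tuple[str, ...]:
        """Greedy longest-match IPA tokenization.

        Whitespace-delimited input is treated as pre-segmented: each chunk is
        tokenized independently and the results concatenated.  Combining
        diacritics and length marks attach to the preceding base token; a tie
        bar joins the next base into the same segment.
        """
        text = unicodedata.normalize("NFC", text.strip())
        if not text:
            raise TokenizationError("empty IPA string")
        if any(ch.isspace() for ch in text):
            out: list[str] = []
            for chunk in text.split():
                out.extend(self.tokenize(chunk))
            return tuple(out)

        tokens: list[str] = []
        i = 0
        n = len(text)
        while i < n:
            match = self._match_base(text, i)
            if match is None:
                raise TokenizationError(
                    f"unknown IPA material {text[i]!r} at position {i} in {text!r}"
                )
            i = match
            # attach diacritics; a tie bar pulls in a further base token
            while i < n and text[i] in DIACRITICS:
                if text[i] in TIE_BARS:
                    j = self._match_base(text, i + 1)
                    if j is None:
                        raise TokenizationError(
                            f"dangling tie bar at position {i} in {text!r}"
                        )
                    i = j
                else:
                    i += 1
            start = sum(map(len, tokens))
            tokens.append(text[start:i])
        return tuple(tokens)

    def _match_base(self, text: str, i: int) -> int | None:
        """Return the end index of the longest inventory token starting at i."""
        for length in range(min(self._max_len, len(text) - i), 0, -1):
            if text[i : i + length] in self.bundles:
                return i + length
        return None

    # -- classification ---------------------------------------------------

    def classify(self, token: str) -> Segment:
        """Feature bundle for a token produced by :meth:`tokenize`.

        Diacritics are stripped for lookup but kept in the token identity; a
        voiceless ring overrides consonant voicing.  An unknown tie-bar
        composite inherits the first base's bundle with manner "stop"
        (affricate rule).
        """
        token = unicodedata.normalize("NFC", token)
        base = self.bundles.get(token)
        if base is None:
            stripped = "".join(
                ch for ch in token if ch not in DIACRITICS or ch in TIE_BARS
            )
            base = self.bundles.get(stripped)
            if base is None and any(t in stripped for t in TIE_BARS):
                for bar in TIE_BARS:
                    stripped = stripped.replace(bar, "͡")
                first = stripped.split("͡")[0]
                head = self.bundles.get(first)
                if head is not None:
                    base = replace(head, manner="stop") if head.major == "consonant" else head
            if base is None:
                stripped_plain = "".join(ch for ch in token if ch not in DIACRITICS)
                base = self.bundles.get(stripped_plain)
            if base is None:
                raise ClassificationError(f"cannot classify IPA token {token!r}")
        seg = replace(base, token=token)
        if seg.major == "consonant" and any(m in token for m in VOICELESS_MARKS):
            seg = replace(seg, voicing="voiceless")
        return seg


@lru_cache(maxsize=1)
def default_segment_table() -> SegmentTable:
    return SegmentTable.from_tsv()


def segment_ipa(text: str, table: SegmentTable | None = None) -> tuple[str, ...]:
    """Tokenize an IPA string into segment tokens (greedy longest match)."""
    table = table or default_segment_table()
    return table.tokenize(text)


def classify(token: str, table: SegmentTable | None = None) -> Segment:
    """Map a segment token to its articulatory feature bundle."""
    table = table or default_segment_table()
    return table.classify(token)


# ---------------------------------------------------------------------------
# sound groups


@dataclass(frozen=True)
class SoundGroup:
    """A named predicate over segments, e.g. ``voiceless stop``."""

    name: str
    feature_class: str
    major: str
    predicate: tuple[tuple[str, str], ...]

    def contains(self, segment: Segment) -> bool:
        if segment.major != self.major:
            return False
        return all(getattr(segment, feat) == val for feat, val in self.predicate)


class GroupRegistry:
    """Ordered collection of sound groups with a sparse-exclusion list."""

    #: groups too thinly attested for stability estimation in the default setup
    DEFAULT_SPARSE = frozenset(
        {
            "voiced glottal",
            "voiceless nasal",
            "voiceless lateral",
            "voiceless vibrant",
            "low front rounded vowel",
        }
    )

    def __init__(self, groups: Iterable[SoundGroup], sparse_excluded: Iterable[str] = ()):
        self.groups: tuple[SoundGroup, ...] = tuple(groups)
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in registry")
        self.sparse_excluded = frozenset(sparse_excluded)
        unknown = self.sparse_excluded - set(names)
        if unknown:
            raise ValueError(f"sparse_excluded names not in registry: {sorted(unknown)}")
        self._by_name = {g.name: g for g in self.groups}

    def __iter__(self) -> Iterator[SoundGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, name: str) -> SoundGroup:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def groups_for(self, segment: Segment) -> tuple[SoundGroup, ...]:
        """All groups whose predicate the segment satisfies."""
        return tuple(g for g in self.groups if g.contains(segment))

    @classmethod
    def from_tsv(
        cls,
        path: str | Path | None = None,
        sparse_excluded: Iterable[str] | None = None,
    ) -> "GroupRegistry":
        rows = _read_tsv("groups.tsv", path)
        groups = []
        for row in rows:
            pred = tuple(
                tuple(kv.split("=", 1)) for kv in row["predicate"].split(";") if kv
            )
            groups.append(
                SoundGroup(
                    name=row["name"],
                    feature_class=row["feature_class"],
                    major=row["major"],
                    predicate=pred,  # type: ignore[arg-type]
                )
            )
        if sparse_excluded is None:
            sparse_excluded = cls.DEFAULT_SPARSE
        return cls(groups, sparse_excluded)


@lru_cache(maxsize=1)
def default_registry() -> GroupRegistry:
    """The default 54-group registry (32 consonant groups, 22 vowel groups)."""
    reg = GroupRegistry.from_tsv()
    assert len(reg) == 54
    return reg


# ---------------------------------------------------------------------------
# L1 acquisition matrix


class L1Matrix:
    """Relative order of acquisition ("earlier"/"later") per feature value.

    Five axes are coded: place and manner of articulation and voicing for
    consonants, openness and backness for vowels.  The coding is relative
    (post-babbling), not an absolute age.
    """

    def __init__(self, rows: Mapping[tuple[str, str], str]):
        self.rows = dict(rows)
        for (axis, _), coding in self.rows.items():
            if axis not in L1_AXES or coding not in ("earlier", "later"):
                raise ValueError(f"malformed L1 row {(axis, coding)}")

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "L1Matrix":
        rows = _read_tsv("l1_matrix.tsv", path)
        return cls({(r["axis"], r["value"]): r["coding"] for r in rows})

    def coding(self, axis: str, value: str | None) -> str:
        if value is None:
            return "none"
        return self.rows.get((axis, value), "none")


@lru_cache(maxsize=1)
def default_l1_matrix() -> L1Matrix:
    return L1Matrix.from_tsv()


def l1_coding(
    group: SoundGroup,
    axis: str | None = None,
    l1: L1Matrix | None = None,
) -> str:
    """Earlier/later acquisition coding of a sound group.

    A group is coded on an axis iff its predicate entails a coded feature
    value on that axis, regardless of granularity level (so "voiced stop" is
    "earlier" on the manner axis and "later" on the voicing axis).  With
    ``axis=None`` a single label is demanded: if the per-axis codings
    conflict the result is "none".
    """
    l1 = l1 or default_l1_matrix()
    pred = dict(group.predicate)
    if axis is not None:
        if axis not in L1_AXES:
            raise ValueError(f"unknown L1 axis {axis!r}")
        return l1.coding(axis, pred.get(_AXIS_FEATURE[axis]))
    codings = {
        c
        for ax in L1_AXES
        if (c := l1.coding(ax, pred.get(_AXIS_FEATURE[ax]))) != "none"
    }
    if len(codings) == 1:
        return codings.pop()
    return "none"
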