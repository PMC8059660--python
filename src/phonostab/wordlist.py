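"""Long-format lexical wordlists: reading, validation, and result-table output.

The only ingest dialect is a UTF-8, header-rowed, tab-separated file with one
word form per row.  Default column names follow the CLDF convention
(``Language_ID``, ``Parameter_ID``, ``Form``, ``Segments``); a ``column_map``
remaps them.  Synonyms (several forms for one language-concept slot) are
retained.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .sound_classes import SegmentTable, TokenizationError, default_segment_table

logger = logging.getLogger(__name__)

#: role → column name used when no column_map is given
DEFAULT_COLUMN_MAP = {
    "language": "Language_ID",
    "concept": "Parameter_ID",
    "form": "Form",
    "segments": "Segments",
}


class WordlistError(ValueError):
    pass


@dataclass(frozen=True)
class WordForm:
    """One language's word for one concept, as a sequence of IPA segments."""

    language_id: str
    concept_id: str
    form: str
    segments: tuple[str, ...]

    def __post_init__(self):
        if not self.language_id or not self.concept_id:
            raise WordlistError("language_id and concept_id must be non-empty")
        if not self.segments:
            raise WordlistError(f"form {self.form!r} has no segments")


@dataclass
class Wordlist:
    """A collection of word forms with the induced language and concept sets."""

    forms: list[WordForm] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for f in self.forms:
            key = (f.language_id, f.concept_id, f.form)
            if key in seen:
                raise WordlistError(f"duplicate form {key}")
            seen.add(key)

    @property
    def languages(self) -> frozenset[str]:
        return frozenset(f.language_id for f in self.forms)

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(f.concept_id for f in self.forms)

    def __len__(self) -> int:
        return len(self.forms)

    def __iter__(self) -> Iterator[WordForm]:
        return iter(self.forms)

    def forms_for(
        self, language: str | None = None, concept: str | None = None
    ) -> list[tuple[int, WordForm]]:
        """(index, form) pairs filtered by language and/or concept."""
        return [
            (i, f)
            for i, f in enumerate(self.forms)
            if (language is None or f.language_id == language)
            and (concept is None or f.concept_id == concept)
        ]

    def segment_inventory(self) -> frozenset[str]:
        return frozenset(s for f in self.forms for s in f.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Language_ID": [f.language_id for f in self.forms],
                "Parameter_ID": [f.concept_id for f in self.forms],
                "Form": [f.form for f in self.forms],
                "Segments": [" ".join(f.segments) for f in self.forms],
            }
        )


def read_wordlist(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    table: SegmentTable | None = None,
) -> Wordlist:
    """Read a long-format TSV wordlist.

    The IPA source column is ``segments`` when present in the file (space
    delimited, passed through the tokenizer per chunk), else ``form``.  Rows
    with an empty IPA cell are skipped with a logged warning; rows whose IPA
    cannot be tokenized raise, naming the offending substring.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    table = table or default_segment_table()

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for role in ("language", "concept", "form"):
        if colmap[role] not in df.columns:
            raise WordlistError(
                f"column {colmap[role]!r} (role {role!r}) missing from {path}"
            )
    seg_col = colmap["segments"] if colmap["segments"] in df.columns else colmap["form"]

    forms: list[WordForm] = []
    skipped = 0
    for idx, row in df.iterrows():
        ipa = unicodedata.normalize("NFC", str(row[seg_col]).strip())
        if not ipa:
            skipped += 1
            logger.warning("row %d: empty IPA cell, skipped", idx)
            continue
        try:
            segments = table.tokenize(ipa)
        except TokenizationError as err:
            raise WordlistError(f"row {idx}: {err}") from err
        forms.append(
            WordForm(
                language_id=str(row[colmap["language"]]).strip(),
                concept_id=str(row[colmap["concept"]]).strip(),
                form=unicodedata.normalize("NFC", str(row[colmap["form"]]).strip()),
                segments=segments,
            )
        )
    if skipped:
        logger.warning("%d rows skipped for empty IPA", skipped)
    wl = Wordlist(forms)
    wl.n_skipped = skipped  # type: ignore[attr-defined]
    return wl


def write_wordlist(path: str | Path, wordlist: Wordlist) -> None:
    wordlist.to_frame().to_csv(path, sep="\t", index=False)


def write_table(
    path: str | Path,
    table: pd.DataFrame | Sequence[Mapping],
    key_columns: Iterable[str] | None = None,
) -> None:
    """Write a pipeline result table as TSV.

    Floats are rendered with 9 significant digits (round-trips to 1e-9),
    missing cells as ``NA``, and rows are sorted by the key columns (default:
    the table's leading non-numeric columns) for deterministic output.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    if len(df):
        if key_columns is None:
            key_columns = [c for c in df.columns if df[c].dtype == object]
        key_columns = [c for c in key_columns if c in df.columns]
        if key_columns:
            df = df.sort_values(list(key_columns), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.9g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
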