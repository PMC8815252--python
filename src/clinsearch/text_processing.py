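"""Query and document text normalization.

The preprocessing pipeline mirrors how free-text imaging-order indications
are prepared before embedding: clinical abbreviations are *expanded by
appending* their long forms to the query (never substituted, so the original
wording still contributes to matching), then the text is tokenized,
lowercased, and stripped of punctuation and stop words; lemmatization is
optional and typically applied to document bodies.

Also provides ``extract_indication`` for pulling the clinical-indication
section out of a radiology report by section-header pattern matching.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "DEFAULT_STOPWORDS",
    "DEFAULT_SECTION_PATTERNS",
    "NOT_FOUND",
    "AbbreviationTable",
    "expand_abbreviations",
    "tokenize_and_clean",
    "lemmatize",
    "extract_indication",
    "preprocess_query",
    "load_abbreviation_table",
    "save_abbreviation_table",
]

#: Standard English stop-word list used when the caller supplies none.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

#: Section headers tried, in order, by :func:`extract_indication`.
DEFAULT_SECTION_PATTERNS: tuple[str, ...] = (
    "INDICATION:",
    "CLINICAL INDICATION:",
    "HISTORY:",
)

#: Sentinel returned when no indication section can be extracted.
NOT_FOUND = "not found"

# Tokens are maximal runs of alphanumerics optionally glued by / ' or -
# so clinical shorthand like "r/o" or "follow-up" survives as one token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[/'-][A-Za-z0-9]+)*")


@dataclass(frozen=True)
class AbbreviationTable:
    """Mapping of abbreviation tokens to one or more expansion texts.

    Abbreviations are single tokens and match case-sensitively by default
    ("PE" ≠ "pe" — clinical abbreviations are case-meaningful). No entry
    may expand to itself.
    """

    entries: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, tuple[str, ...]] = {}
        for abbrev, expansions in dict(self.entries).items():
            if isinstance(expansions, str):
                expansions = (expansions,)
            expansions = tuple(expansions)
            if _TOKEN_RE.fullmatch(abbrev) is None:
                raise ValueError(f"abbreviation is not a single token: {abbrev!r}")
            if any(exp.strip() == abbrev for exp in expansions):
                raise ValueError(f"abbreviation {abbrev!r} maps to itself")
            norm[abbrev] = expansions
        object.__setattr__(self, "entries", norm)

    def __len__(self) -> int:
        return len(self.entries)


def expand_abbreviations(
    text: str,
    table: AbbreviationTable,
    case_sensitive: bool = True,
) -> str:
    """Append the expansion of every abbreviation occurring in ``text``.

    The original text is returned unchanged as a prefix; each matched
    entry's expansions are appended exactly once, in the order abbreviations
    first occur in the text. Unknown tokens pass through silently.
    """
    tokens = _TOKEN_RE.findall(text)
    if case_sensitive:
        lookup = table.entries
        keys = {t for t in tokens}
    else:
        lookup = {k.lower(): v for k, v in table.entries.items()}
        keys = {t.lower() for t in tokens}
        tokens = [t.lower() for t in tokens]
    appended: list[str] = []
    seen: set[str] = set()
    for tok in tokens:
        if tok in keys and tok in lookup and tok not in seen:
            seen.add(tok)
            appended.extend(lookup[tok])
    if not appended:
        return text
    return " ".join([text, *appended])


def tokenize_and_clean(
    text: str,
    stopwords: Iterable[str] | None = None,
) -> list[str]:
    """Lowercased word tokens with stop words and punctuation removed.

    Order-preserving and deterministic; idempotent on its own output
    (re-tokenizing the joined result changes nothing). Empty input yields
    an empty list.
    """
    stops = DEFAULT_STOPWORDS if stopwords is None else set(stopwords)
    return [t for t in (m.lower() for m in _TOKEN_RE.findall(text)) if t not in stops]


# Rule-based English lemmatizer. Irregulars first, then ordered suffix
# rules; a rule applies only if the stem stays at least 3 characters.
_IRREGULAR = {
    "feet": "foot",
    "teeth": "tooth",
    "children": "child",
    "men": "man",
    "women": "woman",
    "mice": "mouse",
    "diagnoses": "diagnosis",
    "metastases": "metastasis",
    "stenoses": "stenosis",
    "emboli": "embolus",
    "nuclei": "nucleus",
    "criteria": "criterion",
}

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ies", "y"),      # arteries -> artery
    ("ches", "ch"),    # headaches -> headache... (matched before 'es')
    ("shes", "sh"),    # rashes -> rash
    ("sses", "ss"),    # masses -> mass
    ("xes", "x"),      # reflexes -> reflex
    ("zes", "ze"),     # sizes -> size
    ("ves", "f"),      # calves -> calf (approximate)
    ("s", ""),         # stones -> stone
)


def _default_lemma(token: str) -> str:
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if token.endswith("ss") or token.endswith("us") or len(token) <= 3:
        return token
    for suffix, repl in _SUFFIX_RULES:
        if token.endswith(suffix):
            stem = token[: -len(suffix)] + repl
            if len(stem) >= 3:
                return stem
            return token
    return token


def lemmatize(
    tokens: Sequence[str],
    lemmatizer: Callable[[str], str] | None = None,
) -> list[str]:
    """Replace each token by its lemma; length-preserving and deterministic.

    The default backend is a rule-based English noun lemmatizer (irregular
    table + suffix stripping); pass ``lemmatizer`` to plug in another.
    """
    fn = lemmatizer or _default_lemma
    return [fn(t) for t in tokens]


def extract_indication(
    report_text: str,
    patterns: Sequence[str] = DEFAULT_SECTION_PATTERNS,
) -> str:
    """Extract the clinical-indication section from report text.

    Scans for the first occurrence of any header in ``patterns`` and returns
    the trimmed text up to the next all-caps section header (a line such as
    ``TECHNIQUE:``) or end of text. Returns the sentinel ``"not found"``
    when no pattern matches or the extracted span is blank — reports with
    blank indications or nonstandard formats are excluded upstream, not
    silently passed on.
    """
    if not patterns:
        raise ValueError("at least one section-header pattern is required")
    first_pos = -1
    first_end = -1
    for pat in patterns:
        pos = report_text.find(pat)
        if pos != -1 and (first_pos == -1 or pos < first_pos):
            first_pos, first_end = pos, pos + len(pat)
    if first_pos == -1:
        return NOT_FOUND
    tail = report_text[first_end:]
    nxt = re.search(r"^[A-Z][A-Z /-]*:", tail, flags=re.MULTILINE)
    span = tail[: nxt.start()] if nxt else tail
    span = span.strip()
    return span if span else NOT_FOUND


def preprocess_query(
    text: str,
    table: AbbreviationTable | None = None,
    stopwords: Iterable[str] | None = None,
    lemmatize_tokens: bool = False,
    case_sensitive: bool = True,
) -> list[str]:
    """Full query pipeline: expand abbreviations, tokenize, clean.

    Lemmatization is off by default for queries (documents are lemmatized
    at index time instead); enable via ``lemmatize_tokens``.
    """
    if table is not None:
        text = expand_abbreviations(text, table, case_sensitive=case_sensitive)
    tokens = tokenize_and_clean(text, stopwords)
    if lemmatize_tokens:
        tokens = lemmatize(tokens)
    return tokens


def load_abbreviation_table(path: str | Path) -> AbbreviationTable:
    """Read a two-column CSV (abbreviation, expansion); repeated
    abbreviation rows accumulate multiple expansions."""
    entries: dict[str, list[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or len(row) < 2:
                continue
            entries.setdefault(row[0].strip(), []).append(row[1].strip())
    return AbbreviationTable({k: tuple(v) for k, v in entries.items()})


def save_abbreviation_table(table: AbbreviationTable, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        for abbrev in sorted(table.entries):
            for exp in table.entries[abbrev]:
                writer.writerow([abbrev, exp])
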