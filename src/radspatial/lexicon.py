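"""Category-typed dictionaries of radiological entities and spatial triggers.

Two dictionaries drive candidate generation: a radiological-entity
vocabulary (findings, anatomy, devices, descriptors, hedges, ...) and a
spatial-trigger vocabulary (prepositions and copular verbs that evoke a
spatial relation).  Both are plain surface-form lexicons loaded from TSV
term lists; the entity lexicon is additionally expanded with prepend
phrases ("area of ..."), descriptor concatenations ("petechial
hemorrhage") and plural forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

CATEGORIES = frozenset(
    {
        "finding",
        "anatomy",
        "device",
        "process",
        "location_descriptor",
        "certainty_descriptor",
        "hedge",
        "position_status",
        "relative_position",
    }
)

SOURCES = frozenset(
    {"base", "manual", "prepend_expansion", "descriptor_expansion", "plural_expansion"}
)

# Latin/Greek plurals common in radiology vocabulary; consulted before the
# regular rules.  Keys match the final word of a term.
IRREGULAR_PLURALS = {
    "focus": "foci",
    "vertebra": "vertebrae",
    "atrium": "atria",
    "metastasis": "metastases",
    "pneumothorax": "pneumothoraces",
    "bronchus": "bronchi",
    "calculus": "calculi",
    "diverticulum": "diverticula",
    "foramen": "foramina",
    "ramus": "rami",
}


class LexiconError(ValueError):
    """Raised for malformed term lists or invalid lexicon operations."""


def normalize(surface: str) -> str:
    """Lowercase, trim and collapse internal whitespace of a surface form."""
    return " ".join(surface.lower().split())


@dataclass(frozen=True)
class TermEntry:
    surface: str
    category: str
    source: str = "base"

    def __post_init__(self) -> None:
        if not self.surface or self.surface != normalize(self.surface):
            raise LexiconError(f"surface not normalized: {self.surface!r}")
        if self.category not in CATEGORIES:
            raise LexiconError(f"unknown category: {self.category!r}")
        if self.source not in SOURCES:
            raise LexiconError(f"unknown source: {self.source!r}")


class Lexicon:
    """A set of :class:`TermEntry` with a surface -> categories index."""

    def __init__(self, entries: Iterable[TermEntry] = (), name: str = "lexicon"):
        self.name = name
        self.entries: set[TermEntry] = set()
        self.index: dict[str, set[str]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: TermEntry) -> None:
        self.entries.add(entry)
        self.index.setdefault(entry.surface, set()).add(entry.category)

    def lookup(self, surface: str) -> set[str]:
        """Case-insensitive exact lookup; empty set when absent."""
        return set(self.index.get(normalize(surface), ()))

    def __contains__(self, surface: str) -> bool:
        return normalize(surface) in self.index

    def __len__(self) -> int:
        return len(self.index)

    @property
    def max_tokens(self) -> int:
        """Longest entry length in whitespace tokens (for n-gram matching)."""
        return max((len(s.split()) for s in self.index), default=0)

    def copy(self, name: str | None = None) -> "Lexicon":
        return Lexicon(self.entries, name=name or self.name)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "entries": [
                {"surface": e.surface, "category": e.category, "source": e.source}
                for e in sorted(self.entries, key=lambda e: (e.surface, e.category))
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        payload = json.loads(Path(path).read_text())
        return cls(
            (TermEntry(e["surface"], e["category"], e.get("source", "base")) for e in payload["entries"]),
            name=payload.get("name", "lexicon"),
        )


@dataclass
class ExpansionConfig:
    """How the entity dictionary is enlarged before matching.

    prepend_phrases are prefixed to every finding term; descriptor_pairs
    concatenate a modifier with an existing target term; pluralize adds
    plural forms of all base/manual/descriptor entries.
    """

    prepend_phrases: list[str] = field(
        default_factory=lambda: [
            "area of",
            "areas of",
            "region of",
            "regions of",
            "focus of",
            "foci of",
        ]
    )
    descriptor_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("petechial", "hemorrhage"),
            ("intraparenchymal", "hemorrhage"),
            ("frontoparietal", "lobe"),
            ("calcified", "atherosclerotic changes"),
        ]
    )
    pluralize: bool = True

    def __post_init__(self) -> None:
        if any(not p.strip() for p in self.prepend_phrases):
            raise LexiconError("empty prepend phrase")


def load_term_list(path: str | Path, category: str, source: str = "base") -> Lexicon:
    """Load a TSV term list (column 1 = surface, optional column 2 = category).

    ``#``-prefixed lines are comments.  The default category applies to rows
    without an override.  Duplicate (surface, category) rows collapse.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"term list not found: {path}")
    if category not in CATEGORIES:
        raise LexiconError(f"unknown category: {category!r}")
    lex = Lexicon(name=path.stem)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        surface = normalize(cols[0])
        if not surface:
            raise LexiconError(f"{path}:{lineno}: empty surface column")
        cat = cols[1].strip() if len(cols) > 1 and cols[1].strip() else category
        if cat not in CATEGORIES:
            raise LexiconError(f"{path}:{lineno}: unknown category {cat!r}")
        lex.add(TermEntry(surface, cat, source))
    if len(lex) == 0:
        raise LexiconError(f"term list is empty: {path}")
    return lex


def merge(*lexicons: Lexicon, name: str = "merged") -> Lexicon:
    out = Lexicon(name=name)
    for lex in lexicons:
        for entry in lex.entries:
            out.add(entry)
    return out


def pluralize(term: str) -> set[str]:
    """Plural form(s) of a (possibly multi-word) term; never the input itself.

    The final word is pluralized: irregulars first, then -is -> -es,
    consonant+y -> -ies, sibilant endings (+es), default +s.
    """
    if not term:
        raise LexiconError("cannot pluralize empty term")
    words = term.split()
    last = words[-1]
    if last in IRREGULAR_PLURALS:
        plural = IRREGULAR_PLURALS[last]
    elif last.endswith("is") and len(last) > 3:
        plural = last[:-2] + "es"
    elif last.endswith("y") and len(last) > 1 and last[-2] not in "aeiou":
        plural = last[:-1] + "ies"
    elif last.endswith(("s", "x", "z", "ch", "sh")):
        plural = last + "es"
    else:
        plural = last + "s"
    return {" ".join(words[:-1] + [plural])}


def expand(lexicon: Lexicon, config: ExpansionConfig) -> Lexicon:
    """Return a new lexicon enlarged per ``config``; the input is unmodified.

    Prepend and descriptor expansion apply only to base/manual entries so
    that re-expansion is idempotent; pluralization skips prepend-derived
    entries (their plural variants come from plural prepend phrases) and
    entries that are themselves plurals.
    """
    if len(lexicon) == 0:
        raise LexiconError("cannot expand an empty lexicon")
    missing = [
        target
        for _, target in config.descriptor_pairs
        if normalize(target) not in lexicon.index
    ]
    if missing:
        raise LexiconError(f"descriptor targets absent from lexicon: {missing}")

    out = lexicon.copy()
    originals = [e for e in lexicon.entries if e.source in ("base", "manual")]
    for entry in originals:
        if entry.category == "finding":
            for phrase in config.prepend_phrases:
                out.add(
                    TermEntry(
                        normalize(f"{phrase} {entry.surface}"),
                        "finding",
                        "prepend_expansion",
                    )
                )
    for descriptor, target in config.descriptor_pairs:
        target_n = normalize(target)
        for cat in lexicon.lookup(target_n):
            out.add(
                TermEntry(
                    normalize(f"{descriptor} {target_n}"), cat, "descriptor_expansion"
                )
            )
    if config.pluralize:
        for entry in list(out.entries):
            if entry.source in ("plural_expansion", "prepend_expansion"):
                continue
            for plural in pluralize(entry.surface):
                if plural not in out.index or entry.category not in out.lookup(plural):
                    out.add(TermEntry(plural, entry.category, "plural_expansion"))
    return out


def lookup(lexicon: Lexicon, surface: str) -> set[str]:
    return lexicon.lookup(surface)


# -- packaged mini-lexicon -----------------------------------------------


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("radspatial").joinpath("data", filename)))


def load_paper_terms() -> Lexicon:
    """Terms printed in the schema/heuristics tables and worked sentences."""
    return load_term_list(_data_path("paper_terms.tsv"), "finding")


def load_synthetic_terms() -> Lexicon:
    """Extra vocabulary used by the synthetic sentence generator."""
    return load_term_list(_data_path("synthetic_terms.tsv"), "finding")


def default_entity_lexicon(expanded: bool = True) -> Lexicon:
    """The packaged radiological-entity dictionary (optionally expanded)."""
    lex = merge(load_paper_terms(), load_synthetic_terms(), name="rad_entities")
    if expanded:
        lex = expand(lex, ExpansionConfig())
    return lex


def default_trigger_lexicon() -> Lexicon:
    """The packaged spatial-trigger dictionary (prepositions + copulas)."""
    return load_term_list(_data_path("spatial_triggers.tsv"), "finding", "base")
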