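"""Render tabular concept rows into templated clinical pseudo-notes.

Each of the six EHR concepts is rendered independently into a short
paragraph of declarative sentences by filling a template with the
encounter's rows.  Missing modalities get a fixed fallback sentence, so an
encounter always yields exactly six notes in canonical concept order.
Rendering is a pure function of (bundle, template): the same inputs always
produce byte-identical text.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import yaml

from meme_ed.concepts import CONCEPT_ORDER, ConceptKind
from meme_ed.schema_io import EncounterBundle, EncounterKey

MSEM_SEPARATOR = "\n\n"
MISSING_VALUE_TEXT = "not recorded"


class TemplateError(KeyError):
    """A template slot does not resolve to any bundle or row field."""


@dataclass(frozen=True)
class NoteTemplate:
    """Fill-in template for one concept's pseudo-note."""

    concept: ConceptKind
    skeleton: str
    row_phrase: str
    row_separator: str = " "
    missing_sentence: str = ""

    def __post_init__(self) -> None:
        if not self.missing_sentence:
            raise ValueError(f"{self.concept}: missing_sentence must be non-empty")


#: concept tag of a whole-narrative (MSEM) note
MSEM_CONCEPT = "msem"


@dataclass(frozen=True)
class ConceptNote:
    """Rendered pseudo-note for one (encounter, concept) pair.

    ``concept`` is one of the six :class:`ConceptKind` values, or the string
    ``"msem"`` for a whole-narrative note.
    """

    key: EncounterKey
    concept: ConceptKind | str
    text: str
    is_fallback: bool = False


def default_templates() -> dict[ConceptKind, NoteTemplate]:
    """The package's default template set (declarative-sentence style)."""
    ref = resources.files("meme_ed").joinpath("data/templates_default.yaml")
    return load_templates_dict(yaml.safe_load(ref.read_text()))


def load_templates(path: str | Path) -> dict[ConceptKind, NoteTemplate]:
    with open(path) as fh:
        return load_templates_dict(yaml.safe_load(fh))


def load_templates_dict(raw: Mapping) -> dict[ConceptKind, NoteTemplate]:
    out = {}
    for name, body in raw.items():
        kind = ConceptKind(name)
        out[kind] = NoteTemplate(
            concept=kind,
            skeleton=body["skeleton"].strip(),
            row_phrase=" ".join(body["row_phrase"].split()),
            row_separator=body.get("row_separator", " "),
            missing_sentence=body["missing_sentence"].strip(),
        )
    return out


# ---------------------------------------------------------------------------
# formatting


_TIMESTAMP_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}[ T](\d{2}:\d{2})(?::\d{2})?$"
)


def _format_value(value) -> str:
    if value is None:
        return MISSING_VALUE_TEXT
    if isinstance(value, float):
        if float(value).is_integer():
            return str(int(value))
        return f"{value:.1f}"  # one decimal: clinical charting granularity
    if isinstance(value, str):
        m = _TIMESTAMP_RE.match(value)
        if m:
            return m.group(1)  # notes chart clock time, not full timestamps
    return str(value)


def _fill(pattern: str, fields: Mapping, concept: ConceptKind) -> str:
    out = []
    for literal, slot, fmt, conv in string.Formatter().parse(pattern):
        out.append(literal)
        if slot is None:
            continue
        if slot not in fields:
            raise TemplateError(
                f"{concept.value} template: slot {slot!r} does not resolve"
            )
        out.append(_format_value(fields[slot]))
    return "".join(out)


def _ordered_rows(rows: list[dict]) -> list[dict]:
    # stable sort: timestamped rows by timestamp, untimestamped keep input order
    if any("charttime" in r for r in rows):
        return sorted(
            rows, key=lambda r: (r.get("charttime") is None, str(r.get("charttime", "")))
        )
    return rows


def render_concept_note(
    bundle: EncounterBundle,
    concept: ConceptKind,
    template: NoteTemplate,
) -> ConceptNote:
    """Render one concept's rows; empty rows yield the fallback sentence.

    Per-row phrases are ordered by timestamp (then input order) and joined
    with the template separator; the joined text fills the skeleton's
    ``{rows}`` slot.  Other skeleton slots resolve against the encounter's
    stay record.  A null field inside a present row renders as
    ``"not recorded"`` so the note structure stays stable for the encoder.
    """
    if template.concept != concept:
        raise ValueError(f"template is for {template.concept}, not {concept}")
    rows = bundle.rows[ConceptKind(concept)]
    if not rows:
        return ConceptNote(bundle.key, concept, template.missing_sentence, True)
    phrases = [
        _fill(template.row_phrase, row, concept) for row in _ordered_rows(rows)
    ]
    fields = dict(bundle.demographics)
    fields["rows"] = template.row_separator.join(phrases)
    # {rows} must pass through verbatim, not via numeric formatting
    text = _fill(template.skeleton, fields, concept)
    return ConceptNote(bundle.key, concept, text, False)


def render_encounter(
    bundle: EncounterBundle,
    templates: Mapping[ConceptKind, NoteTemplate] | None = None,
) -> list[ConceptNote]:
    """Render all six concept notes in canonical order.

    Streams absent from the source schema (and streams with no rows) render
    as fallback sentences, so five-stream dialects still yield six notes.
    """
    templates = templates or default_templates()
    missing = [k for k in CONCEPT_ORDER if k not in templates]
    if missing:
        raise ValueError(f"templates missing for concepts: {missing}")
    return [render_concept_note(bundle, k, templates[k]) for k in CONCEPT_ORDER]


def render_msem_note(
    bundle: EncounterBundle,
    templates: Mapping[ConceptKind, NoteTemplate] | None = None,
) -> ConceptNote:
    """Single heterogeneous note: the six concept texts joined in order.

    This is the input of the multiconcept single-embedding model (MSEM),
    which encodes the whole patient narrative as one text.
    """
    notes = render_encounter(bundle, templates)
    text = MSEM_SEPARATOR.join(n.text for n in notes)
    return ConceptNote(bundle.key, MSEM_CONCEPT, text, all(n.is_fallback for n in notes))


# ---------------------------------------------------------------------------
# JSONL round-trip


def write_notes(notes: Iterable[ConceptNote], stream: IO[str] | str | Path) -> None:
    """One JSON record per line: key, concept, text, is_fallback."""
    if isinstance(stream, (str, Path)):
        with open(stream, "w") as fh:
            write_notes(notes, fh)
        return
    for n in notes:
        concept = n.concept.value if isinstance(n.concept, ConceptKind) else n.concept
        rec = {
            "encounter_id": n.key.encounter_id,
            "patient_id": n.key.patient_id,
            "concept": concept,
            "text": n.text,
            "is_fallback": n.is_fallback,
        }
        stream.write(json.dumps(rec) + "\n")


def read_notes(stream: IO[str] | str | Path) -> Iterator[ConceptNote]:
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            yield from read_notes(fh)
        return
    for lineno, line in enumerate(stream, 1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            raw = rec["concept"]
            concept = MSEM_CONCEPT if raw == MSEM_CONCEPT else ConceptKind(raw)
            yield ConceptNote(
                key=EncounterKey(rec["encounter_id"], rec.get("patient_id", "")),
                concept=concept,
                text=rec["text"],
                is_fallback=bool(rec["is_fallback"]),
            )
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"malformed note record at line {lineno}: {exc}") from exc
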