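"""Read, edit and write paired clinical-note text and BRAT standoff annotations.

BRAT standoff (v1.3) pairs a plain ``.txt`` note with a ``.ann`` file of
offset-anchored records: entities (``T`` lines, possibly with ``;``-separated
discontinuous fragments), attributes (``A`` lines) and events (``E`` lines).
All offsets here are 0-based half-open character offsets into the note text
after line-ending normalization (CRLF and CR are mapped to LF before any
offset is read).

The central editing primitive, :func:`apply_replacements`, substitutes entity
surfaces while shifting every other annotation span by the cumulative length
deltas of edits at earlier offsets, so non-PHI annotations stay aligned with
the text after PHI is replaced.
"""

from __future__ import annotations

import bisect
import copy
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "HEADER_TEXT",
    "HEADER_SEPARATOR",
    "TextDocument",
    "EntityAnnotation",
    "AttributeAnnotation",
    "EventAnnotation",
    "AnnotatedDocument",
    "BratParseError",
    "BratIntegrityError",
    "OverlapError",
    "normalize_line_endings",
    "parse_annotation_file",
    "check_consistency",
    "apply_replacements",
    "write_document",
    "read_document_pair",
    "write_document_pair",
]

#: Warning prefixed to resynthesized notes (legal disclaimer for accidental
#: correspondence between synthetic surrogates and real persons).
HEADER_TEXT = (
    "PERSONAL IDENTIFYING INFORMATION (PHI) IN THIS DOCUMENT HAS BEEN "
    "REPLACED WITH SYNTHETIC TEXT. ANY CORRESPONDENCE TO THE PHI OF ANY "
    "REAL PERSON IS UNINTENTIONAL"
)

#: Separator between the warning header and the original note body.
HEADER_SEPARATOR = "\n\n"


class BratParseError(ValueError):
    """A standoff line could not be parsed (malformed offsets, bad label)."""


class BratIntegrityError(ValueError):
    """An annotation references an identifier that does not exist."""


class OverlapError(ValueError):
    """Two planned replacements target overlapping character ranges."""


def normalize_line_endings(text: str) -> str:
    """Map CRLF and bare CR to LF. Must run before any offset is interpreted."""
    return text.replace("\r\n", "\n").replace("\r", "\n")


@dataclass
class TextDocument:
    doc_id: str
    text: str
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.text = normalize_line_endings(self.text)


@dataclass
class EntityAnnotation:
    """A ``T`` record: category + one or more (start, end) fragments + surface.

    ``surface`` equals the concatenation of the text slices at ``spans``,
    joined by a single space for discontinuous entities.
    """

    tid: str
    category: str
    spans: list[tuple[int, int]]
    surface: str

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]


@dataclass
class AttributeAnnotation:
    aid: str
    name: str
    target: str
    value: str | None = None


@dataclass
class EventAnnotation:
    eid: str
    trigger_type: str
    trigger: str
    args: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class AnnotatedDocument:
    """A note plus its standoff annotations: the unit of substitution."""

    text_doc: TextDocument
    entities: list[EntityAnnotation] = field(default_factory=list)
    attributes: list[AttributeAnnotation] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    #: Unhandled standoff lines (R/N/# ...), preserved verbatim on write.
    extra_lines: list[str] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.text_doc.doc_id

    @property
    def text(self) -> str:
        return self.text_doc.text

    def entity(self, tid: str) -> EntityAnnotation:
        for ent in self.entities:
            if ent.tid == tid:
                return ent
        raise KeyError(tid)

    def counts(self) -> tuple[int, int, int]:
        """(entities, attributes, events) — conserved by substitution."""
        return (len(self.entities), len(self.attributes), len(self.events))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_entity_line(line: str) -> EntityAnnotation:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"malformed T line (missing tab): {line!r}")
    tid = parts[0]
    header = parts[1]
    surface = parts[2] if len(parts) > 2 else ""
    fields = header.split(" ", 1)
    if len(fields) != 2:
        raise BratParseError(f"malformed T line (no offsets): {line!r}")
    category, span_text = fields
    spans: list[tuple[int, int]] = []
    for frag in span_text.split(";"):
        bits = frag.split()
        if len(bits) != 2:
            raise BratParseError(f"malformed span {frag!r} in line {line!r}")
        try:
            start, end = int(bits[0]), int(bits[1])
        except ValueError as exc:
            raise BratParseError(
                f"non-integer offsets in line {line!r}") from exc
        if end <= start:
            raise BratParseError(f"empty or inverted span in line {line!r}")
        spans.append((start, end))
    return EntityAnnotation(tid=tid, category=category, spans=spans,
                            surface=surface)


def _parse_attribute_line(line: str) -> AttributeAnnotation:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"malformed A line: {line!r}")
    bits = parts[1].split()
    if len(bits) < 2:
        raise BratParseError(f"malformed A line (no target): {line!r}")
    value = bits[2] if len(bits) > 2 else None
    return AttributeAnnotation(aid=parts[0], name=bits[0], target=bits[1],
                               value=value)


def _parse_event_line(line: str) -> EventAnnotation:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"malformed E line: {line!r}")
    bits = parts[1].split()
    if not bits or ":" not in bits[0]:
        raise BratParseError(f"malformed E line (no trigger): {line!r}")
    ttype, trigger = bits[0].split(":", 1)
    args = []
    for bit in bits[1:]:
        if ":" not in bit:
            raise BratParseError(f"malformed E argument {bit!r} in {line!r}")
        role, ref = bit.split(":", 1)
        args.append((role, ref))
    return EventAnnotation(eid=parts[0], trigger_type=ttype, trigger=trigger,
                           args=args)


def parse_annotation_file(
    raw: str,
) -> tuple[list[EntityAnnotation], list[AttributeAnnotation],
           list[EventAnnotation]]:
    """Parse standoff content into (entities, attributes, events).

    Unknown line types (R/N/# ...) are tolerated and skipped; use
    :func:`parse_annotation_file_full` to also retrieve them. Input order is
    preserved. Dangling A/E references raise :class:`BratIntegrityError`.
    """
    entities, attributes, events, _ = parse_annotation_file_full(raw)
    return entities, attributes, events


def parse_annotation_file_full(
    raw: str,
) -> tuple[list[EntityAnnotation], list[AttributeAnnotation],
           list[EventAnnotation], list[str]]:
    """As :func:`parse_annotation_file`, plus pass-through lines verbatim."""
    entities: list[EntityAnnotation] = []
    attributes: list[AttributeAnnotation] = []
    events: list[EventAnnotation] = []
    extras: list[str] = []
    for line in normalize_line_endings(raw).split("\n"):
        if not line.strip():
            continue
        if line.startswith("T"):
            entities.append(_parse_entity_line(line))
        elif line.startswith("A") or line.startswith("M"):
            attributes.append(_parse_attribute_line(line))
        elif line.startswith("E"):
            events.append(_parse_event_line(line))
        else:
            extras.append(line)
    tids = {e.tid for e in entities}
    eids = {e.eid for e in events}
    for attr in attributes:
        if attr.target not in tids:
            raise BratIntegrityError(
                f"{attr.aid} targets unknown entity {attr.target}")
    for ev in events:
        if ev.trigger not in tids:
            raise BratIntegrityError(
                f"{ev.eid} trigger {ev.trigger} is not a known entity")
        for role, ref in ev.args:
            if ref not in tids and ref not in eids:
                raise BratIntegrityError(
                    f"{ev.eid} argument {role}:{ref} is unresolved")
    return entities, attributes, events, extras


# ---------------------------------------------------------------------------
# Consistency checking
# ---------------------------------------------------------------------------

def entity_surface_from_text(text: str, spans: Sequence[tuple[int, int]]) -> str:
    """Surface of an entity: text slices joined by one space (BRAT tooling
    convention for discontinuous spans; used for checks, never written back
    into the note)."""
    return " ".join(text[s:e] for s, e in spans)


def check_consistency(doc: AnnotatedDocument) -> list[str]:
    """Return human-readable violations; empty list means the document is
    well formed (spans in bounds and sorted, surfaces match text slices,
    A/E references resolve)."""
    violations: list[str] = []
    n = len(doc.text)
    tids = {e.tid for e in doc.entities}
    eids = {e.eid for e in doc.events}
    for ent in doc.entities:
        prev_end = -1
        for start, end in ent.spans:
            if not (0 <= start < end <= n):
                violations.append(
                    f"{ent.tid}: span ({start},{end}) out of bounds for "
                    f"text of length {n}")
            if start < prev_end:
                violations.append(
                    f"{ent.tid}: spans overlap or are unsorted")
            prev_end = end
        expected = entity_surface_from_text(doc.text, ent.spans)
        if expected != ent.surface:
            violations.append(
                f"{ent.tid}: surface {ent.surface!r} does not match text "
                f"slice {expected!r}")
    for attr in doc.attributes:
        if attr.target not in tids:
            violations.append(
                f"{attr.aid}: dangling reference to {attr.target}")
    for ev in doc.events:
        if ev.trigger not in tids:
            violations.append(f"{ev.eid}: dangling trigger {ev.trigger}")
        for role, ref in ev.args:
            if ref not in tids and ref not in eids:
                violations.append(
                    f"{ev.eid}: dangling argument {role}:{ref}")
    return violations


# ---------------------------------------------------------------------------
# Replacement with span realignment
# ---------------------------------------------------------------------------

def _split_replacement(replacement: str, n_fragments: int) -> list[str]:
    """Distribute a replacement over the fragments of a discontinuous entity.

    Whitespace tokens are partitioned into ``n_fragments`` contiguous,
    near-even groups; if there are fewer tokens than fragments the last token
    is repeated so every fragment stays non-empty.
    """
    if n_fragments == 1:
        return [replacement]
    tokens = replacement.split()
    if not tokens:
        tokens = [replacement or "?"]
    while len(tokens) < n_fragments:
        tokens.append(tokens[-1])
    out: list[str] = []
    base, rem = divmod(len(tokens), n_fragments)
    pos = 0
    for i in range(n_fragments):
        take = base + (1 if i < rem else 0)
        out.append(" ".join(tokens[pos:pos + take]))
        pos += take
    return out


def apply_replacements(
    doc: AnnotatedDocument, plan: Mapping[str, str]
) -> AnnotatedDocument:
    """Replace the surfaces of planned entities, realigning all other spans.

    ``plan`` maps entity tids to replacement surfaces (no line breaks).
    Edits are applied in descending start-offset order so earlier offsets
    are undisturbed while later ones are rewritten; afterwards every span is
    remapped through the cumulative edit deltas. Entity/attribute/event
    counts are conserved. Two planned entities with overlapping spans raise
    :class:`OverlapError`; an *unplanned* entity overlapping an edit has its
    span clipped to cover the replacement and its surface re-read from the
    new text.
    """
    for tid in plan:
        doc.entity(tid)  # raises KeyError on unknown tid
    for surface in plan.values():
        if "\n" in surface or "\r" in surface:
            raise ValueError("replacement surfaces must not contain line breaks")

    # One edit per fragment of each planned entity.
    edits: list[tuple[int, int, str, str]] = []  # (start, end, new_text, tid)
    for tid, replacement in plan.items():
        ent = doc.entity(tid)
        pieces = _split_replacement(replacement, len(ent.spans))
        for (start, end), piece in zip(ent.spans, pieces):
            edits.append((start, end, piece, tid))
    edits.sort(key=lambda e: (e[0], e[1]))
    for (s1, e1, _, t1), (s2, e2, _, t2) in zip(edits, edits[1:]):
        if s2 < e1:
            raise OverlapError(
                f"planned replacements for {t1} and {t2} overlap "
                f"({s1},{e1}) vs ({s2},{e2})")

    # Apply in reverse offset order.
    text = doc.text
    for start, end, piece, _ in reversed(edits):
        text = text[:start] + piece + text[end:]

    # Position remapping through the (ascending) edit list.
    starts = [e[0] for e in edits]
    ends = [e[1] for e in edits]
    new_lens = [len(e[2]) for e in edits]
    cum = [0]
    for (s, e, piece, _) in edits:
        cum.append(cum[-1] + len(piece) - (e - s))

    def new_start_of_edit(i: int) -> int:
        return starts[i] + cum[i]

    def map_pos(p: int, is_end: bool) -> int:
        # edits with end <= p shift p by their cumulative delta
        k = bisect.bisect_right(ends, p)
        if k < len(edits) and starts[k] < p < ends[k]:
            # p lies strictly inside edit k: clip so the span covers the
            # whole replacement (ends map past it, starts to its beginning)
            return (new_start_of_edit(k) + new_lens[k]) if is_end \
                else new_start_of_edit(k)
        return p + cum[k]

    planned_fragment_spans: dict[str, list[tuple[int, int]]] = {}
    for i, (s, e, piece, tid) in enumerate(edits):
        ns = new_start_of_edit(i)
        planned_fragment_spans.setdefault(tid, []).append((ns, ns + len(piece)))

    new_entities: list[EntityAnnotation] = []
    for ent in doc.entities:
        if ent.tid in plan:
            spans = planned_fragment_spans[ent.tid]
            surface = entity_surface_from_text(text, spans)
            new_entities.append(EntityAnnotation(ent.tid, ent.category,
                                                 spans, surface))
        else:
            touched = False
            spans = []
            for s, e in ent.spans:
                ns, ne = map_pos(s, False), map_pos(e, True)
                if text[ns:ne] != doc.text[s:e]:
                    touched = True
                spans.append((ns, ne))
            surface = (entity_surface_from_text(text, spans) if touched
                       else ent.surface)
            new_entities.append(EntityAnnotation(ent.tid, ent.category,
                                                 spans, surface))

    return AnnotatedDocument(
        text_doc=TextDocument(doc.doc_id, text, doc.text_doc.patient_id),
        entities=new_entities,
        attributes=copy.deepcopy(doc.attributes),
        events=copy.deepcopy(doc.events),
        extra_lines=list(doc.extra_lines),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_entity(ent: EntityAnnotation) -> str:
    span_text = ";".join(f"{s} {e}" for s, e in ent.spans)
    return f"{ent.tid}\t{ent.category} {span_text}\t{ent.surface}"


def _format_attribute(attr: AttributeAnnotation) -> str:
    tail = f" {attr.value}" if attr.value is not None else ""
    return f"{attr.aid}\t{attr.name} {attr.target}{tail}"


def _format_event(ev: EventAnnotation) -> str:
    args = "".join(f" {role}:{ref}" for role, ref in ev.args)
    return f"{ev.eid}\t{ev.trigger_type}:{ev.trigger}{args}"


def write_document(
    doc: AnnotatedDocument, header_enabled: bool = False
) -> tuple[str, str]:
    """Serialize to (txt payload, ann payload).

    With ``header_enabled`` the txt payload is prefixed with the replacement
    warning (:data:`HEADER_TEXT` + :data:`HEADER_SEPARATOR`) and every span
    in the ann payload is shifted forward by the prefix length so alignment
    still holds.
    """
    shift = len(HEADER_TEXT + HEADER_SEPARATOR) if header_enabled else 0
    txt = (HEADER_TEXT + HEADER_SEPARATOR + doc.text) if header_enabled else doc.text
    lines: list[str] = []
    for ent in doc.entities:
        shifted = EntityAnnotation(
            ent.tid, ent.category,
            [(s + shift, e + shift) for s, e in ent.spans], ent.surface)
        lines.append(_format_entity(shifted))
    lines.extend(_format_attribute(a) for a in doc.attributes)
    lines.extend(_format_event(e) for e in doc.events)
    lines.extend(doc.extra_lines)
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return txt, ann


def read_document_pair(
    txt_path: str, ann_path: str, patient_id: str | None = None
) -> AnnotatedDocument:
    """Load a paired ``.txt``/``.ann`` basename from disk (UTF-8)."""
    with open(txt_path, encoding="utf-8") as fh:
        text = normalize_line_endings(fh.read())
    with open(ann_path, encoding="utf-8") as fh:
        raw = fh.read()
    entities, attributes, events, extras = parse_annotation_file_full(raw)
    doc_id = os.path.splitext(os.path.basename(txt_path))[0]
    return AnnotatedDocument(
        text_doc=TextDocument(doc_id, text, patient_id),
        entities=entities, attributes=attributes, events=events,
        extra_lines=extras)


def write_document_pair(
    doc: AnnotatedDocument, txt_path: str, ann_path: str,
    header_enabled: bool = False,
) -> None:
    txt, ann = write_document(doc, header_enabled=header_enabled)
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(txt)
    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write(ann)
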