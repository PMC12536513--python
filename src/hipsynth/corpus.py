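"""Synthetic paired .txt/.ann corpora for testing and simulation.

Real de-identification corpora cannot be redistributed, so every other
module is exercised on generated fixtures: note-like filler text with
embedded PHI surfaces at recorded offsets, per-document critical-entity
counts following a configurable distribution, chain structure (how often
each original value repeats) and patient groupings.

Two presets emulate the critical-entity load of typical corpora:

* ``uab-like`` — full EHR dumps, heavily PHI-laden (mean ~388.5, median
  224 critical mentions per document, range 2-2545);
* ``mimic-like`` — discharge summaries, sparse PHI (mean ~6.8, median 5,
  range 2-76).

Counts are drawn log-normal (matching the heavy right skew of per-document
PHI counts), rounded and clipped to the preset range. Filler text is
template boilerplate, not language-model output: determinism and exact
offset bookkeeping matter more than narrative realism here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .brat import (AnnotatedDocument, AttributeAnnotation, EntityAnnotation,
                   EventAnnotation, TextDocument)
from . import catalog as _cat

__all__ = ["CorpusSpec", "generate_corpus", "worked_example_document"]


_DEFAULT_CRITICAL_WEIGHTS = {
    "PATIENT": 0.35,
    "MEDICALRECORD": 0.20,
    "PHONE": 0.15,
    "IDNUM": 0.10,
    "SSN": 0.05,
    "EMAIL": 0.05,
    "ACCOUNT-ID": 0.04,
    "DEVICE": 0.03,
    "FAX": 0.02,
    "VEHICLE_ID": 0.01,
}

_DEFAULT_NONCRITICAL_WEIGHTS = {
    "DATE": 0.35,
    "DOCTOR": 0.25,
    "AGE": 0.10,
    "HOSPITAL": 0.10,
    "CITY": 0.08,
    "STATE": 0.05,
    "TIME": 0.04,
    "PROFESSION": 0.03,
}

_FILLERS = [
    "Seen in clinic. ",
    "Follow-up arranged. ",
    "Vitals within normal limits. ",
    "Plan discussed. ",
    "Medication list reviewed. ",
    "Labs pending. ",
    "No acute distress noted. ",
    "Assessment updated. ",
    "Imaging reviewed. ",
    "Symptoms improving. ",
]


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus; a pure function of its fields.

    ``critical_dist`` is either ``("lognormal", mu, sigma, lo, hi)`` or
    ``("fixed", k)`` and governs critical mentions per document.
    ``chain_length_mean`` sets the geometric mean of mentions per original
    value (default 3, the maximum-entropy choice for a repeat process).
    """

    n_docs: int = 100
    docs_per_patient_mean: float = 4.0
    critical_dist: tuple = ("lognormal", math.log(4.952), 0.7843, 2, 76)
    chain_length_mean: float = 3.0
    critical_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CRITICAL_WEIGHTS))
    noncritical_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NONCRITICAL_WEIGHTS))
    noncritical_per_doc: float = 4.0
    seed: int = 0

    PRESETS = {
        # (mu, sigma, lo, hi): log-normal fits whose rounded, range-clipped
        # expectation recovers the target per-document critical-entity mean
        # (mimic-like 6.8, uab-like 388.5) while keeping the target median.
        "mimic-like": (math.log(4.952), 0.7843, 2, 76),
        "uab-like": (math.log(223.0), 1.10, 2, 2545),
    }

    @classmethod
    def preset(cls, name: str, n_docs: int = 1000, seed: int = 0,
               **overrides) -> "CorpusSpec":
        if name not in cls.PRESETS:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(cls.PRESETS)}")
        mu, sigma, lo, hi = cls.PRESETS[name]
        return cls(n_docs=n_docs, seed=seed,
                   critical_dist=("lognormal", mu, sigma, lo, hi),
                   **overrides)

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.chain_length_mean < 1:
            raise ValueError("chain_length_mean must be >= 1")
        for weights, label in ((self.critical_weights, "critical"),
                               (self.noncritical_weights, "noncritical")):
            if not weights or sum(weights.values()) <= 0:
                raise ValueError(f"no {label} categories with positive weight")
            for name in weights:
                _cat.category_info(name)


def _draw_critical_count(spec: CorpusSpec, rng: np.random.Generator) -> int:
    kind = spec.critical_dist[0]
    if kind == "fixed":
        return int(spec.critical_dist[1])
    if kind == "lognormal":
        _, mu, sigma, lo, hi = spec.critical_dist
        value = int(round(float(np.exp(rng.normal(mu, sigma)))))
        return int(min(max(value, lo), hi))
    raise ValueError(f"unknown distribution kind {kind!r}")


def _original_value(category: str, rng: np.random.Generator) -> str:
    """Fabricate an 'original' PHI surface for the given category."""
    def pick(seq):
        return seq[int(rng.integers(len(seq)))]

    def digits(n):
        return "".join(str(int(d)) for d in rng.integers(0, 10, n))

    if category in ("PATIENT", "DOCTOR"):
        return f"{pick(_cat._FIRST_NAMES)} {pick(_cat._LAST_NAMES)}"
    if category == "MEDICALRECORD":
        return digits(7)
    if category in ("PHONE", "FAX"):
        return f"({digits(3)}) {digits(3)}-{digits(4)}"
    if category == "SSN":
        return f"{digits(3)}-{digits(2)}-{digits(4)}"
    if category == "IDNUM":
        letters = "".join(pick("ABCDEFGHJKLMNPRSTUVWXYZ") for _ in range(2))
        return letters + digits(6)
    if category == "DEVICE":
        return f"DEV-{digits(7)}"
    if category == "ACCOUNT-ID":
        return f"ACCT{digits(7)}"
    if category == "EMAIL":
        f = pick(_cat._FIRST_NAMES).lower()
        l = pick(_cat._LAST_NAMES).lower()
        return f"{f}.{l}@{pick(_cat._EMAIL_DOMAINS)}"
    if category == "VEHICLE_ID":
        chars = "ABCDEFGHJKLMNPRSTUVWXYZ0123456789"
        return "".join(pick(chars) for _ in range(17))
    if category == "DATE":
        m, d = int(rng.integers(1, 13)), int(rng.integers(1, 29))
        y = int(rng.integers(10, 23))
        return f"{m:02d}/{d:02d}/{y:02d}"
    if category == "AGE":
        return str(int(rng.integers(18, 95)))
    if category == "TIME":
        return f"{int(rng.integers(0, 24)):02d}:{int(rng.integers(0, 60)):02d}"
    if category == "HOSPITAL":
        return pick(_cat._HOSPITALS)
    if category == "CITY":
        return pick(_cat._CITIES)
    if category == "STATE":
        return pick(_cat._STATES)
    if category == "PROFESSION":
        return pick(_cat._PROFESSIONS)
    if category == "HOLIDAY":
        return pick(_cat._HOLIDAYS)
    if category == "COUNTRY":
        return pick(_cat._COUNTRIES)
    if category == "STREET":
        return pick(_cat._STREETS)
    if category == "ORGANIZATION":
        return pick(_cat._ORGANIZATIONS)
    if category == "ZIP":
        return digits(5)
    if category == "USERNAME":
        return f"{pick(_cat._FIRST_NAMES)[0].lower()}{pick(_cat._LAST_NAMES).lower()}{digits(2)}"
    if category == "URL":
        return pick(_cat._URLS)
    if category == "IPADDRESS":
        return ".".join(str(int(rng.integers(1, 255))) for _ in range(4))
    if category == "LOCATION-OTHER":
        return pick(_cat._LOCATIONS_OTHER)
    if category == "BIOID":
        return f"BIO{digits(7)}"
    raise ValueError(f"no original-value generator for {category!r}")


def _weighted_choice(weights: dict[str, float],
                     rng: np.random.Generator) -> str:
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _build_document(doc_id: str, patient_id: str, spec: CorpusSpec,
                    rng: np.random.Generator) -> AnnotatedDocument:
    n_critical = _draw_critical_count(spec, rng)
    n_noncritical = int(rng.poisson(spec.noncritical_per_doc))

    # Decompose the critical budget into chains (original value + repeat
    # count); repeats are geometric with the configured mean, truncated by
    # the remaining budget.
    mentions: list[tuple[str, str]] = []  # (category, surface)
    remaining = n_critical
    p_geo = 1.0 / spec.chain_length_mean
    while remaining > 0:
        length = min(int(rng.geometric(p_geo)), remaining)
        category = _weighted_choice(spec.critical_weights, rng)
        surface = _original_value(category, rng)
        mentions.extend([(category, surface)] * length)
        remaining -= length
    for _ in range(n_noncritical):
        category = _weighted_choice(spec.noncritical_weights, rng)
        mentions.append((category, _original_value(category, rng)))

    order = rng.permutation(len(mentions))
    parts: list[str] = [f"Clinical note {doc_id}.\n"]
    pos = len(parts[0])
    entities: list[EntityAnnotation] = []
    for i, j in enumerate(order):
        category, surface = mentions[int(j)]
        filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
        parts.append(filler)
        pos += len(filler)
        parts.append(surface)
        entities.append(EntityAnnotation(
            tid=f"T{i + 1}", category=category,
            spans=[(pos, pos + len(surface))], surface=surface))
        pos += len(surface)
        parts.append(". ")
        pos += 2
    text = "".join(parts)

    # A few attributes and one event to exercise reference conservation.
    attributes: list[AttributeAnnotation] = []
    for k, ent in enumerate(entities):
        if rng.random() < 0.1:
            attributes.append(AttributeAnnotation(
                aid=f"A{len(attributes) + 1}", name="Verified",
                target=ent.tid))
    events: list[EventAnnotation] = []
    if len(entities) >= 2:
        events.append(EventAnnotation(
            eid="E1", trigger_type="ENCOUNTER", trigger=entities[0].tid,
            args=[("Topic", entities[1].tid)]))

    return AnnotatedDocument(
        text_doc=TextDocument(doc_id, text, patient_id),
        entities=entities, attributes=attributes, events=events)


def generate_corpus(spec: CorpusSpec) -> list[AnnotatedDocument]:
    """Generate a corpus of annotated documents; deterministic in ``spec``.

    Documents are grouped into patients by drawing per-patient document
    counts (geometric with mean ``docs_per_patient_mean``) until ``n_docs``
    is reached. Every generated document passes consistency checking by
    construction.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        [spec.seed & 0x7FFFFFFF, 0x5EED]))
    docs: list[AnnotatedDocument] = []
    patient = 0
    while len(docs) < spec.n_docs:
        patient += 1
        k = int(rng.geometric(1.0 / spec.docs_per_patient_mean))
        for _ in range(min(k, spec.n_docs - len(docs))):
            doc_id = f"doc-{len(docs) + 1:05d}"
            docs.append(_build_document(doc_id, f"pat-{patient:05d}",
                                        spec, rng))
    return docs


def worked_example_document() -> AnnotatedDocument:
    """A fixed note mentioning one patient name ('Sandy') exactly six times.

    Mirrors the canonical six-mention example used to illustrate the four
    substitution strategies, for byte-stable strategy tests.
    """
    sentences = [
        ("Patient ", "Sandy", " was admitted overnight."),
        (" ", "Sandy", " reported intermittent chest pain."),
        (" Nursing staff spoke with ", "Sandy", " at length."),
        (" ", "Sandy", " remained stable through the night."),
        (" ", "Sandy", " will follow up in two weeks."),
        (" Discharge plan was reviewed with ", "Sandy", "."),
    ]
    parts: list[str] = []
    entities: list[EntityAnnotation] = []
    pos = 0
    for i, (pre, name, post) in enumerate(sentences):
        parts.append(pre)
        pos += len(pre)
        parts.append(name)
        entities.append(EntityAnnotation(
            tid=f"T{i + 1}", category="PATIENT",
            spans=[(pos, pos + len(name))], surface=name))
        pos += len(name)
        parts.append(post)
        pos += len(post)
    return AnnotatedDocument(
        text_doc=TextDocument("worked-example", "".join(parts)),
        entities=entities)
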