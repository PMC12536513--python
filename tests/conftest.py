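import string

import numpy as np
import pytest

from hipsynth.brat import (AnnotatedDocument, AttributeAnnotation,
                           EntityAnnotation, EventAnnotation, TextDocument)


def build_random_fixture(rng: np.random.Generator):
    """A random document with non-overlapping entities plus a replacement plan.

    Returns (doc, plan, expected_text) where expected_text comes from the
    segment-rebuild oracle: inter-entity text segments interleaved with the
    planned replacements (or original surfaces for unplanned entities).
    """
    letters = string.ascii_lowercase + "     "
    n = int(rng.integers(40, 160))
    text = "".join(letters[int(i)] for i in rng.integers(0, len(letters), n))
    # carve non-overlapping spans
    n_ents = int(rng.integers(1, 7))
    cuts = sorted(rng.choice(n - 1, size=min(2 * n_ents, n - 1),
                             replace=False).tolist())
    spans = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        if b > a:
            spans.append((int(a), int(b)))
    entities = [
        EntityAnnotation(tid=f"T{i + 1}", category="PATIENT",
                         spans=[(s, e)], surface=text[s:e])
        for i, (s, e) in enumerate(spans)
    ]
    doc = AnnotatedDocument(
        text_doc=TextDocument("fixture", text), entities=entities)

    plan = {}
    for ent in entities:
        if rng.random() < 0.7:
            length = int(rng.integers(1, 12))
            plan[ent.tid] = "".join(
                string.ascii_uppercase[int(i)]
                for i in rng.integers(0, 26, length))

    # segment-rebuild oracle
    pieces, pos = [], 0
    for ent in entities:
        s, e = ent.spans[0]
        pieces.append(text[pos:s])
        pieces.append(plan.get(ent.tid, text[s:e]))
        pos = e
    pieces.append(text[pos:])
    return doc, plan, "".join(pieces)


def brute_force_msrs(chains):
    """Independent MSRS counter: max per-chain value multiplicity, else 0."""
    best = 0
    for chain in chains:
        for value in set(chain):
            best = max(best, sum(1 for v in chain if v == value))
    return best


@pytest.fixture
def random_fixture_builder():
    return build_random_fixture


@pytest.fixture
def msrs_oracle():
    return brute_force_msrs


@pytest.fixture
def simple_doc():
    """Two entities, one attribute, one event: 'Sandy came on 07/17/19.'"""
    text = "Sandy came on 07/17/19."
    entities = [
        EntityAnnotation("T1", "PATIENT", [(0, 5)], "Sandy"),
        EntityAnnotation("T2", "DATE", [(14, 22)], "07/17/19"),
    ]
    attributes = [AttributeAnnotation("A1", "Verified", "T1")]
    events = [EventAnnotation("E1", "VISIT", "T1", [("When", "T2")])]
    return AnnotatedDocument(
        text_doc=TextDocument("simple", text),
        entities=entities, attributes=attributes, events=events)
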