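"""Surrogate substitution policies as a two-state reuse/resample chain.

Four policies are provided. *Simple* replaces each PHI mention with a
bracketed category placeholder (``[AGE]``) and is not a hiding-in-plain-sight
strategy. The three HIPS policies differ only in the probability of reusing
the previous surrogate for the next mention of the same original value
(the self-transition probability of a two-state first-order Markov chain):

========== ===================
policy     self-transition
========== ===================
consistent 1.0 (always reuse)
markov     0.5
random     0.0 (always fresh)
========== ===================

The first mention of a chain always draws a fresh surrogate. A fresh draw is
*not* forced to differ from the previous value: pool collisions are allowed,
which is what makes surrogate repeats (and hence masking) possible under the
random policy.

Chains are keyed by (category, normalized original surface) and never cross
document boundaries.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np

from .brat import AnnotatedDocument, apply_replacements
from .catalog import MakerConfig, SurrogateMaker, category_info

__all__ = [
    "StrategyConfig",
    "ChainState",
    "AssignmentLog",
    "ChainRecord",
    "next_surrogate",
    "apply_strategy",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("simple", "consistent", "random", "markov")

_SELF_TRANSITION = {"consistent": 1.0, "markov": 0.5, "random": 0.0}


@dataclass(frozen=True)
class StrategyConfig:
    """A substitution policy, identified by its self-transition probability."""

    name: str
    self_transition: float | None

    @classmethod
    def from_name(
        cls, name: str, self_transition: float | None = None
    ) -> "StrategyConfig":
        name = name.lower()
        if name not in STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")
        if name == "simple":
            return cls("simple", None)
        p = _SELF_TRANSITION[name] if self_transition is None else self_transition
        if not 0.0 <= p <= 1.0:
            raise ValueError("self_transition must lie in [0, 1]")
        return cls(name, p)

    @property
    def is_hips(self) -> bool:
        return self.name != "simple"


def normalize_surface(surface: str) -> str:
    """Chain-key normalization: case-folded, whitespace-collapsed."""
    return re.sub(r"\s+", " ", surface.strip()).casefold()


@dataclass
class ChainState:
    """Per-(document, category, original value) reuse/resample state."""

    key: tuple[str, str]  # (category, normalized original surface)
    last_surrogate: str = ""
    mention_count: int = 0


@dataclass
class ChainRecord:
    """One chain's full surrogate sequence, in mention (offset) order."""

    category: str
    original: str
    critical: bool
    surrogates: list[str] = field(default_factory=list)


class AssignmentLog:
    """Ordered record of mention → surrogate assignments for one document."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.chains: dict[tuple[str, str], ChainRecord] = {}

    def record(self, category: str, original: str, critical: bool,
               surrogate: str) -> None:
        key = (category, normalize_surface(original))
        rec = self.chains.get(key)
        if rec is None:
            rec = ChainRecord(category=category, original=original,
                              critical=critical)
            self.chains[key] = rec
        rec.surrogates.append(surrogate)

    def critical_chains(self) -> list[ChainRecord]:
        return [c for c in self.chains.values() if c.critical]

    @property
    def n_critical_mentions(self) -> int:
        return sum(len(c.surrogates) for c in self.critical_chains())

    def __len__(self) -> int:
        return len(self.chains)


def next_surrogate(
    state: ChainState,
    strategy: StrategyConfig,
    draw,
    rng: np.random.Generator,
) -> str:
    """Advance a chain one mention and return its surrogate.

    The initial mention always draws fresh via ``draw()``; later mentions
    reuse the previous surrogate with probability ``self_transition`` and
    draw fresh otherwise.
    """
    if not strategy.is_hips:
        raise ValueError("next_surrogate applies to HIPS strategies only")
    if state.mention_count == 0:
        value = draw()
    elif rng.random() < strategy.self_transition:
        value = state.last_surrogate
    else:
        value = draw()
    state.last_surrogate = value
    state.mention_count += 1
    return value


def _doc_rng(seed: int, doc_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [seed & 0x7FFFFFFF, zlib.crc32(doc_id.encode("utf-8"))]))


def apply_strategy(
    doc: AnnotatedDocument,
    strategy: StrategyConfig,
    config: MakerConfig | None = None,
    maker: SurrogateMaker | None = None,
) -> tuple[AnnotatedDocument, AssignmentLog]:
    """Substitute every catalog PHI entity in ``doc`` under ``strategy``.

    Mentions are visited in ascending start-offset order for chain-state
    transitions; the text edits themselves are applied in reverse-offset
    order by :func:`hipsynth.brat.apply_replacements`, which also realigns
    every other annotation span. Entity/attribute/event counts are
    conserved. Returns the substituted document and the per-chain
    assignment log (empty for *simple*, which allocates no chain state).
    """
    if maker is None:
        maker = SurrogateMaker(config or MakerConfig())
    cfg = maker.config
    rng = _doc_rng(cfg.seed, doc.doc_id)
    date_off, age_off = maker.document_offsets(rng)

    log = AssignmentLog(doc.doc_id)
    states: dict[tuple[str, str], ChainState] = {}
    plan: dict[str, str] = {}

    for ent in sorted(doc.entities, key=lambda e: (e.start, e.end)):
        cat = category_info(ent.category, cfg.label_map)
        if strategy.name == "simple":
            plan[ent.tid] = f"[{cat.name}]"
            continue
        key = (cat.name, normalize_surface(ent.surface))
        state = states.get(key)
        if state is None:
            state = ChainState(key=key)
            states[key] = state

        def draw(ent=ent, cat=cat):
            return maker.make(cat.name, ent.surface, rng,
                              date_offset=date_off, age_offset=age_off)

        surrogate = next_surrogate(state, strategy, draw, rng)
        plan[ent.tid] = surrogate
        log.record(cat.name, ent.surface, cat.critical, surrogate)

    new_doc = apply_replacements(doc, plan)
    return new_doc, log
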