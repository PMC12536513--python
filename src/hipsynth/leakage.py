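"""Re-identification leakage: MSRS, false-negative injection, analytic model.

The masking statistic is the *Maximum Surrogate Repeat Size* (MSRS): within
one document, the largest number of times any single surrogate value repeats
inside any one critical-entity chain. A missed PHI mention (false negative)
repeating no more often than the MSRS is statistically indistinguishable
from a surrogate, so a document *leaks* only when the PHI signal (critical
false-negative count) exceeds this noise floor:

* consistent — any critical FN leaks (the same surrogate is always reused,
  so a lone real value stands out: the single-occurrence vulnerability);
* random / markov — leak iff the critical FN count exceeds the MSRS.

A patient leaks when at least one of their documents leaks. Simulation
averages leak rates over many seeded false-negative injections at a fixed
false-negative error rate (FNER).

The analytic model for simulated corpora treats the corpus-total number of
unremoved PHI entities as Binomial(N, FNER) with N = documents x entities
per document, and reports the upper-tail probability that it exceeds a
per-strategy masking threshold τ (0 for consistent; for random/markov the
expected repeat count of a fake surrogate drawn from a pool of 1000,
estimated by Monte Carlo in :func:`strategy_threshold`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .strategies import AssignmentLog, StrategyConfig

__all__ = [
    "compute_msrs",
    "inject_false_negatives",
    "document_leak",
    "DocumentProfile",
    "SimulationConfig",
    "LeakageResult",
    "simulate_leakage",
    "strategy_threshold",
    "ThresholdEstimate",
    "expected_fn",
    "analytic_leak_probability",
    "CALIBRATED_THRESHOLD_DRAWS",
]

#: Number of fresh surrogate draws per chain used when estimating the
#: per-strategy masking threshold. With a pool of 1000 this setting
#: reproduces the reference thresholds ~1.015 (random) and ~2.028 (markov);
#: see docs/methods.md for the calibration.
CALIBRATED_THRESHOLD_DRAWS = 30


def compute_msrs(log: AssignmentLog, critical_only: bool = True) -> int:
    """Maximum multiplicity of any surrogate value within any one chain.

    Multiplicities never pool across chains: the same name drawn in two
    different chains does not add up. Documents with no (critical) chains
    return 0; a single-mention chain yields 1.
    """
    chains = log.critical_chains() if critical_only else list(log.chains.values())
    best = 0
    for chain in chains:
        if chain.surrogates:
            best = max(best, max(Counter(chain.surrogates).values()))
    return best


def inject_false_negatives(
    critical_mentions: Sequence, fner: float, rng: np.random.Generator
) -> list:
    """Mark each critical mention FN independently with probability ``fner``."""
    if not 0.0 <= fner <= 1.0:
        raise ValueError("fner must lie in [0, 1]")
    if fner == 0.0:
        return []
    mask = rng.random(len(critical_mentions)) < fner
    return [m for m, hit in zip(critical_mentions, mask) if hit]


def document_leak(strategy: StrategyConfig | str, fn_count: int,
                  msrs: int) -> bool:
    """Leak decision for one document.

    consistent: any critical FN leaks; random/markov: FN count must exceed
    the MSRS. ``simple`` applies no surrogates at all, so like consistent a
    single FN is conspicuous.
    """
    name = strategy.name if isinstance(strategy, StrategyConfig) else strategy
    if fn_count < 0 or msrs < 0:
        raise ValueError("fn_count and msrs must be non-negative")
    if name in ("consistent", "simple"):
        return fn_count > 0
    if name in ("random", "markov"):
        return fn_count > msrs
    raise ValueError(f"unknown strategy {name!r}")


@dataclass(frozen=True)
class DocumentProfile:
    """What the simulation needs from one substituted document."""

    doc_id: str
    patient_id: str
    n_critical: int
    msrs: int

    @classmethod
    def from_log(cls, log: AssignmentLog,
                 patient_id: str | None = None) -> "DocumentProfile":
        return cls(doc_id=log.doc_id,
                   patient_id=patient_id or log.doc_id,
                   n_critical=log.n_critical_mentions,
                   msrs=compute_msrs(log))


@dataclass
class SimulationConfig:
    strategy: StrategyConfig
    fner: float
    n_sims: int = 1000
    base_seed: int = 0
    #: Stricter variant comparing each chain's FN count to that chain's own
    #: repeat ceiling is handled upstream by building per-chain profiles.

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0.0 <= self.fner <= 1.0:
            raise ValueError("fner must lie in [0, 1]")


@dataclass
class LeakageResult:
    strategy: str
    fner: float
    n_sims: int
    base_seed: int
    document_rate: float
    patient_rate: float
    msrs_distribution: dict[int, int]
    per_replicate_document_rates: np.ndarray = field(repr=False)
    per_replicate_patient_rates: np.ndarray = field(repr=False)


def simulate_leakage(
    profiles: Sequence[DocumentProfile], config: SimulationConfig
) -> LeakageResult:
    """Average document- and patient-level leak rates over seeded replicates.

    Replicate ``r`` draws each document's critical FN count as
    Binomial(n_critical, fner) with seed ``base_seed + r``, so any single
    replicate can be re-run in isolation. The document rate is the mean
    fraction of leaked documents; the patient rate the mean fraction of
    patients with >=1 leaked document.
    """
    if not profiles:
        raise ValueError("empty corpus")
    n_crit = np.array([p.n_critical for p in profiles])
    msrs = np.array([p.msrs for p in profiles])
    patients = [p.patient_id for p in profiles]
    unique_patients = sorted(set(patients))
    pat_pos = {p: i for i, p in enumerate(unique_patients)}
    pat_index = np.array([pat_pos[p] for p in patients])
    consistent_rule = config.strategy.name in ("consistent", "simple")

    doc_rates = np.empty(config.n_sims)
    pat_rates = np.empty(config.n_sims)
    for r in range(config.n_sims):
        rng = np.random.default_rng(config.base_seed + r)
        fn = rng.binomial(n_crit, config.fner)
        leaked = fn > 0 if consistent_rule else fn > msrs
        doc_rates[r] = leaked.mean()
        pat_leaked = np.zeros(len(unique_patients), dtype=bool)
        np.logical_or.at(pat_leaked, pat_index, leaked)
        pat_rates[r] = pat_leaked.mean()

    return LeakageResult(
        strategy=config.strategy.name,
        fner=config.fner,
        n_sims=config.n_sims,
        base_seed=config.base_seed,
        document_rate=float(doc_rates.mean()),
        patient_rate=float(pat_rates.mean()),
        msrs_distribution=dict(sorted(Counter(int(m) for m in msrs).items())),
        per_replicate_document_rates=doc_rates,
        per_replicate_patient_rates=pat_rates,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    strategy: str
    value: float
    standard_error: float
    n_replicates: int
    n_draws: int
    pool_size: int


def strategy_threshold(
    strategy: StrategyConfig | str,
    pool_size: int = 1000,
    n_draws: int = CALIBRATED_THRESHOLD_DRAWS,
    n_replicates: int = 100_000,
    rng: np.random.Generator | None = None,
) -> ThresholdEstimate:
    """Expected repeat count of a fake surrogate value under a strategy.

    For the consistent strategy the threshold is exactly 0 by definition
    (a single real value is always distinguishable from the one repeated
    surrogate). For random/markov, one chain is simulated as ``n_draws``
    fresh surrogate draws from a pool of ``pool_size`` values, each draw
    opening a run whose length is geometric with mean
    1/(1 - self_transition); the statistic is the mean, over distinct
    drawn values, of the value's total mention count. The Monte-Carlo mean
    and its standard error are returned.
    """
    if isinstance(strategy, str):
        strategy = StrategyConfig.from_name(strategy)
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if strategy.name in ("consistent", "simple"):
        return ThresholdEstimate(strategy.name, 0.0, 0.0, 0, n_draws,
                                 pool_size)
    if rng is None:
        rng = np.random.default_rng(0)
    p = strategy.self_transition
    values = rng.integers(0, pool_size, size=(n_replicates, n_draws))
    if p > 0:
        runs = rng.geometric(1.0 - p, size=(n_replicates, n_draws))
    else:
        runs = np.ones((n_replicates, n_draws), dtype=np.int64)
    total = runs.sum(axis=1)
    values.sort(axis=1)
    n_distinct = 1 + (np.diff(values, axis=1) > 0).sum(axis=1)
    per_rep = total / n_distinct
    value = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / np.sqrt(n_replicates))
    return ThresholdEstimate(strategy.name, value, se, n_replicates,
                             n_draws, pool_size)


def expected_fn(n_docs: float, entities_per_doc: float, fner: float) -> float:
    """Expected unremoved PHI entities in a corpus: the triple product."""
    if n_docs < 0 or entities_per_doc < 0 or fner < 0:
        raise ValueError("arguments must be non-negative")
    return n_docs * entities_per_doc * fner


def analytic_leak_probability(
    n_total_entities: int, fner: float, tau: float
) -> float:
    """P(X > τ) for X ~ Binomial(N, fner): the analytic leak probability.

    At τ = 0 this is 1 - (1 - fner)^N; with zero trials it is 0. Supports
    curves over corpus sizes and entities/document by passing
    N = n_docs * entities_per_doc.
    """
    if n_total_entities < 0:
        raise ValueError("n_total_entities must be non-negative")
    if not 0.0 <= fner <= 1.0:
        raise ValueError("fner must lie in [0, 1]")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if n_total_entities == 0:
        return 0.0
    return float(stats.binom.sf(tau, n_total_entities, fner))
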