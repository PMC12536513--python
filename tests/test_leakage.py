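"""MSRS, leak rules, false-negative simulation and the analytic model."""

import numpy as np
import pytest

from hipsynth.catalog import MakerConfig, SurrogateMaker
from hipsynth.corpus import CorpusSpec, generate_corpus
from hipsynth.leakage import (DocumentProfile, SimulationConfig,
                              analytic_leak_probability, compute_msrs,
                              document_leak, expected_fn,
                              inject_false_negatives, simulate_leakage,
                              strategy_threshold)
from hipsynth.strategies import AssignmentLog, StrategyConfig, apply_strategy


def log_from_chains(chains, critical=True):
    log = AssignmentLog("doc")
    for i, chain in enumerate(chains):
        for value in chain:
            log.record("PATIENT" if critical else "DOCTOR",
                       f"orig{i}", critical, value)
    return log


class TestMsrs:
    def test_markov_worked_sequence(self):
        log = log_from_chains([["Sara", "Sara", "Ann",
                                "Maria", "Maria", "Maria"]])
        assert compute_msrs(log) == 3

    def test_random_worked_sequence(self):
        log = log_from_chains([["Kim", "Nisha", "Cathy",
                                "Maria", "Hannah", "Lin"]])
        assert compute_msrs(log) == 1

    def test_single_mention_chain(self):
        assert compute_msrs(log_from_chains([["X"]])) == 1

    def test_no_critical_mentions_is_zero(self):
        log = log_from_chains([["Ann", "Ann"]], critical=False)
        assert compute_msrs(log) == 0
        assert compute_msrs(log, critical_only=False) == 2

    def test_multiplicity_never_pools_across_chains(self):
        # the same surrogate in two chains does not add up
        log = log_from_chains([["Sara", "Ann"], ["Sara", "Kim"]])
        assert compute_msrs(log) == 1

    def test_matches_brute_force_on_random_logs(self, msrs_oracle):
        rng = np.random.default_rng(31)
        for _ in range(300):
            chains = [[f"v{int(v)}" for v in rng.integers(0, 6,
                                                          rng.integers(1, 9))]
                      for _ in range(int(rng.integers(1, 5)))]
            log = log_from_chains(chains)
            assert compute_msrs(log) == msrs_oracle(chains)


class TestFalseNegativeInjection:
    def test_zero_rate_empty(self):
        rng = np.random.default_rng(0)
        assert inject_false_negatives(list(range(100)), 0.0, rng) == []

    def test_unit_rate_all(self):
        rng = np.random.default_rng(0)
        mentions = list(range(100))
        assert inject_false_negatives(mentions, 1.0, rng) == mentions

    def test_binomial_mean(self):
        rng = np.random.default_rng(9)
        mentions = list(range(1000))
        counts = [len(inject_false_negatives(mentions, 0.01, rng))
                  for _ in range(10_000)]
        se = np.sqrt(1000 * 0.01 * 0.99 / len(counts))
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            inject_false_negatives([1], 1.5, np.random.default_rng(0))


class TestDocumentLeak:
    @pytest.mark.parametrize("strategy,fn,msrs,expected", [
        ("consistent", 1, 99, True),   # any FN leaks under consistent
        ("consistent", 0, 0, False),
        ("markov", 2, 3, False),       # FN below the noise floor is masked
        ("markov", 4, 3, True),
        ("random", 1, 1, False),
        ("random", 2, 1, True),
        ("simple", 1, 0, True),
        ("markov", 0, 0, False),
    ])
    def test_rule(self, strategy, fn, msrs, expected):
        assert document_leak(strategy, fn, msrs) is expected


def _build_profiles():
    docs = generate_corpus(CorpusSpec.preset("mimic-like", n_docs=150,
                                             seed=5))
    maker = SurrogateMaker(MakerConfig(seed=5))
    out = {}
    for name in ("consistent", "random", "markov"):
        strategy = StrategyConfig.from_name(name)
        out[name] = [
            DocumentProfile.from_log(
                apply_strategy(d, strategy, maker=maker)[1],
                patient_id=d.text_doc.patient_id)
            for d in docs
        ]
    return out


@pytest.fixture(scope="module")
def profiles():
    return _build_profiles()


class TestSimulateLeakage:

    def test_zero_fner_no_leaks(self, profiles):
        for name, profs in profiles.items():
            res = simulate_leakage(profs, SimulationConfig(
                strategy=StrategyConfig.from_name(name), fner=0.0,
                n_sims=5, base_seed=1))
            assert res.document_rate == 0.0
            assert res.patient_rate == 0.0

    def test_consistent_matches_closed_form(self, profiles):
        # per-document leak probability is 1-(1-f)^m under consistent
        fner = 0.02
        profs = profiles["consistent"]
        res = simulate_leakage(profs, SimulationConfig(
            strategy=StrategyConfig.from_name("consistent"), fner=fner,
            n_sims=400, base_seed=3))
        closed = np.mean([1 - (1 - fner) ** p.n_critical for p in profs])
        se = res.per_replicate_document_rates.std(ddof=1) / np.sqrt(400)
        assert abs(res.document_rate - closed) < max(4 * se, 0.003)

    def test_strategy_ordering(self, profiles):
        for fner in (0.005, 0.05):
            rates = {}
            for name, profs in profiles.items():
                rates[name] = simulate_leakage(profs, SimulationConfig(
                    strategy=StrategyConfig.from_name(name), fner=fner,
                    n_sims=100, base_seed=2)).document_rate
            assert rates["consistent"] >= rates["random"] >= rates["markov"]

    def test_patient_rate_at_least_document_rate(self, profiles):
        res = simulate_leakage(profiles["markov"], SimulationConfig(
            strategy=StrategyConfig.from_name("markov"), fner=0.05,
            n_sims=100, base_seed=4))
        assert res.patient_rate >= res.document_rate

    def test_replicates_reproducible(self, profiles):
        cfg = SimulationConfig(strategy=StrategyConfig.from_name("markov"),
                               fner=0.01, n_sims=20, base_seed=8)
        a = simulate_leakage(profiles["markov"], cfg)
        b = simulate_leakage(profiles["markov"], cfg)
        assert np.array_equal(a.per_replicate_document_rates,
                              b.per_replicate_document_rates)

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            simulate_leakage([], SimulationConfig(
                strategy=StrategyConfig.from_name("markov"), fner=0.01))


class TestThresholds:
    def test_consistent_exactly_zero(self):
        est = strategy_threshold("consistent")
        assert est.value == 0.0 and est.standard_error == 0.0

    def test_random_and_markov_reference_values(self):
        rng = np.random.default_rng(21)
        rand = strategy_threshold("random", n_replicates=50_000, rng=rng)
        mark = strategy_threshold("markov", n_replicates=50_000, rng=rng)
        assert rand.value == pytest.approx(1.015, abs=0.01)
        assert mark.value == pytest.approx(2.028, abs=0.02)
        assert 0 < rand.value < mark.value

    def test_threshold_ordering(self):
        rng = np.random.default_rng(2)
        taus = [strategy_threshold(s, n_replicates=20_000, rng=rng).value
                for s in ("consistent", "random", "markov")]
        assert taus[0] < taus[1] < taus[2]


class TestAnalyticModel:
    def test_expected_fn_product(self):
        assert expected_fn(10, 15, 0.01) == pytest.approx(1.5)
        assert expected_fn(123, 456, 0.0) == 0.0
        assert expected_fn(10000, 1500, 0.05) == pytest.approx(750000)

    def test_tau_zero_closed_form(self):
        for n in (1, 10, 300):
            for fner in (0.01, 0.05):
                assert analytic_leak_probability(n, fner, 0.0) == \
                    pytest.approx(1 - (1 - fner) ** n, rel=1e-12)

    def test_no_trials_no_leak(self):
        assert analytic_leak_probability(0, 0.05, 1.0) == 0.0

    def test_monotone_in_fner(self):
        ps = [analytic_leak_probability(300, f, 2.028)
              for f in (0.001, 0.005, 0.01, 0.05, 0.2)]
        assert ps == sorted(ps)

    def test_monotone_in_tau_curves_never_cross(self):
        # consistent (tau=0) >= random (1.015) >= markov (2.028) everywhere
        for n in (10, 150, 4500, 150000):
            for fner in (0.01, 0.05):
                p = [analytic_leak_probability(n, fner, tau)
                     for tau in (0.0, 1.015, 2.028)]
                assert p[0] >= p[1] >= p[2]

    def test_matches_monte_carlo_tail(self):
        rng = np.random.default_rng(77)
        n, fner, tau = 300, 0.01, 2.028
        draws = rng.binomial(n, fner, size=200_000)
        mc = (draws > tau).mean()
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert abs(analytic_leak_probability(n, fner, tau) - mc) < 3 * se
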