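"""Variant choice, learning decisions, innovation, repertoire bookkeeping and
forgetting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertlearn import Individual, RepertoireEntry, Variant, make_fixture
from vertlearn.agents import (add_to_repertoire, choose_variant, decide_express,
                              decide_social, draw_choice_index,
                              draw_forget_index, forget_step, forgetting_probs,
                              innovate, innovate_from_draws, proportional_probs,
                              record_expression, social_learning_pick,
                              softmax_probs)


# ---------------------------------------------------------------------------
# choice rules
# ---------------------------------------------------------------------------

def test_proportional_probs_normalize_adaptation_values():
    probs = proportional_probs(np.array([0.5, 0.25, 0.25]))
    assert probs == pytest.approx([0.5, 0.25, 0.25])


def test_single_variant_is_certain():
    assert proportional_probs(np.array([0.3])) == pytest.approx([1.0])


def test_all_zero_adaptation_degenerates_to_uniform():
    assert proportional_probs(np.array([0.0, 0.0])) == pytest.approx([0.5, 0.5])


def test_empty_repertoire_choice_is_an_error():
    with pytest.raises(Exception):
        proportional_probs(np.empty(0))
    with pytest.raises(Exception):
        softmax_probs(np.empty(0), 0.1)


def test_softmax_equal_values_are_uniform():
    probs = softmax_probs(np.array([0.4, 0.4, 0.4, 0.4]), 0.1)
    assert probs == pytest.approx([0.25] * 4)


def test_softmax_closed_form_two_variants():
    probs = softmax_probs(np.array([1.0, 0.0]), 0.1)
    expected = math.exp(10.0) / (math.exp(10.0) + 1.0)
    assert probs[0] == pytest.approx(expected, rel=1e-12)
    assert probs[0] == pytest.approx(0.9999546, abs=1e-7)


def test_softmax_high_temperature_approaches_uniform():
    probs = softmax_probs(np.array([1.0, 0.0, 0.5]), 1e6)
    assert probs == pytest.approx([1 / 3] * 3, abs=1e-6)


def test_softmax_rejects_nonpositive_temperature():
    with pytest.raises(Exception):
        softmax_probs(np.array([0.5]), 0.0)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
       st.floats(0.01, 10.0))
def test_choice_probability_vectors_are_distributions(values, tau):
    a = np.array(values)
    for probs in (proportional_probs(a), softmax_probs(a, tau)):
        assert np.all(probs >= 0.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
       st.integers(0, 5), st.floats(0.05, 0.95))
def test_raising_one_value_raises_its_choice_probability(values, idx, bump):
    a = np.array(values)
    idx = idx % a.size
    before = proportional_probs(a)[idx]
    a2 = a.copy()
    a2[idx] += bump
    assert proportional_probs(a2)[idx] > before


def test_draw_choice_index_is_inverse_cdf_of_probs():
    # the allocation-free sampler and the probability vector agree exactly
    a = np.array([0.2, 0.0, 0.5, 0.3])
    for rule, tau in ((0, 0.1), (1, 0.1), (1, 2.0)):
        probs = (proportional_probs(a) if rule == 0 else softmax_probs(a, tau))
        cdf = np.cumsum(probs)
        for u in np.linspace(0.001, 0.999, 97):
            expected = int(np.searchsorted(cdf, u * cdf[-1], side="right"))
            expected = min(expected, a.size - 1)
            assert draw_choice_index(a, rule, tau, u) == expected


# ---------------------------------------------------------------------------
# express / learn gates
# ---------------------------------------------------------------------------

def test_express_gate_edge_probabilities(rng):
    assert all(decide_express(1.0, rng) for _ in range(200))
    assert not any(decide_express(0.0, rng) for _ in range(200))


def test_express_gate_frequency(rng):
    hits = sum(decide_express(0.7, rng) for _ in range(100_000))
    assert hits / 100_000 == pytest.approx(0.7, abs=0.01)


def test_social_gate_edges_and_frequency(rng):
    assert all(decide_social(1.0, rng) for _ in range(200))
    assert not any(decide_social(0.0, rng) for _ in range(200))
    hits = sum(decide_social(0.2, rng) for _ in range(100_000))
    assert hits / 100_000 == pytest.approx(0.2, abs=0.01)


# ---------------------------------------------------------------------------
# payoff-biased social learning
# ---------------------------------------------------------------------------

def _variants(n):
    return [Variant(id=i, a1=0.5, a2=0.0) for i in range(n)]


def test_demonstrator_sampling_is_payoff_biased(rng):
    variants = _variants(2)
    payoffs = np.array([0.9, 0.1])
    picks = [social_learning_pick(payoffs, variants, rng).id
             for _ in range(100_000)]
    frac = np.mean([p == 0 for p in picks])
    assert frac == pytest.approx(0.9, abs=0.01)


def test_single_demonstrator_always_copied(rng):
    variants = [Variant(id=7, a1=0.4, a2=0.0), None]
    for _ in range(50):
        assert social_learning_pick(np.array([0.4, 0.0]), variants, rng).id == 7


def test_zero_payoff_pool_degenerates_to_uniform(rng):
    variants = _variants(3)
    picks = [social_learning_pick(np.zeros(3), variants, rng).id
             for _ in range(60_000)]
    counts = np.bincount(picks, minlength=3) / len(picks)
    assert counts == pytest.approx([1 / 3] * 3, abs=0.01)


def test_focal_individual_never_copies_itself(rng):
    variants = _variants(3)
    payoffs = np.array([1.0, 0.2, 0.2])
    picks = {social_learning_pick(payoffs, variants, rng, exclude=0).id
             for _ in range(500)}
    assert 0 not in picks


def test_no_demonstrators_signals_innovation_fallback(rng):
    assert social_learning_pick(np.array([0.0]), [None], rng) is None
    assert social_learning_pick(np.array([0.5]), [Variant(0, 0.5, 0.0)], rng,
                                exclude=0) is None


# ---------------------------------------------------------------------------
# innovation regimes
# ---------------------------------------------------------------------------

def _draw_many(regime, env, n, seed, eps3=0.001, rho_latent=0.0):
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    for i in range(n):
        out[i] = innovate_from_draws(regime, env, eps3, rho_latent,
                                     rng.random(), rng.random(), rng.random())
    return out


def test_single_state_regimes_adapt_to_current_environment_only():
    for regime in (0, 1, 2):
        for env in (1, 2):
            draws = _draw_many(regime, env, 2000, seed=regime * 10 + env)
            own = draws[:, env - 1]
            other = draws[:, 2 - env]
            assert np.all(other == 0.0)
            assert np.all((own >= 0.0) & (own <= 1.0))


def test_type2_high_value_tail_fraction():
    # values above 0.8 only arise from the 5% unrestricted branch: 0.05 * 0.2
    draws = _draw_many(1, 1, 100_000, seed=1)[:, 0]
    assert np.mean(draws > 0.8) == pytest.approx(0.01, abs=0.003)


def test_type3_innovations_mostly_fail():
    eps = 0.001
    draws = _draw_many(2, 1, 100_000, seed=2, eps3=eps)[:, 0]
    assert np.mean(draws <= eps) == pytest.approx(0.95, abs=0.005)


def test_correlated_regime_has_target_correlation_and_uniform_marginals():
    from scipy import stats

    rho_latent = 2.0 * math.sin(math.pi * (-0.9) / 6.0)
    draws = _draw_many(3, 1, 100_000, seed=3, rho_latent=rho_latent)
    r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
    assert r == pytest.approx(-0.9, abs=0.02)
    for col in (0, 1):
        assert stats.kstest(draws[:, col], "uniform").pvalue > 0.001


def test_uniform_both_regime_is_independent_uniform():
    draws = _draw_many(4, 1, 100_000, seed=4)
    assert abs(np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]) < 0.02
    assert np.all((draws >= 0) & (draws <= 1))


def test_object_level_innovate_allocates_ids(rng):
    v = innovate("type1", 1, rng, new_id=123)
    assert v.id == 123 and v.a2 == 0.0 and 0.0 <= v.a1 <= 1.0


def test_unknown_regime_code_is_an_error():
    with pytest.raises(Exception):
        innovate_from_draws(9, 1, 0.001, 0.0, 0.5, 0.5, 0.5)


# ---------------------------------------------------------------------------
# repertoire bookkeeping
# ---------------------------------------------------------------------------

def _individual_with(values, counts):
    entries = [RepertoireEntry(Variant(i, a, 0.0), n)
               for i, (a, n) in enumerate(zip(values, counts))]
    return Individual(id=0, xi=0.2, phi=0.2, repertoire=entries)


def test_duplicate_variant_is_not_added_again(rng):
    ind = _individual_with([0.5, 0.3], [1, 1])
    add_to_repertoire(ind, Variant(1, 0.3, 0.0), rng)
    assert ind.repertoire_size == 2


def test_new_variant_grows_repertoire(rng):
    ind = _individual_with([0.5, 0.3, 0.2], [1, 1, 1])
    add_to_repertoire(ind, Variant(99, 0.9, 0.0), rng)
    assert ind.repertoire_size == 4
    assert ind.repertoire[-1].n == 1


def test_repertoire_cap_forces_one_forgetting_event(rng):
    ind = _individual_with(np.linspace(0.1, 0.9, 500), np.ones(500, dtype=int))
    before_ids = {e.variant.id for e in ind.repertoire}
    add_to_repertoire(ind, Variant(10_000, 0.5, 0.0), rng, max_repertoire=500)
    after_ids = {e.variant.id for e in ind.repertoire}
    assert ind.repertoire_size == 500
    assert 10_000 in after_ids
    assert len(before_ids - after_ids) == 1


def test_record_expression_increments_counts():
    ind = _individual_with([0.5], [1])
    record_expression(ind, 0)
    assert ind.repertoire[0].n == 2
    for _ in range(5):
        record_expression(ind, 0)
    assert ind.repertoire[0].n == 7
    assert ind.expressions == 6


def test_insertion_then_expression_reaches_count_two(rng):
    # a newly learned variant enters at n=1; expressing it brings it to 2
    ind = _individual_with([0.5], [3])
    add_to_repertoire(ind, Variant(5, 0.8, 0.0), rng)
    record_expression(ind, 5)
    assert ind.repertoire[ind.find(5)].n == 2


def test_suboptimal_accounting_only_for_repertoire_choices():
    ind = _individual_with([0.9, 0.5], [1, 1])
    record_expression(ind, 1, benefit=0.5, best_available=0.9,
                      from_repertoire=True)
    assert ind.suboptimal == 1
    assert ind.suboptimal_gap == pytest.approx(0.4)
    record_expression(ind, 1, benefit=0.5, best_available=0.9,
                      from_repertoire=False)
    assert ind.suboptimal == 1
    record_expression(ind, 0, benefit=0.9, best_available=0.9,
                      from_repertoire=True)
    assert ind.suboptimal == 1


def test_expressing_an_unknown_variant_is_an_internal_error():
    ind = _individual_with([0.5], [1])
    with pytest.raises(KeyError):
        record_expression(ind, 77)


# ---------------------------------------------------------------------------
# forgetting
# ---------------------------------------------------------------------------

def test_size_one_repertoire_never_forgets(rng):
    ind = _individual_with([0.5], [4])
    ind.phi = 1.0
    assert forget_step(ind, 0, rng) == -1
    assert ind.repertoire_size == 1


def test_forgetting_weights_hand_example():
    # candidates with counts (1, 3): A = 4, weights (4-1, 4-3) -> (0.75, 0.25)
    probs = forgetting_probs(np.array([1, 3, 10]), protected=2)
    assert probs == pytest.approx([0.75, 0.25, 0.0])


def test_forgetting_sampler_matches_weights(rng):
    ind = _individual_with([0.5, 0.4, 0.9], [1, 3, 10])
    ind.phi = 1.0
    removed = []
    for _ in range(100_000):
        clone = _individual_with([0.5, 0.4, 0.9], [1, 3, 10])
        clone.phi = 1.0
        removed.append(forget_step(clone, 2, rng))
    frac_a = np.mean([r == 0 for r in removed])
    assert frac_a == pytest.approx(0.75, abs=0.01)
    assert 2 not in removed  # the expressed variant is protected


def test_two_entry_repertoire_forgets_the_other_with_certainty(rng):
    # single eligible candidate: the 0/0 weight degenerates to certainty
    ind = _individual_with([0.5, 0.3], [5, 5])
    ind.phi = 1.0
    assert forget_step(ind, 0, rng) == 1
    assert ind.repertoire_size == 1


def test_forget_event_only_with_probability_phi(rng):
    hits = 0
    for _ in range(20_000):
        ind = _individual_with([0.5, 0.3], [1, 1])
        ind.phi = 0.3
        if forget_step(ind, 0, rng) >= 0:
            hits += 1
    assert hits / 20_000 == pytest.approx(0.3, abs=0.015)


def test_forced_forget_draw_covers_all_entries_when_unprotected(rng):
    counts = np.array([2, 2, 2])
    seen = {draw_forget_index(counts, -1, u)
            for u in np.linspace(0.01, 0.99, 50)}
    assert seen == {0, 1, 2}


def test_fixture_repertoire_is_deterministic():
    a = make_fixture("repertoire", 1)
    b = make_fixture("repertoire", 1)
    assert [(e.variant.id, e.variant.a1, e.n) for e in a] == \
           [(e.variant.id, e.variant.a1, e.n) for e in b]
    assert len(a) == 4


def test_object_level_choice_uses_current_environment(rng):
    ind = _individual_with([0.0, 1.0], [1, 1])
    # env 1: value 1.0 at index 1 dominates proportionally
    picks = {choose_variant(ind, 1, rng) for _ in range(50)}
    assert picks == {1}
    # env 2: both zero -> uniform over entries
    picks = {choose_variant(ind, 2, rng) for _ in range(200)}
    assert picks == {0, 1}
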