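import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leatherback_pva.cmr_multievent import (
    N_STATES,
    EncounterHistory,
    MultiEventSpec,
    batch_loglik,
    covariate_model,
    fit_mle,
    history_loglik,
    qaicc,
    simulate_histories,
    transition_matrix,
)

TRUTH = dict(s=0.788, tr=0.239, b1=0.005, b2=0.272, b3=0.54, b4=0.681, p=0.887)

prob = st.floats(0.02, 0.98)


def enumeration_loglik(params, h):
    """Sum over every hidden state path (independent recursive oracle;
    zero-probability branches are pruned but all paths are visited)."""
    T, fc = len(h.events), h.first
    b = [params["b1"], params["b2"], params["b3"], params["b4"]]
    Ms = [
        transition_matrix(params["s"], params["tr"], b, first=(t == fc + 1))
        for t in range(fc + 1, T)
    ]

    def walk(step, state, pr):
        if step == len(Ms):
            return pr
        total = 0.0
        y = h.events[fc + 1 + step]
        for nxt in range(N_STATES):
            q = Ms[step][state, nxt]
            if q == 0.0:
                continue
            e = (params["p"] if nxt == 0 else 0.0) if y == 1 else (
                (1 - params["p"]) if nxt == 0 else 1.0
            )
            if e:
                total += walk(step + 1, nxt, pr * q * e)
        return total

    total = walk(0, 0, 1.0)
    return np.log(total) if total > 0 else -np.inf


@given(s=prob, tr=prob, b1=prob, b2=prob, b3=prob, b4=prob, p=prob)
@settings(max_examples=25, deadline=None)
def test_forward_recursion_equals_path_enumeration(s, tr, b1, b2, b3, b4, p):
    params = dict(s=s, tr=tr, b1=b1, b2=b2, b3=b3, b4=b4, p=p)
    spec = MultiEventSpec()
    for ev in itertools.product([0, 1], repeat=4):
        h = EncounterHistory("x", (1,) + ev, 0)
        a = history_loglik(params, spec, h)
        b_ = enumeration_loglik(params, h)
        assert abs(a - b_) < 1e-12 or (np.isinf(a) and np.isinf(b_))


@given(s=prob, tr=prob, b1=prob, b2=prob, b3=prob, b4=prob, p=prob)
@settings(max_examples=25, deadline=None)
def test_history_probabilities_normalise(s, tr, b1, b2, b3, b4, p):
    params = dict(s=s, tr=tr, b1=b1, b2=b2, b3=b3, b4=b4, p=p)
    spec = MultiEventSpec()
    total = sum(
        np.exp(history_loglik(params, spec, EncounterHistory("x", (1,) + ev, 0)))
        for ev in itertools.product([0, 1], repeat=4)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


@given(s=prob, tr=prob, b1=prob, b2=prob, b3=prob, b4=prob)
@settings(max_examples=50, deadline=None)
def test_transition_matrices_are_row_stochastic(s, tr, b1, b2, b3, b4):
    for first in (True, False):
        M = transition_matrix(s, tr, [b1, b2, b3, b4], first)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert M[N_STATES - 1, N_STATES - 1] == 1.0  # dead is absorbing


def test_single_history_closed_form():
    # seen, then not seen: transient, died, or skipped breeding (p = 1)
    s, b, tau = 0.7, 0.3, 0.2
    params = dict(s=s, tr=tau, b1=b, b2=0.3, b3=0.3, b4=0.3, p=1.0)
    h = EncounterHistory("x", (1, 0), 0)
    expected = tau + (1 - tau) * (1 - s) + (1 - tau) * s * (1 - b)
    assert history_loglik(params, MultiEventSpec(), h) == pytest.approx(np.log(expected))
    # seen twice in a row with certain survival/breeding/detection
    sure = dict(s=1.0, tr=0.0, b1=1.0, b2=1.0, b3=1.0, b4=1.0, p=1.0)
    assert history_loglik(sure, MultiEventSpec(), EncounterHistory("x", (1, 1), 0)) == 0.0


def test_likelihood_invariant_to_history_order_and_ids(rng):
    hs = simulate_histories(TRUTH, 300, 12, rng)
    spec = MultiEventSpec()
    ll = batch_loglik(TRUTH, spec, hs)
    shuffled = [EncounterHistory(f"re{i}", h.events, h.first) for i, h in enumerate(hs)]
    rng.shuffle(shuffled)
    assert batch_loglik(TRUTH, spec, shuffled) == pytest.approx(ll, abs=1e-8)


def test_simulation_degenerate_cases(rng):
    sure = dict(s=1.0, tr=0.0, b1=1.0, b2=1.0, b3=1.0, b4=1.0, p=1.0)
    for h in simulate_histories(sure, 50, 8, rng):
        assert all(e == 1 for e in h.events[h.first:])
    transient = dict(TRUTH, tr=1.0)
    for h in simulate_histories(transient, 50, 8, rng):
        assert sum(h.events) == 1


def test_simulated_return_intervals_follow_breeding_propensities():
    # perfect detection, no mortality: observed gaps directly reflect B2:B3:B4
    params = dict(s=1.0, tr=0.0, b1=0.0, b2=0.272, b3=0.54, b4=0.681, p=1.0)
    hs = simulate_histories(params, 2000, 40, np.random.default_rng(8))
    gaps = []
    for h in hs:
        seen = [t for t, e in enumerate(h.events) if e == 1]
        # only gaps starting early enough that censoring is negligible
        gaps.extend(b - a for a, b in zip(seen, seen[1:]) if a < 20)
    gaps = np.array(gaps)
    p2 = (gaps == 2).mean()
    p3 = (gaps == 3).mean()
    exp2 = 0.272
    exp3 = (1 - 0.272) * 0.54
    assert p2 == pytest.approx(exp2, abs=0.02)
    assert p3 == pytest.approx(exp3, abs=0.02)


def test_mle_recovers_simulated_parameters():
    hs = simulate_histories(TRUTH, 3000, 22, np.random.default_rng(2))
    fit = fit_mle(hs, MultiEventSpec(), n_starts=2, gtol=1e-7, seed=0)
    assert fit.converged
    for k in ("s", "tr", "b2", "b3", "b4", "p"):
        lo, hi = fit.ci[k]
        assert lo <= TRUTH[k] <= hi, (k, fit.estimates[k], (lo, hi))
    assert np.isfinite(fit.qaicc)


def test_boundary_estimates_are_flagged(rng):
    sure = dict(s=1.0, tr=0.0, b1=1.0, b2=1.0, b3=1.0, b4=1.0, p=1.0)
    hs = simulate_histories(sure, 80, 8, rng)
    fit = fit_mle(hs, MultiEventSpec(), n_starts=1, gtol=1e-6)
    assert fit.estimates["s"] > 0.99
    assert fit.boundary  # at least one parameter pinned to the boundary


def test_qaicc_formula():
    assert qaicc(-100.0, 3, 50, 2.0) == pytest.approx(100 + 6 + 24 / 46)
    assert qaicc(-100.0, 3, 50, 1.0) == pytest.approx(200 + 6 + 24 / 46)  # AICc
    assert qaicc(-100.0, 3, 50, 3.0) < qaicc(-100.0, 3, 50, 2.0)
    with pytest.raises(ValueError):
        qaicc(-100.0, 10, 11, 1.5)
    with pytest.raises(ValueError):
        qaicc(-100.0, 3, 50, 0.5)


def test_covariate_model_basics():
    assert np.allclose(covariate_model([0.3, 0.0], [1, 2, 3]), 1 / (1 + np.exp(-0.3)))
    assert covariate_model([0.0, 1.0], [0.0])[0] == pytest.approx(0.5)


def test_covariate_effect_recovery():
    rng = np.random.default_rng(4)
    x = tuple(rng.normal(0, 1, 14))
    beta = (1.3, -0.6)  # survival on the logit scale, driven by the index
    spec = MultiEventSpec(covariate_param="s", covariate=x)
    params = dict(TRUTH, s_beta0=beta[0], s_beta1=beta[1])
    hs = simulate_histories(params, 3000, 15, rng, spec=spec)
    fit = fit_mle(hs, spec, n_starts=1, gtol=1e-6, seed=0)
    est, se = fit.estimates["s_beta1"], fit.se["s_beta1"]
    assert abs(est - beta[1]) < 2 * se


def test_trap_dependence_detection_split():
    rng = np.random.default_rng(6)
    params = dict(TRUTH)
    params.pop("p")
    params.update(p_aware=0.95, p_unaware=0.6)
    spec = MultiEventSpec(trap_dependence=True)
    hs = simulate_histories(params, 2500, 18, rng, spec=spec)
    fit = fit_mle(hs, spec, n_starts=1, gtol=1e-6, seed=0)
    assert fit.estimates["p_aware"] > fit.estimates["p_unaware"]
    lo, hi = fit.ci["p_aware"]
    assert lo <= 0.95 <= hi


def test_history_validation():
    with pytest.raises(ValueError):
        EncounterHistory("x", (0, 1, 0), 0)  # first event must be a detection
    with pytest.raises(ValueError):
        EncounterHistory("x", (1, 2), 0)
    with pytest.raises(ValueError):
        EncounterHistory("x", (1, 0, 1), 1)  # detection before first capture
    with pytest.raises(ValueError):
        fit_mle([], MultiEventSpec())
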