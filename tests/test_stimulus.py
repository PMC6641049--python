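"""Current-stimulus design: mode deletion, selective suppression, prediction."""

import numpy as np
import pytest

from v1circuit.modes import modes
from v1circuit.stimulus import (current_to_perturbation, design_mode_deletion,
                                design_suppression, intensity_sweep,
                                perturbation_to_current, predict_response)


def test_current_perturbation_round_trip(toy_lin):
    rng = np.random.default_rng(2)
    I = rng.normal(scale=10.0, size=toy_lin.W.shape[0])  # pA
    dg = current_to_perturbation(toy_lin, I)
    assert np.allclose(current_to_perturbation(toy_lin, 2 * I), 2 * dg)
    assert np.allclose(perturbation_to_current(toy_lin, dg), I, rtol=1e-10)
    assert np.allclose(current_to_perturbation(toy_lin, np.zeros_like(I)), 0.0)


def _real_mode_index(ms):
    real = [k for k in range(8) if abs(ms.lambdas[k].imag) < 1e-12]
    # prefer the real mode with the largest coefficient magnitude
    return max(real, key=lambda k: abs(ms.xi[k]))


def test_mode_deletion_zeroes_exactly_one_coefficient(toy_lin):
    _, db_b, _ = toy_lin.split_input(theta=0.0)
    ms = modes(toy_lin, db_b)
    k = _real_mode_index(ms)
    stim = design_mode_deletion(toy_lin, ms, k)
    combined = toy_lin.population_means(db_b + stim.dgamma)
    xi_new = np.linalg.solve(ms.Psi, combined.astype(complex))
    assert abs(xi_new[k]) < 1e-10 * max(abs(ms.xi[k]), 1e-30)
    others = np.delete(np.abs(xi_new - ms.xi), k)
    assert others.max() < 1e-10


def test_suppression_changes_only_target_population(toy_lin):
    resp0 = predict_response(toy_lin, None, theta=0.0)
    pm0 = toy_lin.population_means(resp0.rates_raw)
    target = -resp0.rates_raw[toy_lin.pop_of == 4]  # silence L5e
    stim = design_suppression(toy_lin, "L5e", target)
    resp1 = predict_response(toy_lin, stim, intensity=1.0, theta=0.0)
    pm1 = toy_lin.population_means(resp1.rates_raw)
    non_target = np.arange(8) != 4
    assert np.max(np.abs(pm1 - pm0)[non_target]) < 1e-6 * np.abs(pm0).max()
    assert abs(pm1[4]) < 1e-6 * pm0[4]
    # zero target -> zero stimulus
    z = design_suppression(toy_lin, "L5e", np.zeros(np.count_nonzero(~non_target)))
    assert np.allclose(z.dgamma, 0.0) and np.allclose(z.I, 0.0)


def test_response_affine_in_intensity(toy_lin):
    _, db_b, _ = toy_lin.split_input(theta=0.0)
    ms = modes(toy_lin, db_b)
    stim = design_mode_deletion(toy_lin, ms, _real_mode_index(ms))
    r0 = predict_response(toy_lin, stim, intensity=0.0, theta=0.0)
    r1 = predict_response(toy_lin, stim, intensity=1.0, theta=0.0)
    r2 = predict_response(toy_lin, stim, intensity=2.0, theta=0.0)
    assert np.allclose(r2.rates_raw - r0.rates_raw,
                       2 * (r1.rates_raw - r0.rates_raw), atol=1e-8)
    base = predict_response(toy_lin, None, theta=0.0)
    assert np.allclose(r0.rates_raw, base.rates_raw)


def test_rectification_flagged_at_strong_suppression(toy_lin):
    resp0 = predict_response(toy_lin, None, theta=0.0)
    target = -resp0.rates_raw[toy_lin.pop_of == 4]
    stim = design_suppression(toy_lin, "L5e", target)
    strong = predict_response(toy_lin, stim, intensity=3.0, theta=0.0)
    assert strong.rectified
    assert (strong.rates >= 0).all()
    assert strong.rates_raw.min() < 0


def test_intensity_sweep_shape(toy_lin):
    resp0 = predict_response(toy_lin, None, theta=0.0)
    target = -resp0.rates_raw[toy_lin.pop_of == 4]
    stim = design_suppression(toy_lin, "L5e", target)
    xs, table = intensity_sweep(toy_lin, stim, [0.0, 0.5, 1.0], theta=0.0)
    assert table.shape == (3, 8)
    pm0 = toy_lin.population_means(resp0.rates_raw)
    assert np.allclose(table[0], pm0)
    # linear interpolation between endpoints for the target population
    assert table[1, 4] == pytest.approx((table[0, 4] + table[2, 4]) / 2)


def test_designed_currents_move_spiking_rates_in_predicted_directions(real01,
                                                                      lin01):
    """End-to-end cross-model check: applying the mode-deletion currents in
    the spiking simulator shifts every population's mean rate with the sign
    the linear model predicts (common input noise across the two runs)."""
    from v1circuit.spiking import SpikingModel

    _, db_b, _ = lin01.split_input(theta=0.0)
    ms = modes(lin01, db_b)
    k = _real_mode_index(ms)
    stim = design_mode_deletion(lin01, ms, k)
    predicted = lin01.population_means(lin01.solve_direct(stim.dgamma))

    sim = SpikingModel(real01)
    T = 2.0
    base = sim.simulate("stimulated", theta=0.0, T=T, input_seed=11)
    pert = sim.simulate("stimulated", theta=0.0, T=T, input_seed=11,
                        stim_mu=stim.stim_mu(lin01, intensity=1.0))
    pop_of = real01.pop_of
    rb, rp = base.rates(), pert.rates()
    for p in range(8):
        sel = pop_of == p
        change = rp[sel].mean() - rb[sel].mean()
        se = np.sqrt((rb[sel].sum() + rp[sel].sum()) / T) / np.count_nonzero(sel)
        if abs(predicted[p]) > 3 * se:
            assert np.sign(change) == np.sign(predicted[p]), (p, change,
                                                              predicted[p])
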