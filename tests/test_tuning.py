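"""Orientation-selectivity measures and spike-train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1circuit.spiking import SpikeData
from v1circuit.tuning import (evoked_rates, input_current, osi_star,
                              percentile_table, spike_statistics, summarize,
                              tuning_curves_from_rates)


def test_osi_of_perfect_cosine_is_half_modulation(cosine_grid):
    angles, make = cosine_grid
    s = summarize(make(f0=7.0, m=0.3, phi=75.0), angles)
    assert s["OSI"][0] == pytest.approx(0.15, abs=1e-12)
    assert s["PO"][0] == pytest.approx(75.0, abs=1e-9)
    assert s["F0"][0] == pytest.approx(7.0)
    assert s["F1"][0] == pytest.approx(7.0 * 0.15)
    assert s["OSI"][0] == pytest.approx(s["F1"][0] / s["F0"][0])


def test_osi_degenerate_curves(cosine_grid):
    angles, _ = cosine_grid
    flat = summarize(np.full(12, 10.0), angles)
    assert flat["OSI"][0] == pytest.approx(0.0, abs=1e-14)
    single = np.zeros(12)
    single[4] = 5.0
    s = summarize(single, angles)
    assert s["OSI"][0] == pytest.approx(1.0)
    assert s["PO"][0] == pytest.approx(angles[4])
    zero = summarize(np.zeros(12), angles)
    assert not zero["defined"][0] and zero["n_undefined"] == 1
    assert np.isnan(zero["OSI"][0])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(0.1, 50), offset=st.floats(0.1, 40),
       m=st.floats(0.05, 0.95), phi=st.floats(0, 179))
def test_osi_invariances(scale, offset, m, phi):
    """OSI is scale-invariant and decreases under an additive offset."""
    angles = np.arange(0.0, 180.0, 15.0)
    curve = 5.0 * (1.0 + m * np.cos(2 * np.radians(angles - phi)))
    base = summarize(curve, angles)["OSI"][0]
    assert summarize(scale * curve, angles)["OSI"][0] == pytest.approx(base)
    assert summarize(curve + offset, angles)["OSI"][0] < base


def test_osi_star_cosine_and_ordering(cosine_grid):
    angles, make = cosine_grid
    for m in (0.1, 0.3, 0.6):
        curve = make(m=m, phi=20.0)
        assert osi_star(curve, angles)[0] == pytest.approx(m, abs=1e-10)
        assert osi_star(curve, angles)[0] > summarize(curve, angles)["OSI"][0]
    assert osi_star(np.full(12, 4.0), angles)[0] == pytest.approx(0.0, abs=1e-12)


def test_input_current_units():
    # J = 0.15 mV, C_m = 250 pF, 10 spikes/s -> 0.375 pA
    assert input_current(250.0, 0.15, 10.0) == pytest.approx(0.375)
    assert input_current(250.0, 0.15, 0.0) == 0.0


def test_tuning_vector_magnitude_equals_input_current_f1(toy_real):
    """|TV| equals the first Fourier component of the input-current tuning."""
    from v1circuit.tuning import tuning_vectors
    spec = toy_real.spec
    angles = np.arange(0.0, 180.0, 15.0)
    rng = np.random.default_rng(0)
    n = toy_real.n_neurons
    po = rng.uniform(0, 180, n)
    m = 0.4
    f0 = rng.uniform(2, 10, n)
    curves = f0[:, None] * (1 + m * np.cos(2 * np.radians(angles[None, :] - po[:, None])))
    s = summarize(curves, angles)
    tv = tuning_vectors(toy_real, f0, s["OSV"])
    # oracle: F1 of the summed input current per (neuron, source population)
    pop_of = toy_real.pop_of
    k = 123  # one postsynaptic neuron
    syn = np.flatnonzero(toy_real.targets == k)
    for t in range(8):
        sel = syn[pop_of[toy_real.sources[syn]] == t]
        cur = (spec.neuron.C_m * 1e-3
               * toy_real.weights[sel][:, None] * curves[toy_real.sources[sel], :])
        # F1 of the summed input current = |first complex Fourier coefficient|
        f1 = abs((cur.sum(axis=0) @ np.exp(2j * np.radians(angles))) / angles.size)
        assert abs(tv[k, t]) == pytest.approx(f1, rel=1e-9)


def _spike_data(trains, T=10.0, warmup=200.0):
    ids = np.concatenate([np.full(len(t), i, dtype=np.int32)
                          for i, t in enumerate(trains)])
    times = np.concatenate(trains)
    order = np.argsort(times, kind="stable")
    return SpikeData(ids=ids[order], times=times[order], n_neurons=len(trains),
                     condition="spontaneous", theta=None, T=T, warmup=warmup,
                     structure_seed=0, input_seed=0)


def test_spike_statistics_regular_poisson_and_identical():
    rng = np.random.default_rng(1)
    T = 50.0
    regular = np.arange(300.0, 200.0 + T * 1000.0, 100.0)
    poisson = 200.0 + np.sort(rng.uniform(0, T * 1000.0, size=int(8 * T)))
    sp = _spike_data([regular, poisson, poisson.copy()], T=T)
    st_ = spike_statistics(sp, n_pairs=300, seed=0)
    assert st_["cv"][0] == pytest.approx(0.0, abs=1e-12)
    assert st_["cv"][1] == pytest.approx(1.0, abs=0.12)
    # duplicated trains are perfectly correlated
    edges = np.arange(200.0, 200.0 + T * 1000.0 + 10.0, 10.0)
    c1 = np.histogram(poisson, bins=edges)[0]
    assert np.corrcoef(c1, c1)[0, 1] == pytest.approx(1.0)


def test_spike_statistics_excludes_sparse_trains():
    sp = _spike_data([np.array([300.0, 400.0]), np.array([])], T=1.0)
    st_ = spike_statistics(sp, n_pairs=10, seed=0)
    assert st_["n_cv_excluded"] == 2
    assert np.isnan(st_["cv_mean"])


def test_evoked_rates_and_percentiles(cosine_grid):
    angles, make = cosine_grid
    curves = np.stack([make(f0=10.0, m=0.3, phi=0.0), np.full(12, 5.0)])
    ev = evoked_rates(curves)
    assert ev[0] == pytest.approx(13.0)   # F0 * (1 + m) on-grid peak
    assert ev[1] == pytest.approx(5.0)
    assert (ev >= curves.mean(axis=1) - 1e-12).all()
    table = percentile_table(np.arange(16.0), np.repeat(np.arange(8), 2))
    assert table.shape == (8, 5)
    assert table[0, 2] == pytest.approx(0.5)


def test_tuning_curves_from_rates_shape():
    angles = np.arange(0.0, 180.0, 15.0)
    vecs = [np.full(5, float(i)) for i in range(12)]
    a, r = tuning_curves_from_rates(vecs, angles)
    assert r.shape == (5, 12)
    with pytest.raises(ValueError):
        tuning_curves_from_rates(vecs[:4], angles)
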