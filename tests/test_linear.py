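"""Linearized model: Jacobian correctness, decomposition, solvers."""

import numpy as np
import pytest

import v1circuit as v
from v1circuit.linear import LinearResponseModel, r_squared
from v1circuit.meanfield import RateModel


def test_w_equals_finite_difference_jacobian(toy_real, toy_op, toy_lin):
    """The decisive oracle: analytic W against the FD Jacobian of Model B."""
    rm = RateModel(toy_real)
    n = toy_real.n_neurons
    F0 = rm.transfer(toy_op.nu, condition="operating")
    h = 1e-4
    Wd = toy_lin.W.toarray()
    cols = np.arange(n)
    Wfd = np.empty((n, n))
    for j in cols:
        nu = toy_op.nu.copy()
        nu[j] += h
        Wfd[:, j] = (rm.transfer(nu, condition="operating") - F0) / h
    mask = Wd != 0
    rel = np.abs(Wfd[mask] - Wd[mask]) / np.abs(Wd[mask])
    assert rel.max() < 1e-4
    # FD Jacobian vanishes off the synaptic pattern
    off = (~mask) & ~np.eye(n, dtype=bool)
    assert np.abs(Wfd[off]).max() < 1e-10


def test_b_zero_off_thalamic_and_fd(toy_real, toy_op, toy_lin):
    """B is diagonal, zero for populations without thalamic input, and
    matches a finite difference in the compound thalamic rate."""
    pop_of = toy_real.pop_of
    has_th = toy_real.spec.connectivity.thalamic[pop_of] > 0
    assert (toy_lin.B[~has_th] == 0).all()
    assert (toy_lin.B[has_th] > 0).all()
    rm = RateModel(toy_real)
    h = 1e-3  # bump the thalamic rate of every neuron via nu_th_scale at theta-free condition
    F0 = rm.transfer(toy_op.nu, condition="spontaneous", nu_th_scale=0.0)
    F1 = rm.transfer(toy_op.nu, condition="spontaneous", nu_th_scale=h)
    nu_th = toy_real.spec.connectivity.thalamic[pop_of] \
        * toy_real.spec.protocol.nu_bg
    fd = np.zeros_like(toy_lin.B)
    fd[has_th] = (F1 - F0)[has_th] / (h * nu_th[has_th])
    assert np.allclose(fd[has_th], toy_lin.B[has_th], rtol=1e-3)


def test_block_means_of_s_vanish(toy_lin):
    """Q holds the realized block means, so S = W - Q has zero block sums."""
    n = toy_lin.W.shape[0]
    pop_of = toy_lin.pop_of
    sizes = toy_lin.sizes
    Wd = toy_lin.W.toarray()
    for p in range(8):
        for t in range(8):
            blk = Wd[np.ix_(pop_of == p, pop_of == t)]
            assert blk.mean() == pytest.approx(toy_lin.q_blocks[p, t], abs=1e-15)


def test_solve_direct_against_dense(toy_lin):
    rng = np.random.default_rng(4)
    b = rng.normal(size=toy_lin.W.shape[0])
    x = toy_lin.solve_direct(b)
    dense = np.linalg.solve(np.eye(b.size) - toy_lin.W.toarray(), b)
    assert np.allclose(x, dense, rtol=1e-8, atol=1e-10)
    assert np.allclose(toy_lin.solve_direct(np.zeros_like(b)), 0.0)


def test_split_input_structure(toy_lin):
    db, db_b, db_m = toy_lin.split_input(theta=45.0)
    assert np.allclose(db, db_b + db_m)
    assert np.max(np.abs(toy_lin.population_means(db_m))) < 1e-12
    pop_of = toy_lin.pop_of
    has_th = toy_lin.realization.spec.connectivity.thalamic[pop_of] > 0
    assert np.allclose(db[~has_th], 0.0)
    assert (np.abs(db[has_th]) > 0).all()
    # spontaneous condition: no orientation modulation beyond sensitivity scatter
    db_s, db_sb, db_sm = toy_lin.split_input(condition="spontaneous")
    assert np.abs(db_sm).max() < 0.2 * np.abs(db_sb).max()


def test_decomposed_solution_properties(toy_lin):
    db, db_b, db_m = toy_lin.split_input(theta=0.0)
    dnu_b, dnu_m = toy_lin.solve_decomposed(db_b, db_m)
    # baseline is population-wise constant by the symmetry argument
    flat = toy_lin.expand(toy_lin.population_means(dnu_b))
    assert np.allclose(dnu_b, flat, atol=1e-12)
    direct = toy_lin.solve_direct(db)
    assert r_squared(direct, dnu_b + dnu_m) > 0.98
    qm, sm = toy_lin.interference(dnu_b, dnu_m)
    assert qm < np.abs(db).mean() and sm < np.abs(db).mean()


def test_interference_trivial_cases(toy_lin):
    assert toy_lin.interference(np.zeros(toy_lin.W.shape[0]),
                                np.zeros(toy_lin.W.shape[0])) == (0.0, 0.0)
    # Q applied to a zero-block-mean vector vanishes
    rng = np.random.default_rng(1)
    x = rng.normal(size=toy_lin.W.shape[0])
    x -= toy_lin.expand(toy_lin.population_means(x))
    assert np.abs(toy_lin.apply_Q(x)).max() < 1e-12


def test_r_squared_definition():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert r_squared(x, x) == 1.0
    assert r_squared(x, np.full_like(x, x.mean())) == 0.0
    rng = np.random.default_rng(0)
    ref = rng.normal(size=500)
    perm = rng.permutation(ref)
    # permutation null: E[SS_res] = 2 * SS_tot, so R^2 concentrates near -1
    assert r_squared(ref, perm) == pytest.approx(-1.0, abs=0.3)
    with pytest.raises(ValueError):
        r_squared(np.ones(3), np.ones(3))


def test_operating_point_ignores_thalamic_column(toy_real, toy_op):
    """Zeroing the thalamic in-degrees changes nothing at the operating point."""
    import dataclasses
    from v1circuit.params import ConnectivityTable
    spec = toy_real.spec
    K = spec.connectivity.matrix.copy()
    K[:, 9] = 0
    spec2 = dataclasses.replace(
        spec, connectivity=ConnectivityTable(K=tuple(tuple(int(x) for x in r)
                                                     for r in K)))
    real2 = dataclasses.replace(toy_real, spec=spec2, _cache={})
    op2 = v.operating_point(real2)
    assert np.allclose(op2.nu, toy_op.nu, atol=1e-5)
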