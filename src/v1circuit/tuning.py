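"""Tuning-curve and spike-train analysis.

Orientation selectivity is quantified by circular statistics with angle
doubling: the orientation selectivity vector of a tuning curve nu(theta) is

    OSV = sum_theta nu(theta) e^{i 2 theta} / sum_theta nu(theta),

its magnitude is the OSI (equal to F1/F0 with F1 the magnitude of the first
complex Fourier coefficient of the curve) and half its argument is the
preferred orientation.  A perfect cosine curve with modulation m gives
OSI = m/2.  The alternative fit-based index OSI* compares the fitted rates
at the preferred and orthogonal orientation and equals m for the same curve.
"""

from __future__ import annotations

import numpy as np

from .params import N_POP
from .spiking import SpikeData


def tuning_curves_from_spikes(runs: list[SpikeData]) -> tuple[np.ndarray, np.ndarray]:
    """(angles, rates[N, n_angles]) from stimulated runs (spontaneous skipped).

    Rates are spike counts over the analysis window divided by its duration;
    spontaneous rates are not subtracted.
    """
    stim = [r for r in runs if r.condition == "stimulated"]
    if not stim:
        raise ValueError("no stimulated runs supplied")
    order = np.argsort([r.theta for r in stim])
    angles = np.array([stim[i].theta for i in order], dtype=float)
    rates = np.stack([stim[i].rates() for i in order], axis=1)
    return angles, rates


def tuning_curves_from_rates(rate_vectors, angles) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-angle rate solutions (Models B/C) into tuning curves."""
    angles = np.asarray(angles, dtype=float)
    rates = np.stack([np.asarray(v, dtype=float) for v in rate_vectors], axis=1)
    if rates.shape[1] != angles.size:
        raise ValueError("one rate vector per angle required")
    return angles, rates


def summarize(rates, angles) -> dict:
    """Vectorized tuning summary over neurons.

    Returns arrays ``OSV`` (complex), ``OSI``, ``PO`` (degrees in [0, 180)),
    ``F0``, ``F1`` and a boolean ``defined`` mask (False for all-zero
    curves, whose OSV is undefined; such neurons are excluded from
    population statistics and counted in ``n_undefined``).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    angles = np.asarray(angles, dtype=float)
    phase = np.exp(2j * np.radians(angles))
    total = rates.sum(axis=1)
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        osv = (rates @ phase) / total
    osv[~defined] = np.nan
    f0 = rates.mean(axis=1)
    f1 = np.abs(rates @ phase) / angles.size
    po = np.mod(np.degrees(np.angle(osv)) / 2.0, 180.0)
    return {"OSV": osv, "OSI": np.abs(osv), "PO": po, "F0": f0, "F1": f1,
            "defined": defined, "n_undefined": int(np.count_nonzero(~defined))}


def osi_star(rates, angles) -> np.ndarray:
    """Cosine-fit selectivity index (max-min)/(max+min) of the fitted curve.

    Fits a + b cos 2(theta - phi) per neuron in the linear cos/sin basis
    (closed form on the uniform grid); returns NaN where the fitted mean is
    not positive.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    angles = np.asarray(angles, dtype=float)
    x = np.radians(angles)
    basis = np.column_stack([np.ones_like(x), np.cos(2 * x), np.sin(2 * x)])
    coef, *_ = np.linalg.lstsq(basis, rates.T, rcond=None)
    a, bc, bs = coef
    amp = np.hypot(bc, bs)
    out = np.full(rates.shape[0], np.nan)
    ok = a > 0
    out[ok] = amp[ok] / a[ok]
    return out


def input_current(C_m_pF: float, J_mV, nu_mean) -> np.ndarray:
    """Mean synaptic current of one connection, I = C_m J nu-bar, in pA."""
    return np.asarray(C_m_pF * np.asarray(J_mV) * np.asarray(nu_mean) * 1e-3)


def population_current_matrix(realization, nu_mean) -> np.ndarray:
    """Mean input current per projection, averaged over postsynaptic neurons.

    Returns an 8x10 matrix in pA: columns 0..7 recurrent source populations,
    column 8 background, column 9 thalamus (at the mean thalamic rate of the
    stimulated protocol).
    """
    spec = realization.spec
    p = spec.neuron
    pop_of = realization.pop_of
    nu_mean = np.asarray(nu_mean, dtype=float)
    out = np.zeros((N_POP, N_POP + 2))
    for t in range(N_POP):
        masked = np.where(pop_of == t, nu_mean, 0.0)
        contrib = realization.J_csr @ masked  # mV/s per postsynaptic neuron
        for post in range(N_POP):
            out[post, t] = contrib[pop_of == post].mean()
    out *= p.C_m * 1e-3  # -> pA
    k_bg = spec.connectivity.background.astype(float)
    k_th = spec.connectivity.thalamic.astype(float)
    out[:, N_POP] = p.C_m * p.J_e * k_bg * spec.protocol.nu_bg * 1e-3
    out[:, N_POP + 1] = p.C_m * p.J_e * k_th * spec.protocol.nu0_th * 1e-3
    return out


def tuning_vectors(realization, nu_mean, osv) -> np.ndarray:
    """Aggregate input tuning vector per (postsynaptic neuron, source pop).

    TV_ij = C_m J_ij nu-bar_j OSV_j summed over the presynaptic neurons of
    each source population; complex array of shape (N, 8) in pA.  Undefined
    presynaptic summaries (NaN OSV) contribute nothing.
    """
    spec = realization.spec
    pop_of = realization.pop_of
    w = np.asarray(nu_mean, dtype=float) * np.nan_to_num(np.asarray(osv))
    out = np.zeros((realization.n_neurons, N_POP), dtype=complex)
    for t in range(N_POP):
        masked = np.where(pop_of == t, w, 0.0)
        out[:, t] = realization.J_csr @ masked
    return out * spec.neuron.C_m * 1e-3


def spike_statistics(spikes: SpikeData, bin_ms: float = 10.0,
                     n_pairs: int = 1000, seed: int = 0,
                     min_spikes: int = 3) -> dict:
    """ISI irregularity and pairwise count correlations of one run.

    CV is the per-neuron SD/mean of inter-spike intervals (neurons with
    fewer than ``min_spikes`` spikes excluded and counted); correlations are
    Pearson coefficients of binned spike counts over a seeded random sample
    of neuron pairs (zero-variance pairs dropped).
    """
    trains = spikes.trains()
    cvs = np.full(spikes.n_neurons, np.nan)
    for i, t in enumerate(trains):
        if t.size >= min_spikes:
            isi = np.diff(t)
            m = isi.mean()
            if m > 0:
                cvs[i] = isi.std() / m
    valid = ~np.isnan(cvs)

    t0 = spikes.warmup
    t1 = spikes.warmup + spikes.T * 1000.0
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    rng = np.random.default_rng(seed)
    i_idx = rng.integers(0, spikes.n_neurons, size=n_pairs)
    j_idx = rng.integers(0, spikes.n_neurons, size=n_pairs)
    keep = i_idx != j_idx
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    needed = np.unique(np.concatenate([i_idx, j_idx]))
    counts = {i: np.histogram(trains[i], bins=edges)[0] for i in needed}
    corrs = []
    for a, b in zip(i_idx, j_idx):
        ca, cb = counts[a], counts[b]
        if ca.std() == 0 or cb.std() == 0:
            continue
        corrs.append(np.corrcoef(ca, cb)[0, 1])
    corrs = np.asarray(corrs)
    return {"cv": cvs, "cv_mean": float(np.nanmean(cvs)) if valid.any() else np.nan,
            "cv_sd": float(np.nanstd(cvs)) if valid.any() else np.nan,
            "n_cv_excluded": int(np.count_nonzero(~valid)),
            "corr_mean": float(corrs.mean()) if corrs.size else np.nan,
            "corr_sd": float(corrs.std()) if corrs.size else np.nan,
            "n_pairs_used": int(corrs.size)}


def evoked_rates(rates) -> np.ndarray:
    """Per-neuron evoked rate: the maximum over stimulus angles."""
    return np.atleast_2d(np.asarray(rates, dtype=float)).max(axis=1)


def percentile_table(values, pop_of: np.ndarray,
                     percentiles=(5, 25, 50, 75, 95)) -> np.ndarray:
    """Box-plot-ready per-population percentiles (NaN entries ignored)."""
    values = np.asarray(values, dtype=float)
    out = np.full((N_POP, len(percentiles)), np.nan)
    for p in range(N_POP):
        v = values[pop_of == p]
        v = v[~np.isnan(v)]
        if v.size:
            out[p] = np.percentile(v, percentiles)
    return out
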