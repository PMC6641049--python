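"""Model A: clock-driven LIF network simulation with delta synapses.

The membrane potential decays exponentially toward the reset potential
between grid steps (exact propagator; with instantaneous synapses this makes
the integration exact up to the rounding of spike and delivery times to the
dt grid).  External background and thalamic drive are compound Poisson
processes delivering jumps of J_e; constant drive (downscaling compensation,
injected currents) enters as a deterministic mean term.  Spikes reset the
membrane to V_r and clamp it there for the refractory period; input arriving
during the clamp is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import N_POP, POP_NAMES, ModelSpec, thalamic_rates


@dataclass
class SpikeData:
    """Spike events of one simulation run.

    ``ids``/``times`` are parallel arrays ordered by time; times are in ms
    and lie in (warmup, warmup + T*1000].
    """

    ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    condition: str
    theta: float | None
    T: float          # analyzed duration (s)
    warmup: float     # discarded interval (ms)
    structure_seed: int
    input_seed: int

    def counts(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Per-neuron mean rate over the analysis window (spikes/s)."""
        return self.counts() / self.T

    def trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays (ms)."""
        order = np.argsort(self.ids, kind="stable")
        ids = self.ids[order]
        times = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return [times[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]


@njit(cache=True)
def _run_lif(V, dt_over_tau, theta_thr, mu_eff, ext_lam, j_ext, ref_steps,
             n_steps, record_from, dt, indptr, syn_tgt, syn_w, syn_dsteps,
             D, seed):
    """Clock-driven LIF loop with event-resolved external input.

    V is measured relative to V_r (reset at 0).  Recurrent deliveries occur
    on the grid (delays are grid multiples); within each step the external
    Poisson jumps are placed at exact exponentially distributed times with
    analytic decay between them, so threshold crossings shorter than dt are
    not lost to time binning.  Spike times are reported at the end of the
    enclosing step; the refractory clamp covers tau_ref (input during the
    clamp is discarded).
    """
    np.random.seed(seed)
    n = V.size
    buf = np.zeros((D, n))
    ref = np.zeros(n, dtype=np.int64)
    cap = 1024
    sp_id = np.empty(cap, dtype=np.int32)
    sp_t = np.empty(cap, dtype=np.float64)
    ns = 0
    for t in range(n_steps):
        row = t % D
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = 0.0
                buf[row, i] = 0.0
                continue
            mu = mu_eff[i]
            v = V[i] + buf[row, i]  # recurrent jumps land on the grid point
            buf[row, i] = 0.0
            spiked = v >= theta_thr
            if not spiked:
                lam = ext_lam[i]
                pos = 0.0
                if lam > 0.0:
                    while True:
                        gap = np.random.exponential(1.0) / lam
                        if pos + gap >= 1.0:
                            break
                        pos += gap
                        v = mu + (v - mu) * np.exp(-gap * dt_over_tau)
                        v += j_ext
                        if v >= theta_thr:
                            spiked = True
                            break
                if not spiked:
                    v = mu + (v - mu) * np.exp(-(1.0 - pos) * dt_over_tau)
                    spiked = v >= theta_thr  # drift crossing (mu above threshold)
            if spiked:
                if t >= record_from:
                    if ns == cap:
                        cap *= 2
                        new_id = np.empty(cap, dtype=np.int32)
                        new_t = np.empty(cap, dtype=np.float64)
                        new_id[:ns] = sp_id
                        new_t[:ns] = sp_t
                        sp_id = new_id
                        sp_t = new_t
                    sp_id[ns] = i
                    sp_t[ns] = (t + 1) * dt
                    ns += 1
                v = 0.0
                ref[i] = ref_steps - 1  # clamp completes tau_ref after this step
                for s in range(indptr[i], indptr[i + 1]):
                    buf[(t + syn_dsteps[s]) % D, syn_tgt[s]] += syn_w[s]
            V[i] = v
        if not np.isfinite(V[0]):
            raise FloatingPointError("membrane potential diverged")
    return sp_id[:ns], sp_t[:ns]


class SpikingModel:
    """Spiking network simulator bound to one network realization."""

    def __init__(self, realization):
        self.realization = realization

    def simulate(self, condition: str = "stimulated", theta: float = 0.0,
                 T: float | None = None, input_seed: int = 0,
                 stim_mu=None, warmup: float | None = None) -> SpikeData:
        """Run one condition/angle for ``T`` seconds after the warm-up.

        ``stim_mu`` adds a constant per-neuron drive in mV (e.g. R*I for an
        injected current).  Initial membrane potentials are uniform between
        reset and threshold; the warm-up interval removes the residual
        transient and is excluded from the returned spikes.
        """
        real = self.realization
        spec = real.spec
        p = spec.neuron
        prot = spec.protocol
        if T is None:
            T = prot.T
        if warmup is None:
            warmup = prot.warmup
        n = real.n_neurons
        pop_of = real.pop_of

        nu_bg = spec.connectivity.background.astype(float)[pop_of] * prot.nu_bg
        nu_th = thalamic_rates(spec, real.theta_hat, theta, condition)
        ext_lam = (nu_bg + nu_th) * p.dt * 1e-3
        mu_eff = np.asarray(spec.dc_mean, dtype=float)[pop_of].copy()
        if stim_mu is not None:
            mu_eff = mu_eff + np.asarray(stim_mu, dtype=float)

        indptr, syn_tgt, syn_w, syn_dsteps = real.by_source()
        D = int(syn_dsteps.max()) + 1 if syn_dsteps.size else 2

        ss = np.random.SeedSequence(int(input_seed))
        init_ss, noise_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        V0 = rng.uniform(0.0, p.theta, size=n)
        kernel_seed = int(noise_ss.generate_state(1)[0] % (2**31))

        ref_steps = int(round(p.tau_ref / p.dt))
        n_warm = int(round(warmup / p.dt))
        n_steps = n_warm + int(round(T * 1000.0 / p.dt))

        ids, times = _run_lif(
            V0, p.dt / p.tau_m, p.theta, mu_eff, ext_lam, p.J_e, ref_steps,
            n_steps, n_warm, p.dt, indptr, syn_tgt, syn_w, syn_dsteps,
            D, kernel_seed)
        return SpikeData(ids=ids, times=times, n_neurons=n, condition=condition,
                         theta=theta if condition == "stimulated" else None,
                         T=T, warmup=warmup,
                         structure_seed=real.structure_seed,
                         input_seed=int(input_seed))

    def run_protocol(self, T: float | None = None, input_seed: int = 0,
                     angles=None, include_spontaneous: bool = True,
                     stim_mu=None) -> list[SpikeData]:
        """Simulate all stimulus angles plus the spontaneous condition.

        Per-angle input noise uses deterministic substreams of
        ``input_seed`` so that runs are reproducible and independent.
        """
        prot = self.realization.spec.protocol
        if angles is None:
            angles = prot.angles
        ss = np.random.SeedSequence(int(input_seed))
        subs = ss.spawn(len(angles) + 1)
        out = []
        for theta, sub in zip(angles, subs[:-1]):
            seed = int(sub.generate_state(1)[0] % (2**31))
            out.append(self.simulate("stimulated", theta=theta, T=T,
                                     input_seed=seed, stim_mu=stim_mu))
        if include_spontaneous:
            seed = int(subs[-1].generate_state(1)[0] % (2**31))
            out.append(self.simulate("spontaneous", T=T, input_seed=seed,
                                     stim_mu=stim_mu))
        return out


def population_rate_table(spikes: SpikeData, spec: ModelSpec):
    """Population-mean rates (spikes/s) of one run, as a dict by name."""
    rates = spikes.rates()
    pop_of = spec.populations.population_of()
    return {POP_NAMES[p]: float(rates[pop_of == p].mean()) for p in range(N_POP)}
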