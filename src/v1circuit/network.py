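"""Sampling a concrete synaptic realization from a model specification.

Connectivity is fixed in-degree: each neuron of population P receives exactly
K[P, T] synapses from distinct, uniformly drawn neurons of population T
(self-connections excluded, no multapses).  Efficacies are Gaussian with SD
equal to 10% of the mean, hard-clipped at zero toward the wrong sign (Dale's
principle); delays are Gaussian, clipped below at the simulation step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .params import N_POP, ModelSpec, assign_preferred_orientations


@njit(cache=True)
def _sample_partners(n_targets, n_pre, k, exclude_self, seed, out):
    """Uniform k-subsets of presynaptic partners per target (Floyd's method).

    O(k) per target.  With ``exclude_self`` the target's own index (equal to
    its position in the presynaptic population) is removed from the urn by
    sampling from n_pre - 1 and remapping around it.
    """
    np.random.seed(seed)
    marked = np.zeros(n_pre, dtype=np.uint8)
    chosen = np.empty(k, dtype=np.int64)
    for t in range(n_targets):
        m = n_pre - 1 if exclude_self else n_pre
        cnt = 0
        for j in range(m - k, m):
            r = np.random.randint(0, j + 1)
            pick = j if marked[r] else r
            marked[pick] = 1
            chosen[cnt] = pick
            cnt += 1
        for c in range(k):
            marked[chosen[c]] = 0
        for c in range(k):
            v = chosen[c]
            if exclude_self and v >= t:
                v += 1
            out[t, c] = v


def _available_memory_bytes() -> int:
    """Free physical memory, honoring container cgroup limits if present."""
    try:
        avail = os.sysconf("SC_AVPHYS_PAGES") * os.sysconf("SC_PAGE_SIZE")
    except (ValueError, OSError):  # pragma: no cover - non-POSIX fallback
        avail = 1 << 62
    for limit_file, usage_file in (
            ("/sys/fs/cgroup/memory.max", "/sys/fs/cgroup/memory.current"),
            ("/sys/fs/cgroup/memory/memory.limit_in_bytes",
             "/sys/fs/cgroup/memory/memory.usage_in_bytes")):
        try:
            with open(limit_file) as fh:
                raw = fh.read().strip()
            if raw.isdigit():
                limit = int(raw)
                used = 0
                try:
                    with open(usage_file) as fh:
                        used = int(fh.read().strip())
                except (OSError, ValueError):
                    pass
                avail = min(avail, max(limit - used, 0))
        except OSError:
            continue
    return avail


@dataclass
class NetworkRealization:
    """A sampled synapse table plus per-neuron input orientations.

    Synapses are stored as flat arrays grouped by (postsynaptic, presynaptic)
    population block; sparse matrices for the rate/linear models and the
    by-source adjacency for the spiking simulator are derived lazily and
    cached.
    """

    spec: ModelSpec
    sources: np.ndarray   # int32, synapse-indexed
    targets: np.ndarray   # int32, synapse-indexed
    weights: np.ndarray   # float64, mV
    delays: np.ndarray    # float64, ms
    theta_hat: np.ndarray  # float64, degrees, per neuron
    structure_seed: int
    orientation_seed: int
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_neurons(self) -> int:
        return self.spec.populations.total

    @property
    def n_synapses(self) -> int:
        return self.sources.size

    @property
    def pop_of(self) -> np.ndarray:
        if "pop_of" not in self._cache:
            self._cache["pop_of"] = self.spec.populations.population_of()
        return self._cache["pop_of"]

    def _csr(self, data) -> sp.csr_matrix:
        n = self.n_neurons
        m = sp.csr_matrix((data, (self.targets, self.sources)), shape=(n, n))
        return m

    @property
    def J_csr(self) -> sp.csr_matrix:
        """Sparse efficacy matrix, rows = targets (mV)."""
        if "J" not in self._cache:
            self._cache["J"] = self._csr(self.weights)
        return self._cache["J"]

    @property
    def J2_csr(self) -> sp.csr_matrix:
        """Sparse matrix of squared efficacies (mV^2), same pattern as J."""
        if "J2" not in self._cache:
            j2 = self.J_csr.copy()
            j2.data = j2.data**2
            self._cache["J2"] = j2
        return self._cache["J2"]

    def by_source(self):
        """(indptr, targets, weights, delay_steps) CSR-style by source neuron."""
        if "by_source" not in self._cache:
            order = np.argsort(self.sources, kind="stable")
            src = self.sources[order]
            indptr = np.searchsorted(src, np.arange(self.n_neurons + 1))
            dt = self.spec.neuron.dt
            dsteps = np.maximum(np.rint(self.delays / dt), 1).astype(np.int32)
            self._cache["by_source"] = (indptr.astype(np.int64),
                                        self.targets[order].copy(),
                                        self.weights[order].copy(),
                                        dsteps[order].copy())
        return self._cache["by_source"]


def build(spec: ModelSpec, structure_seed: int,
          orientation_seed: int | None = None) -> NetworkRealization:
    """Sample a network realization reproducibly from ``structure_seed``.

    For every target neuron and presynaptic population, exactly K[P, T]
    distinct sources are drawn uniformly (excluding the target itself).
    Preferred input orientations use an independent stream so that wiring and
    orientation assignment can be varied separately.
    """
    pops = spec.populations
    sizes = np.asarray(pops.sizes)
    offsets = pops.offsets
    K = spec.connectivity.recurrent
    if np.any(K.diagonal() > sizes - 1) or np.any(K > sizes[None, :]):
        raise ValueError("in-degree exceeds available distinct presynaptic partners")

    n_syn = int((sizes[:, None] * K).sum())
    need = n_syn * (4 + 4 + 8 + 8) * 2.5  # synapse arrays plus derived CSR copies
    avail = _available_memory_bytes()
    if need > avail:
        raise MemoryError(
            f"realization needs ~{need / 1e9:.1f} GB but only "
            f"{avail / 1e9:.1f} GB of physical memory is available; "
            "use a downscaled specification")

    ss = np.random.SeedSequence(structure_seed)
    rng = np.random.default_rng(ss)
    if orientation_seed is None:
        orientation_seed = int(np.random.SeedSequence(structure_seed).spawn(1)[0]
                               .generate_state(1)[0] % (2**31))
    theta_hat = assign_preferred_orientations(spec, orientation_seed)

    jm = spec.mean_weights()
    sd_frac = spec.neuron.J_sd_frac
    exc = pops.excitatory
    dt = spec.neuron.dt

    src_parts, tgt_parts, w_parts, d_parts = [], [], [], []
    for post in range(N_POP):
        n_post = int(sizes[post])
        for pre in range(N_POP):
            k = int(K[post, pre])
            if k == 0:
                continue
            n_pre = int(sizes[pre])
            idx = np.empty((n_post, k), dtype=np.int32)
            block_seed = int(rng.integers(2**31))
            _sample_partners(n_post, n_pre, k, pre == post, block_seed, idx)
            src = (idx + offsets[pre]).astype(np.int32).ravel()
            tgt = np.repeat(np.arange(n_post, dtype=np.int32) + offsets[post], k)
            mean = jm[post, pre]
            w = rng.normal(mean, sd_frac * abs(mean), size=src.size)
            w = np.maximum(w, 0.0) if mean > 0 else np.minimum(w, 0.0)
            if exc[pre]:
                d = rng.normal(spec.neuron.d_exc, spec.neuron.d_exc_sd, src.size)
            else:
                d = rng.normal(spec.neuron.d_inh, spec.neuron.d_inh_sd, src.size)
            src_parts.append(src)
            tgt_parts.append(tgt)
            w_parts.append(w)
            d_parts.append(np.maximum(d, dt))

    if not src_parts:  # no recurrent synapses (externally driven neurons only)
        src_parts = [np.empty(0, np.int32)]
        tgt_parts = [np.empty(0, np.int32)]
        w_parts = [np.empty(0)]
        d_parts = [np.empty(0)]
    return NetworkRealization(
        spec=spec, sources=np.concatenate(src_parts),
        targets=np.concatenate(tgt_parts), weights=np.concatenate(w_parts),
        delays=np.concatenate(d_parts), theta_hat=theta_hat,
        structure_seed=int(structure_seed), orientation_seed=int(orientation_seed))


def validate(real: NetworkRealization) -> dict:
    """Check all realization invariants; returns a pass/fail report per check.

    Each entry is ``{"ok": bool, "violations": int}``.
    """
    spec = real.spec
    sizes = np.asarray(spec.populations.sizes)
    offsets = spec.populations.offsets
    K = spec.connectivity.recurrent
    pop_of = real.pop_of
    report = {}

    # exact in-degrees per (post, pre) block
    pre_pop = pop_of[real.sources]
    bad = 0
    for pre in range(N_POP):
        mask = pre_pop == pre
        counts = np.bincount(real.targets[mask], minlength=real.n_neurons)
        expected = K[pop_of, pre]
        bad += int(np.count_nonzero(counts != expected))
    report["in_degrees"] = {"ok": bad == 0, "violations": bad}

    n_self = int(np.count_nonzero(real.sources == real.targets))
    report["no_self_connections"] = {"ok": n_self == 0, "violations": n_self}

    pair = real.targets.astype(np.int64) * real.n_neurons + real.sources
    n_dup = int(pair.size - np.unique(pair).size)
    report["no_multapses"] = {"ok": n_dup == 0, "violations": n_dup}

    exc_src = spec.populations.excitatory[pre_pop]
    n_dale = int(np.count_nonzero(np.where(exc_src, real.weights < 0,
                                           real.weights > 0)))
    report["dale"] = {"ok": n_dale == 0, "violations": n_dale}

    n_delay = int(np.count_nonzero(real.delays < spec.neuron.dt))
    report["delays"] = {"ok": n_delay == 0, "violations": n_delay}

    in_range = np.all((real.theta_hat >= 0) & (real.theta_hat < 180))
    report["theta_hat_range"] = {"ok": bool(in_range),
                                 "violations": int(np.count_nonzero(
                                     ~((real.theta_hat >= 0) & (real.theta_hat < 180))))}
    report["ok"] = all(v["ok"] for k, v in report.items() if k != "ok")
    return report
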