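"""Model parameters for the layered V1 microcircuit.

The network is the eight-population cortical microcircuit (layers 2/3, 4, 5
and 6, one excitatory and one inhibitory population each) with fixed
in-degree connectivity, Poisson background drive to every population, and
orientation-tuned Poisson thalamic drive to L4 and L6.  All constants of the
standard model live here, together with the six named parameter variants, the
stimulus protocol, the tuned thalamic input rate, and an activity-preserving
downscaling transformation used for desk-scale work.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

POP_NAMES = ("L2/3e", "L2/3i", "L4e", "L4i", "L5e", "L5i", "L6e", "L6i")
N_POP = 8

#: population sizes of the standard (full-scale) model
_SIZES = (20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948)

#: in-degrees, rows = postsynaptic population, first 8 columns = recurrent
#: presynaptic populations (order POP_NAMES), column 8 = background,
#: column 9 = thalamus
_INDEGREES = (
    # 23e   23i    4e    4i    5e   5i    6e   6i     bg  th
    (2199, 1079,  979,  467,  159,   0,  109,   0,  1600,  0),
    (2990,  860,  703,  289,  380,   0,   60,   0,  1500,  0),
    ( 159,   34, 1117,  794,   32,   0,  667,   0,  2100, 93),
    (1480,   16, 1813,  953,   16,   0, 1608,   0,  1900, 57),
    (2188,  374, 1135,   31,  420, 496,  296,   0,  2000,  0),
    (1165,  159,  570,   12,  300, 404,  124,   0,  1900,  0),
    ( 325,   38,  467,   91,  285,  21,  581, 752,  2900, 47),
    ( 766,    5,   74,    2,  136,   8,  979, 459,  2100, 17),
)

VARIANTS = (
    "standard",
    "high_background",
    "low_background",
    "strong_inhibition",
    "strong_synapses",
    "low_connectivity",
)


@dataclass(frozen=True)
class PopulationTable:
    """Names, sizes and excitatory/inhibitory identity of the populations."""

    sizes: tuple[int, ...] = _SIZES
    names: tuple[str, ...] = POP_NAMES

    @property
    def total(self) -> int:
        return int(sum(self.sizes))

    @property
    def excitatory(self) -> np.ndarray:
        """Boolean flag per population; populations alternate e/i."""
        return np.array([n.endswith("e") for n in self.names])

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each population in a flat neuron enumeration."""
        return np.concatenate([[0], np.cumsum(self.sizes)]).astype(np.int64)

    def slice_of(self, pop: int | str) -> slice:
        p = self.index(pop)
        off = self.offsets
        return slice(int(off[p]), int(off[p + 1]))

    def index(self, pop: int | str) -> int:
        if isinstance(pop, str):
            return self.names.index(pop)
        return int(pop)

    def population_of(self) -> np.ndarray:
        """int8 vector mapping neuron id -> population index."""
        return np.repeat(np.arange(N_POP, dtype=np.int8), self.sizes)


@dataclass(frozen=True)
class NeuronParams:
    """LIF single-neuron and synapse parameters (identical for all neurons)."""

    tau_m: float = 10.0      # membrane time constant (ms)
    tau_ref: float = 2.0     # refractory period (ms)
    R: float = 40.0          # membrane resistance (MOhm)
    C_m: float = 250.0       # capacitance (pF)
    V_thr: float = -50.0     # spike threshold (mV)
    V_r: float = -65.0       # reset / resting potential (mV)
    J_e: float = 0.15        # mean excitatory efficacy (mV)
    J_sd_frac: float = 0.1   # SD of efficacies relative to their mean
    g: float = 4.0           # inhibition/excitation ratio
    d_exc: float = 1.5       # excitatory delay mean (ms)
    d_exc_sd: float = 0.75   # excitatory delay SD (ms)
    d_inh: float = 0.7       # inhibitory delay mean (ms)
    d_inh_sd: float = 0.35   # inhibitory delay SD (ms)
    dt: float = 0.1          # simulation step (ms)

    def __post_init__(self):
        if self.V_thr <= self.V_r:
            raise ValueError("V_thr must exceed V_r")
        if min(self.tau_m, self.tau_ref, self.dt) <= 0 or self.g <= 0:
            raise ValueError("tau_m, tau_ref, dt and g must be positive")

    @property
    def theta(self) -> float:
        """Distance from reset to threshold (mV)."""
        return self.V_thr - self.V_r


@dataclass(frozen=True)
class ConnectivityTable:
    """In-degree table K[post, pre]; columns 0..7 recurrent, 8 bg, 9 thalamus."""

    K: tuple[tuple[int, ...], ...] = _INDEGREES

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.K, dtype=np.int64)

    @property
    def recurrent(self) -> np.ndarray:
        return self.matrix[:, :N_POP]

    @property
    def background(self) -> np.ndarray:
        return self.matrix[:, N_POP]

    @property
    def thalamic(self) -> np.ndarray:
        return self.matrix[:, N_POP + 1]


@dataclass(frozen=True)
class StimulusProtocol:
    """External drive and stimulus grid.

    ``nu_bg`` is the single-axon background rate; each neuron receives a
    compound Poisson process of rate K_bg * nu_bg.  In the stimulated
    condition the compound thalamic rate follows
    ``K_th * nu0_th * (1 + m cos 2(theta - theta_hat))``; in the spontaneous
    condition it is untuned at the background intensity, ``K_th * nu_bg``.
    """

    nu_bg: float = 8.0            # spikes/s per background axon
    nu0_th: float = 30.0          # spikes/s per thalamic axon (stimulated)
    m: float = 0.3                # orientation modulation amplitude
    angles: tuple[float, ...] = tuple(float(a) for a in range(0, 180, 15))
    T: float = 100.0              # analysis duration per angle (s)
    warmup: float = 200.0         # discarded warm-up interval (ms)


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one network model."""

    populations: PopulationTable = field(default_factory=PopulationTable)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    connectivity: ConnectivityTable = field(default_factory=ConnectivityTable)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    variant: str = "standard"
    scale: float = 1.0
    #: multiplier applied to all recurrent efficacy means (variants, downscaling)
    j_rec_factor: float = 1.0
    #: per-population constant compensation input (mV), used by downscaling
    dc_mean: tuple[float, ...] = (0.0,) * N_POP

    def mean_weights(self) -> np.ndarray:
        """8x8 matrix of mean recurrent efficacies (mV), [post, pre].

        Excitatory columns carry +J_e, inhibitory columns -g*J_e; the L4e ->
        L2/3e projection has a doubled mean.  ``j_rec_factor`` scales all
        recurrent means.
        """
        p = self.neuron
        exc = self.populations.excitatory
        jm = np.where(exc[None, :], p.J_e, -p.g * p.J_e) * np.ones((N_POP, 1))
        jm[0, 2] *= 2.0  # L4e -> L2/3e exception
        return jm * self.j_rec_factor

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "populations": {"names": list(self.populations.names),
                            "sizes": list(self.populations.sizes)},
            "neuron": dataclasses.asdict(self.neuron),
            "connectivity": [list(r) for r in self.connectivity.K],
            "protocol": {**dataclasses.asdict(self.protocol),
                         "angles": list(self.protocol.angles)},
            "variant": self.variant,
            "scale": self.scale,
            "j_rec_factor": self.j_rec_factor,
            "dc_mean": list(self.dc_mean),
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(
            populations=PopulationTable(sizes=tuple(int(s) for s in d["populations"]["sizes"]),
                                        names=tuple(d["populations"]["names"])),
            neuron=NeuronParams(**d["neuron"]),
            connectivity=ConnectivityTable(K=tuple(tuple(int(k) for k in row)
                                                   for row in d["connectivity"])),
            protocol=StimulusProtocol(**{**d["protocol"],
                                         "angles": tuple(d["protocol"]["angles"])}),
            variant=d["variant"],
            scale=d["scale"],
            j_rec_factor=d["j_rec_factor"],
            dc_mean=tuple(d["dc_mean"]),
        )

    @staticmethod
    def from_json(s_or_path) -> "ModelSpec":
        try:
            d = json.loads(s_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(s_or_path) as fh:
                d = json.load(fh)
        return ModelSpec.from_dict(d)


def standard_spec() -> ModelSpec:
    """The standard parameter set at full scale."""
    return ModelSpec()


def variant_spec(name: str) -> ModelSpec:
    """One of the six parameter sets.

    ``high_background``/``low_background`` scale the background axon rate by
    2 / 0.5, ``strong_inhibition`` doubles g, ``strong_synapses`` doubles all
    recurrent efficacies, ``low_connectivity`` halves all recurrent in-degrees
    (rounded to nearest integer).  External in-degrees are untouched.
    """
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid: {', '.join(VARIANTS)}")
    spec = standard_spec()
    if name == "standard":
        return spec
    if name == "high_background":
        return dataclasses.replace(
            spec, variant=name,
            protocol=dataclasses.replace(spec.protocol, nu_bg=2 * spec.protocol.nu_bg))
    if name == "low_background":
        return dataclasses.replace(
            spec, variant=name,
            protocol=dataclasses.replace(spec.protocol, nu_bg=spec.protocol.nu_bg / 2))
    if name == "strong_inhibition":
        return dataclasses.replace(
            spec, variant=name,
            neuron=dataclasses.replace(spec.neuron, g=2 * spec.neuron.g))
    if name == "strong_synapses":
        return dataclasses.replace(spec, variant=name, j_rec_factor=2.0)
    # low_connectivity
    K = spec.connectivity.matrix.copy()
    K[:, :N_POP] = np.rint(K[:, :N_POP] / 2).astype(np.int64)
    return dataclasses.replace(
        spec, variant=name,
        connectivity=ConnectivityTable(K=tuple(tuple(int(k) for k in row) for row in K)))


def thalamic_rate(spec: ModelSpec, population: int | str, theta_hat: float,
                  theta: float, condition: str = "stimulated") -> float:
    """Compound thalamic input rate (spikes/s) for one neuron.

    Stimulated: ``K_th * nu0_th * (1 + m cos 2(theta - theta_hat))``;
    spontaneous: ``K_th * nu_bg`` (untuned).  Angles in degrees.
    """
    p = spec.populations.index(population)
    k_th = float(spec.connectivity.thalamic[p])
    if k_th == 0.0:
        return 0.0
    prot = spec.protocol
    if condition == "spontaneous":
        return k_th * prot.nu_bg
    mod = 1.0 + prot.m * math.cos(2.0 * math.radians(theta - theta_hat))
    return k_th * prot.nu0_th * mod


def thalamic_rates(spec: ModelSpec, theta_hat: np.ndarray, theta: float,
                   condition: str = "stimulated") -> np.ndarray:
    """Vector of compound thalamic rates for all neurons (spikes/s)."""
    pop_of = spec.populations.population_of()
    k_th = spec.connectivity.thalamic.astype(float)[pop_of]
    prot = spec.protocol
    if condition == "spontaneous":
        return k_th * prot.nu_bg
    if condition == "operating":
        return np.zeros_like(k_th)
    mod = 1.0 + prot.m * np.cos(2.0 * np.radians(theta - np.asarray(theta_hat)))
    return k_th * prot.nu0_th * mod


def assign_preferred_orientations(spec: ModelSpec, seed: int) -> np.ndarray:
    """Per-neuron preferred input orientation, uniform on [0, 180) degrees.

    Orientations only matter for neurons with a nonzero thalamic in-degree
    (L4 and L6) but are assigned to all neurons for uniform bookkeeping.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 180.0, size=spec.populations.total)


def downscale(spec: ModelSpec, factor: float) -> ModelSpec:
    """Reduced-scale model preserving the full-scale operating point.

    Population sizes and recurrent in-degrees are multiplied by ``factor``
    (rounded, minimum 1 for originally positive in-degrees).  To keep the
    statistics of the synaptic input -- and with them rates, spike-train
    irregularity and the asynchronous-irregular regime -- at their full-scale
    values, recurrent efficacies are scaled by 1/sqrt(factor) (exactly
    preserving the input variance) and a per-population DC compensation input
    restores the recurrent mean, evaluated at the full-scale population
    mean-field rates of the spontaneous condition.  External in-degrees are
    left unscaled: background and thalamic drive are compound Poisson rates,
    so reducing them would only degrade the dynamics without saving anything.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    if factor * min(spec.populations.sizes) < 10:
        raise ValueError("factor too small: smallest population would drop below 10")
    if factor == 1.0:
        return spec
    sizes = tuple(int(x) for x in np.rint(np.array(spec.populations.sizes) * factor))
    K = spec.connectivity.matrix.copy()
    k_rec = K[:, :N_POP].copy()
    k_scaled = np.rint(k_rec * factor).astype(np.int64)
    k_scaled[(k_rec > 0) & (k_scaled < 1)] = 1
    K[:, :N_POP] = k_scaled

    # DC compensation: restore the recurrent mean input at reference rates
    from .meanfield import population_rates  # deferred to avoid an import cycle
    nu_ref = population_rates(spec, condition="spontaneous")
    root = math.sqrt(factor)
    jm = spec.mean_weights()  # full-scale means (mV)
    tau_s = spec.neuron.tau_m * 1e-3
    # scaled network carries K' synapses of mean J/sqrt(f)
    missing = k_rec - k_scaled / root
    dc = tau_s * (jm * missing) @ nu_ref + np.asarray(spec.dc_mean)

    return dataclasses.replace(
        spec,
        populations=PopulationTable(sizes=sizes, names=spec.populations.names),
        connectivity=ConnectivityTable(K=tuple(tuple(int(k) for k in row) for row in K)),
        scale=spec.scale * factor,
        j_rec_factor=spec.j_rec_factor / root,
        dc_mean=tuple(float(x) for x in dc),
    )


def toy_spec(n_per_pop: int = 25, k_rec: int = 5, k_bg: int = 400,
             k_th: int = 30, nu_bg: float = 8.0, nu0_th: float = 15.0,
             j_e: float = 0.6) -> ModelSpec:
    """A small but structurally faithful model for desk-scale tests.

    Keeps the eight-population layout and the thalamic targeting pattern
    (L4 and L6 only) with uniform recurrent in-degrees.
    """
    sizes = (n_per_pop,) * N_POP
    K = np.zeros((N_POP, N_POP + 2), dtype=np.int64)
    K[:, :N_POP] = k_rec
    K[:, N_POP] = k_bg
    K[:, N_POP + 1] = [0, 0, k_th, k_th, 0, 0, k_th, k_th]
    return ModelSpec(
        populations=PopulationTable(sizes=sizes),
        neuron=NeuronParams(J_e=j_e),
        connectivity=ConnectivityTable(K=tuple(tuple(int(k) for k in row) for row in K)),
        protocol=StimulusProtocol(nu_bg=nu_bg, nu0_th=nu0_th),
        variant="standard",
    )
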