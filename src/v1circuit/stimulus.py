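"""Design of external current stimuli from the linearized model.

A constant injected current I adds a zero-variance drive R*I to a neuron's
input; at the operating point it acts as an effective rate perturbation
dgamma_i = (dF_i/dmu_i) * R * I_i which simply adds to the thalamic
perturbation: dnu = (1 - W)^{-1} (dbeta + dgamma).  Because all gains are
known analytically, stimuli can be designed in closed form, e.g. to cancel
one baseline eigenmode of the input (dgamma = -xi_k Psi_k) or to change the
rates of exactly one population ( dgamma = (1 - W) dnu_target ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linear import LinearResults
from .modes import ModeSet
_SENS_FLOOR = 1e-300


@dataclass
class CurrentStimulus:
    """Per-neuron injected currents with their effective perturbation."""

    I: np.ndarray        # pA per neuron
    dgamma: np.ndarray   # equivalent input perturbation (spikes/s)
    label: str

    def stim_mu(self, lin: LinearResults, intensity: float = 1.0) -> np.ndarray:
        """Constant drive R*I in mV, as consumed by Models A and B."""
        R = lin.realization.spec.neuron.R
        return intensity * R * self.I * 1e-3  # MOhm * pA = 1e-3 mV


@dataclass
class PredictedResponse:
    """Linear rate prediction under combined thalamic and current input."""

    rates: np.ndarray      # reported absolute rates, clipped at zero
    rates_raw: np.ndarray  # unclipped linear rates
    dnu: np.ndarray
    rectified: bool        # True when any linear rate went negative
    intensity: float


def current_to_perturbation(lin: LinearResults, I_pA) -> np.ndarray:
    """dgamma = dF/dmu * R * I  (currents in pA, perturbation in spikes/s)."""
    I_pA = np.asarray(I_pA, dtype=float)
    R = lin.realization.spec.neuron.R
    return lin.dF_dmu * R * I_pA * 1e-3


def perturbation_to_current(lin: LinearResults, dgamma) -> np.ndarray:
    """Currents (pA) realizing a requested effective perturbation."""
    dgamma = np.asarray(dgamma, dtype=float)
    sens = lin.dF_dmu * lin.realization.spec.neuron.R * 1e-3
    dead = (np.abs(sens) < _SENS_FLOOR) & (dgamma != 0)
    if np.any(dead):
        ids = np.flatnonzero(dead)[:10]
        raise ValueError(
            f"{int(dead.sum())} neurons have zero current sensitivity but a "
            f"nonzero requested perturbation (e.g. ids {ids.tolist()})")
    out = np.zeros_like(dgamma)
    ok = np.abs(sens) >= _SENS_FLOOR
    out[ok] = dgamma[ok] / sens[ok]
    return out


def design_mode_deletion(lin: LinearResults, modeset: ModeSet,
                         k: int) -> CurrentStimulus:
    """Current stimulus cancelling baseline input mode ``k``.

    Adding dgamma = -xi_k Psi_k to the input zeroes the k-th mode
    coefficient of the combined baseline input while leaving all other
    coefficients untouched.
    """
    comp = -(modeset.xi[k] * modeset.Psi[:, k])
    comp = np.real_if_close(comp, tol=1e6)
    if np.iscomplexobj(comp):
        raise ValueError("selected mode is complex; delete the conjugate pair")
    dgamma = lin.expand(comp.real)
    return CurrentStimulus(I=perturbation_to_current(lin, dgamma),
                           dgamma=dgamma, label=f"mode-deletion-{k}")


def design_suppression(lin: LinearResults, population,
                       target_rate_change) -> CurrentStimulus:
    """Current stimulus changing only one population's rates.

    ``target_rate_change`` is the desired per-neuron rate change (scalar or
    vector over that population's neurons, spikes/s; negative values suppress
    activity).  dgamma = (1 - W) dnu_target makes the linear response to
    dbeta + dgamma differ from the unstimulated response by exactly
    dnu_target, i.e. zero outside the chosen population.
    """
    real = lin.realization
    p = real.spec.populations.index(population)
    dnu_t = np.zeros(real.n_neurons)
    dnu_t[lin.pop_of == p] = target_rate_change
    dgamma = dnu_t - lin.W @ dnu_t
    return CurrentStimulus(I=perturbation_to_current(lin, dgamma),
                           dgamma=dgamma, label=f"suppress-{real.spec.populations.names[p]}")


def predict_response(lin: LinearResults, stimulus: CurrentStimulus | None,
                     intensity: float = 1.0, theta: float = 0.0,
                     condition: str = "stimulated") -> PredictedResponse:
    """Linear rates under a stimulus angle plus a scaled current stimulus.

    The linear solve is exact (no rectification); reported absolute rates
    are clipped at zero and flagged when clipping occurred, since negative
    linear rates signal that the model left its domain of validity.
    """
    dbeta, _, _ = lin.split_input(theta=theta, condition=condition)
    dgamma = 0.0 if stimulus is None else intensity * stimulus.dgamma
    dnu = lin.solve_direct(dbeta + dgamma)
    raw = lin.nu_op + dnu
    rect = bool(np.any(raw < 0))
    return PredictedResponse(rates=np.maximum(raw, 0.0), rates_raw=raw,
                             dnu=dnu, rectified=rect, intensity=intensity)


def intensity_sweep(lin: LinearResults, stimulus: CurrentStimulus,
                    intensities, theta: float = 0.0):
    """Population-mean linear rates versus stimulus intensity.

    Returns ``(intensities, rates)`` with ``rates`` of shape
    ``(len(intensities), 8)`` (unclipped means).
    """
    out = []
    for s in intensities:
        resp = predict_response(lin, stimulus, intensity=float(s), theta=theta)
        out.append(lin.population_means(resp.rates_raw))
    return np.asarray(intensities, dtype=float), np.asarray(out)
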