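"""Neuron-resolved mean-field rate model (diffusion approximation).

Each LIF neuron driven by Poisson input is summarized by the mean mu and
variance sigma^2 of its membrane-potential drive; its stationary rate is the
first-passage (Siegert) transfer function

    F(mu, sigma) = 1 / Phi,
    Phi = tau_ref + tau_m * sqrt(pi) * int_{(V_r-mu)/sigma}^{(V_thr-mu)/sigma}
          e^{x^2} (1 + erf x) dx .

Self-consistent network rates solve nu_i = F_i(nu, nu_th); the fixed point is
found by integrating the pseudo-time relaxation dnu/ds = -nu + F(nu) with an
adaptive Runge-Kutta 4(5) scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import erfcx, roots_legendre

from .params import N_POP, POP_NAMES, ModelSpec, thalamic_rates

_CLIP = 1e280  # cap on e^{x^2}-type integrand values; keeps Phi finite-huge


class ConvergenceError(RuntimeError):
    """Fixed-point iteration did not reach the requested residual."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


def _gl_nodes(n):
    x, w = roots_legendre(n)
    return x, w


def _siegert_integral(a, b, n_quad):
    """Vectorized int_a^b erfcx(-x) dx, split at zero for accuracy."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x, w = _gl_nodes(n_quad)
    total = np.zeros(np.broadcast(a, b).shape)
    mid = np.clip(0.0, a, b)
    for lo, hi in ((a, mid), (mid, b)):
        half = 0.5 * (hi - lo)
        nodes = 0.5 * (hi + lo)[..., None] + half[..., None] * x
        vals = np.minimum(erfcx(-nodes), _CLIP)
        total = total + half * (vals @ w)
    return total


def siegert_rate(mu, sigma, params, n_quad: int = 200):
    """Stationary LIF rate (spikes/s) for drive mean ``mu`` and SD ``sigma`` (mV).

    ``mu`` is the mean depolarization relative to the reset/rest potential
    V_r.  Vectorized over ``mu``/``sigma``.  Deep subthreshold drive returns
    ~0; the rate is bounded by 1/tau_ref.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    # mu is the depolarization relative to V_r, so the first-passage limits
    # (V_r - mu)/sigma .. (V_thr - mu)/sigma become (0-mu)/sigma .. (theta-mu)/sigma
    a = (0.0 - mu) / sigma
    b = (params.theta - mu) / sigma
    integral = _siegert_integral(a, b, n_quad)
    phi = params.tau_ref * 1e-3 + params.tau_m * 1e-3 * np.sqrt(np.pi) * integral
    return 1.0 / phi


def transfer_derivatives(mu, sigma, params, n_quad: int = 200):
    """Analytic (dF/dmu, dF/dsigma) of the Siegert rate, in (spikes/s)/mV.

    Uses the Leibniz rule on the integral limits; the scaled complementary
    error function keeps the expressions stable.  dF = -Phi' / Phi^2 is
    evaluated as -Phi' * F^2 to avoid overflow for silent neurons.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = siegert_rate(mu, sigma, params, n_quad=n_quad)
    a = (0.0 - mu) / sigma
    b = (params.theta - mu) / sigma
    fa = np.minimum(erfcx(-a), _CLIP)
    fb = np.minimum(erfcx(-b), _CLIP)
    pref = params.tau_m * 1e-3 * np.sqrt(np.pi) / sigma
    dphi_dmu = -pref * (fb - fa)
    dphi_dsigma = -pref * (b * fb - a * fa)
    return -dphi_dmu * nu**2, -dphi_dsigma * nu**2


# ---------------------------------------------------------------------------
# population-level mean field (8 coupled populations; used for reference
# rates in downscaling and for quick orientation)
# ---------------------------------------------------------------------------

def _population_moments(spec: ModelSpec, nu, nu_ext):
    p = spec.neuron
    tau_s = p.tau_m * 1e-3
    jm = spec.mean_weights()
    j2 = jm**2 * (1.0 + p.J_sd_frac**2)
    k = spec.connectivity.recurrent.astype(float)
    k_bg = spec.connectivity.background.astype(float)
    k_th = spec.connectivity.thalamic.astype(float)
    ext = k_bg * spec.protocol.nu_bg + k_th * nu_ext
    mu = tau_s * ((jm * k) @ nu + p.J_e * ext) + np.asarray(spec.dc_mean)
    var = tau_s * ((j2 * k) @ nu + p.J_e**2 * ext)
    return mu, var


def population_rates(spec: ModelSpec, condition: str = "spontaneous",
                     tol: float = 1e-8, max_s: float = 500.0) -> np.ndarray:
    """Self-consistent population-mean rates of the 8-population model.

    Treats every neuron of a population as statistically identical (exact in
    the spontaneous and operating conditions, where the thalamic drive is
    untuned).  Used for downscaling reference rates and quick summaries.
    """
    prot = spec.protocol
    nu_ext = {"spontaneous": prot.nu_bg, "stimulated": prot.nu0_th,
              "operating": 0.0}[condition]
    p = spec.neuron

    def rhs(_, nu):
        mu, var = _population_moments(spec, nu, nu_ext)
        return siegert_rate(mu, np.sqrt(var), p, n_quad=120) - nu

    nu = np.ones(N_POP)
    s = 0.0
    while s < max_s:
        sol = solve_ivp(rhs, (s, s + 50.0), nu, method="RK45",
                        rtol=1e-10, atol=1e-12)
        nu = sol.y[:, -1]
        s = sol.t[-1]
        if np.max(np.abs(rhs(0.0, nu))) < tol:
            return nu
    raise ConvergenceError("population mean-field did not converge")


# ---------------------------------------------------------------------------
# neuron-resolved model
# ---------------------------------------------------------------------------

@dataclass
class InputMoments:
    """Per-neuron drive mean (mV) and variance (mV^2), with source terms."""

    mu: np.ndarray
    sigma2: np.ndarray
    components: dict

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)


def input_moments(nu, realization, condition: str = "stimulated",
                  theta: float = 0.0, stim_mu=None,
                  nu_th_scale: float = 1.0) -> InputMoments:
    """Drive moments for all neurons given network rates ``nu`` (spikes/s).

    Recurrent terms are weighted sums over the realized synapses,
    mu_rec = tau_m * sum_j J_ij nu_j and sigma_rec^2 = tau_m * sum_j J_ij^2
    nu_j; background and thalamic terms use the compound rates (in-degrees
    folded in).  ``stim_mu`` adds a zero-variance constant drive (mV), e.g.
    an injected current R*I.
    """
    spec = realization.spec
    p = spec.neuron
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (realization.n_neurons,):
        raise ValueError("rate vector length does not match the network")
    tau_s = p.tau_m * 1e-3
    mu_rec = tau_s * (realization.J_csr @ nu)
    var_rec = tau_s * (realization.J2_csr @ nu)
    pop_of = realization.pop_of
    nu_bg = spec.connectivity.background.astype(float)[pop_of] * spec.protocol.nu_bg
    nu_th = nu_th_scale * thalamic_rates(spec, realization.theta_hat, theta, condition)
    mu_bg = tau_s * p.J_e * nu_bg
    var_bg = tau_s * p.J_e**2 * nu_bg
    mu_th = tau_s * p.J_e * nu_th
    var_th = tau_s * p.J_e**2 * nu_th
    mu_dc = np.asarray(spec.dc_mean)[pop_of]
    if stim_mu is not None:
        mu_dc = mu_dc + np.asarray(stim_mu, dtype=float)
    comp = {"recurrent": (mu_rec, var_rec), "background": (mu_bg, var_bg),
            "thalamic": (mu_th, var_th), "dc": (mu_dc, np.zeros_like(mu_dc))}
    return InputMoments(mu=mu_rec + mu_bg + mu_th + mu_dc,
                        sigma2=var_rec + var_bg + var_th, components=comp)


@dataclass
class RateResults:
    """Stationary per-neuron rates with convergence diagnostics."""

    nu: np.ndarray
    condition: str
    theta: float | None
    residual: float
    nfev: int
    pseudo_time: float
    model: "RateModel"

    def summary(self) -> pd.DataFrame:
        """Population table of mean/median rates (spikes/s)."""
        pop_of = self.model.realization.pop_of
        df = pd.DataFrame({"population": np.array(POP_NAMES)[pop_of],
                           "rate": self.nu})
        out = df.groupby("population", sort=False)["rate"].agg(
            ["mean", "median", "std", "size"])
        return out.reindex(POP_NAMES)

    def population_means(self) -> np.ndarray:
        pop_of = self.model.realization.pop_of
        return np.array([self.nu[pop_of == p].mean() for p in range(N_POP)])


class RateModel:
    """Model B: neuron-resolved self-consistent firing rates.

    Parameters
    ----------
    realization : NetworkRealization
        Sampled synaptic connectivity (weights define the recurrent input
        moments).
    n_quad : int
        Gauss-Legendre order for the Siegert integral.
    """

    def __init__(self, realization, n_quad: int = 200):
        self.realization = realization
        self.n_quad = n_quad

    def transfer(self, nu, condition="stimulated", theta=0.0, stim_mu=None,
                 nu_th_scale=1.0):
        """F(nu): one application of the network transfer function."""
        mom = input_moments(nu, self.realization, condition, theta, stim_mu,
                            nu_th_scale)
        sigma = np.sqrt(np.maximum(mom.sigma2, 1e-30))
        return siegert_rate(mom.mu, sigma, self.realization.spec.neuron,
                            n_quad=self.n_quad)

    def fit(self, condition: str = "stimulated", theta: float = 0.0,
            stim_mu=None, x0=None, tol: float = 1e-6,
            max_pseudo_time: float = 400.0, nu_th_scale: float = 1.0,
            ivp_rtol: float = 1e-8, chunk: float = 25.0) -> RateResults:
        """Solve nu = F(nu) by pseudo-time relaxation (RK45).

        Starts from 1 spike/s everywhere (or ``x0``) and integrates until the
        fixed-point residual ||F(nu) - nu||_inf falls below ``tol``.
        ``ivp_rtol`` controls the trajectory accuracy only; the fixed point
        itself is certified by the residual check, so a loose value speeds up
        large problems without affecting the answer beyond ``tol``.
        """
        n = self.realization.n_neurons
        nu = np.full(n, 1.0) if x0 is None else np.asarray(x0, dtype=float).copy()
        nfev = 0
        s = 0.0
        residuals = []

        def rhs(_, y):
            return self.transfer(y, condition, theta, stim_mu, nu_th_scale) - y

        while True:
            res = float(np.max(np.abs(rhs(0.0, nu))))
            residuals.append(res)
            nfev += 1
            if res < tol:
                return RateResults(nu=nu, condition=condition,
                                   theta=theta if condition == "stimulated" else None,
                                   residual=res, nfev=nfev, pseudo_time=s, model=self)
            if len(residuals) > 2 and res > 0.5 * residuals[-2]:
                # exponential relaxation should shrink the residual by orders
                # of magnitude per chunk; a plateau means the integrator's
                # accuracy floor sits above tol
                raise ConvergenceError(
                    f"residual plateaued at {res:g} above tol={tol:g}; "
                    "tighten ivp_rtol or relax tol", residuals=residuals)
            if s >= max_pseudo_time:
                raise ConvergenceError(
                    f"no fixed point after pseudo-time {s:g} (residual {res:g})",
                    residuals=residuals)
            sol = solve_ivp(rhs, (s, s + chunk), nu, method="RK45",
                            rtol=ivp_rtol, atol=1e-10)
            nu = np.maximum(sol.y[:, -1], 0.0)
            nfev += sol.nfev
            s = sol.t[-1]


def operating_point(realization, **kw) -> RateResults:
    """Model B rates with the thalamus silenced (background active).

    This is the linearization point of Model C; thalamic input perturbations
    then equal the thalamic rates themselves.
    """
    return RateModel(realization).fit(condition="operating", **kw)
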