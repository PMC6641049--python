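"""Model C: linear response of the network about its operating point.

The rate map nu = F(nu, nu_th) is linearized at the operating point with the
thalamus silenced (background active).  The Jacobian splits into the
effective recurrent connectivity W (anatomical weights times the local gains
of the postsynaptic neurons) and a diagonal thalamic sensitivity B; the
stationary response to an input perturbation is

    dnu = (1 - W)^{-1} dbeta,      dbeta = B dnu_th .

W further decomposes into a block-constant baseline part Q (empirical block
means over all ordered neuron pairs, zeros included) and the zero-block-mean
deviations S = W - Q.  Population-constant baseline input is processed by Q,
the tuned modulation by S, with negligible interference between the two
pathways for fixed in-degree wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meanfield import (RateResults, input_moments, operating_point,
                        transfer_derivatives)
from .params import N_POP, POP_NAMES, thalamic_rates


def r_squared(reference, prediction) -> float:
    """Coefficient of determination of ``prediction`` against ``reference``."""
    reference = np.asarray(reference, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if reference.shape != prediction.shape:
        raise ValueError("length mismatch")
    ss_tot = float(np.sum((reference - reference.mean())**2))
    if ss_tot == 0.0:
        raise ValueError("reference has zero variance")
    ss_res = float(np.sum((reference - prediction)**2))
    return 1.0 - ss_res / ss_tot


@dataclass
class LinearResults:
    """Linearization products: operating point, W, B, Q and solvers."""

    model: "LinearResponseModel"
    nu_op: np.ndarray          # operating-point rates (spikes/s)
    W: sp.csr_matrix           # effective connectivity (per presynaptic spikes/s)
    B: np.ndarray              # diagonal thalamic sensitivity (per spikes/s)
    q_blocks: np.ndarray       # 8x8 block values of Q
    dF_dmu: np.ndarray         # local gain wrt mean input ((spikes/s)/mV)
    dF_dsigma: np.ndarray
    sigma_op: np.ndarray       # drive SD at the operating point (mV)
    op_results: RateResults
    _cache: dict = field(default_factory=dict, repr=False)

    # -- structure helpers --------------------------------------------------
    @property
    def realization(self):
        return self.model.realization

    @property
    def pop_of(self) -> np.ndarray:
        return self.realization.pop_of

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.realization.spec.populations.sizes)

    def population_means(self, x) -> np.ndarray:
        """Per-population means of a neuron vector."""
        x = np.asarray(x, dtype=float)
        sums = np.bincount(self.pop_of, weights=x, minlength=N_POP)
        return sums / self.sizes

    def expand(self, v_pop) -> np.ndarray:
        """Expand an 8-vector to a population-constant neuron vector."""
        return np.asarray(v_pop, dtype=float)[self.pop_of]

    def apply_Q(self, x) -> np.ndarray:
        """Q @ x using the rank-8 block structure (Q is never materialized)."""
        sums = np.bincount(self.pop_of, weights=np.asarray(x, float),
                           minlength=N_POP)
        return (self.q_blocks @ sums)[self.pop_of]

    def apply_S(self, x) -> np.ndarray:
        return self.W @ x - self.apply_Q(x)

    # -- solvers -------------------------------------------------------------
    def _solve(self, matvec, b, label):
        n = b.size
        if n <= 2000:
            A = np.eye(n) - np.array([matvec(col) for col in np.eye(n)]).T
            x = np.linalg.solve(A, b)
        else:
            op = spla.LinearOperator((n, n), matvec=lambda v: v - matvec(v))
            x, info = spla.gmres(op, b, rtol=1e-12, atol=0.0, maxiter=500)
            if info != 0:
                raise RuntimeError(f"{label} solve did not converge (info={info})")
        resid = np.max(np.abs((x - matvec(x)) - b))
        scale = np.max(np.abs(b)) if np.max(np.abs(b)) > 0 else 1.0
        if resid > 1e-8 * scale:
            raise RuntimeError(f"{label} solve residual {resid:g} too large")
        return x

    def solve_direct(self, dbeta) -> np.ndarray:
        """dnu = (1 - W)^{-1} dbeta via a sparse solve."""
        return self._solve(lambda v: self.W @ v, np.asarray(dbeta, float), "direct")

    def split_input(self, theta: float = 0.0, condition: str = "stimulated"):
        """(dbeta, dbeta_B, dbeta_M) for one stimulus angle.

        dbeta = B * nu_th (the thalamic perturbation equals the thalamic rate
        at this operating point); the baseline holds population means and the
        modulation the zero-mean deviations.
        """
        real = self.realization
        nu_th = thalamic_rates(real.spec, real.theta_hat, theta, condition)
        dbeta = self.B * nu_th
        dbeta_b = self.expand(self.population_means(dbeta))
        return dbeta, dbeta_b, dbeta - dbeta_b

    def collapsed_baseline_matrix(self) -> np.ndarray:
        """Q-hat: the 8x8 matrix q_PT * N_T acting on population vectors."""
        return self.q_blocks * self.sizes[None, :]

    def solve_decomposed(self, dbeta_B, dbeta_M):
        """Baseline via the collapsed 8x8 system, modulation via (1 - S)."""
        bpop = self.population_means(dbeta_B)
        qhat = self.collapsed_baseline_matrix()
        dnu_b = self.expand(np.linalg.solve(np.eye(N_POP) - qhat, bpop))
        dnu_m = self._solve(self.apply_S, np.asarray(dbeta_M, float), "modulation")
        return dnu_b, dnu_m

    def interference(self, dnu_B, dnu_M):
        """(mean |Q dnu_M|, mean |S dnu_B|): pathway cross-talk magnitudes."""
        return (float(np.mean(np.abs(self.apply_Q(dnu_M)))),
                float(np.mean(np.abs(self.apply_S(dnu_B)))))

    def summary(self) -> pd.DataFrame:
        """Per-population operating rates, gains, and thalamic sensitivity."""
        df = pd.DataFrame(
            {"population": np.array(POP_NAMES)[self.pop_of],
             "nu_op": self.nu_op, "dF_dmu": self.dF_dmu, "B": self.B})
        out = df.groupby("population", sort=False).mean(numeric_only=True)
        return out.reindex(POP_NAMES)


def ensemble_collapsed_model(spec) -> dict:
    """Population-level linearization of the ensemble-expected network.

    Works at any scale, including the full-scale model, because it never
    touches individual synapses: the operating point is the population
    mean-field fixed point with the thalamus silenced, the collapsed
    baseline matrix is Q-hat_PT = K_PT * E[W entry], and the baseline input
    is the population-mean thalamic perturbation scaled by the feed-forward
    sensitivity.  Returns a dict with ``nu_op``, ``qhat``, ``B`` and
    ``dbeta_B`` (all 8-dimensional).
    """
    from .meanfield import (_population_moments, population_rates,
                            transfer_derivatives)
    p = spec.neuron
    nu_op = population_rates(spec, condition="operating")
    mu, var = _population_moments(spec, nu_op, 0.0)
    sigma = np.sqrt(var)
    dmu, dsig = transfer_derivatives(mu, sigma, p)
    tau_s = p.tau_m * 1e-3
    jm = spec.mean_weights()
    j2 = jm**2 * (1.0 + p.J_sd_frac**2)
    K = spec.connectivity.recurrent.astype(float)
    qhat = (dmu[:, None] * tau_s * jm
            + dsig[:, None] * tau_s * j2 / (2.0 * sigma[:, None])) * K
    B = dmu * tau_s * p.J_e + dsig * tau_s * p.J_e**2 / (2.0 * sigma)
    B = np.where(spec.connectivity.thalamic > 0, B, 0.0)
    dbeta_B = B * spec.connectivity.thalamic * spec.protocol.nu0_th
    return {"nu_op": nu_op, "qhat": qhat, "B": B, "dbeta_B": dbeta_B,
            "mu": mu, "sigma": sigma}


class LinearResponseModel:
    """Builds the linearized network from a sampled realization.

    ``fit`` solves for the operating point (thalamus silent), evaluates the
    analytic transfer-function derivatives there, and assembles W, B and the
    baseline block matrix Q.
    """

    def __init__(self, realization, n_quad: int = 200):
        self.realization = realization
        self.n_quad = n_quad

    def fit(self, op: RateResults | None = None) -> LinearResults:
        real = self.realization
        spec = real.spec
        p = spec.neuron
        if op is None:
            op = operating_point(real)
        if op.residual > 1e-5:
            raise RuntimeError("operating point is not converged")
        mom = input_moments(op.nu, real, condition="operating")
        sigma = np.sqrt(np.maximum(mom.sigma2, 1e-30))
        dmu, dsig = transfer_derivatives(mom.mu, sigma, p, n_quad=self.n_quad)

        tau_s = p.tau_m * 1e-3
        tgt = real.targets
        j = real.weights
        wdata = dmu[tgt] * tau_s * j + dsig[tgt] * tau_s * j**2 / (2.0 * sigma[tgt])
        W = sp.csr_matrix((wdata, (tgt, real.sources)),
                          shape=(real.n_neurons, real.n_neurons))

        # thalamic sensitivity per unit compound input rate (J_th = J_e, the
        # in-degree is already folded into nu_th)
        has_th = spec.connectivity.thalamic[real.pop_of] > 0
        B = np.where(has_th,
                     dmu * tau_s * p.J_e + dsig * tau_s * p.J_e**2 / (2.0 * sigma),
                     0.0)

        sizes = np.asarray(spec.populations.sizes)
        P = sp.csr_matrix((np.ones(real.n_neurons),
                           (np.arange(real.n_neurons), real.pop_of)),
                          shape=(real.n_neurons, N_POP))
        block_sums = np.asarray((P.T @ W @ P).todense())
        q_blocks = block_sums / np.outer(sizes, sizes)

        return LinearResults(model=self, nu_op=op.nu, W=W, B=B,
                             q_blocks=q_blocks, dF_dmu=dmu, dF_dsigma=dsig,
                             sigma_op=sigma, op_results=op)
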