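"""Eigenmode analysis of the baseline pathway.

The baseline matrix Q has rank at most eight; acting on population-constant
vectors it is exactly represented by the collapsed 8x8 matrix
Q-hat_PT = q_PT * N_T.  Its eigenvalues are the exceptional eigenvalues of
the effective connectivity W (the remaining spectrum of W forms a random
bulk whose radius is set by the variance of the entries).  Decomposing the
baseline input into the eigenvectors Psi_i with coefficients xi_i turns the
baseline solve into eight independent scalar gains lambda~_i = 1/(1 -
lambda_i):

    dnu_B = sum_i lambda~_i xi_i Psi_i .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from .linear import LinearResults
from .params import N_POP, POP_NAMES


def collapse(lin: LinearResults) -> np.ndarray:
    """The collapsed baseline matrix Q-hat (8x8)."""
    return lin.collapsed_baseline_matrix()


@dataclass
class ModeSet:
    """Eigenmodes of the collapsed baseline system for one input."""

    lambdas: np.ndarray    # 8 eigenvalues of Q-hat (possibly complex)
    gains: np.ndarray      # lambda~ = (1 - lambda)^{-1}
    Psi: np.ndarray        # 8x8, columns are population-level eigenvectors
    xi: np.ndarray         # mode coefficients of the supplied baseline input
    lin: LinearResults

    def input_modes(self) -> np.ndarray:
        """8x8 array: column k is the population-level input mode xi_k Psi_k."""
        return self.Psi * self.xi[None, :]

    def output_modes(self) -> np.ndarray:
        """Column k is the population-level output mode lambda~_k xi_k Psi_k."""
        return self.Psi * (self.gains * self.xi)[None, :]

    def baseline_output(self) -> np.ndarray:
        """Sum of the output modes, expanded to all neurons (real part)."""
        total = self.output_modes().sum(axis=1)
        return self.lin.expand(np.real_if_close(total, tol=1e6).real)

    def expand_mode(self, k: int, output: bool = True) -> np.ndarray:
        """One mode as a per-neuron vector (complex in general)."""
        col = (self.output_modes() if output else self.input_modes())[:, k]
        return col[self.lin.pop_of]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "eigenvalue": self.lambdas, "gain": self.gains, "xi": self.xi})
        for p, name in enumerate(POP_NAMES):
            df[name] = self.Psi[p, :]
        return df


def decompose_collapsed(qhat: np.ndarray, bpop: np.ndarray):
    """Eigen-decomposition of an 8x8 collapsed matrix plus input expansion.

    Returns ``(lambdas, gains, Psi, xi)`` ordered by descending eigenvalue
    magnitude.  Coefficients solve the population-level system Psi xi =
    dbeta_B, exact also for non-orthogonal eigenvectors.  Eigenvectors are
    normalized to unit Euclidean norm at population level with their
    largest-magnitude entry rotated to the positive real axis.
    """
    lam, vec = np.linalg.eig(qhat)
    if np.linalg.cond(vec) > 1e8:
        raise np.linalg.LinAlgError(
            "collapsed baseline matrix is near-defective; use the direct "
            "baseline solve instead of the mode decomposition")
    for k in range(N_POP):  # sign/phase convention
        pivot = vec[np.argmax(np.abs(vec[:, k])), k]
        vec[:, k] *= np.abs(pivot) / pivot
    order = np.argsort(-np.abs(lam))
    lam, vec = lam[order], vec[:, order]
    xi = np.linalg.solve(vec, np.asarray(bpop, dtype=complex))
    return lam, 1.0 / (1.0 - lam), vec, xi


def modes(lin: LinearResults, dbeta_B) -> ModeSet:
    """Eigen-decompose the realization's Q-hat and expand a baseline input.

    ``dbeta_B`` may be a population-constant neuron vector or an 8-vector.
    """
    dbeta_B = np.asarray(dbeta_B)
    bpop = dbeta_B if dbeta_B.shape == (N_POP,) else lin.population_means(dbeta_B)
    lam, gains, vec, xi = decompose_collapsed(lin.collapsed_baseline_matrix(), bpop)
    return ModeSet(lambdas=lam, gains=gains, Psi=vec, xi=xi, lin=lin)


def conjugate_groups(lambdas) -> list[tuple[int, ...]]:
    """Indices of real modes and conjugate pairs (for real contributions)."""
    groups, used = [], set()
    for k in range(len(lambdas)):
        if k in used:
            continue
        if abs(lambdas[k].imag) > 1e-12:
            mates = [j for j in range(len(lambdas)) if j not in used and j != k
                     and np.isclose(lambdas[j], np.conj(lambdas[k]))]
            if mates:
                groups.append((k, mates[0]))
                used |= {k, mates[0]}
                continue
        groups.append((k,))
        used.add(k)
    return groups


def bulk_radius(lin: LinearResults) -> float:
    """Circular-law estimate of the bulk spectral radius of W.

    Uses the block-wise entry variances (zeros included):
    r^2 = mean over postsynaptic neurons of sum_j Var(W_ij).
    """
    W = lin.W
    sizes = lin.sizes
    W2 = W.copy()
    W2.data = W2.data**2
    import scipy.sparse as sp_
    P = sp_.csr_matrix((np.ones(W.shape[0]), (np.arange(W.shape[0]), lin.pop_of)),
                       shape=(W.shape[0], N_POP))
    s1 = np.asarray((P.T @ W @ P).todense())
    s2 = np.asarray((P.T @ W2 @ P).todense())
    n_pairs = np.outer(sizes, sizes)
    var = s2 / n_pairs - (s1 / n_pairs)**2
    row_var = (var * sizes[None, :]).sum(axis=1)  # sum_j Var(W_ij) per post pop
    return float(np.sqrt(np.average(row_var, weights=sizes)))


def spectrum(lin: LinearResults, k: int = 10, margin: float = 1.2):
    """Leading eigenvalues of W with a bulk/exceptional classification.

    Returns ``(eigenvalues, radius, exceptional_mask)`` where eigenvalues are
    the ``k`` largest in magnitude (Arnoldi iteration on the sparse W) and an
    eigenvalue is flagged exceptional when its magnitude exceeds
    ``margin * radius``.
    """
    if k > 20:
        raise ValueError("k must be at most 20")
    n = lin.W.shape[0]
    if n <= 2000:
        lam = np.linalg.eigvals(lin.W.toarray())
        lam = lam[np.argsort(-np.abs(lam))][:k]
    else:
        lam = spla.eigs(lin.W, k=k, which="LM", return_eigenvectors=False)
        lam = lam[np.argsort(-np.abs(lam))]
    radius = bulk_radius(lin)
    return lam, radius, np.abs(lam) > margin * radius
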