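"""Persistence: HDF5 containers for realizations and linear models,
tab-separated spike-event files with JSON sidecars, JSON model specs."""

from __future__ import annotations

import json

import h5py
import numpy as np
import scipy.sparse as sp

from .linear import LinearResponseModel, LinearResults
from .meanfield import RateResults
from .network import NetworkRealization
from .params import ModelSpec
from .spiking import SpikeData


def save_realization(real: NetworkRealization, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("sources", "targets", "weights", "delays", "theta_hat"):
            f.create_dataset(name, data=getattr(real, name))
        f.attrs["spec_json"] = real.spec.to_json()
        f.attrs["structure_seed"] = real.structure_seed
        f.attrs["orientation_seed"] = real.orientation_seed


def load_realization(path) -> NetworkRealization:
    with h5py.File(path, "r") as f:
        return NetworkRealization(
            spec=ModelSpec.from_json(f.attrs["spec_json"]),
            sources=f["sources"][:], targets=f["targets"][:],
            weights=f["weights"][:], delays=f["delays"][:],
            theta_hat=f["theta_hat"][:],
            structure_seed=int(f.attrs["structure_seed"]),
            orientation_seed=int(f.attrs["orientation_seed"]))


def save_rates(res: RateResults, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("nu", data=res.nu)
        f.attrs["condition"] = res.condition
        f.attrs["theta"] = -1.0 if res.theta is None else res.theta
        f.attrs["residual"] = res.residual
        f.attrs["nfev"] = res.nfev


def save_linear(lin: LinearResults, path) -> None:
    with h5py.File(path, "w") as f:
        W = lin.W.tocsr()
        f.create_dataset("W_data", data=W.data)
        f.create_dataset("W_indices", data=W.indices)
        f.create_dataset("W_indptr", data=W.indptr)
        f.create_dataset("B", data=lin.B)
        f.create_dataset("nu_op", data=lin.nu_op)
        f.create_dataset("q_blocks", data=lin.q_blocks)
        f.create_dataset("dF_dmu", data=lin.dF_dmu)
        f.create_dataset("dF_dsigma", data=lin.dF_dsigma)
        f.create_dataset("sigma_op", data=lin.sigma_op)
        f.attrs["spec_json"] = lin.realization.spec.to_json()


def load_linear(lin_path, realization: NetworkRealization) -> LinearResults:
    """Reattach stored linearization products to their realization."""
    with h5py.File(lin_path, "r") as f:
        n = realization.n_neurons
        W = sp.csr_matrix((f["W_data"][:], f["W_indices"][:], f["W_indptr"][:]),
                          shape=(n, n))
        op = RateResults(nu=f["nu_op"][:], condition="operating", theta=None,
                         residual=0.0, nfev=0, pseudo_time=0.0, model=None)
        return LinearResults(
            model=LinearResponseModel(realization), nu_op=f["nu_op"][:], W=W,
            B=f["B"][:], q_blocks=f["q_blocks"][:], dF_dmu=f["dF_dmu"][:],
            dF_dsigma=f["dF_dsigma"][:], sigma_op=f["sigma_op"][:],
            op_results=op)


def save_spikes(spikes: SpikeData, path_prefix) -> None:
    """Write ``<prefix>.tsv`` ("id<TAB>time_ms" lines) and ``<prefix>.json``."""
    with open(f"{path_prefix}.tsv", "w") as fh:
        for i, t in zip(spikes.ids, spikes.times):
            fh.write(f"{i}\t{t:.1f}\n")
    meta = {"n_neurons": spikes.n_neurons, "condition": spikes.condition,
            "theta": spikes.theta, "T": spikes.T, "warmup": spikes.warmup,
            "structure_seed": spikes.structure_seed,
            "input_seed": spikes.input_seed}
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_spikes(path_prefix) -> SpikeData:
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    data = np.loadtxt(f"{path_prefix}.tsv", ndmin=2)
    ids = data[:, 0].astype(np.int32) if data.size else np.empty(0, np.int32)
    times = data[:, 1] if data.size else np.empty(0)
    return SpikeData(ids=ids, times=times, **meta)
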