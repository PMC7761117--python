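"""Seeded realizations of the spiking-bursting process and plug-in estimation.

The exact model constrains only the lag-tau pair probabilities of the hidden
dichotomous state.  The simulator realizes the minimal completion consistent
with them: a stationary first-order Markov chain on {spiking, bursting} whose
one-step joint equals the exact 2x2 table, so all empirical analysis defaults
to lag tau = 1.  (At larger lags the chain's effective correlation decays
geometrically — a property of the completion, not of the one-lag table.)

While bursting, every node reads 1; while spiking, each time bin is an
independent draw from the spatial spike distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .decoder import PhiStarResult, phi_star_from_joint
from .info import Bipartition, IIResult, mib_phi_from_joint
from .model import (
    OneTimeDist,
    SpikingBurstingModel,
    TwoTimeJoint,
    dichotomous_joint,
)

__all__ = [
    "RealizationMatrix",
    "simulate",
    "estimate_tables",
    "empirical_ii",
    "save_realization",
    "load_realization",
]


@dataclass(frozen=True)
class RealizationMatrix:
    """T x N binary matrix of time bins by nodes, with its seed and lag."""

    values: np.ndarray
    seed: int
    lag_tau: int = 1

    def __post_init__(self):
        v = np.ascontiguousarray(self.values, dtype=np.uint8)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("realization must be a T x N matrix with T >= 2")
        if np.any(v > 1):
            raise ValueError("realization entries must be 0/1")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def _simulate_dichotomous(model: SpikingBurstingModel, n_steps: int, rng) -> np.ndarray:
    """Boolean bursting indicator from the stationary Markov completion."""
    d = model.dichotomous
    jt = dichotomous_joint(d)
    stay_s = jt.pss / d.ps  # P(spiking -> spiking)
    stay_b = jt.pbb / d.pb if d.pb > 0 else 1.0  # P(bursting -> bursting)
    u = rng.random(n_steps)
    burst = np.empty(n_steps, dtype=bool)
    burst[0] = u[0] < d.pb
    for t in range(1, n_steps):
        if burst[t - 1]:
            burst[t] = u[t] < stay_b
        else:
            burst[t] = u[t] >= stay_s
    return burst


def simulate(model: SpikingBurstingModel, n_steps: int, seed: int, lag_tau: int = 1) -> RealizationMatrix:
    """Generate a seeded realization of the process.

    The hidden state starts from its stationary distribution (ps, pb); during
    bursts all nodes are 1; spiking bins are sampled per node for independent
    spike tables, otherwise by inverse-CDF over the 2^N word table.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    burst = _simulate_dichotomous(model, n_steps, rng)
    n = model.n_nodes
    spikes = model.spikes
    if spikes.p_vec is not None:
        vals = (rng.random((n_steps, n)) < np.asarray(spikes.p_vec)).astype(np.uint8)
    else:
        cdf = np.cumsum(spikes.probs)
        words = np.searchsorted(cdf, rng.random(n_steps), side="right")
        words = np.minimum(words, 2 ** n - 1)
        vals = ((words[:, None] >> np.arange(n)[None, :]) & 1).astype(np.uint8)
    vals[burst] = 1
    return RealizationMatrix(values=vals, seed=seed, lag_tau=lag_tau)


def _word_indices(values: np.ndarray) -> np.ndarray:
    n = values.shape[1]
    return values @ (1 << np.arange(n, dtype=np.int64))


def estimate_tables(data: RealizationMatrix, tau: int | None = None) -> tuple[OneTimeDist, TwoTimeJoint]:
    """Plug-in frequency estimates of the one-time and lag-tau tables.

    The pair table is symmetrized, (J + J^T)/2, matching the stationarity
    symmetry of the exact table.
    """
    tau = data.lag_tau if tau is None else tau
    if not 0 < tau < data.n_steps:
        raise ValueError("need 0 < tau < T")
    n = data.n_nodes
    w = _word_indices(data.values)
    m = 2 ** n
    one = np.bincount(w, minlength=m).astype(float)
    one /= one.sum()
    pair_idx = w[:-tau] * m + w[tau:]
    joint = np.bincount(pair_idx, minlength=m * m).astype(float).reshape(m, m)
    joint /= joint.sum()
    joint = 0.5 * (joint + joint.T)
    return OneTimeDist(n, one), TwoTimeJoint(n, joint)


def empirical_ii(
    data: RealizationMatrix,
    tau: int | None = None,
    bp: Bipartition | None = None,
) -> tuple[IIResult, PhiStarResult]:
    """Plug-in integrated information from a realization.

    The MIB search runs definitionally on the estimated pair table; Phi* is
    evaluated on ``bp`` (default: the balanced bipartition with the
    lowest-index nodes in A, mirroring the symmetric-split convention).
    """
    _, joint = estimate_tables(data, tau)
    if bp is None:
        bp = Bipartition(data.n_nodes, (1 << (data.n_nodes // 2)) - 1)
    ii = mib_phi_from_joint(joint)
    ps = phi_star_from_joint(joint, bp)
    return ii, ps


# ---------------------------------------------------------------------------
# plain-text persistence
# ---------------------------------------------------------------------------

def save_realization(data: RealizationMatrix, path: str | Path) -> None:
    """Write the matrix as headerless delimited text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, data.values, fmt="%d", delimiter=" ")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"seed": data.seed, "lag_tau": data.lag_tau}))


def load_realization(path: str | Path) -> RealizationMatrix:
    path = Path(path)
    vals = np.loadtxt(path, dtype=np.uint8, ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"seed": -1, "lag_tau": 1}
    return RealizationMatrix(values=vals, seed=int(meta["seed"]), lag_tau=int(meta["lag_tau"]))
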