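"""Parameterization and exact probability tables of the spiking-bursting model.

The model is a binary vector process on ``N`` nodes driven by a hidden
two-state ("dichotomous") component that switches the whole system between a
*spiking* mode — each time bin drawn independently from a spatial spike
distribution ``s_x`` — and a *bursting* mode in which every node is locked at
1.  The dichotomous component is stationary with spiking probability ``ps``
and a single lag-tau correlation parameter ``eps`` (the scaling-invariant
analogue of the Pearson coefficient ``rho``).

Word encoding
-------------
An N-bit word is an integer index: node ``i`` maps to bit ``i`` of the index,
node 0 being the least significant bit.  The all-ones word is index
``2**N - 1``.  This convention is fixed throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConstraintError",
    "DichotomousParams",
    "JointTable2",
    "SpikeTable",
    "SpikingBurstingModel",
    "OneTimeDist",
    "TwoTimeJoint",
    "validate_dichotomous",
    "dichotomous_joint",
    "rho_eps_convert",
    "independent_spike_table",
    "subsystem_spike_table",
    "one_time_dist",
    "two_time_joint",
    "scaling_transform",
    "model_from_config",
    "load_model",
]

#: absolute tolerance for sum-to-one and nonnegativity of probability tables
PROB_TOL = 1e-12


class ConstraintError(ValueError):
    """A parameter set violates a nonnegativity/normalization constraint."""


def _clamp_probs(p: np.ndarray) -> np.ndarray:
    """Clamp tiny negative round-off (within -PROB_TOL) to exactly 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -PROB_TOL):
        raise ConstraintError(f"negative probability encountered: min={p.min():.3e}")
    return np.where(p < 0, 0.0, p)


# ---------------------------------------------------------------------------
# dichotomous (bursting) component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DichotomousParams:
    """Validated parameters of the two-state bursting component.

    ``ps`` is the probability of the spiking (non-bursting) state,
    ``eps`` the scaling-invariant time-correlation parameter (>= 0 here).
    """

    ps: float
    eps: float

    @property
    def pb(self) -> float:
        return 1.0 - self.ps

    @property
    def eps_max(self) -> float:
        """Upper bound of eps: pb/ps."""
        return self.pb / self.ps

    @property
    def rho(self) -> float:
        """Lag-tau Pearson correlation of the dichotomous component."""
        return self.eps * self.ps / self.pb

    @property
    def ps_max(self) -> float:
        """Upper bound of ps at this eps (nonnegative-correlation branch)."""
        return 1.0 / (1.0 + self.eps)

    @property
    def is_degenerate(self) -> bool:
        """eps == 0: time-uncorrelated, all delayed informations vanish."""
        return self.eps == 0.0


def validate_dichotomous(ps: float, eps: float) -> DichotomousParams:
    """Validate ``(ps, eps)`` against the nonnegativity constraints.

    Requires 0 < ps < 1 (the boundary values make the process deterministic
    or burst-free in a way the information formulas treat separately) and
    0 <= eps <= eps_max = pb/ps, equivalently ps <= 1/(1+eps).
    """
    if not 0.0 < ps < 1.0:
        raise ConstraintError(f"ps={ps} violates 0 < ps < 1")
    if eps < 0.0:
        raise ConstraintError(
            f"eps={eps} < 0: only nonnegative time correlations are supported"
        )
    ps_max = 1.0 / (1.0 + eps)
    if ps > ps_max + PROB_TOL:
        raise ConstraintError(
            f"ps={ps} > ps_max={ps_max:.12g} = 1/(1+eps): "
            "off-diagonal joint probability ps*pb - eps*ps^2 would be negative"
        )
    eps_max = (1.0 - ps) / ps
    if eps > eps_max + PROB_TOL:
        raise ConstraintError(f"eps={eps} > eps_max={eps_max:.12g} = pb/ps")
    return DichotomousParams(ps=float(ps), eps=float(eps))


@dataclass(frozen=True)
class JointTable2:
    """2x2 two-time joint table of the dichotomous component.

    Cell ``pqr`` is the joint probability of state q at time t and state r at
    time t+tau, q, r in {s(piking), b(ursting)}.  Stationarity forces
    ``psb == pbs``.
    """

    pss: float
    psb: float
    pbs: float
    pbb: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.pss, self.psb], [self.pbs, self.pbb]])

    @property
    def ps(self) -> float:
        return self.pss + self.psb

    @property
    def pb(self) -> float:
        return self.pbb + self.pbs


def dichotomous_joint(params: DichotomousParams) -> JointTable2:
    """Exact 2x2 joint: pss = ps^2(1+eps), psb = ps*pb - eps*ps^2,
    pbb = pb^2 + eps*ps^2."""
    ps, pb, eps = params.ps, params.pb, params.eps
    pss = ps * ps * (1.0 + eps)
    psb = ps * pb - eps * ps * ps
    pbb = pb * pb + eps * ps * ps
    cells = _clamp_probs([pss, psb, psb, pbb])
    total = cells.sum()
    if abs(total - 1.0) > 1e-9:
        raise ConstraintError(f"joint table sums to {total}, not 1")
    return JointTable2(pss=cells[0], psb=cells[1], pbs=cells[2], pbb=cells[3])


def rho_eps_convert(ps: float, value: float, direction: str = "rho_to_eps") -> float:
    """Convert between the Pearson correlation rho and the scaling-invariant
    eps: eps = rho * pb / ps."""
    if not 0.0 < ps < 1.0:
        raise ConstraintError(f"ps={ps} violates 0 < ps < 1")
    pb = 1.0 - ps
    if direction == "rho_to_eps":
        return value * pb / ps
    if direction == "eps_to_rho":
        return value * ps / pb
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# spiking component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTable:
    """One-time spatial distribution ``s_x`` of spontaneous spiking.

    ``probs[k]`` is the probability of the word with integer index ``k``
    (node i = bit i, LSB first).  ``p_vec`` is retained when the table was
    built from independent per-node probabilities (enables fast sampling and
    exact subsystem products); ``None`` for a general user-supplied table.
    """

    n_nodes: int
    probs: np.ndarray
    p_vec: tuple[float, ...] | None = None

    def __post_init__(self):
        probs = _clamp_probs(self.probs)
        if probs.shape != (2 ** self.n_nodes,):
            raise ValueError(
                f"expected {2 ** self.n_nodes} word probabilities, got {probs.shape}"
            )
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConstraintError(f"spike table sums to {probs.sum()}, not 1")
        probs = probs / probs.sum()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def s1(self) -> float:
        """Probability of the all-ones word (system-wide simultaneous spike)."""
        return float(self.probs[-1])

    def word_labels(self) -> list[str]:
        n = self.n_nodes
        return [format(k, f"0{n}b")[::-1] for k in range(2 ** n)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"word": self.word_labels(), "prob": self.probs})


def independent_spike_table(p_vec) -> SpikeTable:
    """Spike table for spatially independent nodes with per-node spike
    probabilities ``p_vec``: s_x = prod_i (P_i if bit i set else 1-P_i)."""
    p = np.asarray(p_vec, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConstraintError("per-node spike probabilities must lie in [0, 1]")
    n = p.size
    words = np.arange(2 ** n)
    probs = np.ones(2 ** n)
    for i in range(n):
        bit = (words >> i) & 1
        probs *= np.where(bit == 1, p[i], 1.0 - p[i])
    return SpikeTable(n_nodes=n, probs=probs, p_vec=tuple(float(v) for v in p))


def _extract_subword(words: np.ndarray, mask: int) -> np.ndarray:
    """Gather the bits of ``words`` selected by ``mask`` into a compact index."""
    sub = np.zeros_like(words)
    k = 0
    for i in range(int(mask).bit_length()):
        if (mask >> i) & 1:
            sub |= ((words >> i) & 1) << k
            k += 1
    return sub


def subsystem_spike_table(table: SpikeTable, mask: int) -> SpikeTable:
    """Marginal spike table over the node subset given by bitmask ``mask``."""
    if mask == 0:
        raise ValueError("subsystem mask must be nonempty")
    n_sub = bin(mask).count("1")
    words = np.arange(2 ** table.n_nodes)
    sub = _extract_subword(words, mask)
    probs = np.bincount(sub, weights=table.probs, minlength=2 ** n_sub)
    p_vec = None
    if table.p_vec is not None:
        p_vec = tuple(table.p_vec[i] for i in range(table.n_nodes) if (mask >> i) & 1)
    return SpikeTable(n_nodes=n_sub, probs=probs, p_vec=p_vec)


# ---------------------------------------------------------------------------
# combined model and its exact tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikingBurstingModel:
    """The combined model: a spike table plus dichotomous parameters."""

    spikes: SpikeTable
    dichotomous: DichotomousParams

    @property
    def n_nodes(self) -> int:
        return self.spikes.n_nodes

    @property
    def s1(self) -> float:
        return self.spikes.s1

    @property
    def is_degenerate(self) -> bool:
        """True when all time-delayed informations vanish identically
        (s1 = 1 always-ones state, or eps = 0 no time correlation)."""
        return self.spikes.s1 == 1.0 or self.dichotomous.is_degenerate


@dataclass(frozen=True)
class OneTimeDist:
    """One-time distribution p(x) over N-bit words."""

    n_nodes: int
    probs: np.ndarray

    def __post_init__(self):
        probs = _clamp_probs(self.probs)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def p1(self) -> float:
        return float(self.probs[-1])

    def to_frame(self) -> pd.DataFrame:
        n = self.n_nodes
        words = [format(k, f"0{n}b")[::-1] for k in range(2 ** n)]
        return pd.DataFrame({"word": words, "prob": self.probs})


@dataclass(frozen=True)
class TwoTimeJoint:
    """Joint distribution p(x, y) over ordered pairs of words at lag tau.

    ``probs[ix, iy]`` indexes the earlier word by row.  Stationarity plus
    ``psb == pbs`` make the table symmetric under swapping x and y.
    """

    n_nodes: int
    probs: np.ndarray

    def __post_init__(self):
        probs = _clamp_probs(self.probs)
        m = 2 ** self.n_nodes
        if probs.shape != (m, m):
            raise ValueError(f"expected {(m, m)} joint, got {probs.shape}")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def p11(self) -> float:
        return float(self.probs[-1, -1])

    def marginal_x(self) -> OneTimeDist:
        return OneTimeDist(self.n_nodes, self.probs.sum(axis=1))

    def marginal_y(self) -> OneTimeDist:
        return OneTimeDist(self.n_nodes, self.probs.sum(axis=0))


def one_time_dist(model: SpikingBurstingModel) -> OneTimeDist:
    """Exact one-time table: p(x != 1) = ps*s_x, p(x = 1) = ps*s1 + pb."""
    d = model.dichotomous
    p = d.ps * model.spikes.probs.copy()
    p[-1] = d.ps * model.spikes.s1 + d.pb
    return OneTimeDist(model.n_nodes, p)


def two_time_joint(model: SpikingBurstingModel) -> TwoTimeJoint:
    """Exact lag-tau joint table.

    p(x!=1, y!=1) = pss*s_x*s_y;  p(x!=1, y=1) = p(x=1, y!=1) = pi*s_x with
    pi = pss*s1 + psb;  p(1,1) = p11 = pss*s1^2 + 2*psb*s1 + pbb.
    """
    jt = dichotomous_joint(model.dichotomous)
    s = model.spikes.probs
    s1 = model.spikes.s1
    pi = jt.pss * s1 + jt.psb
    p11 = jt.pss * s1 * s1 + 2.0 * jt.psb * s1 + jt.pbb
    M = jt.pss * np.outer(s, s)
    M[:-1, -1] = pi * s[:-1]
    M[-1, :-1] = pi * s[:-1]
    M[-1, -1] = p11
    return TwoTimeJoint(model.n_nodes, M)


# ---------------------------------------------------------------------------
# scaling invariance
# ---------------------------------------------------------------------------

def admissible_alpha_range(model: SpikingBurstingModel) -> tuple[float, float]:
    """Interval of scaling parameters alpha keeping all probabilities valid.

    Lower bound: s1' = 1 - (1-s1)/alpha >= 0.  Upper bound: ps' = alpha*ps
    must not exceed ps_max(eps) (eps is invariant).
    """
    d = model.dichotomous
    lo = 1.0 - model.s1
    hi = d.ps_max / d.ps
    return lo, hi


def scaling_transform(model: SpikingBurstingModel, alpha: float) -> SpikingBurstingModel:
    """Relabel a fraction of system-wide spikes as (uncorrelated) bursts.

    The transformation s_x' = s_x/alpha (x != 1), s1' = 1 - (1-s1)/alpha,
    ps' = alpha*ps, pss' = alpha^2*pss leaves the observable process — hence
    every one- and two-time table — exactly invariant; eps is unchanged.
    """
    if alpha <= 0:
        raise ConstraintError("alpha must be positive")
    lo, hi = admissible_alpha_range(model)
    if not (lo - PROB_TOL <= alpha <= hi + PROB_TOL):
        raise ConstraintError(
            f"alpha={alpha} outside admissible interval [{lo:.12g}, {hi:.12g}]"
        )
    s = model.spikes.probs.copy()
    s[:-1] = s[:-1] / alpha
    s[-1] = 1.0 - (1.0 - model.s1) / alpha
    new_spikes = SpikeTable(model.n_nodes, s)  # p_vec no longer product form
    new_dich = validate_dichotomous(alpha * model.dichotomous.ps, model.dichotomous.eps)
    return SpikingBurstingModel(spikes=new_spikes, dichotomous=new_dich)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def model_from_config(cfg: dict) -> SpikingBurstingModel:
    """Build a model from a config mapping.

    Expected shape::

        {"n_nodes": N,
         "spike": {"mode": "independent", "p": [..]}          # or
                  {"mode": "table", "probs": {"010": 0.1, ..}},
         "dichotomous": {"ps": .., "eps": ..}  # or {"pb": .., "rho": ..}}
    """
    n = int(cfg["n_nodes"])
    spike_cfg = cfg["spike"]
    if spike_cfg["mode"] == "independent":
        p = spike_cfg["p"]
        if np.isscalar(p):
            p = [p] * n
        if len(p) != n:
            raise ValueError(f"expected {n} per-node probabilities, got {len(p)}")
        spikes = independent_spike_table(p)
    elif spike_cfg["mode"] == "table":
        probs = np.zeros(2 ** n)
        for word, prob in spike_cfg["probs"].items():
            idx = int(word[::-1], 2)  # node 0 is the first character
            probs[idx] = float(prob)
        spikes = SpikeTable(n_nodes=n, probs=probs)
    else:
        raise ValueError(f"unknown spike mode {spike_cfg['mode']!r}")

    dich_cfg = cfg["dichotomous"]
    if "ps" in dich_cfg:
        ps = float(dich_cfg["ps"])
    else:
        ps = 1.0 - float(dich_cfg["pb"])
    if "eps" in dich_cfg:
        eps = float(dich_cfg["eps"])
    else:
        eps = rho_eps_convert(ps, float(dich_cfg["rho"]), "rho_to_eps")
    return SpikingBurstingModel(spikes=spikes, dichotomous=validate_dichotomous(ps, eps))


def load_model(path: str | Path) -> SpikingBurstingModel:
    """Load a model config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_config(cfg)
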