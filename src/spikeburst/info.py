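"""Entropy, mutual information, effective information and the MIB search.

All logarithms are base 2 (results in bits).  The workhorse is the universal
closed form ``i0(p, eps)`` — the time-delayed mutual information of the bare
dichotomous component — in terms of which the whole-system and subsystem
mutual informations of the spiking-bursting model are single evaluations at
rescaled first arguments:

    I_xy          = i0((1 - s1) * ps, eps)
    I_{xA,yA}     = i0((1 - sA) * ps, eps)
    phi_eff(A|B)  = i0((1-s1)ps) - i0((1-sA)ps) - i0((1-sB)ps)

"Whole minus sum" integrated information Phi is phi_eff at the minimum
information bipartition (MIB), the bipartition minimizing phi_eff normalized
by the smaller subsystem entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .model import (
    OneTimeDist,
    SpikingBurstingModel,
    TwoTimeJoint,
    _extract_subword,
    dichotomous_joint,
    one_time_dist,
    subsystem_spike_table,
    validate_dichotomous,
)

__all__ = [
    "Bipartition",
    "IIResult",
    "all_bipartitions",
    "entropy",
    "mutual_information",
    "i0",
    "i_xy_closed",
    "i_xy_expanded",
    "effective_information",
    "effective_information_from_joint",
    "mib_phi",
    "mib_phi_from_joint",
]

#: default cap on exhaustive bipartition enumeration (2^(N-1)-1 candidates)
DEFAULT_N_CAP = 12

LN2 = np.log(2.0)


def brace(q):
    """The entropy summand {q} = -q*log2(q), with {0} = 0."""
    return -xlogy(q, q) / LN2


def entropy(dist) -> float:
    """Base-2 entropy of a discrete distribution (array or OneTimeDist)."""
    p = dist.probs if isinstance(dist, OneTimeDist) else np.asarray(dist, dtype=float)
    return float(brace(p).sum())


def mutual_information(joint) -> float:
    """I(x;y) = H(x) + H(y) - H(x,y) for a 2-D joint table (>= 0)."""
    if isinstance(joint, TwoTimeJoint):
        joint = joint.probs
    elif hasattr(joint, "as_array"):  # JointTable2
        joint = joint.as_array()
    joint = np.asarray(joint, dtype=float)
    hx = entropy(joint.sum(axis=1))
    hy = entropy(joint.sum(axis=0))
    hxy = float(brace(joint).sum())
    return hx + hy - hxy


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def i0(p, eps):
    """Universal closed-form delayed mutual information of the dichotomous
    component with spiking probability ``p`` and correlation ``eps``:

        i0 = 2{p} + 2{1-p} - {p^2(1+eps)} - 2{p(1-p) - eps p^2}
             - {(1-p)^2 + eps p^2}

    Evaluated in the equivalent Kullback-Leibler regrouping

        ln 2 * i0 = pss*ln(1+eps) + 2*psb*log1p(-eps*p/(1-p))
                    + pbb*log1p(eps*p^2/(1-p)^2)

    which is free of the catastrophic cancellation the brace form suffers for
    small arguments (i0 ~ const * p^2 there).  Defined for first argument
    strictly inside (0, 1); vectorized in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("i0 first argument must lie strictly inside (0, 1)")
    q = 1.0 - p
    r = p / q
    if np.any(eps * r > 1.0 + 1e-12):
        raise ValueError("(p, eps) outside the validity region: ps*pb - eps*ps^2 < 0")
    pss = p * p * (1.0 + eps)
    psb = np.maximum(p * q - eps * p * p, 0.0)
    pbb = q * q + eps * p * p
    ratio = np.minimum(eps * r, 1.0)
    mid = np.where(psb > 0, psb * np.log1p(-np.where(ratio < 1, ratio, 0.0)), 0.0)
    val = (pss * np.log1p(eps) + 2 * mid + pbb * np.log1p(eps * r * r)) / LN2
    return val if val.ndim else float(val)


def _i0_term(s: float, ps: float, eps: float) -> float:
    """i0 at the rescaled argument (1-s)*ps, with the degenerate limits
    (argument 0, or eps = 0) contributing exactly 0 bits."""
    arg = (1.0 - s) * ps
    if eps == 0.0 or arg <= 0.0:
        return 0.0
    return float(i0(arg, eps))


def i_xy_closed(s1: float, ps: float, eps: float) -> float:
    """Whole-system delayed mutual information I_xy = i0((1-s1)*ps, eps).

    Degenerate parameter corners (s1 = 1, eps = 0) give exactly 0.
    """
    return _i0_term(s1, ps, eps)


def i_xy_expanded(s1: float, ps: float, eps: float) -> float:
    """I_xy via the five-term expansion in the raw model probabilities,

        2(1-s1){ps} + 2{p1} - (1-s1)^2 {pss} - 2(1-s1){pi} - {p11},

    an independent route that must agree with :func:`i_xy_closed`.
    """
    if s1 == 1.0 or eps == 0.0:
        return 0.0
    d = validate_dichotomous(ps, eps)
    jt = dichotomous_joint(d)
    p1 = d.ps * s1 + d.pb
    pi = jt.pss * s1 + jt.psb
    p11 = jt.pss * s1 * s1 + 2.0 * jt.psb * s1 + jt.pbb
    r = 1.0 - s1
    return float(
        2 * r * brace(d.ps) + 2 * brace(p1)
        - r * r * brace(jt.pss) - 2 * r * brace(pi) - brace(p11)
    )


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """A split of the N nodes into nonempty disjoint subsets A and B.

    Subsets are bitmasks over node indices.  Canonical form places node 0
    in A, so each unordered split is enumerated exactly once.
    """

    n_nodes: int
    mask_a: int

    def __post_init__(self):
        full = (1 << self.n_nodes) - 1
        if not 0 < self.mask_a < full:
            raise ValueError("both parts of a bipartition must be nonempty")

    @property
    def mask_b(self) -> int:
        return ((1 << self.n_nodes) - 1) ^ self.mask_a

    @property
    def size_a(self) -> int:
        return bin(self.mask_a).count("1")

    def canonical(self) -> "Bipartition":
        if self.mask_a & 1:
            return self
        return Bipartition(self.n_nodes, self.mask_b)

    def nodes_a(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if (self.mask_a >> i) & 1)

    def nodes_b(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if (self.mask_b >> i) & 1)


def all_bipartitions(n_nodes: int, cap: int = DEFAULT_N_CAP):
    """Yield all 2^(N-1) - 1 canonical bipartitions (node 0 always in A)."""
    if n_nodes < 2:
        raise ValueError("bipartitions require at least 2 nodes")
    if n_nodes > cap:
        raise ValueError(
            f"N={n_nodes} exceeds the exhaustive-enumeration cap {cap}; "
            "raise `cap` explicitly to proceed"
        )
    full = (1 << n_nodes) - 1
    for m in range(1, full, 2):  # odd masks keep node 0 in A
        yield Bipartition(n_nodes, m)


def marginalize_joint(joint: TwoTimeJoint, mask: int) -> np.ndarray:
    """Marginal two-time joint over the node subset ``mask`` (2^k x 2^k)."""
    n_sub = bin(mask).count("1")
    words = np.arange(2 ** joint.n_nodes)
    sub = _extract_subword(words, mask)
    m = 2 ** n_sub
    out = np.zeros((m, m))
    np.add.at(out, (sub[:, None], sub[None, :]), joint.probs)
    return out


# ---------------------------------------------------------------------------
# effective information and the MIB
# ---------------------------------------------------------------------------

def effective_information(model: SpikingBurstingModel, bp: Bipartition) -> float:
    """phi_eff(A|B) by the closed form: whole-system MI minus the two
    subsystem MIs, each an i0 evaluation at a rescaled argument."""
    d = model.dichotomous
    s1 = model.s1
    sa = subsystem_spike_table(model.spikes, bp.mask_a).s1
    sb = subsystem_spike_table(model.spikes, bp.mask_b).s1
    return (
        _i0_term(s1, d.ps, d.eps)
        - _i0_term(sa, d.ps, d.eps)
        - _i0_term(sb, d.ps, d.eps)
    )


def effective_information_from_joint(joint: TwoTimeJoint, bp: Bipartition) -> float:
    """phi_eff computed definitionally from an explicit two-time joint:
    I(x;y) - I(xA;yA) - I(xB;yB) with subsystem joints by marginalization."""
    return (
        mutual_information(joint.probs)
        - mutual_information(marginalize_joint(joint, bp.mask_a))
        - mutual_information(marginalize_joint(joint, bp.mask_b))
    )


@dataclass(frozen=True)
class IIResult:
    """Whole-minus-sum integrated information and its per-bipartition table.

    ``records`` has one row per canonical bipartition: mask_a, size_a,
    phi_eff, h_a, h_b, normalized (phi_eff / min(h_a, h_b); +inf where the
    normalization entropy is 0 — such bipartitions are excluded from the
    argmin).  ``degenerate`` marks results where no bipartition had a
    nonzero normalization (Phi reported as 0).
    """

    i_xy: float
    records: pd.DataFrame
    mib: Bipartition | None
    phi: float
    degenerate: bool = False

    def to_json_dict(self) -> dict:
        return {
            "i_xy": self.i_xy,
            "phi": self.phi,
            "mib_mask_a": None if self.mib is None else self.mib.mask_a,
            "degenerate": self.degenerate,
            "bipartitions": self.records.to_dict(orient="records"),
        }


def _assemble_ii(i_xy, rows, n_nodes) -> IIResult:
    df = pd.DataFrame(rows)
    norm = np.minimum(df["h_a"], df["h_b"])
    df["normalized"] = np.where(norm > 0, df["phi_eff"] / np.where(norm > 0, norm, 1.0), np.inf)
    finite = df[np.isfinite(df["normalized"])]
    if finite.empty:
        return IIResult(i_xy=i_xy, records=df, mib=None, phi=0.0, degenerate=True)
    best = finite["normalized"].min()
    # ties broken by the smallest canonical A-mask for determinism
    cand = finite[finite["normalized"] <= best + 1e-15]
    row = cand.loc[cand["mask_a"].idxmin()]
    mib = Bipartition(n_nodes, int(row["mask_a"]))
    return IIResult(i_xy=i_xy, records=df, mib=mib, phi=float(row["phi_eff"]))


def mib_phi(model: SpikingBurstingModel, cap: int = DEFAULT_N_CAP) -> IIResult:
    """Exhaustive MIB search over all canonical bipartitions of the model.

    Phi = phi_eff(MIB); Phi > 0 iff phi_eff > 0 for every bipartition,
    since the normalizing entropies are positive.
    """
    d = model.dichotomous
    rows = []
    dist = one_time_dist(model)
    i_xy = i_xy_closed(model.s1, d.ps, d.eps)
    for bp in all_bipartitions(model.n_nodes, cap=cap):
        ha = entropy(_marginal_words(dist, bp.mask_a))
        hb = entropy(_marginal_words(dist, bp.mask_b))
        rows.append(
            {
                "mask_a": bp.mask_a,
                "size_a": bp.size_a,
                "phi_eff": effective_information(model, bp),
                "h_a": ha,
                "h_b": hb,
            }
        )
    return _assemble_ii(i_xy, rows, model.n_nodes)


def _marginal_words(dist: OneTimeDist, mask: int) -> np.ndarray:
    words = np.arange(2 ** dist.n_nodes)
    sub = _extract_subword(words, mask)
    return np.bincount(sub, weights=dist.probs, minlength=2 ** bin(mask).count("1"))


def mib_phi_from_joint(joint: TwoTimeJoint, cap: int = DEFAULT_N_CAP) -> IIResult:
    """MIB search computed definitionally from an explicit (e.g. empirical)
    two-time joint table."""
    dist = joint.marginal_x()
    i_xy = mutual_information(joint.probs)
    rows = []
    for bp in all_bipartitions(joint.n_nodes, cap=cap):
        rows.append(
            {
                "mask_a": bp.mask_a,
                "size_a": bp.size_a,
                "phi_eff": effective_information_from_joint(joint, bp),
                "h_a": entropy(_marginal_words(dist, bp.mask_a)),
                "h_b": entropy(_marginal_words(dist, bp.mask_b)),
            }
        )
    return _assemble_ii(i_xy, rows, joint.n_nodes)
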