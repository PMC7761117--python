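"""Decoder-based integrated information Phi* via mismatched decoding.

Phi*(A|B) = I_xy - I*_xy(A|B), where I* is the information extractable by a
decoder that wrongly assumes the transition probabilities factorize across
the bipartition, q(y|x) = p(yA|xA) * p(yB|xB), maximized over a scalar
decoding exponent beta >= 0:

    I*(beta) = - sum_y p(y) log2 sum_x p(x) q(y|x)^beta
               + sum_{x,y} p(x,y) log2 q(y|x)^beta

I*(0) = 0 exactly, and I* <= I_xy (the matched decoder attains I_xy), so
Phi* is non-negative — the motivation for this variant of integrated
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .info import Bipartition, marginalize_joint, mutual_information
from .model import SpikingBurstingModel, TwoTimeJoint, two_time_joint

__all__ = [
    "MismatchError",
    "PhiStarResult",
    "mismatched_conditional",
    "i_star",
    "phi_star",
    "phi_star_from_joint",
]

#: beta search interval; the objective is 0 at beta = 0
BETA_MAX = 100.0
#: absolute tolerance of the beta refinement
BETA_TOL = 1e-8


class MismatchError(ValueError):
    """The factorized decoder is structurally incompatible with the joint."""


def mismatched_conditional(joint: TwoTimeJoint, bp: Bipartition) -> np.ndarray:
    """Factorized decoding kernel q(y|x) = p(yA|xA) * p(yB|xB).

    Rows (conditioning word x) sum to 1.  Raises :class:`MismatchError` when
    a subsystem conditioning state has zero marginal probability.
    """
    n = joint.n_nodes
    ja = marginalize_joint(joint, bp.mask_a)
    jb = marginalize_joint(joint, bp.mask_b)
    pa = ja.sum(axis=1)
    pb = jb.sum(axis=1)
    for name, marg, bits in (("A", pa, bp.nodes_a()), ("B", pb, bp.nodes_b())):
        bad = np.nonzero(marg <= 0)[0]
        if bad.size:
            raise MismatchError(
                f"subsystem {name} (nodes {bits}) state index {int(bad[0])} "
                "has zero marginal probability; conditional undefined"
            )
    cond_a = ja / pa[:, None]
    cond_b = jb / pb[:, None]

    words = np.arange(2 ** n)
    from .model import _extract_subword

    sub_a = _extract_subword(words, bp.mask_a)
    sub_b = _extract_subword(words, bp.mask_b)
    q = cond_a[np.ix_(sub_a, sub_a)] * cond_b[np.ix_(sub_b, sub_b)]
    return q


def _objective_factory(joint: TwoTimeJoint, bp: Bipartition):
    """Return I*(beta) as a callable, with the structural-mismatch check."""
    p_xy = joint.probs
    p_x = p_xy.sum(axis=1)
    p_y = p_xy.sum(axis=0)
    q = mismatched_conditional(joint, bp)
    if np.any((q <= 0) & (p_xy > 0)):
        raise MismatchError(
            "q(y|x) = 0 on a pair with p(x,y) > 0: objective diverges to -inf"
        )
    log2q = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), -np.inf)
    # second term: only pairs with p(x,y) > 0 contribute (there log2q is finite)
    support = p_xy > 0
    coef2 = float((p_xy[support] * log2q[support]).sum())

    def objective(beta: float) -> float:
        if beta == 0.0:
            return 0.0
        qb = np.where(q > 0, np.exp(beta * np.log(np.where(q > 0, q, 1.0))), 0.0)
        inner = p_x @ qb  # sum_x p(x) q(y|x)^beta, per y
        if np.any((inner <= 0.0) & (p_y > 0)):
            return -np.inf  # q^beta underflowed: true objective is far negative
        term1 = -float(np.dot(p_y[p_y > 0], np.log2(inner[p_y > 0])))
        return term1 + beta * coef2

    return objective


def i_star(joint: TwoTimeJoint, bp: Bipartition, beta_max: float = BETA_MAX):
    """Maximize the mismatched-decoding objective over beta in [0, beta_max].

    A coarse scan (log-spaced, 64 points) brackets the maximum; a bounded
    scalar search (golden-section / Brent) refines it to ``BETA_TOL`` in
    beta.  The larger of the refined and scanned values is kept, so a scan
    point can never beat the returned maximum.  Returns ``(i_star, beta)``.
    """
    objective = _objective_factory(joint, bp)
    grid = np.concatenate([[0.0], np.logspace(-3, np.log10(beta_max), 63)])
    vals = np.array([objective(b) for b in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if hi <= lo:
        hi = lo + 1e-6
    res = minimize_scalar(
        lambda b: -objective(b), bounds=(lo, hi), method="bounded",
        options={"xatol": BETA_TOL},
    )
    best_val, best_beta = float(vals[k]), float(grid[k])
    if -res.fun > best_val:
        best_val, best_beta = float(-res.fun), float(res.x)
    if best_val < 0.0:  # beta = 0 always achieves exactly 0
        best_val, best_beta = 0.0, 0.0
    return best_val, best_beta


@dataclass(frozen=True)
class PhiStarResult:
    """Decoder-based integrated information for one bipartition."""

    i_xy: float
    i_star: float
    beta_opt: float
    phi_star: float
    bipartition: Bipartition

    def to_json_dict(self) -> dict:
        return {
            "i_xy": self.i_xy,
            "i_star": self.i_star,
            "beta_opt": self.beta_opt,
            "phi_star": self.phi_star,
            "mask_a": self.bipartition.mask_a,
        }


def phi_star_from_joint(joint: TwoTimeJoint, bp: Bipartition) -> PhiStarResult:
    """Phi* = I_xy - I* from an explicit two-time joint table."""
    ixy = mutual_information(joint.probs)
    istar, beta = i_star(joint, bp)
    istar = min(istar, ixy)  # numerically enforce I* <= I_xy
    return PhiStarResult(
        i_xy=ixy, i_star=istar, beta_opt=beta,
        phi_star=max(ixy - istar, 0.0), bipartition=bp,
    )


def phi_star(model: SpikingBurstingModel, bp: Bipartition) -> PhiStarResult:
    """Phi* for a spiking-bursting model, from its exact two-time table."""
    return phi_star_from_joint(two_time_joint(model), bp)
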