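"""Sign analysis of whole-minus-sum integrated information.

Under spatially independent spiking (s_A * s_B = s1 for every bipartition),
effective information depends on the bipartition only through s = s_A:

    f(s) = i0((1-s1)ps, eps) - i0((1-s)ps, eps) - i0((1-s1/s)ps, eps),
           s1 < s < 1.

Its extremum at the symmetric point s = sqrt(s1),

    g(s1) = f(sqrt(s1)) = i0((1-s1)ps, eps) - 2*i0((1-sqrt(s1))ps, eps),

controls the sign of integrated information: g < 0 at s1 = 0, g -> +0 as
s1 -> 1, and (numerically) g changes sign exactly once, at the threshold
s1min(ps, eps).  For weak time correlations i0 collapses to
eps^2/(2 ln 2) * (p/(1-p))^2, and the threshold becomes the root of a
quadratic in sqrt(s1) with the universal ps -> 0 limit 3 - 2*sqrt(2) ~ 0.17.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .info import all_bipartitions, i0
from .model import SpikingBurstingModel, subsystem_spike_table, validate_dichotomous

__all__ = [
    "AnomalyError",
    "ThresholdCurve",
    "PositivityReport",
    "f_curve",
    "g_fn",
    "s1min_exact",
    "sign_change_counts",
    "i0_approx",
    "s1min_asymptotic",
    "positivity_conditions",
    "count_f_extrema",
    "threshold_curve",
]

LN2 = np.log(2.0)
SQRT2M1 = np.sqrt(2.0) - 1.0

#: grid step of the pre-scan that certifies a unique sign change of g
SIGN_SCAN_STEP = 1e-3
#: absolute tolerance of the bisection root
ROOT_TOL = 1e-12


class AnomalyError(RuntimeError):
    """Numerical evidence contradicts an assumed uniqueness property."""


def f_curve(s, s1: float, ps: float, eps: float):
    """Effective information as a function of the bipartition coordinate
    s = s_A, for independent spiking.  Domain s1 < s < 1; vectorized in s."""
    s = np.asarray(s, dtype=float)
    if np.any((s <= s1) | (s >= 1.0)):
        raise ValueError(f"f(s) requires s1 < s < 1 (s1={s1})")
    val = (
        i0((1.0 - s1) * ps, eps)
        - i0((1.0 - s) * ps, eps)
        - i0((1.0 - s1 / s) * ps, eps)
    )
    return val if np.ndim(val) else float(val)


def g_fn(s1, ps: float, eps: float):
    """g(s1) = i0((1-s1)ps, eps) - 2*i0((1-sqrt(s1))ps, eps): effective
    information of the symmetric bipartition s_A = s_B = sqrt(s1).

    Defined on 0 <= s1 < 1; g(0) = -i0(ps, eps) < 0.  Vectorized in s1.
    """
    s1 = np.asarray(s1, dtype=float)
    if np.any((s1 < 0.0) | (s1 >= 1.0)):
        raise ValueError("g(s1) requires 0 <= s1 < 1")
    val = i0((1.0 - s1) * ps, eps) - 2.0 * i0((1.0 - np.sqrt(s1)) * ps, eps)
    return val if np.ndim(val) else float(val)


def _scan_grid(step: float) -> np.ndarray:
    """s1 scan grid: log-spaced tail toward 0 (the threshold falls below any
    fixed linear step as ps -> 1) plus a linear sweep at ``step``."""
    return np.unique(np.concatenate([
        np.logspace(-9, np.log10(step), 61), np.arange(step, 1.0, step),
    ]))


def _scan_sign_changes(ps: float, eps: float, step: float) -> int:
    vals = g_fn(_scan_grid(step), ps, eps)
    signs = np.sign(vals)
    nz = signs[signs != 0]
    return int(np.sum(nz[1:] != nz[:-1]))


def s1min_exact(ps: float, eps: float, step: float = SIGN_SCAN_STEP) -> float:
    """Exact threshold: the unique root of g(s1) on (0, 1) by bisection.

    A grid pre-scan (step ``step``) certifies that g changes sign exactly
    once; anything else raises :class:`AnomalyError`.
    """
    validate_dichotomous(ps, eps)
    if eps == 0.0:
        raise ValueError("eps must be positive: g vanishes identically at eps=0")
    n_changes = _scan_sign_changes(ps, eps, step)
    if n_changes != 1:
        raise AnomalyError(
            f"g(s1) shows {n_changes} sign changes on (0,1) at ps={ps}, eps={eps}; "
            "expected exactly one"
        )
    grid = _scan_grid(step)
    vals = g_fn(grid, ps, eps)
    k = int(np.nonzero(np.sign(vals[1:]) != np.sign(vals[:-1]))[0][0])
    lo, hi = grid[k], grid[k + 1]
    return float(bisect(lambda s: g_fn(s, ps, eps), lo, hi, xtol=ROOT_TOL))


def sign_change_counts(ps_values, rho_values, step: float = SIGN_SCAN_STEP) -> np.ndarray:
    """Count sign changes of g(s1) on (0, 1) for every (ps, rho) pair.

    ``rho`` is converted to eps = rho * pb / ps per pair; the evaluation is
    vectorized over the (rho, s1) grid for each ps.  Returns an integer
    array of shape (len(ps_values), len(rho_values)).
    """
    ps_values = np.asarray(ps_values, dtype=float)
    rho_values = np.asarray(rho_values, dtype=float)
    s1_grid = _scan_grid(step)
    out = np.empty((ps_values.size, rho_values.size), dtype=int)
    for i, ps in enumerate(ps_values):
        eps_row = rho_values * (1.0 - ps) / ps  # shape (R,)
        p_whole = (1.0 - s1_grid)[None, :] * ps  # (1, S)
        p_half = (1.0 - np.sqrt(s1_grid))[None, :] * ps
        vals = _i0_raw(p_whole, eps_row[:, None]) - 2.0 * _i0_raw(
            p_half, eps_row[:, None]
        )
        signs = np.sign(vals)
        out[i] = np.sum(signs[:, 1:] != signs[:, :-1], axis=1)
    return out


def _i0_raw(p, eps):
    """i0 in the stable KL regrouping, no domain checks, broadcasting."""
    q = 1.0 - p
    r = p / q
    psb = np.maximum(p * q - eps * p * p, 0.0)
    pss = p * p * (1.0 + eps)
    pbb = q * q + eps * p * p
    ratio = np.minimum(eps * r, 1.0)
    mid = np.where(psb > 0, psb * np.log1p(-np.where(ratio < 1, ratio, 0.0)), 0.0)
    return (pss * np.log1p(eps) + 2 * mid + pbb * np.log1p(eps * r * r)) / LN2


# ---------------------------------------------------------------------------
# weak-correlation asymptotics
# ---------------------------------------------------------------------------

#: applicability cutoff adopted for the "|eps| << 1" condition
EPS_SMALL_CUTOFF = 0.2


def i0_approx(ps: float, eps: float) -> tuple[float, bool]:
    """Leading-order i0 for weak time correlations,

        i0(ps, eps) ~ eps^2 / (2 ln 2) * (ps / (1 - ps))^2,

    with a validity flag: |eps| <= 0.2 (our cutoff for "small") and
    ps strictly below 1/(1+|eps|).
    """
    val = eps * eps / (2.0 * LN2) * (ps / (1.0 - ps)) ** 2
    valid = (abs(eps) <= EPS_SMALL_CUTOFF) and (ps < 1.0 / (1.0 + abs(eps)))
    return float(val), bool(valid)


def s1min_asymptotic(ps) -> float:
    """Weak-correlation threshold: root in (0,1) of the quadratic in
    u = sqrt(s1),

        ps*(sqrt(2)-1)*u^2 - u + (1-ps)*(sqrt(2)-1) = 0,

    evaluated in the cancellation-free conjugate form.  Independent of eps;
    ps -> 0 limit is (sqrt(2)-1)^2 = 3 - 2*sqrt(2) ~ 0.1716.
    """
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("s1min_asymptotic requires 0 < ps < 1")
    c = SQRT2M1
    disc = 1.0 - 4.0 * ps * (1.0 - ps) * c * c
    u = 2.0 * (1.0 - ps) * c / (1.0 + np.sqrt(disc))
    val = u * u
    return val if val.ndim else float(val)


# ---------------------------------------------------------------------------
# positivity report
# ---------------------------------------------------------------------------

def count_f_extrema(s1: float, ps: float, eps: float, step: float = SIGN_SCAN_STEP) -> int:
    """Count interior extrema of f on (s1, 1) by sign changes of finite
    differences on a grid.  More than three is an anomaly (the symmetric
    extremum would then no longer control the sign of f's minimum)."""
    pad = (1.0 - s1) * step  # grid scaled to the (s1, 1) domain
    grid = np.linspace(s1 + pad, 1.0 - pad, max(int(1.0 / step), 16))
    vals = f_curve(grid, s1, ps, eps)
    d = np.diff(vals)
    sd = np.sign(d)
    sd = sd[sd != 0]
    n_ext = int(np.sum(sd[1:] != sd[:-1]))
    if n_ext > 3:
        raise AnomalyError(
            f"f(s) shows {n_ext} interior extrema at s1={s1}, ps={ps}, eps={eps}"
        )
    return n_ext


@dataclass(frozen=True)
class PositivityReport:
    """Sign verdicts for whole-minus-sum integrated information.

    mode: "exact" (spatially independent spiking — both the necessary-and-
    sufficient bipartition-minimum criterion and the sufficient g > 0
    criterion apply), "positive-correlation" (only necessary conditions
    transfer), "negative-correlation" (only sufficient conditions transfer),
    or "degenerate" (integrated information is identically 0).
    """

    mode: str
    min_f: float | None
    necessary_sufficient_positive: bool | None
    g_value: float | None
    sufficient_positive: bool | None
    symmetric_bipartition_exists: bool | None
    detail: str = ""


def positivity_conditions(model: SpikingBurstingModel, atol: float = 1e-12) -> PositivityReport:
    """Evaluate the sign conditions for positive integrated information.

    For independent spiking the minimum of f over realized bipartition
    coordinates {s_A} gives the necessary-and-sufficient verdict, g(s1) > 0
    the sufficient one; they coincide when a symmetric bipartition
    (s_A = sqrt(s1)) exists.  For spatially correlated tables only the
    directional implication that survives the correlation sign is reported.
    """
    d = model.dichotomous
    if model.is_degenerate:
        return PositivityReport(
            mode="degenerate", min_f=None, necessary_sufficient_positive=None,
            g_value=None, sufficient_positive=None,
            symmetric_bipartition_exists=None,
            detail="eps = 0 or s1 = 1: integrated information is identically 0",
        )
    s1 = model.s1
    sa_list = []
    for bp in all_bipartitions(model.n_nodes):
        sa = subsystem_spike_table(model.spikes, bp.mask_a).s1
        sb = subsystem_spike_table(model.spikes, bp.mask_b).s1
        sa_list.append((sa, sb))

    g_val = float(g_fn(s1, d.ps, d.eps))
    sufficient = g_val > 0.0

    independent = all(abs(sa * sb - s1) <= atol for sa, sb in sa_list)
    if independent:
        count_f_extrema(s1, d.ps, d.eps)
        fvals = [float(f_curve(sa, s1, d.ps, d.eps)) for sa, _ in sa_list]
        min_f = min(fvals)
        sym = any(abs(sa - np.sqrt(s1)) <= 1e-9 for sa, _ in sa_list)
        return PositivityReport(
            mode="exact", min_f=min_f, necessary_sufficient_positive=min_f > 0.0,
            g_value=g_val, sufficient_positive=sufficient,
            symmetric_bipartition_exists=sym,
            detail="independent spiking: min_f > 0 is necessary and sufficient",
        )
    if all(sa * sb <= s1 + atol for sa, sb in sa_list):
        return PositivityReport(
            mode="positive-correlation", min_f=None,
            necessary_sufficient_positive=None, g_value=g_val,
            sufficient_positive=None, symmetric_bipartition_exists=None,
            detail="s1 >= sA*sB: independent-case necessary conditions still hold; "
                   "g > 0 is no longer sufficient",
        )
    if all(sa * sb >= s1 - atol for sa, sb in sa_list):
        return PositivityReport(
            mode="negative-correlation", min_f=None,
            necessary_sufficient_positive=None, g_value=g_val,
            sufficient_positive=sufficient, symmetric_bipartition_exists=None,
            detail="s1 <= sA*sB: independent-case sufficient conditions still hold",
        )
    return PositivityReport(
        mode="mixed-correlation", min_f=None, necessary_sufficient_positive=None,
        g_value=g_val, sufficient_positive=None,
        symmetric_bipartition_exists=None,
        detail="correlation sign varies across bipartitions; no directional verdict",
    )


# ---------------------------------------------------------------------------
# threshold curves (data behind the s1min figures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdCurve:
    """s1min sampled on a (ps, eps) grid with a method tag per point."""

    table: pd.DataFrame  # columns: ps, eps, s1min, method

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def threshold_curve(ps_values, eps_values, method: str = "exact-root") -> ThresholdCurve:
    """Tabulate s1min over a parameter grid.

    method "exact-root": bisection root of g per point; "asymptotic": the
    eps-independent weak-correlation quadratic root.
    """
    rows = []
    for ps in np.atleast_1d(np.asarray(ps_values, dtype=float)):
        for eps in np.atleast_1d(np.asarray(eps_values, dtype=float)):
            if method == "exact-root":
                try:
                    validate_dichotomous(ps, eps)
                except ValueError:
                    continue
                val = s1min_exact(ps, eps)
            elif method == "asymptotic":
                val = s1min_asymptotic(ps)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"ps": ps, "eps": eps, "s1min": val, "method": method})
    return ThresholdCurve(table=pd.DataFrame(rows))
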