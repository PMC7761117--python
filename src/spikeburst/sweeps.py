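"""Figure-level parameter sweeps, written as tidy CSV tables.

Each sweep kind reproduces the data behind one family of curves:

- ``i0-vs-ps``: the universal closed form and its weak-correlation
  approximation with validity bounds, across eps values;
- ``f-vs-s``: effective information versus the bipartition coordinate
  at several spiking intensities;
- ``s1min-vs-ps`` / ``s1min-vs-eps``: the positivity threshold, exact and
  asymptotic;
- ``phi-vs-s1``: whole-minus-sum and decoder-based effective information on
  the symmetric 3|3 bipartition of the 6-node equal-rate model, raw and
  scaled by eps^2.

Deterministic: re-running a spec yields byte-identical CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import f_curve, i0_approx, s1min_asymptotic, s1min_exact
from .decoder import phi_star
from .info import Bipartition, effective_information, i0
from .model import (
    SpikingBurstingModel,
    independent_spike_table,
    validate_dichotomous,
)

__all__ = ["SweepSpec", "run_sweep", "symmetric_six_node_model", "default_s1_grid"]

SWEEP_KINDS = ("i0-vs-ps", "f-vs-s", "s1min-vs-ps", "s1min-vs-eps", "phi-vs-s1")


def default_s1_grid(n_log: int = 25, n_lin: int = 25) -> np.ndarray:
    """s1 grid logarithmic near 0 and linear near 1, resolving the sign
    transition region around ~0.1."""
    lo = np.logspace(-3, np.log10(0.5), n_log, endpoint=False)
    hi = np.linspace(0.5, 0.99, n_lin)
    return np.unique(np.concatenate([lo, hi]))


def symmetric_six_node_model(s1: float, ps: float, eps: float) -> SpikingBurstingModel:
    """6-node model with equal per-node rate P = s1^(1/6) (independent
    spiking), the configuration used for the measure comparison."""
    p = s1 ** (1.0 / 6.0)
    return SpikingBurstingModel(
        spikes=independent_spike_table([p] * 6),
        dichotomous=validate_dichotomous(ps, eps),
    )


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of one sweep."""

    kind: str
    fixed: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    out: str | None = None

    def __post_init__(self):
        if self.kind not in SWEEP_KINDS:
            raise ValueError(f"unknown sweep kind {self.kind!r}; choose from {SWEEP_KINDS}")


def _sweep_i0_vs_ps(spec: SweepSpec) -> pd.DataFrame:
    eps_values = np.atleast_1d(spec.fixed.get("eps", [0.01, 0.1, 0.2, 0.5, 1.0]))
    n = int(spec.grid.get("n_ps", 200))
    rows = []
    for eps in eps_values:
        ps_max = 1.0 / (1.0 + eps)
        ps_grid = np.linspace(ps_max / n, ps_max * (1 - 1e-9), n)
        for ps in ps_grid:
            approx, valid = i0_approx(ps, eps)
            rows.append(
                {"eps": eps, "ps": ps, "i0": float(i0(ps, eps)),
                 "i0_approx": approx, "approx_valid": valid,
                 "ps_validity_bound": 1.0 / (1.0 + abs(eps))}
            )
    return pd.DataFrame(rows)


def _sweep_f_vs_s(spec: SweepSpec) -> pd.DataFrame:
    ps = float(spec.fixed.get("ps", 0.7))
    eps = float(spec.fixed.get("eps", 0.1))
    s1_values = np.atleast_1d(spec.fixed.get("s1", [0.05, 0.02, 0.0131, 0.005]))
    n = int(spec.grid.get("n_s", 400))
    rows = []
    for s1 in s1_values:
        s_grid = np.linspace(s1 + (1 - s1) / n, 1.0 - (1 - s1) / n, n)
        f_vals = f_curve(s_grid, s1, ps, eps)
        s_sym = np.sqrt(s1)
        for s, f in zip(s_grid, f_vals):
            rows.append({"s1": s1, "ps": ps, "eps": eps, "s": s, "f": f,
                         "is_symmetric_point": False})
        rows.append({"s1": s1, "ps": ps, "eps": eps, "s": s_sym,
                     "f": float(f_curve(s_sym, s1, ps, eps)),
                     "is_symmetric_point": True})
    return pd.DataFrame(rows).sort_values(["s1", "s"]).reset_index(drop=True)


def _sweep_s1min_vs_ps(spec: SweepSpec) -> pd.DataFrame:
    eps_values = np.atleast_1d(spec.fixed.get("eps", [0.1, 0.5, 1.0]))
    n = int(spec.grid.get("n_ps", 50))
    rows = []
    for eps in eps_values:
        ps_max = 1.0 / (1.0 + eps)
        for ps in np.linspace(0.02, ps_max - 1e-6, n):
            rows.append({"eps": eps, "ps": ps,
                         "s1min_exact": s1min_exact(ps, eps),
                         "s1min_asymptotic": float(s1min_asymptotic(ps))})
    return pd.DataFrame(rows)


def _sweep_s1min_vs_eps(spec: SweepSpec) -> pd.DataFrame:
    ps_values = np.atleast_1d(spec.fixed.get("ps", [0.5, 0.6, 0.7]))
    n = int(spec.grid.get("n_eps", 50))
    rows = []
    for ps in ps_values:
        eps_max = (1.0 - ps) / ps
        for eps in np.linspace(eps_max / n, eps_max * (1 - 1e-9), n):
            rows.append({"ps": ps, "eps": eps,
                         "s1min_exact": s1min_exact(ps, eps),
                         "s1min_asymptotic": float(s1min_asymptotic(ps))})
    return pd.DataFrame(rows)


def _sweep_phi_vs_s1(spec: SweepSpec) -> pd.DataFrame:
    ps = float(spec.fixed.get("ps", 0.6))
    eps_values = np.atleast_1d(spec.fixed.get("eps", [0.05, 0.1, 0.2]))
    s1_grid = spec.grid.get("s1")
    s1_grid = default_s1_grid() if s1_grid is None else np.asarray(s1_grid, float)
    bp = Bipartition(6, 0b000111)
    rows = []
    for eps in eps_values:
        s1min = float(s1min_asymptotic(ps))
        for s1 in s1_grid:
            model = symmetric_six_node_model(s1, ps, eps)
            phi_eff = effective_information(model, bp)
            star = phi_star(model, bp)
            rows.append(
                {"ps": ps, "eps": eps, "s1": s1, "phi_eff": phi_eff,
                 "phi_star": star.phi_star, "i_xy": star.i_xy,
                 "phi_eff_per_eps2": phi_eff / eps ** 2,
                 "phi_star_per_eps2": star.phi_star / eps ** 2,
                 "s1min_asymptotic": s1min}
            )
    return pd.DataFrame(rows)


_DISPATCH = {
    "i0-vs-ps": _sweep_i0_vs_ps,
    "f-vs-s": _sweep_f_vs_s,
    "s1min-vs-ps": _sweep_s1min_vs_ps,
    "s1min-vs-eps": _sweep_s1min_vs_eps,
    "phi-vs-s1": _sweep_phi_vs_s1,
}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run a sweep; write CSV when ``spec.out`` is set; return the table."""
    df = _DISPATCH[spec.kind](spec)
    if spec.out is not None:
        Path(spec.out).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(spec.out, index=False)
    return df
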