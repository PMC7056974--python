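"""Expected pairwise diversity around hard and soft sweeps.

The headline predictions, all expressed relative to the no-sweep baseline
pi0:

* standing variation (and de novo via the effective start p0A):
      E[pi_SV / pi0] = P_R_sw + P_NE * P_R_sd
* star-like closed form (no coalescence during the sweep phase):
      E_SL[pi_SV / pi0] = 1 - P_C_sd * [Hl/Hh (1/p0 + 1) - 1]^(-2 r_eff/(Hl s))
* recurrent mutation (no standing phase; escape also by mutation):
      E[pi_M / pi0] = P_R_sw + P_M_sw + P_NE * P_M_sd
* the crossover distance below which recurrent-mutation sweeps retain more
  diversity than standing-variation sweeps:
      R_lim ~ Theta_b / (p0 (1 - F)).

The star-like form systematically overestimates the full prediction because
it drops sweep-phase coalescence; it is exposed as a labelled approximation,
never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .params import LocusPair, PopulationConfig, SelectionConfig
from .trajectory import effective_start_frequency
from .events import (
    p_mutation_origin,
    p_recombination_standing,
    sweep_phase_probabilities,
)

__all__ = [
    "SweepScenario",
    "DiversityCurve",
    "expected_diversity_standing",
    "expected_diversity_starlike",
    "expected_diversity_recurrent",
    "r_lim",
    "diversity_curve",
]

# The analytic ratios contain (1 - sigma)-like factors; exactly sigma = 1 is
# allowed in params but clamped here to avoid 0/0 in the effective-rate ratios.
SIGMA_MAX = 1.0 - 1e-6


@dataclass(frozen=True)
class SweepScenario:
    """Origin of the swept allele.

    ``de_novo``   — single copy; the model substitutes p0A for 1/(2N).
    ``standing``  — previously neutral variant standing at frequency ``p0``.
    ``recurrent`` — repeated mutation at scaled rate ``theta_b`` = 2 N mu_b.
    """

    origin: Literal["de_novo", "standing", "recurrent"]
    p0: float | None = None
    theta_b: float | None = None

    def __post_init__(self) -> None:
        if self.origin == "standing":
            if self.p0 is None or not 0.0 < self.p0 < 1.0:
                raise ValueError("standing scenario needs p0 in (0, 1)")
            if self.theta_b is not None:
                raise ValueError("theta_b is only meaningful for recurrent scenarios")
        elif self.origin == "recurrent":
            if self.theta_b is None or self.theta_b <= 0:
                raise ValueError("recurrent scenario needs theta_b > 0")
            if self.p0 is not None:
                raise ValueError("p0 is only meaningful for standing scenarios")
        elif self.origin == "de_novo":
            if self.p0 is not None or self.theta_b is not None:
                raise ValueError("de_novo scenario takes no p0 or theta_b")
        else:
            raise ValueError(f"unknown sweep origin {self.origin!r}")


def _clamp_sigma(pop: PopulationConfig, pair: LocusPair):
    if pop.sigma > SIGMA_MAX:
        pop = PopulationConfig(N=pop.N, sigma=SIGMA_MAX)
        pair = LocusPair(r=pair.r, N=pair.N, sigma=SIGMA_MAX)
    return pop, pair


def expected_diversity_standing(pop: PopulationConfig, sel: SelectionConfig,
                                pair: LocusPair, p0: float | None = None) -> float:
    """E[pi_SV/pi0] after a sweep from standing variation (or de novo if p0=None).

    With ``p0 is None`` the de novo effective start p0A is used, so the same
    expression covers hard sweeps.
    """
    pop, pair = _clamp_sigma(pop, pair)
    if p0 is None:
        p0 = effective_start_frequency(pop, sel)
    if pair.r == 0.0:
        return 0.0
    ph = sweep_phase_probabilities(pop, sel, pair, p_lower=p0)
    prsd = p_recombination_standing(pop, pair, p0)
    return float(ph.P_R_sw + ph.P_NE * prsd)


def expected_diversity_starlike(pop: PopulationConfig, sel: SelectionConfig,
                                pair: LocusPair, p0: float | None = None) -> float:
    """Star-like closed form for E[pi_SV/pi0]; an upper bound on the full value."""
    pop, pair = _clamp_sigma(pop, pair)
    if p0 is None:
        p0 = effective_start_frequency(pop, sel)
    if pair.r == 0.0:
        return 0.0
    x = 4.0 * pop.N * pair.r_eff * p0 * (1.0 - p0) / (1.0 + pop.F)
    pc_sd = 1.0 / (1.0 + x)
    base = (sel.Hl / sel.Hh) * (1.0 / p0 + 1.0) - 1.0
    expo = -2.0 * pair.r_eff / (sel.Hl * sel.s)
    return float(1.0 - pc_sd * base ** expo)


def expected_diversity_recurrent(pop: PopulationConfig, sel: SelectionConfig,
                                 pair: LocusPair, theta_b: float) -> float:
    """E[pi_M/pi0] after a soft sweep fed by recurrent mutation at rate theta_b."""
    if theta_b <= 0:
        raise ValueError(f"theta_b must be positive, got {theta_b}")
    pop, pair = _clamp_sigma(pop, pair)
    mu_b = theta_b / (2.0 * pop.N)
    p0a = effective_start_frequency(pop, sel)
    ph = sweep_phase_probabilities(pop, sel, pair, p_lower=p0a, mu_b=mu_b)
    pmsd = p_mutation_origin(pop, mu_b, p0a)
    return float(ph.P_R_sw + ph.P_M_sw + ph.P_NE * pmsd)


def r_lim(pop: PopulationConfig, theta_b: float, p0: float) -> float:
    """Crossover distance R_lim ~ Theta_b / (p0 (1 - F)).

    Below R_lim a recurrent-mutation sweep leaves more diversity than a
    standing sweep from p0; above, the standing sweep does.  Uses the
    Phi ~ F approximation, matching how the quantity is usually plotted.
    """
    if theta_b <= 0 or not 0.0 < p0 < 1.0:
        raise ValueError("need theta_b > 0 and p0 in (0, 1)")
    if pop.sigma >= 1.0:
        raise ValueError("R_lim diverges at sigma = 1 (1 - F = 0)")
    return theta_b / (p0 * (1.0 - pop.F))


@dataclass(frozen=True)
class DiversityCurve:
    """E[pi/pi0] on a grid of scaled recombination distances R = 2Nr."""

    R_grid: np.ndarray
    values: np.ndarray
    scenario: SweepScenario
    pop: PopulationConfig
    sel: SelectionConfig
    starlike: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        p0_or_thetab = (
            self.scenario.theta_b if self.scenario.origin == "recurrent"
            else self.scenario.p0
        )
        df = pd.DataFrame({
            "scenario": self.scenario.origin,
            "sigma": self.pop.sigma,
            "h": self.sel.h,
            "s": self.sel.s,
            "N": self.pop.N,
            "p0_or_thetab": p0_or_thetab,
            "R": self.R_grid,
            "expected_relative_diversity": self.values,
        })
        if self.starlike is not None:
            df["starlike_relative_diversity"] = self.starlike
        return df


def diversity_curve(pop: PopulationConfig, sel: SelectionConfig,
                    scenario: SweepScenario, R_grid,
                    include_starlike: bool = False) -> DiversityCurve:
    """Evaluate the scenario's expected relative diversity over an R grid."""
    R_grid = np.asarray(R_grid, dtype=float)
    if R_grid.ndim != 1 or np.any(R_grid < 0) or np.any(np.diff(R_grid) < 0):
        raise ValueError("R_grid must be a sorted 1-D array of non-negative values")
    values = np.empty_like(R_grid)
    star = np.empty_like(R_grid) if include_starlike else None
    for i, R in enumerate(R_grid):
        pair = LocusPair.from_scaled(R, pop.N, pop.sigma)
        if scenario.origin == "recurrent":
            values[i] = expected_diversity_recurrent(pop, sel, pair, scenario.theta_b)
        else:
            p0 = scenario.p0 if scenario.origin == "standing" else None
            values[i] = expected_diversity_standing(pop, sel, pair, p0)
        if include_starlike:
            if scenario.origin == "recurrent":
                raise ValueError("the star-like closed form applies to standing/de-novo sweeps only")
            p0 = scenario.p0 if scenario.origin == "standing" else None
            star[i] = expected_diversity_starlike(pop, sel, pair, p0)
    return DiversityCurve(R_grid=R_grid, values=values, scenario=scenario,
                          pop=pop, sel=sel, starlike=star)
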