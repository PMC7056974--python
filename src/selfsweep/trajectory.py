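"""Deterministic trajectory of a beneficial allele under dominance and selfing.

Backward in time the allele frequency obeys

    dp/dt = -s p (1-p) (Hl + (1-F)(1-2h) p),      Hl = F + h - Fh,

so the bracket interpolates between the low-frequency effective dominance Hl
at p=0 and the high-frequency one Hh = 1 - h + Fh at p=1 (Hl + (1-F)(1-2h)
equals Hh).  The deterministic phase is bracketed by an effective starting
frequency p0A = (1+F)/(4NsHl) — which absorbs the conditioned stochastic
acceleration of a fixing de novo mutation — and an effective final frequency
1 - eps with eps = (1+F)/(4NsHh).

All sweep-phase probability integrals downstream are taken in frequency
space, dividing hazards by |dp/dt|; the explicit time grid is reconstructed
here only for plotting and for seeding the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .params import PopulationConfig, SelectionConfig

__all__ = [
    "Trajectory",
    "dp_dt",
    "selection_bracket",
    "effective_start_frequency",
    "effective_final_epsilon",
    "sojourn_time",
    "solve_trajectory",
]

# h is kept off the exact boundaries in the analytic model: Eq-9-style
# integrals are undefined at h in {0,1} with sigma=0.  The simulator has no
# such restriction.
H_MIN = 1e-3
H_MAX = 1.0 - 1e-3


def selection_bracket(p: float | np.ndarray, h: float, F: float):
    """The dominance bracket Hl + (1-F)(1-2h)p of the trajectory ODE."""
    Hl = F + h - F * h
    return Hl + (1.0 - F) * (1.0 - 2.0 * h) * p


def dp_dt(p, s: float, h: float, F: float):
    """Backward-time derivative of the beneficial allele frequency.

    Negative on (0,1) for s > 0; the forward-time rate is its negation.
    Accepts scalars or arrays.
    """
    return -s * p * (1.0 - p) * selection_bracket(p, h, F)


def effective_start_frequency(pop: PopulationConfig, sel: SelectionConfig) -> float:
    """Effective starting frequency p0A = (1+F)/(4NsHl) of a fixing de novo allele.

    Used in place of 1/(2N) whenever a scenario starts from a single copy:
    mutations destined to fix rise faster than the deterministic rate while
    rare, which is equivalent to starting the deterministic path higher.
    """
    p0a = (1.0 + pop.F) / (4.0 * pop.N * sel.s * sel.Hl)
    if p0a >= 1.0:
        raise ValueError(
            f"effective starting frequency {p0a:.3g} >= 1; "
            "N*s*Hl is too small for the deterministic sweep model"
        )
    if pop.N * sel.s * sel.Hl < 10.0:
        warnings.warn(
            "N*s*Hl < 10: the deterministic-trajectory approximation is dubious",
            stacklevel=2,
        )
    return p0a


def effective_final_epsilon(pop: PopulationConfig, sel: SelectionConfig) -> float:
    """Effective final distance eps = (1+F)/(4NsHh); the sweep ends at 1 - eps.

    Obtained from p0A by swapping the low-frequency effective dominance for
    the high-frequency one (an allele rising with dominance h finishes like
    one declining with dominance 1-h).  This endpoint is used for every
    scenario, including standing variation with p0 > 1/(2N).
    """
    eps = (1.0 + pop.F) / (4.0 * pop.N * sel.s * sel.Hh)
    if eps >= 1.0:
        raise ValueError(
            f"effective final epsilon {eps:.3g} >= 1; N*s*Hh too small"
        )
    return eps


def sojourn_time(sel: SelectionConfig, p_start: float, p_end: float,
                 F: float | None = None) -> float:
    """Deterministic sojourn time (generations) to go from p_start to p_end.

    Computed as the quadrature tau = int_{p_start}^{p_end} dp / |dp/dt|.
    The integrand behaves like 1/(s Hl p) near 0 and 1/(s Hh (1-p)) near 1,
    so endpoints must be strictly inside (0, 1).
    """
    F = sel.F if F is None else F
    if not (0.0 < p_start < p_end < 1.0):
        raise ValueError(
            f"need 0 < p_start < p_end < 1, got ({p_start}, {p_end})"
        )

    def integrand(p: float) -> float:
        return 1.0 / (-dp_dt(p, sel.s, sel.h, F))

    tau, _ = integrate.quad(integrand, p_start, p_end, epsabs=1e-10, epsrel=1e-8,
                            limit=200)
    return tau


@dataclass(frozen=True)
class Trajectory:
    """A solved deterministic sweep path.

    ``times`` counts generations before the end of the deterministic phase
    (time 0 is frequency ``p_end``; time ``tau`` is ``p_start``), matching the
    backward-time convention of the sweep-phase integrals.
    """

    p_start: float
    p_end: float
    times: np.ndarray
    freqs: np.ndarray
    tau: float

    def frequency_forward(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, p) with t running forward from onset (p_start) to fixation edge."""
        return self.tau - self.times[::-1], self.freqs[::-1]


def solve_trajectory(pop: PopulationConfig, sel: SelectionConfig,
                     p_start: float, p_end: float,
                     n_points: int = 512) -> Trajectory:
    """Integrate the trajectory ODE backward from p_end down to p_start.

    Returns the path on a time grid together with the sojourn time.  The ODE
    solution is cross-checkable against :func:`sojourn_time` (they agree to
    ~1e-6 relative, tested).
    """
    if not (0.0 < p_start < p_end < 1.0):
        raise ValueError("trajectory endpoints must satisfy 0 < p_start < p_end < 1")
    tau = sojourn_time(sel, p_start, p_end, F=pop.F)

    def rhs(t, y):
        return dp_dt(y[0], sel.s, sel.h, pop.F)

    # integrate backward in time from p_end (t=0) for exactly tau generations;
    # the rate is regular on [p_start, p_end] so no event handling is needed
    t_grid = np.linspace(0.0, tau, n_points)
    sol = integrate.solve_ivp(
        rhs, (0.0, tau), [p_end], t_eval=t_grid,
        method="DOP853", rtol=1e-10, atol=1e-13,
    )
    return Trajectory(p_start=p_start, p_end=p_end, times=sol.t, freqs=sol.y[0],
                      tau=tau)
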