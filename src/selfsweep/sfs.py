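"""Post-sweep site-frequency spectrum under the star-like approximation.

Construction (a soft-sweep star-like genealogy, per-lineage escape):

1. Each of the n sampled lineages independently escapes the derived
   background with probability ``P_esc`` — by recombination during the sweep
   phase, by recombination during the standing phase (standing / de novo
   origins), or by recombination or recurrent mutation (recurrent origin).
   Per-lineage probabilities are taken as the single-lineage analogues of the
   pairwise phase probabilities: the sweep-phase escape hazard is half the
   pairwise one, and the standing/origin retention is the square root of the
   pairwise coalescence probability, so that for n = 2 the monomorphic mass
   reproduces the star-like pairwise diversity closed form exactly.
2. Lineages that never escape coalesce star-like into a single ancestral
   lineage at the sweep origin.  Conditional on k escapees, the sample is
   represented by m = k + 1 exchangeable ancestral lineages (the star clade
   carries multiplicity n - k) whose deeper genealogy is the neutral
   coalescent: a mutation subtends i of m ancestors with weight 1/i, the
   subtended subset uniform — mapping multiplicities back to derived counts
   l among the n samples.  Binomial mixing over k yields the spectrum.
3. An adjusted singleton class adds the mutations that arise on the derived
   background during the sweep and standing phases (ignored for pairwise
   diversity, visible in the SFS): theta/2 times the expected derived-lineage
   branch length, all assigned to l = 1 before renormalization.

The derived-allele polarity is assumed known (unfolded spectrum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .params import LocusPair, PopulationConfig, SelectionConfig
from .trajectory import dp_dt, effective_final_epsilon, effective_start_frequency
from .diversity import SweepScenario, _clamp_sigma
from .events import p_mutation_origin, p_recombination_standing

__all__ = ["SFSResult", "neutral_sfs", "sweep_sfs", "relative_segregating_sites"]


@dataclass(frozen=True)
class SFSResult:
    """Site-frequency spectrum over derived-allele counts l = 1..n-1.

    ``probs[l-1]`` is the probability that a polymorphic site shows l derived
    copies among n haplotypes.  ``singleton_adjustment`` is the extra l = 1
    weight (in units of theta) from derived-background mutations, and
    ``seg_sites_rel`` the expected number of segregating sites relative to
    the neutral expectation theta * a_{n-1}.
    """

    n: int
    probs: np.ndarray
    singleton_adjustment: float = 0.0
    seg_sites_rel: float = 1.0
    escape_probability: float = 1.0


def _harmonic(m: int) -> float:
    return sum(1.0 / j for j in range(1, m + 1))


def neutral_sfs(n: int) -> SFSResult:
    """Equilibrium neutral spectrum: probs[l] proportional to 1/l."""
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    w = 1.0 / np.arange(1, n)
    return SFSResult(n=n, probs=w / w.sum())


def _per_lineage_quantities(pop, sel, pair, scenario, n):
    """Per-lineage escape probability and derived-background dwell time.

    Returns (P_esc, dwell_weight) with dwell_weight in units of theta (i.e.
    expected derived-branch generations summed over the n lineages, divided
    by 4Ne).
    """
    eps = effective_final_epsilon(pop, sel)
    p_upper = 1.0 - eps
    if scenario.origin == "recurrent":
        p_lower = effective_start_frequency(pop, sel)
        mu_b = scenario.theta_b / (2.0 * pop.N)
    else:
        p_lower = (scenario.p0 if scenario.origin == "standing"
                   else effective_start_frequency(pop, sel))
        mu_b = 0.0
    if p_lower >= p_upper:
        raise ValueError("sweep endpoints collapsed; check p0 against 1 - eps")

    s, h, F = sel.s, sel.h, pop.F

    def rhs(p, y):
        g = -dp_dt(p, s, h, F)
        haz1 = pair.r_eff * (1.0 - p) + mu_b * (1.0 - p) / p
        surv = np.exp(-y[0])
        return [-haz1 / g, -surv / g]

    sol = integrate.solve_ivp(rhs, (p_upper, p_lower), [0.0, 0.0],
                              method="DOP853", rtol=1e-10, atol=1e-12)
    lam1, dwell_sw = sol.y[:, -1]
    q_sw = math.exp(-lam1)  # P(lineage still on derived background at origin)

    # origin / standing phase: per-lineage retention = sqrt of the pairwise
    # coalescence probability (exact n=2 consistency with the star-like
    # pairwise closed form)
    rate_c = (1.0 + F) / (2.0 * pop.N * p_lower)
    if scenario.origin == "recurrent":
        p_keep_pair = 1.0 - p_mutation_origin(pop, mu_b, p_lower)
        rate_out = mu_b * (1.0 - p_lower) / p_lower
    else:
        p_keep_pair = 1.0 - p_recombination_standing(pop, pair, p_lower)
        rate_out = pair.r_eff * (1.0 - p_lower)
    q_origin = math.sqrt(p_keep_pair)
    p_esc = 1.0 - q_sw * q_origin

    dwell_sd = q_sw / (rate_c + rate_out) if (rate_c + rate_out) > 0 else 0.0
    dwell_weight = n * (dwell_sw + dwell_sd) / (4.0 * pop.Ne)
    return p_esc, dwell_weight


def _starlike_escape_probability(pop, sel, pair, p0: float) -> float:
    """Per-lineage escape using the printed star-like closed forms.

    Kept consistent with the pairwise star-like diversity: per-lineage
    sweep-phase survival is the square root of the pairwise star-like P_NE
    and standing retention the square root of the pairwise P_C_sd.
    """
    x = 4.0 * pop.N * pair.r_eff * p0 * (1.0 - p0) / (1.0 + pop.F)
    pc_sd = 1.0 / (1.0 + x)
    base = (sel.Hl / sel.Hh) * (1.0 / p0 + 1.0) - 1.0
    q_sw = base ** (-pair.r_eff / (sel.Hl * sel.s))
    return 1.0 - q_sw * math.sqrt(pc_sd)


def _class_weights(n: int, p_esc: float) -> tuple[np.ndarray, float]:
    """Mix completion-genealogy mutation weights over the escape count.

    Returns (weights over l = 1..n-1 in units of theta, expected total
    weight of segregating sites from the completion genealogy).
    """
    w = np.zeros(n - 1)
    total = 0.0
    for k in range(n + 1):
        bk = math.comb(n, k) * p_esc ** k * (1.0 - p_esc) ** (n - k)
        if k == 0:
            continue  # single star root: no completion polymorphism
        if k == n:
            for l in range(1, n):
                w[l - 1] += bk / l
            total += bk * _harmonic(n - 1)
            continue
        m = k + 1
        c = n - k  # clade multiplicity
        for i in range(1, m):
            # weight 1/i split between subsets containing the clade (l = c+i-1)
            # and subsets of singletons only (l = i)
            with_clade = i / m
            l1 = c + i - 1
            if 1 <= l1 <= n - 1:
                w[l1 - 1] += bk * with_clade / i
            if 1 <= i <= n - 1:
                w[i - 1] += bk * (1.0 - with_clade) / i
        total += bk * _harmonic(m - 1)
    return w, total


def sweep_sfs(pop: PopulationConfig, sel: SelectionConfig, pair: LocusPair,
              scenario: SweepScenario, n: int,
              singleton_adjustment: bool = True) -> SFSResult:
    """Expected unfolded SFS at a linked neutral site right after fixation.

    Star-like regime: intended for modest sample sizes (n up to ~20).
    """
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    pop, pair = _clamp_sigma(pop, pair)
    p_esc, dwell_weight = _per_lineage_quantities(pop, sel, pair, scenario, n)
    if scenario.origin != "recurrent":
        # use the printed star-like closed forms so the n = 2 monomorphic
        # mass reproduces the pairwise star-like diversity to machine precision
        p0 = (scenario.p0 if scenario.origin == "standing"
              else effective_start_frequency(pop, sel))
        p_esc = _starlike_escape_probability(pop, sel, pair, p0)
    w, total = _class_weights(n, p_esc)
    adj = dwell_weight if singleton_adjustment else 0.0
    w[0] += adj
    total += adj
    if total <= 0:
        # fully monomorphic limit (R = 0, no adjustment): degenerate all-singleton
        probs = np.zeros(n - 1)
        probs[0] = 1.0
    else:
        probs = w / w.sum()
    return SFSResult(
        n=n, probs=probs, singleton_adjustment=adj,
        seg_sites_rel=total / _harmonic(n - 1),
        escape_probability=p_esc,
    )


def relative_segregating_sites(pop: PopulationConfig, sel: SelectionConfig,
                               pair: LocusPair, scenario: SweepScenario,
                               n: int, singleton_adjustment: bool = True) -> float:
    """Expected segregating sites after the sweep over the neutral theta*a_{n-1}."""
    return sweep_sfs(pop, sel, pair, scenario, n,
                     singleton_adjustment=singleton_adjustment).seg_sites_rel
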