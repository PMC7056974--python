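"""Independent brute-force oracles used by the test suite.

The two-lineage oracle re-implements, from scratch, the discrete-generation
competing-risks chain that the sweep-phase integrals approximate: walk the
deterministic trajectory one generation at a time and apply the
per-generation pairwise probabilities of coalescence, recombination and
recurrent mutation.  Monte-Carlo passes sample the chain by inverse-CDF on
the per-generation survival products — mathematically identical to stepping
each replicate generation by generation, at a fraction of the cost.

Nothing here calls the package's integral machinery; only the printed
closed-form ingredients (F, Phi, Hl/Hh, the trajectory ODE) are restated.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def _inbreeding(sigma):
    return sigma / (2.0 - sigma)


def _phi(sigma, r):
    q = 2.0 * (1.0 - r) * r
    return (sigma * (2.0 - sigma - q * (2.0 - 3.0 * sigma))
            / ((2.0 - sigma) * (2.0 - (1.0 - q) * sigma)))


def per_generation_path(N, sigma, s, h, p_lower):
    """Deterministic allele-frequency path, one value per generation.

    Returned backward in time: index 0 is the fixation edge 1 - eps, the
    last index is p_lower.
    """
    F = _inbreeding(sigma)
    Hl = F + h - F * h
    Hh = 1.0 - h + F * h
    eps = (1.0 + F) / (4.0 * N * s * Hh)
    p_upper = 1.0 - eps

    def fwd(t, y):
        p = y[0]
        return s * p * (1.0 - p) * (Hl + (1.0 - F) * (1.0 - 2.0 * h) * p)

    def reached(t, y):
        return y[0] - p_upper
    reached.terminal = True
    reached.direction = 1

    sol = integrate.solve_ivp(fwd, (0.0, 1e7), [p_lower], events=reached,
                              dense_output=True, rtol=1e-10, atol=1e-12,
                              method="RK45")
    tau = sol.t_events[0][0]
    tgrid = np.arange(0.0, tau + 1.0)
    path_fwd = sol.sol(tgrid)[0]
    return path_fwd[::-1].copy()


def two_lineage_mc(N, sigma, s, h, r, p_lower, mu_b, M, rng):
    """Monte-Carlo estimate of (P_NE, P_R_sw) with standard errors.

    M stochastic two-lineage passes along the discretized trajectory,
    applying per generation Pc = (1+F)/(2Np), Pr = 2 r_eff (1-p),
    Pm = 2 mu_b (1-p)/p.
    """
    F = _inbreeding(sigma)
    r_eff = r * (1.0 - 2.0 * F + _phi(sigma, r))
    path = per_generation_path(N, sigma, s, h, p_lower)

    pc = (1.0 + F) / (2.0 * N * path)
    pr = 2.0 * r_eff * (1.0 - path)
    pm = 2.0 * mu_b * (1.0 - path) / path
    ptot = np.clip(pc + pr + pm, 0.0, 1.0)

    # survival products: surv[k] = P(no event in the first k generations)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - ptot)])
    u = rng.random(M)
    # inverse CDF of the event generation: first k with surv[k+1] < u
    k = np.searchsorted(-surv, -u, side="right") - 1
    no_event = k >= len(ptot)
    k_event = np.minimum(k, len(ptot) - 1)
    # event type conditional on the generation
    cond_r = pr[k_event] / ptot[k_event]
    recomb = (~no_event) & (rng.random(M) < cond_r)

    p_ne = no_event.mean()
    p_r = recomb.mean()
    se = lambda p: math.sqrt(max(p * (1 - p), 1e-12) / M)
    return p_ne, se(p_ne), p_r, se(p_r)
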