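"""Population, selection, and two-locus parameters under partial selfing.

Self-fertilization at rate sigma induces Wright's inbreeding coefficient
F = sigma/(2 - sigma) at equilibrium.  Inbreeding rescales the machinery a
sweep model runs on: the effective population size drops to Ne = N/(1+F),
and the effective recombination rate between a selected and a linked neutral
locus drops to r_eff = r(1 - 2F + Phi), where Phi is the joint probability
of identity-by-descent at both loci.  Everything downstream (trajectories,
event probabilities, diversity, SFS, simulation) consumes these scalings
through the three dataclasses defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PopulationConfig",
    "SelectionConfig",
    "LocusPair",
    "inbreeding_coefficient",
    "joint_ibd_phi",
    "effective_recombination",
]


def inbreeding_coefficient(sigma: float) -> float:
    """Equilibrium inbreeding coefficient F = sigma / (2 - sigma).

    Parameters
    ----------
    sigma : float
        Selfing rate, the probability that an offspring is produced by
        self-fertilization.  Must lie in [0, 1].
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"selfing rate sigma must be in [0, 1], got {sigma}")
    return sigma / (2.0 - sigma)


def joint_ibd_phi(sigma: float, r: float) -> float:
    """Joint two-locus identity-by-descent probability Phi.

    Phi = sigma(2 - sigma - 2(1-r)r(2-3 sigma))
          / [(2 - sigma)(2 - (1 - 2(1-r)r) sigma)]

    At r = 0 this reduces to F, and at sigma = 0 it vanishes.  Phi feeds the
    effective recombination factor 1 - 2F + Phi, which is approximately 1 - F
    unless sigma is close to one and r is large (roughly r > 0.1).
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"selfing rate sigma must be in [0, 1], got {sigma}")
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction r must be in [0, 0.5], got {r}")
    q = 2.0 * (1.0 - r) * r
    num = sigma * (2.0 - sigma - q * (2.0 - 3.0 * sigma))
    den = (2.0 - sigma) * (2.0 - (1.0 - q) * sigma)
    return num / den


def effective_recombination(r: float, sigma: float) -> float:
    """Effective recombination rate r_eff = r (1 - 2F + Phi) under selfing."""
    F = inbreeding_coefficient(sigma)
    phi = joint_ibd_phi(sigma, r)
    return r * (1.0 - 2.0 * F + phi)


@dataclass(frozen=True)
class PopulationConfig:
    """Census size and mating system, with derived coalescent scalings.

    Attributes
    ----------
    N : int
        Diploid census size (2N haplotypes).
    sigma : float
        Selfing rate in [0, 1].
    F : float
        Derived: Wright's inbreeding coefficient sigma/(2-sigma).
    Ne : float
        Derived: effective size N/(1+F), in [N/2, N].
    """

    N: int
    sigma: float = 0.0
    F: float = field(init=False)
    Ne: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"population size N must be positive, got {self.N}")
        F = inbreeding_coefficient(self.sigma)  # validates sigma
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "Ne", self.N / (1.0 + F))


@dataclass(frozen=True)
class SelectionConfig:
    """Selection and dominance of the beneficial allele.

    Fitnesses at the selected locus are 1 : 1 + hs : 1 + s.  Under partial
    selfing the allele experiences an effective dominance Hl = F + h - Fh
    while rare and Hh = 1 - h + Fh while common; both collapse to 1 at full
    selfing (F = 1) and to h, 1-h in outcrossers.

    ``F`` must be supplied (take it from a :class:`PopulationConfig`) so the
    derived coefficients are fixed at construction.
    """

    s: float
    h: float
    F: float = 0.0
    Hl: float = field(init=False)
    Hh: float = field(init=False)

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"selective advantage s must be positive, got {self.s}")
        if not 0.0 < self.h < 1.0:
            raise ValueError(
                f"dominance h must lie strictly in (0, 1) for the analytic model, got {self.h}"
            )
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"inbreeding coefficient F must be in [0, 1], got {self.F}")
        object.__setattr__(self, "Hl", self.F + self.h - self.F * self.h)
        object.__setattr__(self, "Hh", 1.0 - self.h + self.F * self.h)


@dataclass(frozen=True)
class LocusPair:
    """A selected locus and one linked neutral locus.

    Attributes
    ----------
    r : float
        Per-generation recombination fraction between the loci.
    N : int
        Diploid census size (used for the population-scaled R = 2Nr).
    sigma : float
        Selfing rate.
    R : float
        Derived: population-scaled recombination rate 2Nr.
    phi : float
        Derived: joint two-locus IBD probability.
    r_eff : float
        Derived: effective rate r(1 - 2F + Phi); zero at sigma = 1.
    """

    r: float
    N: int
    sigma: float = 0.0
    R: float = field(init=False)
    phi: float = field(init=False)
    r_eff: float = field(init=False)

    def __post_init__(self) -> None:
        phi = joint_ibd_phi(self.sigma, self.r)  # validates sigma, r
        F = inbreeding_coefficient(self.sigma)
        object.__setattr__(self, "R", 2.0 * self.N * self.r)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "r_eff", self.r * (1.0 - 2.0 * F + phi))

    @classmethod
    def from_scaled(cls, R: float, N: int, sigma: float = 0.0) -> "LocusPair":
        """Build from the population-scaled rate R = 2Nr."""
        if R < 0:
            raise ValueError(f"scaled recombination rate R must be >= 0, got {R}")
        return cls(r=R / (2.0 * N), N=N, sigma=sigma)
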