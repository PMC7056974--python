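"""User-facing simulator interface: configs, replicate runs, curve estimation.

The estimator reports, per linked neutral position, the *expected* pairwise
diversity and site-frequency spectrum conditional on each replicate's
realized genealogy ("branch-mode" accounting): the forward engine records
the window pedigree, the trace recovers the sample genealogy per position,
and neutral-equilibrium expectations complete it below the window.  Ratios
to the neutral baseline are therefore free of mutational sampling noise.
Actual 0/1 haplotype samples (with neutral mutations overlaid at rate
theta/(4N) per position) are available from :func:`run_replicate` /
:meth:`ReplicateSample.to_ms` for interoperability with sweep-scan tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..params import PopulationConfig, SelectionConfig
from ..diversity import SweepScenario
from . import engine

__all__ = ["SimConfig", "SimResult", "ReplicateSample", "run_replicate",
           "estimate_curves"]

_SCEN_CODE = {"de_novo": engine.DE_NOVO, "standing": engine.STANDING,
              "recurrent": engine.RECURRENT}


def _interval_switch_probs(r_values: np.ndarray) -> np.ndarray:
    """Per-interval strand-switch probabilities realizing the target r's.

    Positions sit on a line at increasing recombination fractions from the
    selected locus; chaining interval switches with probability rho_k gives
    marginal fraction r_k exactly: 1-2*rho_k = (1-2*r_k)/(1-2*r_{k-1}).
    """
    rho = np.empty(len(r_values))
    r_prev = 0.0
    for k, r in enumerate(r_values):
        if not 0.0 <= r <= 0.45:
            raise ValueError(
                f"recombination fraction {r} outside [0, 0.45]; fractions "
                "above ~0.45 make the interval construction degenerate")
        if r < r_prev:
            raise ValueError("recombination fractions must be non-decreasing")
        rho[k] = 0.5 * (1.0 - (1.0 - 2.0 * r) / (1.0 - 2.0 * r_prev))
        r_prev = r
    return rho


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a forward-simulation campaign.

    ``R_values`` are scaled distances 2Nr of the linked neutral positions
    (non-decreasing, at most 13).  ``scenario=None`` runs a neutral control
    for ``neutral_generations`` generations instead of a sweep.  Standing
    scenarios hold the allele at p0 for ``standing_hold`` generations of
    count-conditioned neutral reproduction (default: eight times the
    pairwise standing-phase coalescence timescale 2*N*p0/(1+F), long enough
    for the standing-phase coalescence/recombination race to resolve) before
    selection switches on.  ``theta`` (= 4N mu per position) is used only
    when haplotypes with mutations are exported.
    """

    pop: PopulationConfig
    sel: SelectionConfig | None
    scenario: SweepScenario | None
    R_values: tuple = (1.0, 10.0, 100.0)
    theta: float = 0.4
    n_sample: int = 10
    n_replicates: int = 2000
    seed: int = 0
    t_cap: int = 16384
    restart_cap: int = 10_000
    neutral_generations: int = 2000
    standing_hold: int | None = None
    r_values: np.ndarray = field(init=False)
    rho: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.R_values) > 13:
            raise ValueError("at most 13 linked positions per campaign")
        if not 2 <= self.n_sample <= 16:
            raise ValueError("n_sample must be in [2, 16]")
        if self.n_sample > 2 * self.pop.N:
            raise ValueError("cannot sample more haplotypes than 2N")
        r = np.asarray(self.R_values, dtype=float) / (2.0 * self.pop.N)
        object.__setattr__(self, "r_values", r)
        object.__setattr__(self, "rho", _interval_switch_probs(r))
        if self.scenario is not None and self.sel is None:
            raise ValueError("sweep scenarios need a SelectionConfig")

    def _kernel_args(self):
        fixed_t = self.neutral_generations
        if self.scenario is None:
            scen, p0_count, mu_b = engine.NEUTRAL, 0, 0.0
            s = h = 0.0
        else:
            scen = _SCEN_CODE[self.scenario.origin]
            p0_count = (math.ceil(2 * self.pop.N * self.scenario.p0)
                        if self.scenario.origin == "standing" else 0)
            mu_b = (self.scenario.theta_b / (2.0 * self.pop.N)
                    if self.scenario.origin == "recurrent" else 0.0)
            s, h = self.sel.s, self.sel.h
            if self.scenario.origin == "standing":
                if self.standing_hold is not None:
                    fixed_t = self.standing_hold
                else:
                    fixed_t = int(8.0 * 2.0 * self.pop.N * self.scenario.p0
                                  / (1.0 + self.pop.F))
        return scen, p0_count, mu_b, s, h, fixed_t


@dataclass(frozen=True)
class SimResult:
    """Aggregated Monte-Carlo summaries of a campaign.

    ``pi_mean`` / ``pi_se`` are per-position means and standard errors of
    E[pi/pi0 | genealogy] — what a mutation-based experiment measures in
    expectation, finite-window depth effects included.  ``escape_mean`` is
    the fraction of sample pairs whose lineages avoid coalescing on the
    derived background: exactly the probability the analytic diversity
    ratios model, so it is the estimand used when validating them.  ``sfs``
    is the pooled expected spectrum per position (normalized over classes
    1..n-1) and ``seg_mean`` the relative number of segregating sites.
    """

    config: SimConfig
    pi_mean: np.ndarray
    pi_se: np.ndarray
    escape_mean: np.ndarray
    escape_se: np.ndarray
    seg_mean: np.ndarray
    seg_se: np.ndarray
    sfs: np.ndarray
    fixation_time_mean: float
    fixation_time_sd: float
    onset_time_mean: float
    n_replicates: int
    n_lost: int

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame({
            "R": np.asarray(cfg.R_values, dtype=float),
            "pi_ratio_mean": self.pi_mean,
            "pi_ratio_se": self.pi_se,
            "pair_escape_mean": self.escape_mean,
            "pair_escape_se": self.escape_se,
            "seg_sites_rel_mean": self.seg_mean,
            "seg_sites_rel_se": self.seg_se,
        })


def estimate_curves(cfg: SimConfig) -> SimResult:
    """Run the replicate loop and aggregate diversity / SFS summaries."""
    if cfg.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    scen, p0_count, mu_b, s, h, fixed_t = cfg._kernel_args()
    K = len(cfg.R_values)
    n = cfg.n_sample
    reps = cfg.n_replicates
    out_pi = np.zeros((reps, K))
    out_esc = np.zeros((reps, K))
    out_seg = np.zeros((reps, K))
    out_sfs = np.zeros((K, n - 1))
    out_T = np.zeros(reps, dtype=np.int64)
    out_onset = np.zeros(reps, dtype=np.int64)
    out_attempts = np.zeros(reps, dtype=np.int64)
    ne2 = 2.0 * cfg.pop.Ne
    status = engine.run_campaign(
        cfg.seed % (2 ** 31), reps, cfg.pop.N, cfg.pop.sigma, s, h,
        scen, p0_count, mu_b, cfg.rho, cfg.t_cap, cfg.restart_cap,
        fixed_t, n, cfg.pop.F, ne2,
        out_pi, out_esc, out_seg, out_sfs, out_T, out_onset, out_attempts)
    if status != engine.OK:
        raise RuntimeError(
            f"forward simulation exhausted {cfg.restart_cap} restarts; "
            "the beneficial allele may effectively never fix at these parameters")
    sq = math.sqrt(reps)
    # window length includes the conditioning phases; the sweep itself runs
    # from selection onset to fixation
    sweep_lens = out_T - out_onset
    return SimResult(
        config=cfg,
        pi_mean=out_pi.mean(axis=0),
        pi_se=out_pi.std(axis=0, ddof=1) / sq,
        escape_mean=out_esc.mean(axis=0),
        escape_se=out_esc.std(axis=0, ddof=1) / sq,
        seg_mean=out_seg.mean(axis=0),
        seg_se=out_seg.std(axis=0, ddof=1) / sq,
        sfs=out_sfs / out_sfs.sum(axis=1, keepdims=True),
        fixation_time_mean=float(sweep_lens.mean()),
        fixation_time_sd=float(sweep_lens.std(ddof=1)),
        onset_time_mean=float(out_onset.mean()),
        n_replicates=reps,
        n_lost=int(out_attempts.sum() - reps),
    )


@dataclass
class ReplicateSample:
    """One conditioned replicate: per-position sample genealogies.

    Events are (coalescence time in generations before sampling, bitmask of
    merged samples); roots are the clusters still distinct at the window
    boundary.  ``to_ms`` overlays neutral mutations and emits ms-style
    haplotype blocks (one block per linked position).
    """

    config: SimConfig
    fixation_time: int
    onset_time: int
    attempts: int
    sample_ids: np.ndarray
    event_times: list
    event_masks: list
    root_masks: list

    def _full_tree(self, k: int, rng: np.random.Generator):
        """Window events + a sampled Kingman completion for position k.

        Returns a list of (tau, mask) merge events up to the sample MRCA.
        """
        ne2 = 2.0 * self.config.pop.Ne
        events = list(zip(self.event_times[k], self.event_masks[k]))
        roots = list(self.root_masks[k])
        tau = float(self.fixation_time)
        while len(roots) > 1:
            m = len(roots)
            rate = m * (m - 1) / 2.0 / ne2
            tau += rng.exponential(1.0 / rate)
            i, j = rng.choice(m, size=2, replace=False)
            merged = roots[i] | roots[j]
            roots = [r for t, r in enumerate(roots) if t not in (i, j)] + [merged]
            events.append((tau, merged))
        return events

    def haplotypes(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """0/1 matrix (n_sample x S_k) of neutral mutations at position k.

        Mutations are Poisson with rate theta/(4N) per branch generation on
        the full (window + completion) genealogy; columns are segregating
        sites in random order.
        """
        n = self.config.n_sample
        mu = self.config.theta / (4.0 * self.config.pop.N)
        events = self._full_tree(k, rng)
        # branch intervals: each cluster lives from its birth to its merge
        birth = {1 << i: 0.0 for i in range(n)}
        cols = []
        for tau, mask in sorted(events, key=lambda e: e[0]):
            merged_children = [m for m in birth if m & mask and (m | mask) == mask]
            for m in merged_children:
                if m == mask:
                    continue
                length = tau - birth.pop(m)
                nmut = rng.poisson(mu * length)
                if nmut and bin(m).count("1") < n:
                    col = np.array([(m >> i) & 1 for i in range(n)], dtype=np.int8)
                    cols.extend([col] * nmut)
            birth[mask] = tau
        if not cols:
            return np.zeros((n, 0), dtype=np.int8)
        mat = np.column_stack(cols)
        return mat[:, rng.permutation(mat.shape[1])]

    def to_ms(self, rng: np.random.Generator | None = None) -> str:
        """ms-style text: one '//' block per linked neutral position."""
        rng = rng or np.random.default_rng(self.config.seed + 1)
        blocks = []
        for k in range(len(self.config.R_values)):
            mat = self.haplotypes(k, rng)
            S = mat.shape[1]
            lines = ["//", f"segsites: {S}"]
            if S:
                pos = np.sort(rng.random(S))
                lines.append("positions: " + " ".join(f"{p:.5f}" for p in pos))
                lines.extend("".join(str(int(x)) for x in row) for row in mat)
            blocks.append("\n".join(lines))
        origin = (self.config.scenario.origin if self.config.scenario
                  else "neutral")
        header = (f"selfsweep {2 * self.config.pop.N} {len(blocks)} "
                  f"-origin {origin} -sigma {self.config.pop.sigma}\n"
                  f"{self.config.seed}\n")
        return header + "\n".join(blocks) + "\n"


def run_replicate(cfg: SimConfig, seed: int | None = None) -> ReplicateSample:
    """Simulate one conditioned replicate and return its traced genealogies."""
    scen, p0_count, mu_b, s, h, fixed_t = cfg._kernel_args()
    K = len(cfg.R_values)
    n = cfg.n_sample
    ev_tau = np.zeros((K, n - 1))
    ev_mask = np.zeros((K, n - 1), dtype=np.int64)
    ev_nums = np.zeros(K, dtype=np.int64)
    root_mask = np.zeros((K, n), dtype=np.int64)
    root_pos = np.zeros((K, n), dtype=np.int64)
    root_nums = np.zeros(K, dtype=np.int64)
    sample_out = np.zeros(n, dtype=np.int64)
    use_seed = (cfg.seed if seed is None else seed) % (2 ** 31)
    status, T, onset, attempts = engine.run_single(
        use_seed, cfg.pop.N, cfg.pop.sigma, s, h, scen, p0_count, mu_b,
        cfg.rho, cfg.t_cap, cfg.restart_cap, fixed_t, n,
        cfg.pop.F, ev_tau, ev_mask, ev_nums, root_mask, root_pos, root_nums,
        sample_out)
    if status != engine.OK:
        raise RuntimeError("replicate exhausted the restart cap without fixation")
    return ReplicateSample(
        config=cfg, fixation_time=int(T), onset_time=int(onset),
        attempts=int(attempts), sample_ids=sample_out.copy(),
        event_times=[ev_tau[k, :ev_nums[k]].copy() for k in range(K)],
        event_masks=[ev_mask[k, :ev_nums[k]].copy() for k in range(K)],
        root_masks=[root_mask[k, :root_nums[k]].copy() for k in range(K)],
    )
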