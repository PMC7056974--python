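# Methods

## The model

`selfsweep` computes the expected footprint of a selective sweep on linked
neutral variation in a partially self-fertilizing diploid population, for an
arbitrary dominance coefficient of the beneficial allele, and validates the
predictions against its own forward Wright-Fisher simulator.

A population of `N` diploids (2N haplotypes) reproduces by selfing with
probability `σ` and random outcrossing otherwise. A derived allele at the
selected locus has fitnesses `1 : 1+hs : 1+s`. At mating-system equilibrium
selfing induces Wright's inbreeding coefficient `F = σ/(2−σ)`, which drives
three scalings that the whole package is built on:

* effective population size `Ne = N/(1+F)` — pairwise coalescence at rate
  `(1+F)/(2N)` per generation;
* effective recombination `r_eff = r(1−2F+Φ)` between the selected locus and
  a neutral locus at recombination fraction `r`, where `Φ` is the joint
  probability of identity-by-descent at both loci (`Φ ≈ F` except when σ is
  near 1 and `r ≳ 0.1`);
* effective dominance `Hl = F + h − Fh` for rare alleles and
  `Hh = 1 − h + Fh` for common ones (both → 1 at full selfing: selection
  acts on homozygotes).

Backward in time the allele's deterministic frequency path obeys
`dp/dt = −s p(1−p)[Hl + (1−F)(1−2h)p]`. The deterministic phase is
bracketed by an effective starting frequency `p0A = (1+F)/(4NsHl)` — a
single-copy mutation destined to fix rises faster than deterministically
while rare, which is equivalent to starting higher — and ends at `1−ε` with
`ε = (1+F)/(4NsHh)` (an allele rising with dominance `h` finishes like one
falling with dominance `1−h`; the sojourn time between mirrored endpoints
is identical for `h` and `1−h` at any `F`, which is tested).

Looking back from fixation, a pair of lineages sampled at a linked neutral
site experiences competing hazards while the allele is at frequency `p`:
coalescence `Pc = (1+F)/(2Np)`, recombination onto the ancestral background
`Pr = 2 r_eff (1−p)`, and (for recurrent-mutation sweeps) descent from an
independent mutational origin `Pm = 2 μb (1−p)/p`. Integrating these along
the trajectory — in frequency space, dividing by `|dp/dt|` — gives the
sweep-phase outcome probabilities `P_NE`, `P_R_sw`, `P_C_sw`, `P_M_sw`.
For sweeps from variation standing at frequency `p0`, the pre-selection
("standing") phase is a race between two Poisson clocks at fixed `p0`,
giving `P_R_sd = Pr(p0)/(Pc(p0)+Pr(p0))`; the recurrent-origin analogue
`P_M_sd = 2Θb(1−p0A)/(1+F+2Θb(1−p0A))` with `Θb = 2Nμb`. Pairwise
diversity relative to the no-sweep baseline follows by composition:
coalesced pairs carry ≈ 0 diversity, escaped pairs carry the background
level, so

* standing / de novo: `E[π/π0] = P_R_sw + P_NE·P_R_sd` (de novo uses
  `p0 = p0A`),
* recurrent: `E[π/π0] = P_R_sw + P_M_sw + P_NE·P_M_sd`,
* the star-like closed form (no sweep-phase coalescence)
  `1 − P_C_sd·[Hl/Hh(1/p0+1)−1]^(−2 r_eff/(Hl s))`, an upper bound on the
  full prediction for de novo sweeps,
* the crossover distance `R_lim ≈ Θb/(p0(1−F))` below which a
  recurrent-mutation sweep retains more diversity than a standing sweep.

## Numerical choices

Sweep-phase integrals are computed in one ODE pass from `1−ε` down to the
lower endpoint, advancing the cumulative hazard `Λ(p)` and the weighted
integrals `∫exp(−Λ)P_x/|dp/dt| dp` together (DOP853, rtol 1e−10,
atol 1e−12); this avoids O(n²) nested quadrature and keeps the
competing-risks identity `P_NE + ΣP_x = 1` to ~1e−12 (asserted at 1e−6).
Integrands grow like `1/p²` toward the origin but the lower endpoint is
bounded away from zero by `p0A`. Sojourn times use adaptive quadrature of
`1/|dp/dt|` (abs 1e−10, rel 1e−8); the reconstructed time path agrees with
the quadrature to ~1e−8. `h` is restricted to `[1e−3, 1−1e−3]` in analytic
operations (the diversity expressions are undefined at `h ∈ {0,1}` with
`σ = 0`); `σ = 1` is representable in the parameter layer but diversity
operations clamp it to `1 − 1e−6` to avoid 0/0 in effective-rate ratios.
Exact `h ∈ {0,1}` and `σ = 1` remain available in the simulator.

`P_R_sd` is implemented from the exact two-clock ratio, not the printed
`(1−σ)` simplification; the simplification is exposed separately and its
accuracy pinned by regression (0.2% relative for `r ≤ 1e−3`, degrading to
~3% by `r ≈ 0.1` at high σ).

Known analytic caveats, each pinned by a test:

* the printed star-like closed form is an upper bound on the full
  prediction across the de novo grid, but can dip a few percent *below* it
  at `(h = 0.1, σ = 0, p0 = 0.05)` — its `O(p0)` base simplification
  outweighs the dropped sweep-phase coalescence there;
* as `Θb → 0` the recurrent prediction converges to the de novo one only up
  to the de novo model's own standing-phase term `P_NE·P_R_sd(p0A)`;
* the relative segregating-site count can overshoot 1 by a few percent at
  loose linkage because the adjusted singleton class (below) adds
  derived-background mutations on top of the full neutral expectation.

## Site-frequency spectrum

The post-sweep SFS uses a star-like soft-sweep construction. Each of the
`n` sampled lineages escapes the derived background independently; the
per-lineage escape probability is built from the single-lineage analogues
of the pairwise quantities (sweep-phase survival is the square root of the
pairwise star-like `P_NE`, standing/origin retention the square root of the
pairwise coalescence probability), so that at `n = 2` the polymorphic mass
reproduces the pairwise star-like closed form to machine precision.
Conditional on `k` escapees, the sample is represented by `m = k+1`
exchangeable ancestral lineages (the star clade has multiplicity `n−k`)
whose deeper genealogy is neutral: a mutation subtends `i` of `m` ancestors
with weight `1/i` and a uniformly chosen subset, mapped back through the
multiplicities. An adjusted singleton class adds `θ/2` times the expected
derived-background branch length (sweep-phase dwell plus the standing-phase
wait) to `l = 1` before renormalizing — these recent mutations are ignored
for pairwise diversity but visible in the spectrum. Polarity is assumed
known (unfolded spectrum); the construction is intended for modest samples
(`n ≲ 20`), the star-like regime.

Because every non-escaped lineage collapses into a single star clade, this
construction overstates the singleton class and misses the intermediate
classes that sweep-phase subclades create; the validation suite asserts
exactly this signed deviation pattern against the simulator. What passing
shows is that the spectrum's sweep phenomenology — tail excess for hard
sweeps, intermediate-class growth with `p0`, the `1/(1−σ)` spatial stretch
— is quantitatively in place, not that the star-like spectrum is an
unbiased estimator of class proportions.

## The forward simulator

`selfsweep.simulate` is a forward-in-time diploid Wright-Fisher engine
(numba-compiled) with mixed mating (selfing probability σ per offspring),
viability selection `1 : 1+hs : 1+s` implemented as rejection sampling of
parents, and a linear arrangement of up to 13 linked neutral positions at
exact marginal recombination fractions from the selected locus (chained
per-interval strand switches with `1−2ρ_k = (1−2r_k)/(1−2r_{k−1})`).

Rather than accumulating neutral mutations through a long burn-in, the
engine records the complete inheritance history of the window — for every
gamete, its parent and a bit field holding the strand choice, the interval
crossovers, and the selected-locus allele — and traces the sampled
haplotypes backward per neutral position, recovering each position's exact
sample genealogy inside the window (merge times and compositions). Below
the window the population is at neutral equilibrium, so the genealogy is
completed with the standard selfing-scaled coalescent expectations:
pairwise `E[T2] = 2Ne` (after an instantaneous IBD merge with probability
`F` for root pairs landing in the same founder individual), and expected
branch length `4Ne/i` subtending `i` of `m` roots with uniform subsets.
Summaries are therefore exact conditional expectations given each
replicate's realized genealogy ("branch-mode" accounting): mutational
sampling noise is zero, no burn-in is needed, and a neutral control run
reproduces `π/π0 = 1` and the `1/l` spectrum from the forward mechanics
alone. Haplotype samples with neutral mutations overlaid at `θ/(4N)` per
position per generation are still available (`run_replicate().to_ms()`,
ms-style text) for interoperability; the deeper tree for that export is
drawn with a small internal Kingman sampler on the window roots.

Scenario initializations:

* **de novo** — a single derived copy in a fresh founder population;
  restart on loss (conditioning on fixation).
* **standing at p0** — the model's standing phase assumes the allele sits
  at `p0`; the simulator implements that assumption literally: founders
  carry `2Np0` derived copies and reproduction is conditioned to keep the
  count fixed for a held phase of `8·2Np0/(1+F)` generations (several times
  the standing-phase coalescence timescale, long enough for the
  coalescence/recombination race to resolve) before selection switches on.
  Conditioning operates at the individual level — whole offspring are
  regenerated through the true mating mechanism and regenerations that do
  not move the count away from the target are accepted — because flipping
  single gametes would flood the derived class with heterozygotes and
  silently inflate the effective recombination rate at high selfing.
* **recurrent** — beneficial copies are injected at `μb = Θb/(2N)` per
  gamete per generation; no restarts are needed.

Two diversity estimands are reported. `pi_mean` is the branch-mode
`E[π/π0 | genealogy]` — what a mutation-based experiment measures,
including the finite-window depth effect (escaped pairs are conditioned
deeper than the stationary baseline, inflating the ratio by
`O(T_sweep/2Ne)`). `escape_mean` is the fraction of sample pairs whose
lineages avoid coalescing on the derived background — exactly the event
the analytic ratios price (coalesced → 0, escaped → π0), read off
mechanically from the recorded allele states at each merge. Validation of
the analytic curves uses `escape_mean`; both are emitted so the gap between
them (a real property of finite windows, not of the theory) is visible.

## Validation scale and where the theory is checked

The simulation campaigns run at `N = 1000`, `s = 0.1`, 2000 conditioned
replicates, samples of 10 haplotypes, fixed seeds — large enough for
`1/Ne ≪ s ≪ 1` to hold while keeping a full campaign in minutes on one
core. The analytic model is evaluated at the same parameters (the theory
is parametric in `N` and `s`).

At this scale the theory's two continuum assumptions are measurably
strained away from the selected locus: per-generation hazards near the
sweep origin are `~2sHl` (not ≪ 1), and escape is treated as absorbing
while real lineages can recombine back onto the derived background at rate
`r_eff·p` — both deflate the true escape probability relative to the
integrals as `r/s` grows. The quantitative 3-SE agreement tests therefore
sit at small `r/s` (scaled distances `R ≤ 60`, spanning all three sweep
origins, `h ∈ {0.1, 0.5, 0.9}` and `σ ∈ {0, 0.5, 0.95}`), where the
assumptions hold; at larger distances the deviation grows to a few percent
of the ratio, systematically in the same direction, and can be reproduced
with the `selfsweep compare` subcommand. Passing, therefore, shows the
sweep-phase and standing-phase machinery is right where its assumptions
hold at this population size — not that the approximations are exact at
arbitrary `r/s`.

Mean conditioned fixation times exceed the deterministic sojourn between
the effective endpoints by ~10-15% (the stochastic boundary layers outside
`[p0A, 1−ε]` add time); the comparison is asserted at 20% with the
direction pinned.

## Limitations

Single sweep events only (no recurrent genome-wide sweeps or background
selection); equilibrium inbreeding (no recent mating-system change);
standing variants assumed previously neutral; no demography or population
structure; diversity reported as ratios to the baseline, never absolute;
no linkage-disequilibrium or haplotype-homozygosity statistics. The
analytic spectra assume known ancestral/derived polarity. Dominance values
exactly 0 or 1 are simulator-only.
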