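# Model and methods

`betamito` simulates a pancreatic beta-cell as a continuous-time Markov
chain over a dynamic population of attributed mitochondrial compartments
coupled to cytosolic metabolite and signalling pools.  The chain is
executed exactly with the Gillespie direct method: each enabled rule
instance carries a propensity, waiting times are exponential in the total
propensity, and the firing rule is chosen proportionally to its share.
Mitochondria are created, removed, merged and split at runtime, which is
what distinguishes this simulator from fixed-compartment reaction tools.

## State

A mitochondrion carries a volume `v`, integer `health` and `damage` units
(density `u` units per volume unit, default 400), and two lists of anchor
sites: Fis1 sites (peripheral fission) and MFF sites (midzone fission),
each holding a count of bound Drp1 clusters.  Volumes are quantized on the
unit grid — `v = (health + damage)/u` exactly — so unit accounting is
exact under every operation.  Drp1 is coarse-grained into clusters of 10
molecules; ATP and pyruvate into packets (nominally 10^6 molecules per
packet), because a cell turns over ~10^8 ATP molecules per second and
simulating them individually is pointless in an exact SSA.  Cytosolic
Ca2+ is the one continuous variable: between events it relaxes
exponentially (time constant `tau_Ca`) toward a Hill-type target set by
the current ATP level; this matches the response-curve abstraction of the
triggering pathway and avoids millions of discrete Ca2+ events.

## Rules

**Drp1 cycle.** Free unphosphorylated clusters bind open anchor slots
(mass action in free clusters x open slots); bound clusters unbind slowly.
PKA (activated by cAMP) phosphorylates free Drp1, making it
binding-incompetent; calcineurin (activated by Ca2+) reverses this.  Only
free Drp1 cycles between phospho-states.  A site whose bound count
reaches `ring_threshold` (default 27 clusters = 270 monomers) is "armed".
The threshold equals the site capacity: a ring must be complete to
constrict.  The threshold is deliberately large: it represents the full
fission-machinery commitment at a site, not a minimal ring, and it makes
the cellular Drp1 pool (612 sites x 27 = 16524 clusters of a 20000
wild-type pool) the limiting resource under knockdown — the property
behind the steep fission loss when Drp1 is depleted by a quarter, and
behind fission ceasing while free Drp1 is still plentiful.

**Fission.** An armed site fires at `k_fission * v` (bigger mitochondria
split more often).  MFF sites produce midzone events (position ~
N(0.5, 0.05), truncated to (0,1)); Fis1 sites produce peripheral events
(position ~ N(0.09, 0.04), folded so the ratio names the small side).
Health and damage partition by the ceil/floor complement scheme: with
ratio `r` and asymmetry `a`, the small daughter receives
`ceil(H*r - D*a)` health units; damage fills the remainder of its
`round(U*r)` units, clamped so all four attributes stay non-negative.
Conservation is exact by construction.  Midzone events use `a = 0`.  The
triggering ring disassembles and returns to the free unphosphorylated
pool (the simplest conserving choice); the remaining anchor sites move to
the small daughter independently with probability `r`, volume-
proportional in expectation.

**Fusion.** Any unordered pair of mitochondria below the damage-fraction
threshold `Thr_damage` merges at a constant pairwise rate; attributes add
and site lists concatenate.  Mitochondria at or above the threshold model
depolarized organelles that can no longer fuse.

**Mitophagy.** A mitochondrion is removable when its damage fraction is at
least `Thr_damage` and its volume fits an autophagosome
(`v <= v_phagy_max`, default 0.5 — about half an average organelle).  Its
bound Drp1 returns to the free pool and its anchor sites relocate to a
surviving mitochondrion, keeping the Fis1/MFF totals constant as in the
knockdown protocol; destroying sites with the organelle would secularly
erode fission capacity over long runs, which no experiment here intends.
The size cutoff matters beyond realism: when fission is lost and
mitochondria grow large, even their peripheral fragments exceed the
cutoff, so quality control cannot silently compensate by processing more
volume per event — this is what lets full Drp1 depletion drive damage to
saturation.

**Metabolism.** Glycolysis is one lumped Michaelis-Menten step in
extracellular glucose producing 2 pyruvate + 2 ATP packets per firing.
Pyruvate is either fermented away (Michaelis-Menten, large `Km_LDH_pyr`)
or oxidized by a mitochondrion at
`k_oxphos * v * f * pyr/(Km + pyr)` yielding `atp_per_pyr` packets, where

    f = f_ATP * (0.1 + 0.9 / (1 + exp(damage_m * (damage_lim - h)))),
    h = health / (health + damage),

a sigmoid rising from `0.1*f_ATP` (fully damaged) to `~f_ATP` (healthy)
with midpoint `0.55*f_ATP` at `h = damage_lim`.  ROS damage converts one
health unit to damage at `k_ros` times the mitochondrion's oxPhos rate;
repair converts back at `k_repair` per damage unit (weak — mitophagy, not
repair, is the dominant outlet).  ATP is consumed first-order; cAMP is
synthesized saturably from ATP and degraded first-order.

A deliberate kinetic feature: `Km_LDH_pyr` is large, so at sub-saturating
pyruvate the fermentation leak is small and the pyruvate pool buffers
oxPhos — ATP output is clamped by glycolytic supply as long as total
oxPhos *capacity* (`k_oxphos * sum(v*f)`) exceeds it.  Secretion is then
insensitive to moderate damage (and to knockdowns at low glucose, where
capacity is ample), and falls sharply only once accumulated damage pushes
capacity below supply.  This reproduces two observed phenotypes at once:
knockdowns leave low-glucose secretion essentially unchanged, and the
secretion loss at high glucose has a knee rather than a gradual slope.

**Secretion.** Insulin granules leave a rapid-release pool at
`k_sec * rrp * hill(ca; K_sec_ca, n_sec)` and the pool refills
glucose-dependently up to a capacity of 200 granules.  Basal secretion is
defined operationally as the 2.5 mM condition (at 0 mM the refill pathway
is off and secretion decays to zero, making ratios degenerate).

## Parameters

The five health-coupling parameters default to the fitted knockdown set:
`f_ATP = 1.54`, `damage_lim = 53.3%`, `damage_m = 28.7`,
`asym_fission = 9.22%`, `Thr_damage = 74.0%`, with scan bounds 0.9-1.6,
25-75%, 10-50, 0-10% and 10-90% respectively.  The initial cell holds 68
mitochondria of total volume 68 (one volume unit each), 306 Fis1 and 306
MFF sites spread volume-proportionally, 20000 free Drp1 clusters
(wild type), and an initial damage fraction of 30% representing a normal
standing damage load (it also shortens the burn-in transient).

All kinetic constants of the metabolic/signalling cascade and the
fission-position distributions are repo-calibrated stand-ins, not
published values.  They were chosen, once, against these criteria and are
not meant to be tuned per experiment:

* ATP, Ca2+ and cAMP reach steady state within simulated minutes;
* insulin secretion is sigmoidal in glucose with a threshold near 5 mM
  and a basal-to-stimulated range of roughly an order of magnitude;
* at a 50% damage threshold the network damage is in the mid-40s% without
  sorting and drops by ~10 points at 5% asymmetry, with the healthy edge
  of the distribution moving accordingly;
* Fis1 knockdown attenuates 25 mM secretion gradually over the 40-100
  site range while Drp1 depletion produces an all-or-none collapse whose
  boundary lies near a 25-30% pool reduction.

Two calibration choices deserve explanation.  Unit density is `u = 400`
because at coarse granularity (100 units per volume unit) the `ceil` in
the fission rule donates up to one extra health unit to ~9-unit daughters,
an upward rounding bias of several damage points that manufactures an
artificial healthy tail.  Biogenesis (one volume quantum of fresh, healthy
material at `k_grow * max(0, V_target - total volume)`) targets a
mass-proportionally chosen mitochondrion: growth is proportional to
existing mass, and uniform choice would concentrate dilution in the
smallest organelles and broaden the damage distribution artificially.

## Experiments and problem sizes

Steady-state statistics use a fixed horizon of 3000 s with snapshots every
10 s and a burn-in fraction of 0.5; event rates (fission by type,
mitophagy, secretion) are window counts divided by elapsed time, averaged
over replicates (replicate `r` of a batch uses seed `base_seed + r`;
default N = 5).  Drp1-depletion conditions run longer (7000 s for the
secretion scan, 12000 s with burn-in 0.6 for full depletion): once
quality control has ceased the network has no steady state short of
damage saturation, and the approach slows about six-fold as oxPhos (and
with it ROS production) falls to its floor.

The Sobol analysis follows the Saltelli scheme with quasi-random base
matrices (first/second/total-order estimators, bootstrap confidence
intervals), implemented in `betamito.sensitivity` and validated against
the Ishigami function's closed-form indices plus an independent
third-party estimator.  The model output is steady-state secretion at
25 mM; the packaged default is a scaled-down design (`n_base = 256`,
~`n_base*(2d+2)` runs at full second-order sampling) — the test suite uses
`n_base = 16` without second-order terms, which is enough to resolve the
total-order ranking.  The fitting hook is a small global-best particle
swarm (deterministic given seed, bounds-reflecting, non-finite losses
resampled); the default objective targets a knockdown/wild-type secretion
ratio at 25 mM.

## What the model does not capture

No OPA1/MFN fusion machinery, no PINK1-Parkin mitophagy signalling, no
membrane potential, NADH or per-enzyme glycolysis/respiratory chain, no
Ca2+ oscillations or electrophysiology (the ATP->Ca2+ Hill curve collapses
the KATP pathway), no spatial structure, and no cell proliferation.
Damage is a single abstract pool standing in for heterogeneous damage
markers.  Numerical conclusions drawn from the packaged defaults are
statements about this calibrated model, not measurements of Min6 cells;
the defaults reproduce the qualitative regulatory structure (damage
sorting, threshold tracking, knockdown phenotypes, sensitivity ranking)
rather than any particular wet-lab kinetic constant.  Steady-state damage
at the no-sorting corner sits in the upper half of its plausible band
(~48% at a 50% threshold), a known consequence of fragment-only removal
below the autophagosome cutoff.
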