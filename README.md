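# betamito

Stochastic multi-level simulation of pancreatic beta-cell mitochondrial
dynamics and glucose-stimulated insulin secretion.

Beta-cells couple glucose metabolism to insulin release through
mitochondrial ATP production, and mitochondrial *quality control* —
fission, fusion and mitophagy — decides how much of the network stays
healthy enough to produce that ATP.  Recent imaging distinguishes two
fission modes: **midzone** fission (MFF-anchored) splits an organelle into
two similar halves, while **peripheral** fission (Fis1-anchored) pinches
off a small, disproportionately damaged fragment that mitophagy can
remove.  `betamito` implements this biology as an exact continuous-time
Markov chain (Gillespie direct method) over a dynamic population of
attributed mitochondrial compartments, coupled to glycolysis/oxidative
phosphorylation, cAMP, a Ca2+ response curve and rapid-release-pool
insulin secretion — so that molecular perturbations (Fis1, MFF or Drp1
knockdown, damage-sorting strength, fusion thresholds) propagate all the
way to the insulin dose-response.

The model's core couplings, in the field's notation:

* oxPhos modifier of each mitochondrion (health fraction
  `h = health/(health+damage)`):
  `f = f_ATP * (0.1 + 0.9/(1 + exp(damage_m * (damage_lim - h))))`
* damage-sorting peripheral fission at ratio `r` and asymmetry
  `asym_fission`: small daughter health `= ceil(H*r - D*asym_fission)`,
  complements exactly conserved — e.g. a 25/75 split at 5% asymmetry
  gives the small daughter 25%+5% = 30% of the mother's damage;
* fusion blocked and mitophagy enabled at damage fraction
  `>= Thr_damage`.

The five health-coupling parameters default to the fitted knockdown set
(`f_ATP=1.54`, `damage_lim=53.3%`, `damage_m=28.7`, `asym_fission=9.22%`,
`Thr_damage=74.0%`).  See `docs/methods.md` for the full rule set,
parameter meanings and calibration rationale.

## Worked example

Compare wild type against a Fis1 knockdown (60 of 306 peripheral anchor
sites) at 25 mM glucose, five replicates each:

```python
from betamito import SimConfig, summarize_condition

wt = summarize_condition(SimConfig(), replicates=5, base_seed=0)
kd = summarize_condition(SimConfig(n_fis1=60), replicates=5, base_seed=0)
for name, s in [("WT", wt), ("Fis1-KD", kd)]:
    print(f"{name}: damage {s.mean_damage_pct:.1f}%  "
          f"secretion {s.secretion_rate:.3f}/s  "
          f"fission {s.peripheral_fission_rate:.2f}+"
          f"{s.midzone_fission_rate:.2f}/s")
```

```
WT: damage 36.8%  secretion 0.298/s  fission 0.49+0.47/s
Fis1-KD: damage 48.9%  secretion 0.263/s  fission 0.11+0.57/s
```

Knocking down Fis1 cuts peripheral fission four-fold while midzone
fission is mildly enhanced (more free Drp1 for the remaining sites).
With damage-sorting quality control weakened, steady-state network damage
rises ~12 points; because oxPhos capacity falls toward the glycolytic
supply it must match, 25 mM insulin secretion drops by ~12% at this level
— and progressively more as Fis1 falls further, while low-glucose
secretion is unaffected.  Deeper scans (`betamito.experiments`) reproduce
the factorial damage-threshold x asymmetry landscape, the Fis1/MFF/Drp1
knockdown phenotypes, the glucose dose-response and a Sobol sensitivity
analysis of secretion.

## Command line

```sh
betamito simulate --seed 1 --t-end 3000 --out runs/wt
betamito scan --asym 0,0.05 --threshold 0.5 --reps 5 --out runs/scan
betamito knockdown --protein drp1 --levels 20000,15000,10000 --out runs/kd
betamito dose-response --glucose 0,2.5,5,10,15,20,25 --out runs/dr
betamito sobol --n 256 --out runs/sobol
betamito fit --target-reduction 0.40 --budget 36 --out runs/fit
```

Outputs are plain CSV tables (per-mitochondrion snapshots and cytosolic
pools), a JSONL event log and a JSON run manifest (resolved config,
seeds, checksums) sufficient to re-run bit-identically.

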