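# Methods

## The kinetic well model

`reporter_kinetics.simulate_well` integrates, per imaging field, the state
(N_live, N_apop, N_nec, m, c, g, P):

```
u(t)    = 1 - exp(-t/tau_ind)                    induction ramp
w(t)    = exp(-k_shut * max(0, t - t_shut))      transcription shutoff
dN_live = r (1 - arrest*u) N_live (1 - N_tot/K) - k_d [t > t_death] N_live
dN_apop = k_d [t > t_death] N_live - k_n N_apop
dN_nec  = k_n N_apop
dm      = alpha0 (1 + (beta-1) u) w - delta_m m
dc      = k_c m - delta_c c
dg      = k_g m - delta_g g
dP      = k_p c (N_live + eps_apop N_apop)
```

Assumptions: per-cell molecular state is homogeneous across the well;
drug-induced transcription rises along a smooth exponential ramp (signal
transduction plus mRNA accumulation are not instantaneous); cells that
commit to death stop transcribing, which the shutoff factor `w` applies to
the whole production term; secondary-necrotic cells detach and contribute
neither confluence nor PGE2; apoptotic cells retain a reduced footprint
(200 vs 400 µm²) and a fractional PGE2 output `eps_apop`.  m, c, g start at
the drug-free steady state, so vehicle wells are flat per cell.  The
shutoff term is the one structural addition beyond a minimal
transcription–translation cascade: without it the reporter would be
monotone in time, whereas a destabilized reporter in a dying culture peaks
and decays.

Integration is fixed-step RK4 (0.5 h internal step, states clamped at 0)
sampled onto the 2 h imaging grid — deterministic and platform-stable; the
vehicle trajectory agrees with the closed-form logistic solution to better
than 1e-6 relative.

### Calibration of the shipped presets

The rate constants are not measured quantities; they were fixed once, by
numerical search, against four kinetic anchors and then frozen:

1. 100 µM 5-FU: cumulative PGE2 reaches 7.0× the vehicle control at 48 h
   (sets `beta = 19.14` for the 5-FU preset given the other constants);
2. 50 µM cisplatin: the PGE2 release rate dP/dt peaks at ~8 h (early death
   onset `t_death = 5 h`, `k_d = 0.22/h`);
3. reporter peaks at ~24 h (cisplatin, `t_shut = 24 h`) and ~48 h (5-FU,
   `t_shut = 48 h`), cisplatin preceding 5-FU;
4. reporter half-life 2 h (`delta_g = ln 2 / 2`, the "d2" destabilized
   variant) so fluorescence tracks transcription on the 2 h scan grid.

Growth: `r = 0.055/h` (~12.6 h doubling), `K = 2400` cells/field,
`N0 = 1000` cells/field (~38 % seeding confluence at 400 µm²/cell in a
1.048576 mm² field), chosen so a vehicle well runs ~38 → 89 % confluence
over 72 h.  mRNA/protein turnover (`delta_m = 0.6/h`, `delta_c = 0.15/h`)
put COX-2 protein on a slower clock than the reporter, as expected for a
stable enzyme versus a destabilized fluorophore.

Within this model the cisplatin anchors are partly incompatible with the
observation that caspase activity *follows* the PGE2 peak: an 8 h
release-rate peak requires the live pool to shrink while per-cell COX-2 is
still rising, so the model's death onset for cisplatin is early (5 h).  We
kept the printed numeric anchors and accept that the caspase proxy
(`N_apop`) rises earlier than a caspase reagent would report; the
reporter-decay/caspase coincidence holds only loosely for cisplatin.

## The synthetic screen

`synthetic_screen.build_library` draws 1280 compounds: antibacterial 13 %,
anti-inflammatory 8 %, antihypertensive 8 %, 69 antineoplastic,
20 anthelmintic, remainder "other".  Cytostatic/cytotoxic categories draw
coupled effects from the copula `arrest ~ Beta(5,2)`,
`beta = 1 + 9 * arrest^1.5 * exp(eps)`, `eps ~ N(0, 0.15)` — growth
suppression and promoter induction rise together, which downstream scoring
must surface as an anti-correlation.  Ramp constants draw from U(4, 8) h.
Near-complete arresters additionally progress to death late in the window
(`t_death = 44 h`, `k_d = 0.12 * arrest^10`): at the 10 µM screening dose,
arrest dominates and only the strongest compounds kill outright within
72 h.  This steepens the confluency-score response exactly where induction
is strongest, mirroring the observation that growth collapse and reporter
induction arrive together.  Inert categories draw `arrest ≈ 0`,
`beta ≈ 1` with small noise.

Eight compounds (fixed roster, named after classic fluorescent/absorbing
drugs) are flagged intrinsically fluorescent and add a constant
+1.0 GCU offset from the first scan.

Plate layout: 16×24 wells, outer two rows/columns buffer, 240 usable inner
wells, 9 DMSO + 9 5-FU control wells as triplets anchored upper-left
(C3–C5 / D3–D5), center (H12–H14 / I12–I14) and bottom-right
(N20–N22 / M20–M22); 222 compounds per plate in column-major order, 6
plates for the default library.  The replicate structure of a multi-run
screen is not modeled; the default is a single copy of each compound.

Measurement: GCU = 0.1165·g + 0.02 (vehicle wells read ≈ 0.30 GCU),
multiplicative log-normal noise (sd 0.05) per time point on both channels,
averaged over `field_count` fields (default 1, as in a 384-well screen).

### What the generator does not emulate

No photobleaching, focus drift, meniscus or edge effects; no plate-batch
or run-order effects; noise is i.i.d. across time points rather than
autocorrelated; the GCU calibration is exactly linear.  Tests passing on
this generator show the *pipeline arithmetic* is right under the stated
conditions — they do not certify instrument-specific robustness.

## Imaging

White top-hat = image − opening with a disc of radius round(10 µm / pixel
scale); GFP mask = subtracted image ≥ 0.2 GCU; 8-connectivity components
(merging diagonal neighbours into "small clusters"); area strictly
> 80 µm².  Object means are measured on the subtracted image — the same
quantity the threshold was applied to; a switch (`mean_on_subtracted`)
selects raw-image means, since an instrument's convention could be either.
Wells with no objects report 0.0 GCU; the scoring floor (0.05 GCU) keeps
the subsequent fold change finite.

Confluence segmentation is this package's own invention (vendor algorithms
are proprietary): a standard-deviation filter over a 10 µm window fires on
speckled cell interiors, the mask is eroded by the half-window halo, and
components strictly > 250 µm² count toward coverage.  On rendered fields it
lands within ±5 percentage points of ground truth at the densities used in
testing; only the > 250 µm² debris filter is a published constant.

The renderer places elliptical cells (full axes U(12, 30) µm) with a dome
intensity profile (bright center, dimmer rim).  The dome matters: a 10 µm
top-hat radius would annihilate a *flat* object wider than 20 µm, while a
dome keeps a detectable core for every cell size in range.  At sparse
density cells are placed with ≥ 1 px separation (so 8-connectivity keeps
them resolvable); at high density placement degrades gracefully to
touching/overlapping cells, and each cell's ground-truth area counts only
newly claimed pixels so total truth area equals covered area.

## Scoring

Fold changes divide each compound well by its own plate's per-time-point
DMSO-control mean (never pooled across plates); floors: 0.05 GCU,
1 confluence point.  GFP score = trapezoid AUC of the GFP fold change
divided by total duration.  The time-normalized default makes the score
unit-free (vehicle ≈ 1) and the published hit threshold of 5 readable as
"average five-fold induction"; a raw AUC-in-hours of a vehicle-like curve
would be ≈ 72 and incompatible with a threshold of 5.  Confluency score =
plain mean of the confluence fold change over all acquired points.

Autofluorescence QC flags a compound when its GFP fold change exceeds 2
anywhere in the first 2 h (t = 0 included).  Reporter-driven signal cannot
jump that early — transcription, translation and maturation take hours —
while an intrinsically fluorescent compound is bright from the first scan.
The 2 h window (rather than a longer one) leaves ~3-sigma noise headroom
for the fastest genuine inducers in the library, whose fold change can
reach ~1.55 by 4 h; with the default ramp constants a 4 h window would
start colliding with real induction.

Spearman: average ranks for ties; p two-sided from the t approximation
(n ≥ 10) or exact enumeration of all n! permutations (n < 10) —
reproducible to the last digit, no asymptotic edge cases at small n.

## Expression pharmacodynamics

Baseline split: 2-component 1-D Gaussian mixture on log2 baseline
expression, initialized at the data quartiles (deterministic), threshold at
the posterior crossover; a fixed-threshold mode covers the case where a
study's literal cutoff is known.  With the default panel (modes at log2 3
and 9, sd 0.5) recovery of planted labels is exact; recovery degrades
continuously as the modes approach, which is reported, not hidden, by the
misclassification count in tests.  GI50 quartiles cut at interpolated
25/50/75 percentiles with ties assigned downward, so tied values at a cut
produce unequal group sizes (e.g. 8/10/10/10 over 38 lines).  The
panel generator couples induction to a latent sensitivity that also
generates GI50 (`fc24 = 0.8·s + noise` for baseline-positive lines,
`log10 GI50 = -5.3 - 0.6·s`), leaving 22 of 60 lines without GI50 per drug.

## Design choices on open points

* PGE2 is modeled as cumulative medium concentration (non-decreasing); the
  "8 h peak" anchor is therefore applied to the release *rate* dP/dt.
* The QC window default is 2 h (see Scoring above).
* The constitutive-promoter line (`4T1_COX2REST`) keeps arrest and death
  under drug; "no induction" is tested as a PGE2 ratio near 1 against its
  own vehicle control (0.6–1.4 at 24 h) contrasted with > 3 for the
  wild-type line, not as exact equality, because arrested growth alone
  perturbs cumulative PGE2.
* Time grids are hours as floats; wells are letter+number (A1..P24); areas
  µm²; pixel indexing 0-based, x right / y down.
* Seeds: a run seed drives the library draw directly and the measurement
  noise as seed+1000, so library composition and noise stream are
  independently reproducible.

## Problem sizes

The default test and acceptance runs use the full 1280-compound screen
(6 plates, 1440 simulated wells, 37 time points) — the fast path is
vectorized and takes seconds.  Image-path checks run on 20 rendered
512×512 fields (~100–200 cells each) and one rendered well time course;
the expression stage's recovery statistics use 200 panel replicates.

## Known limitations

* One field per well with homogeneous per-cell state: no spatial effects,
  no cell-to-cell transcriptional heterogeneity in the fast path (the
  renderer adds per-cell log-normal brightness, but the fast path does
  not propagate it into scores).
* The caspase proxy is a state variable (apoptotic count), not a reagent
  model; see the cisplatin calibration caveat above.
* The anthelmintic category holds only 20 compounds; a rank correlation
  estimated from ~19 QC-passing members has a sampling sd of ~0.06 around
  its ~-0.89 population value, so single-seed values can occasionally be
  nearer -0.7 — an irreducible property of the stated category size, not a
  pipeline defect.
* The expression stage models one gene, one probe scale; no microarray
  normalization or multi-gene analysis.
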