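# Methods

## Scope and coordinate conventions

The package models one circular bacterial chromosome carrying a single
integrated *pac*-type prophage. All coordinates are 0-based with half-open
intervals; interval arithmetic is modulo the chromosome length. The default
layout is P22-like: chromosome 4,857,450 bp, phage genome unit
G = 41,724 bp, headful capacity `round(1.05·G)` = 43,810 bp, packaging
initiated at a *pac* site placed at the centre of the prophage (the site
lies mid-*terS*; no base-pair coordinate is published, and no estimator
depends on its exact placement) and proceeding unidirectionally toward
attR. Reverse-oriented prophages are handled by mirroring coordinates, not
by duplicated code paths.

## Induction simulator

Each cell is stepped in 1-minute increments. Per cell the state is the
number of integrated prophage copies A (attL/attR junctions), empty attB
junctions B, excised circles, and episomal phage genome-equivalents E.
The per-minute update order is:

1. **In situ doubling.** From `repl_delay` after de-repression, A doubles
   every `repl_doubling` minutes while the cell's total phage DNA
   (A + E) is below `copy_cap` — episomal DNA competes with the
   integrated array for replication capacity, which is what makes
   locked-in (excision-deficient) mutants amplify their flanking DNA more
   than wild type. Each copy created deposits escape-replication gradient
   mass (below).
2. **Episomal amplification.** E grows by `episomal_amp`-fold per
   `repl_doubling` interval, capped at `episomal_cap`.
3. **Excision.** Once excisionase is available (`intxis_delay` after
   de-repression), each minute up to `exc_sat` copies each excise with
   probability `1 − exp(−k_exc)` — the flux saturates because excisionase
   is limiting. Every excision converts one integrated copy into one
   circle plus one attB junction.
4. **Reintegration.** Each attB junction re-acquires a circle with
   per-minute probability `reint_rate · min(E, reint_sat)` (Int-mediated
   site-specific recombination, favoured when circles are abundant).

De-repression times are drawn per cell from a truncated normal
(SOS default mean 35 min, sd 10 min, min 0 — phage repressors autocleave
far more slowly than LexA); thermal and infection modes de-repress at
t = 0, and a `spont_fraction` of thermal-mutant cells starts 30 min early
(leaky repression). Knockouts: `pri` removes all replication, `int`/`xis`
remove excision (`int` also reintegration).

### Default kinetic constants

| parameter | default | rationale |
|---|---|---|
| derepression (SOS) | N(35, 10) min, ≥0 | repressor cleavage takes tens of minutes |
| intxis_delay (SOS / thermal) | 30 / 0 min | int/xis transcripts are late after SOS, immediate after thermal induction |
| k_exc (SOS / thermal) | 0.05 / 0.2 min⁻¹ | thermal induction de-represses completely and at once |
| exc_sat | 4 copies | excisionase-limited flux |
| repl_delay, repl_doubling | 10, 10 min | in situ theta replication precedes excision under SOS |
| copy_cap | 64 genome equivalents | shared replication capacity (machinery titration) |
| escape_scale | 50 kb | decay length of flanking amplification |
| episomal_amp / cap | 4× per 10 min / 400 | rolling-circle concatemer growth |
| reint_rate, reint_sat | 0.02 min⁻¹, 20 | circle reintegration, off in thermal mode (persistent Xis keeps Int-Xis recombination excisive) and under plasmid int/xis complementation |

These constants are phenomenological, not measured rate constants: they
were fixed once, by a deterministic-flux cohort calculation, to the values
at which the simulator reproduces the qualitative programs that the
induction biology dictates — SOS wild type holds ~100 % integration, dips
between 30 and 60 min and rises after 60 min (in situ replication plus
reintegration outpacing excision); a replication-deficient (Δpri) lysogen
stays flat and then falls steeply from 60 to 90 min; a thermal mutant
collapses before 30 min; excision mutants stay at 100 %; and excision
precedes the first replication event in most thermal cells but essentially
never under SOS. A hard bound worth knowing: with a bounded integrated
copy number and irreversibly accumulating attB junctions, the population
ratio attL/(attL+attB) is eventually monotone non-increasing, so *some*
late source of attL — continued amplification with saturating excision
and/or circle reintegration — is structurally required for the late rise;
both are included and both are exposed in the config.

### Escape replication

Fork escape is modelled as a static gradient rather than explicit fork
positions: each in situ copy created adds `exp(−d/escape_scale)` to the
amplification multiplier of a bacterial window at distance d from the
nearest prophage edge, so after one doubling the profile is
`1 + exp(−d/L_esc)`. The pool stores only the cumulative gradient mass;
the profile is materialized per window on demand.

## Packaging simulator

Series counts: LT series are Poisson with mean `n_integrated ·
series_per_template`; episomal series Poisson with mean `E ·
series_per_template / E[series length]` (so packaged phage genome
equivalents match the episomal pool); GT series Poisson with mean
`gt_init_prob · n_chromosomes`. Each series draws a truncated-geometric
number of headfuls (continuation probability `processivity`, cap
`max_headfuls`; mean `(1 − p^m)/(1 − p)`), with headful sizes
N(capacity, 1 % of capacity). LT series start at *pac* and run
unidirectionally; GT series start uniformly; episomal series run on the
phage circle and are mapped back onto the prophage interval (wrapped
fragments split into parts).

Because the default GT initiation probability (2·10⁻⁴ per chromosome copy)
yields well below one GT series per thousand-cell run, GT series can be
importance-oversampled: `gt_oversample` (or an automatic boost targeting
~200 simulated series) multiplies the simulated series count while each
fragment carries weight 1/boost. All downstream statistics (marker
frequencies, coverage, read sampling) are weight-aware, so expectations
are exactly those of the unboosted process; only the variance shrinks.

Marker transfer requires the fragment to contain the marker plus a 2 kb
margin on each side — a stand-in for the flanking homology needed for
recombination in the recipient, exposed as `margin`.

## Read simulator

Reads are emitted as alignment records (interval + junction tag), not
sequence; there is no error or quality model. Junction molecules are
sampled as an explicit component: the expected number of attL-spanning
reads is `λ · n_integrated · (read_len − 2·min_overlap + 1)` with
`λ = depth/(read_len · n_cells)`, and likewise for attB, so the attL:attB
read ratio is an unbiased binomial readout of the integrated fraction.
Bulk reads are Poisson per 100 bp window with rates proportional to local
molecule abundance (bacterial windows: cells × escape-replication
multiplier; prophage windows: integrated + episomal copies). Capsid reads
are uniform within fragments with Poisson counts `reads_per_kb ×
length_kb × weight`. `min_overlap` defaults to 10 bp; reads are
single-end 75 bp.

## Estimators

- **Integration percentage** uses attL reads only in the numerator
  (attR junctions exist in the simulation but are not tagged), and a zero
  junction total is an error, not 0 %.
- **Fisher tests** use the two-sided convention that sums all tables with
  probability ≤ the observed table (verified in the tests against full
  hypergeometric enumeration for every table with row sums ≤ 12).
- **Staircase segmentation** runs an exact O(n²) dynamic program on
  log-depth with an L0 penalty and a minimum segment length
  (`min_step`, default 5 kb). The default penalty is SIC-like,
  `20 · σ̂² · log n`, with σ̂ the MAD of first differences over covered
  windows only; the ×20 inflation absorbs read-length-correlated window
  noise and the ramps that headful-boundary jitter smears across step
  edges (at ×3 the fit over-segments marginal ramps; the DP itself is
  verified against exhaustive search). Zero windows are handled by a
  pseudo-count of half the smallest positive value. The staircase is the
  leading run of segments above 1 % of the first step's height; trailing
  segments shorter than half the median interior step are the smeared
  series-end ramp and are trimmed. The first band is the pac-anchored
  partial step (capacity minus the pac→attR phage segment), so the
  recovered headful size is the mean boundary-to-boundary distance,
  excluding that first band. Processivity is
  `(h_m/h_1)^{1/(m−1)}`, the geometric mean of successive height ratios,
  clamped to [0, 1].
- **LT-region detection** walks downstream of attR over coverage smoothed
  with a 20-window moving average, extending while coverage ≥ threshold ×
  background (default 5×) and tolerating gaps of up to 5 smoothed
  windows; background is the median bacterial coverage outside the
  candidate zone (default the first quarter of the chromosome downstream
  of attR). When the background is exactly zero (no GT reads), the walk
  simply requires positive smoothed coverage.
- **Plate counts**: TrU = tfu/pfu · 10⁹ with log₁₀ (zero counts flagged
  below detection); co-transduction frequency with an exact
  Clopper–Pearson CI; 2^-ΔCT as stated.

## Scenarios and determinism

Presets (`P22_SOS_WT`, `P22_thermal_tsc`, `P22_dpri`, `P22_dint`,
`P22_dxis`, `P22_infection`, `ES18_SOS_WT`, `arabinose_sweep(T)`) differ
from the SOS wild type only in the fields their labels imply. The
arabinose sweep models plasmid int/xis complementation of an
excision-deficient lysogen: excision (k = 0.2 min⁻¹) becomes available for
all cells at absolute time T, reintegration is off, and packaging is
assessed at a fixed 250 min epoch; early T gives saturated episomal
(phage) output and no integrated templates (no LT), late T the reverse.
Every stochastic entry point takes an explicit seed; scenarios derive
per-stage child seeds from one root seed via `SeedSequence.spawn`, and
identical config + seed reproduce outputs byte for byte.

## Problem sizes

Defaults were chosen so a full desk run is light: 1,000 cells for
induction scenarios, ~6,000 LT series for staircase recovery (segmentation
then operates on ~7,000 hundred-bp windows), capsid sequencing at
1 read/kb (~1–7 M reads), WGS at 30–50×. At these sizes the staircase
recovers the 43.81 kb headful to within ±0.2 kb and processivity 0.8 to
within ±0.01 across seeds.

## What the generator does and does not emulate

Synthetic data reproduce junction-read mixtures, escape-replication
coverage gradients, the pac-anchored coverage staircase and LT/GT marker
statistics, with Poisson sampling noise throughout. They do not include
sequencing error, mapping ambiguity, GC or library-preparation bias,
paired-end structure, real recombination efficiencies (marker frequencies
are per packaged particle, not per transductant colony), cell lysis
timing, or specialized transduction (aberrant-excision hybrids). Passing
tests therefore demonstrate correctness of the estimators on data
generated by this model, not performance on real sequencing runs; the
optional SAM/BED ingestion path exists so the same estimators can be
pointed at real alignments.

## Known limitations

- Kinetic constants are qualitative: the simulator reproduces directions
  and orderings of the induction programs, not absolute copy numbers.
- Excision is modelled as uniform and independent across integrated
  copies; whether late excision is uniform across an in situ amplified
  array is not known.
- Whether re-initiation efficiency truly decays geometrically is an
  assumption; the processivity estimator makes it explicit and would
  report a non-constant ratio pattern as step-height ratios that disagree.
- The LT-region rule (threshold × background) is a formalization of what
  is, in practice, often read off a coverage plot by eye; the threshold is
  a parameter.
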