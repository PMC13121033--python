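# Methods

## Model

A nutrient supplied as a 1:1 mixture of light and heavy isotopologues
(here cystine, cleaved intracellularly to cysteine carrying ¹³C₃ and ¹⁵N)
stamps every downstream metabolite with a characteristic doublet. For a
species incorporating one labeled moiety, the heavy twin sits at

Δm = n_C·(m¹³C − m¹²C) + n_N·(m¹⁵N − m¹⁴N)

above the light feature (4.00710 Da for n_C = 3, n_N = 1), co-elutes with
it, and carries a share f = A_heavy/(A_light + A_heavy) of the summed
signal. If the probability that any given cysteine unit in a molecule is
heavy is p, then a one-cysteine species has f = p, while a two-cysteine
species distributes as (1−p)² : 2p(1−p) : p² over M+0 : M+4 : M+8; the
pair search compares only M+0 with M+4, so its fraction is
2p(1−p) / ((1−p)² + 2p(1−p)) = 2p/(1+p). Empirically p ≈ 0.24 rather than
the naive 0.5 (residual unlabeled intracellular cysteine and biosynthetic
dilution), which fixes the two default acceptance windows at 0.20–0.28 and
0.34–0.42.

All masses — the tracer shift, adduct and isotope offsets, base
metabolites, formula enumeration — derive from one atomic-mass table
(`rmatrace.chem`, backed by the NIST table in pyteomics), so no constant
is entered twice.

## Pipeline stages and their parameters

Defaults below are the method's operating point; each is a config field.

| stage | parameter | default | why |
|---|---|---|---|
| intensity | min any (non-blank) area | > 25,000 counts | instrument noise floor |
| intensity | min labeled-mix area | > 15,000 counts | pair must be measurable in a labeled sample |
| blank | enrichment fold | ≥ 4 | solvent/background exclusion |
| mass floor | minimum neutral mass | 120 Da | one Dalton below cysteine; nothing lighter can carry a cysteine |
| merge | mass window | ≤ 50 ppm | split features from small mass defects |
| merge | RT window | ≤ 0.1 min, or ≤ 0.2 min with r ≥ 0.9 | co-elution, or near co-elution with correlated areas |
| pairing | mass window | ≤ 10 ppm of theoretical partner | Orbitrap accuracy after alignment |
| pairing | RT window | ≤ 0.25 min | isotopologues co-elute |
| pairing | fraction windows | 0.20–0.28, 0.34–0.42 | calibrated on known fates (see above) |
| adduct flag | windows | ≤ 200 ppm, ≤ 0.8 min | generous: flags are cheap, deletions are not |
| isotope flag | windows | ≤ 200 ppm, ≤ 0.4 min, r ≥ 0.7, area < parent | natural satellites are smaller and correlated |
| stringent | Δppm < 1.0, ΔRT < 0.06 min | known fates never exceeded 0.66 ppm / 0.04 min | removes marginal matches |
| dedup | keep higher total ion count | negative mode on ties | determinism |

Boundary conventions: intensity floors are strict (`>`, literal reading of
"over"), the mass floor is inclusive at 120 Da ("less than 120" removed),
the blank fold is inclusive, and the stringent cutoffs are exclusive upper
bounds (`≥` removed). Merge/dedup ppm uses the smaller mass of the two as
denominator (symmetric, conservative); the pair-search ppm is referenced
to the theoretical partner mass. Pearson correlations use
pairwise-complete samples and require at least 3 shared points — below
that the correlation branch simply fails. Duplicate merging groups by
transitive closure; the merged peak takes element-wise area sums and the
mass/RT of the member with the largest total area. When several partners
satisfy all gates, all are emitted and the downstream screens adjudicate.
A partner detected in a sample where the parent is absent contributes
fraction 1.0 (outside every window) rather than an error.

## Formula enumeration

Bounded exhaustive search over C, H, N, O, P, S with per-element caps that
scale linearly with the target mass (caps 39/72/20/20/9/10 at a 500 Da
reference). Retained candidates must match within tolerance (5 ppm for
features; 10 ppm for added masses, since a difference inherits two errors),
have ring-plus-double-bond equivalents C − H/2 + N/2 + 1 ≥ 0, and pass
element-ratio plausibility screens (0.1 ≤ H/C ≤ 6, N/C ≤ 4, O/C ≤ 3,
P/C ≤ 2, S/C ≤ 3). Carbon-free candidates bypass the rdbe and ratio
screens — required so that pure-inorganic leaving groups such as H₃PO₄
enumerate. Hydrogen is solved from the residual mass rather than looped,
making the search fast enough for exhaustive correctness checks against a
six-nested-loop reference.

## Support analytics

**Cell-volume-hours.** Exponential growth N(t) = N₀·2^{kt} over an
interval T integrates to N₀/(k ln 2)(2^{kT} − 1); the k → 0 limit N₀·T is
substituted below |k| < 10⁻¹². Per-segment growth rates are inferred from
the volume ratio. With destructively sampled replicate wells, each well's
interval value is added to the *mean* accumulated value of the previous
timepoint — the replicates are coupled through the running mean because
each timepoint consumes its wells.

**Flux regression.** Medium metabolite moles are regressed on accumulated
cell-volume-hours by ordinary least squares; the slope (mol·µl⁻¹·h⁻¹) is
negative for net consumption. Points are excluded when accumulated growth
exceeds 300 µl·h (crowding slows growth and shifts fluxes) or when the
metabolite has fallen to ≤ 10 % of its initial moles (uptake is no longer
substrate-saturated); depletion exclusions propagate to user-declared
linked metabolites (e.g. glutamate efflux when cystine runs out).
Regressions pool replicates.

**Calibration.** Concentration is fitted as a function of response ratio
with linear, power-law and quadratic models; the minimum residual sum of
squares wins, with ties broken toward the simpler model so that data
exactly on a line select "linear". Power fits require positive
concentrations (log–log); quantification beyond 2× the standard range
raises an extrapolation warning.

**NRF2 classification.** The activation score is the sum over nine target
genes (ABCC2, ABCC3, AKR1B10, AKR1C1, GCLM, GSR, ME1, NQO1, TXNRD1) of
(x_i − x̄)/σ_x, with mean and s.d. (ddof = 1) across all cell lines in the
matrix; the score is invariant to shifting or rescaling a gene column.
Classification uses fixed published top-quintile cutoffs (Chronos
< −0.3028 and score > 4.06, both strict); `quintile_thresholds` can
recompute cutoffs for a new dataset, but the defaults are constants by
design so results do not drift with the input cohort.

**Fractional labeling** (tumour tracing) is M+3 / Σ(M+0..M+3) and a sample
is excluded unless both M+0 and M+3 are detected.

## The synthetic-data generator

The generator emulates the labeling experiment at the feature-table level:
eleven samples (six labeled-mix, three unlabeled controls, two blanks); 50
one-cysteine and 10 two-cysteine fates at p = 0.24; 20 adduct and 20
isotope satellites riding on the fates; 200 unpaired noise features; 20
blank-enriched contaminants. Compound total intensities are lognormal
around 10⁷ counts (sd 0.35) with per-sample loading factors (lognormal sd
0.2) shared across a compound's isotopologues — this is what makes
satellite–parent correlations high, as in real data — plus independent
per-peak lognormal noise (sd 0.05). The intensity scale matters: satellite
features at 1–30 % relative abundance must themselves clear the ion-count
floors, because that is the regime in which the adduct/isotope screens
operate. Isotope-satellite relative abundance follows ~1.1 % per estimated
carbon (carbon count ≈ 0.45·m/12), clipped to 3–30 %.

Two deliberate design choices:

* **Placement guard.** Planted compound groups are rejection-sampled so
  that no *cross-group* mass difference among co-eluting species (RT
  within 1.2 min) falls within 0.25 Da of any screening-relevant offset
  (0, ±4.0071, ±8.0142, adduct and isotope deltas; dimer relations get
  0.45 Da). Ground truth is identifiable by construction: every pairing,
  merge or flag the pipeline can make involves peaks of one planted group.
* **Correlated jitter.** Mass (ppm) and RT errors are the sum of a
  component shared within a compound group and an independent residual
  (shared variance fraction 0.8). Co-eluting isotopologues of one compound
  sit in the same scans and inherit the same local calibration and
  alignment error, so fully independent per-peak jitter would overstate
  the pair-level Δppm/ΔRT spread by √2.

What the generator does **not** emulate: peak-shape and integration
artifacts, intensity-dependent mass error, RT drift between batches,
in-source fragments, chimeric features, or real compound-density mass
clustering (true tables are not uniform in mass). Passing the end-to-end
recovery tests therefore demonstrates the correctness of the decision
logic at the stated tolerances, not detection performance on real
chromatography.

`simulate_growth_series` produces exponential-growth volume series with
medium moles following initial − rate·CVH plus Gaussian noise scaled to
the dynamic range.

## Numerical and testing choices

* Masses are serialized at full precision (`repr`) so tables round-trip
  losslessly; 1 ppm at 1000 Da is 10⁻³ Da.
* Pair search and duplicate merging use mass-sorted windows; both are
  verified against naive all-pairs references (plain loops, flooding for
  connected components) on random tables up to 500 peaks.
* Stochastic estimator checks (flux slope at 5 % noise) assert that
  *bias* over 40 replicate series stays below the typical standard error;
  a single draw against a 1σ bound would fail a third of the time by
  construction regardless of correctness.
* Deterministic outputs: sorted emission orders, explicit tie-breaks
  (negative mode, then lexicographic id), seeded generators everywhere.
* Problem sizes in the test suite (≈ 200–500 features per table, 20
  oracle tables, 200-fate fraction studies) keep the whole suite in a few
  seconds while leaving every rule exercised at its boundary.

## Known limitations

* Only the single tracer shift is searched; simultaneous M+8 gating for
  two-cysteine species exists in the generator and the fraction algebra,
  not as an independent search gate.
* The adduct/isotope rule lists are sensible CHNOPS defaults, not a claim
  about any particular instrument's in-source behavior; both are CSV-
  overridable.
* Formula enumeration ranks by mass error only; no isotope-pattern or
  MS/MS evidence is consulted, and isobaric regioisomers are out of reach
  by construction.
* The NRF2 classifier's published cutoffs apply to the release they were
  derived from; applying them to other expression/dependency matrices
  requires recomputing quintiles.
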