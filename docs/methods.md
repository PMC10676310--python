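# Methods

## Scope and data model

`mirstab` analyses two-group plasma RT-qPCR panels exported as delimited
text: a Cp (crossing-point) table with per-well status flags, a Tm-calling
table with melting peaks, and raw melt fluorescence series, joined through
a panel layout mapping each (plate, well) to a (sample, assay). Assays are
typed as targets (eligible for stability analysis), extraction spike-ins
(UniSp2/4/5), reverse-transcription spike-ins (UniSp6, cel-miR-39-3p), one
interplate calibrator (UniSp3) per panel, and a blank. Cp is treated as
computed upstream by the instrument software; the package never re-derives
it from amplification curves.

Because instrument export layouts vary with regional settings, all readers
are driven by a `Dialect` (separator, decimal mark, status vocabulary,
wide/long melt layout, peak-column cap of 5). The defaults — tab-separated,
header row, decimal point, wells addressed as "A1", plates identified by a
`Plate` column or the file name — are a pragmatic guess to be adjusted
against real files; unknown status strings fail loudly rather than being
coerced.

## QC pipeline

The stage order is fixed: calibrate → cutoff → reaction categorization and
melt review → spike-in sample exclusion → complete cases → group merge.
Every removal is written to an audit log (one JSON record with stage and
reason), and a workflow ledger asserts datapoint conservation
(`in = out + removed`) at every node.

**Interplate calibration.** `Cp_adj = Cp − (mean calibrator Cp on the
plate − grand mean over plates)`. The offset is applied to all wells of
the plate, calibrator wells included, which makes the operation idempotent;
a plate without a usable calibrator Cp is an error.

**Detection-limit cutoff.** Cp strictly greater than 35 cycles is set to
missing ("above the threshold"; Cp = 35.00 exactly is retained). Assays
left with no detected value are dropped and reported.

**Reaction categorization.** The instrument's Cp status (approved /
uncertain / absent / late) and Tm status (approved / inconclusive / absent)
are combined through a decision matrix: both approved → auto-approved; Cp
absent or late → rejected; every other combination that carries a Cp →
melt review. The matrix is overridable in configuration.

**Melt review.** Manual melt-curve assessment is replaced by deterministic
rules. Peaks are located on −dF/dT after smoothing the fluorescence with a
centred 5-point moving average; local maxima below a 0.1 FU/°C noise floor
are ignored, and peak positions are refined by a local parabola. A
reaction is rejected if there is no clear peak, the primary peak is below
0.5 FU, a secondary peak reaches at least half the primary, more than two
peaks are present, or the primary peak lies more than 1.5 °C from the
reference Tm — the median primary-peak temperature of auto-approved
reactions of the same assay (with no reference available, the proximity
test is skipped and flagged in the reason). Instrument-reported peak
heights are preferred when present; otherwise the −dF/dT amplitude is
used. An override file (well → verdict) can mimic true manual calls.

**Spike-in QC.** Within each group, a sample is excluded when its UniSp2
Cp lies outside Tukey fences (quartiles by linear interpolation,
±1.5×IQR, computed once on the pre-exclusion group — single pass, which
also makes the rule order-independent with the ΔCp window), or when
Cp(UniSp4) − Cp(UniSp2) falls outside the closed interval [5, 8] cycles.
UniSp5 is not consulted: at its dilution it sits above the detection limit
in plasma. Missing spike values exclude the sample with reason "spike
missing". The hemolysis indicator ΔCp = Cp(miR-23a-3p) − Cp(miR-451a)
flags "hemolysed" above 7 cycles and "borderline" within 2 cycles below
(the conventional 5/7-cycle bands; configurable); miR-451a typically comes
from a separate QC panel, so this check is optional and outside the main
pipeline.

**Complete cases.** Per group, assays split into complete (detected in
every retained sample), incomplete, and excluded (no values); only
complete cases enter stability analysis. Groups are merged on their common
assay set.

## Stability algorithms

All algorithms run on Cp values directly, assuming amplification
efficiency 2 so that Cp differences are log2 expression ratios. Sample SDs
use the n−1 denominator throughout. Lower values mean more stable.

- **delta-Ct**: S_i = mean_{j≠i} SD_samples(Cp_i − Cp_j).
- **BestKeeper**: the mean absolute deviation around the arithmetic mean.
  Only the MAD enters the ensemble (the full BestKeeper
  regression/correlation analysis is out of scope); geometric-mean
  centring, the original tool's convention, is available behind a flag.
  MAD is deliberately *not* invariant to per-sample shifts — it ignores
  the other candidates — which is why it systematically disagrees with
  the other three algorithms.
- **geNorm**: M_i is the mean pairwise-difference SD over the current
  candidate set; the worst candidate is excluded stepwise (ties broken by
  excluding the later candidate in input order) and reports its M at
  exclusion; the final two candidates share the final-round M and hence
  tie at rank 1. The stepwise-reported variant is used because only it
  produces the characteristic two-way tie at the top of published
  stability tables. The pairwise-variation criterion for choosing how
  many references to use is not implemented.
- **NormFinder** (ungrouped): with z_ij = y_ij − mean_i(y_ij)
  (sample-centred values) and u_i = Var_j(z_ij), the method-of-moments
  inversion σ̂²_i = (k/(k−2))(u_i − Ŝ/k²), Ŝ = (k/(k−1))Σu_i gives
  ρ_i = σ̂_i. Negative variance estimates are floored at zero before the
  square root.
- **NormFinder** (grouped): the same decomposition per group yields
  σ̂²_ig; intergroup deviations d̂_ig (per-gene group means of z, centred
  across groups) are shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g), with
  γ̂²_g = max(0, Var_i(d̂_ig) − mean_i(σ̂²_ig/n_g)) estimated per group
  (with two groups the d̂ columns are mirror images, so the groups differ
  only through their intragroup terms). The stability is
  ρ_i = mean_g(|d̃_ig| + SE_ig) with SE_ig the posterior SE of the
  shrinkage estimate, √(γ̂²v/(γ̂²+v)), v = σ̂²_ig/n_g. The **best-pair
  search** scores every unordered pair with the pair's averaged shrunken
  deviations and intragroup variance (σ̂²_i + σ̂²_j)/4, combined exactly
  like a single candidate, and returns the arg-min with the full table.
  The implementation is pinned by an independent scalar transcription of
  these formulas in the test suite (agreement to 1e-6).
- **RefFinder**: competition ranks (ties share the minimum rank; the next
  distinct value counts all strictly better candidates plus one) per
  algorithm, aggregated as the geometric mean of the four ranks and
  re-ranked. Plain competition ranks reproduce every published aggregate
  value checked.

Output tables round to 3 decimals; all internal computation is full
precision. No multiple-testing machinery is involved — this is ranking,
not hypothesis testing.

## Synthetic cohorts

The generator emulates the study conditions of a two-group plasma panel:
60 carcinoma and 48 benign samples, a 48-assay panel (40 miRNA targets +
U6, five spike-ins, calibrator, blank), eight samples per 384-well plate
(plates = ⌈n/8⌉). Target values follow

    Cp_ij = baseline_i(group) + sample_j + plate_p(j) + ε_ij

with per-assay group-specific baselines and SDs defaulting to values
observed in plasma for this panel, a shared within-sample effect
(SD 0.8 cycles), plate offsets (SD 0.3) removable by calibration, and
mechanistic missingness: values above the detection limit (Cp 35) are
emitted as "late" calls up to 45 cycles and "absent" beyond — low-abundance
assays censor out exactly as they do in real plasma data. Because observed
SDs are reused as residual SDs on top of the sample and plate effects, the
simulated marginal spread slightly exceeds the observed values; two assays
whose published SD was not reported (detected in ≤2% of samples) use a
nominal 0.3, and never-detected assays get baseline 37.5. Four
designed-stable references (hsa-miR-23a/27a-3p, -126-3p, -191-5p) are
planted with zero group shift and residual SD 0.5 (about a quarter of the
panel median) — the recovery experiments measure whether the ensemble
finds them. All other assays carry the observed benign-vs-carcinoma mean
difference as their group shift.

Spike-ins sit at 100-fold concentration steps (UniSp2 ≈ 19,
UniSp4 ≈ 25.64; UniSp5 defaults to 35.9, above the detection limit, as
observed in plasma) with bounded uniform technical noise (±0.4 cycles).
Bounded noise is a deliberate choice: the 1.5×IQR rule is scale-free, so
with Gaussian noise ~0.7 % of perfectly normal samples would be flagged
regardless of the SD; with uniform noise the fences sit at about twice the
noise bound and only planted failures are flagged, giving the clean
margins the QC-exactness tests rely on. Injected failures — ΔCp forced
into [3.2, 4.6] or [8.4, 9.6], UniSp2 shifted by 3–5 cycles with the ΔCp
ladder preserved — and melt artifacts (sub-0.5 FU peaks, half-height
doubles, triples) are recorded in a ground-truth object. Melt artifacts
are planted only in assays with baseline Cp above 28 cycles, reflecting
that primer-dimer and non-specific products concentrate in weakly
amplifying reactions; this also reproduces the observed structure of a
low-Cp complete-case core (~13 assays) with the weaker assays incomplete.
Raw melt curves (−dF/dT = sum of Gaussian bumps, σ ≈ 0.8 °C, integrated
to a fluorescence series on a 65–95 °C, 0.2 °C grid) are materialised for
the wells that reach melt review.

Randomness is organised as deterministic sub-streams per sample/plate
derived from one seed, so cohorts are byte-reproducible and injections are
idempotent per seed.

What the generator does **not** model: amplification kinetics, hemolysis
chemistry (a flag can add miR-23a/451 pairs for testing the indicator, but
the default cohort is hemolysis-free), assay cross-correlations beyond the
shared sample effect, and truncation effects that make observed
mean/SD of heavily censored assays differ from their latent values.
Passing the recovery tests therefore shows the ensemble finds designed
low-variance, group-balanced references under realistic noise, censoring
and QC contamination — not that it would resolve the subtler correlation
structure of real plasma panels.

## Numerical and design choices

- Quartiles by linear interpolation (numpy default), matching the stated
  outlier rule.
- ΔCp window closed: [5, 8] retains the bounds ("less than five" / "more
  than eight" excluded).
- Cutoff boundary: Cp = 35.00 retained, anything strictly above censored.
- Duplicate temperatures in melt exports collapsed by mean; a grid still
  non-monotone afterwards is a format error.
- Tables round-trip through TSV with the token "NA" for missing values and
  round-trip float parsing.
- geNorm needs ≥ 3 candidates; NormFinder ≥ 3 candidates and (grouped)
  ≥ 2 groups of ≥ 3 samples; delta-Ct ≥ 2 candidates and samples.
- Degenerate variance cases: shrinkage factors are defined as 0 when both
  the intergroup and scaled intragroup variances vanish; negative
  moment estimates are floored at 0.

## Problem sizes used in the checks

The test suite and the acceptance script run the default cohort
(108 samples × 48 assays) end to end; recovery rates are measured over 20
replicate cohorts, algorithm/oracle equivalence over 200 random 5×12
matrices and 20 random grouped matrices. These sizes keep a full run in
the tens of seconds while matching the study scale where it matters (the
cohort dimensions and complete-case sizes).

## Known limitations

- The automated melt classifier reproduces the published rejection rules,
  but real manual review sees curve shape beyond peak lists; the override
  file exists precisely to reinsert human calls.
- The exact instrument export column layout is configurable but the
  defaults are unverified against real LightCycler files.
- The grouped-NormFinder γ̂² estimator is interpreted per group; with two
  groups this differs from a pooled estimate only through the intragroup
  means. The reproduction test against the study's deposited complete-case
  matrices (which would pin this numerically) requires those files to be
  supplied by the user, as they are not redistributable here.
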