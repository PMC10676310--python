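# mirstab

Stability analysis of endogenous reference miRNAs in plasma RT-qPCR panels.

## The problem

Circulating miRNAs are promising minimally invasive biomarkers — for
example in high-grade serous ovarian carcinoma (HGSOC), where early
diagnosis tools are lacking — but RT-qPCR quantification is only as good as
its normalization. There is no universal endogenous control: the usual
candidates (e.g. U6 snRNA) drop out of plasma samples or vary between
disease groups, so suitable references must be validated per study, on
quality-controlled data. `mirstab` packages that whole workflow for
two-group plasma cohorts measured on custom miRNA PCR panels
(LightCycler-style text exports):

1. **Parsing** of Cp tables, Tm-calling tables and raw melt-curve series,
   plus panel layout and sample sheet.
2. **Interplate calibration** against an interplate calibrator assay
   (UniSp3): `Cp_adj = Cp − (plate calibrator mean − grand calibrator mean)`.
3. **Detection-limit cutoff**: Cp > 35 set to missing; assays with no
   detected value removed.
4. **Reaction categorization and melt-curve review**: reactions approved by
   both the Cp and Tm software calls are auto-approved; reactions with a Cp
   but any other status combination get an automated version of manual melt
   review — reject if no clear peak, primary peak < 0.5 FU, a second peak ≥
   half the primary, more than two peaks, or the primary peak far from the
   assay's reference Tm.
5. **Spike-in sample QC**: a sample is excluded when its UniSp2 Cp is a
   ±1.5×IQR outlier within its group or when Cp(UniSp4) − Cp(UniSp2) falls
   outside 5–8 cycles (the spikes are added at 100-fold concentration
   steps, ≈ 6.64 cycles). A hemolysis indicator
   ΔCp = Cp(miR-23a-3p) − Cp(miR-451a) is available as an optional check.
6. **Complete-case assembly** per group (assays detected in every retained
   sample) and merging of groups on the common assay set.
7. **Stability ensemble** on the complete cases.

## The statistics

For a complete-case matrix of Cp values (assays *i*, samples *j*; Cp
differences are log2 expression ratios at amplification efficiency 2):

- **comparative delta-Ct** — S_i = mean over partners j≠i of
  SD(Cp_i − Cp_j) (sample SD, n−1);
- **BestKeeper (MAD)** — MAD_i = mean_j |Cp_ij − mean(Cp_i)|;
- **geNorm** — M_i = mean over partners of V_ik = SD(Cp_i − Cp_k), with
  stepwise exclusion of the worst candidate; the reported M is the value at
  the exclusion round, and the final two candidates share the final M;
- **NormFinder** — model-based variance decomposition of sample-centred
  values; with groups, the stability is the mean over groups of
  |d̃_ig| + SE(d̃_ig), where d̃ is the intergroup deviation shrunk by
  γ²/(γ² + σ²_ig/n_g). A grouped **best-pair search** scores every
  candidate pair by averaging the members' shrunken deviations and a
  quarter of their summed variances;
- **RefFinder** — G_i = (r_i,ΔCt · r_i,BK · r_i,NF · r_i,geNorm)^(1/4),
  the geometric mean of the four competition ranks (ties share the minimum
  rank), re-ranked for the final ordering.

A synthetic-cohort generator (`mirstab.simulate`) emulates the whole data
world — two-group plasma panel with per-assay baselines, shared sample and
plate effects, detection-limit censoring, spike-ins, melt curves, and
injectable QC failures with recorded ground truth — so the pipeline is
fully exercisable without instrument data. See `docs/methods.md` for model
details and limitations.

## Worked example

```python
import mirstab

cohort = mirstab.simulate_cohort(seed=1)              # 60 HGSOC + 48 benign
bundle = mirstab.run_pipeline_from_cohort(cohort)
print(bundle.workflow.render())
print(mirstab.format_stability_table(bundle.stability["combined"]).head(5))
```

prints the filtering ledger (Cp datapoints arriving at each node):

```
[input] in=4428 removed=0 (samples -0, assays -0) -> out=4428
[cp_cutoff] in=4428 removed=830 (samples -0, assays -0) -> out=3598
[reaction_qc] in=3598 removed=90 (samples -0, assays -0) -> out=3508
[spike_qc] in=3508 removed=326 (samples -10, assays -0) -> out=3182
[complete_cases] in=3182 removed=1820 (samples -0, assays -0) -> out=1362
[combine_groups] in=1362 removed=88 (samples -0, assays -0) -> out=1274
```

and the top of the combined stability table:

```
        Target  Avg. STDEV  Rank   MAD  Rank  Stability  Rank  Avg.M  Rank  Geom. mean value  Rank
hsa-miR-23a-3p       1.809     1 0.753     4      0.585     1  0.626     1             1.414     1
hsa-miR-126-3p       1.832     3 0.709     2      0.666     3  0.626     1             2.060     2
hsa-miR-27a-3p       1.818     2 0.733     3      0.608     2  0.689     3             2.449     3
hsa-miR-191-5p       1.843     4 0.700     1      0.666     4  0.752     4             2.828     4
hsa-miR-486-5p       2.399     5 1.528     5      1.669     5  1.805     5             5.000     5
```

Ten samples were excluded by spike-in QC (exactly the generator's planted
failures), 830 datapoints fell above the Cp 35 cutoff, and the four
designed-stable references planted by the generator occupy the top four
aggregate ranks. The same run is available from the shell:

```bash
mirstab run --simulate --seed 1 --outdir results/
mirstab simulate --seed 1 --outdir exports/      # write instrument exports
mirstab qc --indir exports/ --outdir results/    # ... and analyse them
```

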