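# mferg-emd

Adaptive filtering and normative-template correlation analysis of
multifocal electroretinogram (mfERG) recordings, built around empirical
mode decomposition (EMD).

## The problem

An mfERG exam records the quasi-simultaneous first-order-kernel responses
of 61 hexagonal retinal sectors (here 84 samples per sector at 1017 Hz,
amplitudes in nV).  Each sector waveform is tri-phasic — a trough N1, a
peak P1 and often a second trough N2 — but individual sectors have very
low signal-to-noise ratio, so clinical analysis fuses them into 10
clusters: the whole field (SUM), five eccentricity rings R1–R5 and four
quadrants (IN, SN, ST, IT).  The question this package addresses is
whether subtle, diffuse waveform alterations (as seen in early
neurodegenerative disease) can be detected by comparing a subject's
cluster waveforms against a normative database, and whether EMD-based
denoising sharpens that comparison.

## The method

For sector *S* of subject *i* with trace x_S(n):

1. **Normative template.**  X_S^TEM(n) = mean over the control subjects'
   sector-S traces.  A control subject is always evaluated against the
   leave-one-out template that excludes their own recording.
2. **Adaptive EMD filter.**  x_S is decomposed into 4 intrinsic mode
   functions (IMFs) plus residue, x = Σ_k IMF_k + r.  The four partial
   reconstructions x^(k) = Σ_{j≥k} IMF_j + r (k = 1..4) progressively
   strip the highest-frequency modes.  The filter keeps the x^(k) with
   the highest Pearson correlation against X_S^TEM; if all four
   correlations are negative the sector is non-analyzable (NaS).
3. **Cluster features.**  Per cluster: the Pearson correlation of the
   cluster-averaged trace with the cluster-averaged template, computed on
   raw signals (PCC_RAW) and on filtered signals (PCC_EMD), and the N1
   amplitude A_N1 = |baseline − min in the 9–32 ms window| on raw
   signals.
4. **Group statistics.**  Per cluster × feature: Shapiro–Wilk-gated
   two-sample testing (Welch's t-test if both groups are normal at
   α = 0.05, Mann–Whitney U otherwise) and the rank-based AUC, with a
   fixed a-priori direction (controls higher for PCC, patients higher
   for A_N1).

Because clinical recordings are rarely shareable, the package ships a
seeded synthetic cohort generator (`mferg_emd.simulate`) that emulates
the statistical structure this analysis assumes — tri-Gaussian sector
waveforms with eccentricity-dependent gain, subject-level amplitude and
timing variability, common-mode plus per-sector noise, and a
configurable patient-group perturbation — so the whole chain is testable
end to end.

## Worked example

```bash
mferg-emd simulate --seed 1 --out cohort.csv
mferg-emd run --input cohort.csv --out results/
```

which prints (numbers from this exact invocation):

```
analysis written to results/
  mean AUC A_N1: 0.471
  mean AUC PCC_RAW: 0.909
  mean AUC PCC_EMD: 0.951
  mean 4-IMF energy fraction (controls): 129.84%
```

Reading: on this synthetic cohort (6 controls, 15 patients) the N1
amplitude barely discriminates the groups (mean AUC ≈ 0.47, chance is
0.5), correlating raw cluster waveforms against the normative template
discriminates well (0.91), and EMD-filtering the sectors before
correlating discriminates best (0.95).  `results/summary.csv` holds the per-cluster means ± SD,
p-values, tests used and AUCs; `results/usage_table.csv` tabulates which
reconstruction depth k the filter chose per group and the NaS rates;
`results/features.csv` has every per-subject feature.  The 4-IMF energy
share can exceed 100% because IMFs are not exactly orthogonal on noisy
traces (see `docs/methods.md`).

The same analysis is available as a library:

```python
from mferg_emd import CohortConfig, make_cohort, run_pipeline
result = run_pipeline(make_cohort(CohortConfig(seed=1)))
print(result.mean_auc)
```

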