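# drgpd

Stimulated-echo-corrected proton-density mapping of the dorsal root ganglia
(DRG) and the cohort statistics linking DRG metrics to small-fibre
neuropathy (SFN).

## Who this is for

Quantitative-MRI and neuroimaging researchers working with multi-echo
spin-echo (CPMG) acquisitions of the lumbosacral DRG — in Fabry disease or
other small-fibre neuropathies — who need (a) B1-robust M0/T2 maps, (b) a
CSF-normalised DRG proton density (DRG-PD) per subject, and (c) the
rank-based group comparisons, effect sizes, ROC, ICC and regression models
used to relate those metrics to clinical status. Everything is testable
without patient data through built-in phantom and cohort generators.

## The method in brief

A CPMG train ideally decays as `S_k = M0·exp(−TE_k/T2)`, but B1
inhomogeneity lowers the effective refocusing flip angle α below 180°,
creating stimulated echoes that flatten the decay and bias naive fits. Per
voxel, the pipeline:

1. fits `log S_k` by weighted least squares → preliminary `(M0, T2)`;
2. estimates α from the first-to-second echo ratio, which carries the
   stimulated-echo excess: `S2/S1 > exp(−ΔTE/T2)` whenever α < 180°;
3. simulates a unit-M0 extended-phase-graph (EPG) train at `(α, T2)`, fits
   it the same way, and divides the measured estimates by the fitted
   values — the biases κ_M0, κ_T2 — to undo the distortion;
4. iterates 2–3 to a fixed point.

`DRG-PD = median(M0_corr over DRG voxels) / 98th percentile(CSF M0 in the
same slice)`, making the metric invariant to any global or per-slice
intensity scaling. DRG-T2 is the median corrected T2 (ms) and DRG-Vol the
labelled volume (mm³). The statistics layer implements Mann–Whitney U,
Cliff's δ (with `AUC = (δ+1)/2` as an exact rank identity), ROC, Spearman
ρ, ICC(2,1), and multivariable linear/logistic models with AIC and
McFadden pseudo-R². See `docs/methods.md` for assumptions and numerical
details.

## Worked example

```python
import numpy as np
from drgpd import (SequenceParams, TissueState, epg_cpmg, fit_voxel,
                   CohortSpec, cohort_generate, sfn_analysis)

seq = SequenceParams()                      # 10 echoes, 15 ms spacing
train = epg_cpmg(TissueState(M0=1.0, T2=95.0, T1=1000.0), alpha=130.0, seq=seq)
print(np.round(train.amplitudes, 4))
# [0.7014 0.7388 0.5514 0.5228 0.4355 0.3809 0.3257 0.2915 0.2373 0.2222]

vf = fit_voxel(train.amplitudes, seq)
print(f"M0_prelim={vf.M0_prelim:.3f}  T2_prelim={vf.T2_prelim:.1f}")
print(f"M0_corr={vf.M0_corr:.3f}  T2_corr={vf.T2_corr:.1f}  alpha={vf.alpha_eff:.1f}")
# M0_prelim=0.877  T2_prelim=108.7
# M0_corr=1.000  T2_corr=95.0  alpha=130.0
```

The naive fit underestimates M0 by 12% and overestimates T2 by 14% (the
second echo is *higher* than the first — a pure stimulated-echo
signature); the corrected fit recovers the generating values and the flip
angle. At cohort level:

```python
table, _ = cohort_generate(CohortSpec(seed=1))   # n=80 synthetic cohort
res = sfn_analysis(table)
gc = res["group_comparisons"][("classical", "drg_pd")]
print(f"n={gc.n_pos}/{gc.n_neg}  medians {gc.median_pos:.3f}/{gc.median_neg:.3f}  "
      f"p={gc.p_value:.4f}  delta={gc.delta:.2f}")
print(f"AUC={res['roc']['classical'].auc:.3f}  (delta+1)/2={(gc.delta+1)/2:.3f}")
# n=8/9  medians 0.758/0.707  p=0.0002  delta=0.97
# AUC=0.986  (delta+1)/2=0.986
```

SFN-positive classical-phenotype subjects show elevated DRG-PD; the ROC
AUC equals the rank transform of Cliff's δ exactly.

### Command line

```bash
drgpd phantom --out run/ph --seed 1          # synthetic dataset (NIfTI + CSV)
drgpd fit --echoes run/ph/echoes.nii.gz --out run/maps
drgpd pd  --m0 run/maps/M0.nii.gz --t2 run/maps/T2.nii.gz \
          --labels run/ph/labels.nii.gz --out run/metrics.csv
drgpd stats --cohort run/ph/cohort.csv --out run/stats
drgpd pipeline --out run/all --seed 1        # all of the above
```

Every output directory receives the resolved `config.yaml` and a
`provenance.json`; identical config + seed reruns are byte-identical.

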