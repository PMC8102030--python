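# herbdiff

Differentiating two closely related herbal drugs — *Chrysanthemum
morifolium* flower (CM) and *Chrysanthemum indicum* flower (CI) — from
HPLC fingerprints and marker-compound contents.  The two species look
alike, share most of their phenolic chemistry (caffeoylquinic acids and
flavone glycosides), and are routinely confused in trade, yet they are
used for different medicinal and food purposes.  `herbdiff` implements
the complete analytical workflow a quality-control lab would run, as a
tested Python package for analytical chemists and chemometricians:

1. **Fingerprint similarity** — 18 common HPLC peaks matched by retention
   time; each sample's area vector scored against the pooled mean
   chromatogram by angle cosine or Pearson correlation.
2. **Marker screening** — OPLS-DA (one predictive + k orthogonal latent
   components, NIPALS) on relative peak areas; candidate markers satisfy
   VIP > 1.0 and Student's-t p < 0.05.
3. **Single-standard quantification (SSDMC/QAMS)** — one calibrated
   internal reference per compound class quantifies its whole family via
   relative response factors:

       RRF_x = (1/N) Σ_i (A_si/C_si)/(A_xi/C_xi),   C_x = A_x·C_s·RRF_x/A_s

   with relative retention times (RRT = rt_x/rt_s) for standard-free peak
   identification, molecular-weight-ratio extrapolation
   (RRF = Mr_x/Mr_base · RRF_base) for analytes lacking standards, and a
   full validation battery (linearity, LOD/LOQ at S/N 3/10, repeatability
   and precision RSDs, 75/100/125% spike recovery, paired-t / F-test
   comparison against the external standard method).
4. **MS annotation** — monoisotopic masses from molecular formulas,
   [M-H]⁻ m/z, ppm errors, and greedy neutral-loss assignment (caffeoyl,
   sugar residues, malonyl, CH₃, CO₂ ...).
5. **Species call** — a binary logistic discriminant affine in the six
   marker contents: Y = b₀ + Σ b_x·C_x, with Y < 0 ⇒ CM and Y ≥ 0 ⇒ CI;
   both the published equation and a freshly fitted penalized model.

Because no raw chromatograms are deposited with the study, every stage is
driven by a first-class synthetic-data generator (`herbdiff.simulate`)
that reproduces the study's structure: 53 CM + 33 CI batches, published
per-class content totals, CI deficiency of peaks 11/12/14/15/16 and
six-fold linarin enrichment, seven-level two-fold calibration dilutions,
1% multiplicative area noise, and 0.02-min retention-time jitter.

## Worked example

```sh
herbdiff run-all --seed 42 --outdir demo
```

prints (and writes to `demo/summary.json`):

```
seed: 42
n_samples: 86
n_common_peaks: 18
mean_similarity: {'CI': 0.8436, 'CM': 0.904}
opls: {'r2x': 0.7113, 'r2y': 0.6995, 'q2': 0.6317}
selected_markers: [11, 12, 14, 15, 16, 17, 18]
n_quant_results: 860
holdout_accuracy_pct: 100.0
resubstitution_accuracy_pct: 100.0
fitted_model: {'intercept': 14.8379, 'coefficients': {6: -1.0176, 10: -10.1094,
  11: -25.7767, 13: -7.9159, 15: -24.5015, 16: -15.6923}}
```

Reading the output: the 86 synthetic batches all match the 18-peak
template; CM samples sit closer to the pooled mean chromatogram (cosine
0.904) than CI samples (0.844); the OPLS-DA model cross-validates at
Q² = 0.63 and the VIP/t screen selects the structurally class-distinct
peaks (the CI-deficient peaks 11–16, linarin 18, plus peaks whose
*relative* areas shift with the class); SSDMC quantification of the six
marker peaks feeds a logistic discriminant whose negative scores flag CM —
here it labels every held-out sample correctly.  Stage tables
(`similarity.csv`, `markers.csv`, `rrf.csv`, `quant.csv`,
`classification.csv`) land in the run directory.

Library use mirrors scikit-learn:

```python
import numpy as np
from herbdiff import OPLSDA, match_common_peaks, generate_sample_set

tables = generate_sample_set()                 # 53 CM + 33 CI batches
m = match_common_peaks(tables)                 # samples x 18 peak areas
model = OPLSDA(n_ortho=1).fit(m.rpa(), np.array(m.class_labels))
model.vip_, model.r2x_, model.r2y_, model.q2_
```

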