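# chrombind

Quantification toolkit for studies of transcription-factor (TF) binding
to mitotic chromosomes and its relation to TF mobility, single-molecule
binding kinetics and genome occupancy.

Many TFs remain associated with condensed mitotic chromosomes, largely
through non-specific DNA binding.  Measuring that association — and
relating it to interphase dynamics — requires a chain of bespoke
quantifications that this package implements as a tested, reusable
library:

- **Mitotic bound fraction (MBF)** from two-channel metaphase images:
  `MBF = S_chrom·V_chrom / (S_cyto·V_cyto + S_chrom·V_chrom)` with
  `V_chrom = 0.16`, plus three-bin classification (depleted < 16.5% ≤
  intermediate ≤ 23% < enriched) and per-TF summaries.
- **FRAP kinetics**: double normalization of three-ROI traces,
  single-exponential recovery fit `I(t) = I0 − a·e^{−βt}`, half-time
  `t_1/2 = ln2/β` and immobile fraction `Imof = 1 − a/(1 − (I0 − a))`,
  with bootstrap confidence intervals.
- **Single-molecule kinetics**: spot detection (2D Gaussian refinement),
  track linking, chromatin-bound event calling (confinement in a
  160-nm-diameter region for ≥ 2 consecutive frames), Hoechst-class
  assignment, pseudo on-rates `ψon = N_b/(A_a·N_tot·T)` and the
  residence-time proxy `τ_res = (1/N_tot)Σ t_b,j`.
- **Sequence features** (composition categories, GRAVY sum, charge runs,
  disorder content, DBD net charge, positive-charge dispersion, DBD
  family flags) and **lasso stability selection** of MBF-predictive
  features (repeated 401/100 splits, CV-chosen penalty, ≥ 90% retention
  rule) as a scikit-learn-compatible estimator.
- **Co-localization**: nuclear pixel-wise Pearson correlation and TF
  signal fractions in k-means-defined chromatin-density regions.
- **Association statistics**: Pearson/Spearman correlations and the
  Wilcoxon rank-sum test with exact small-sample p-values, and the
  fraction of occupied motifs (FOM).
- **Synthetic data generators** for every stage, with closed-form ground
  truth, used by the test suite and the reproduction script.

## Worked example

```python
import chrombind as cb
from chrombind.synthetic import gen_metaphase_cell, gen_frap_trace

# a metaphase cell with chromosomes twice as bright as the cytoplasm
cell = gen_metaphase_cell(200.0, 100.0, noise_sd=10.0, seed=7)
m = cb.quantify_cell(cell.dna, cell.tf)
print(f"true MBF {cell.true_mbf:.4f}")
print(f"est: S_chrom={m.s_chrom:.1f} S_cyto={m.s_cyto:.1f} mbf={m.mbf:.4f} bin={m.bin}")

# a FRAP trace and its recovery fit
tr = gen_frap_trace(0.85, 0.45, 0.12, noise_sd=0.02, seed=3)
fit = cb.fit_trace(tr.trace)
print(f"frap: I0={fit.i0:.3f} a={fit.a:.3f} beta={fit.beta:.4f} "
      f"t_half={fit.t_half:.2f} imof={fit.imof:.3f}")
```

prints

```
true MBF 0.2759
est: S_chrom=200.2 S_cyto=100.0 mbf=0.2761 bin=enriched
frap: I0=0.855 a=0.463 beta=0.1219 t_half=5.69 imof=0.239
```

The cell's planted 2:1 chromosome/cytoplasm intensity ratio corresponds
to a true MBF of 32/116 ≈ 0.276 under the 16%/84% volume bookkeeping; the
segmentation-based estimate recovers it to three decimals and bins the TF
as chromosome-enriched.  The FRAP fit recovers the planted recovery rate
within a few percent at realistic noise; `t_half` is the recovery
half-time in seconds and `imof` the fraction of molecules that never
exchanged during the recording (truth: 5.78 s and 0.250).

A command-line interface mirrors the library
(`chrombind simulate|mbf|frap|smk|feats|select|coloc|assoc --help`).

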