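# rsfi

Resting-state functional interactivity analysis: compare **cyclicity
analysis** (signed-area lead matrices) with the classical similarity-based
connectivity measures — zero-lag correlation, lagged correlation, and
dynamic-time-warping distance — on multivariate BOLD-like time series.

## Who this is for

Researchers analyzing region-of-interest (ROI) fMRI time series who want to

* extract pairwise interaction features beyond zero-lag correlation,
* test how preprocessing choices (band-pass filtering, global signal
  regression, scaling) change those features,
* fingerprint individuals across scan sessions, and
* probe group separability with classical and neural classifiers.

Because real cohorts are rarely shareable, the package ships a synthetic
generator that emulates the assumed data structure — cyclic signals with a
planted temporal ordering, stable subject signatures, a shared global
component, and autocorrelated noise — so every claim in the test suite is
checked against known ground truth.

## The measures

For two signals `f(t)`, `g(t)` observed on `[0, T]` and equal-valued at the
endpoints, cyclicity analysis assigns the signed algebraic area

```
A_fg = 1/2 ∮ ( g df − f dg )
```

positive when `g` follows `f`. Over `N` regions this yields a skew-symmetric
**lead matrix** `A`; the phases of the leading eigenvector of `A` recover the
collective temporal ordering of the regions, and the construction is
invariant under monotone re-parameterizations of time — the defining
property of *cyclic* (repetitive but aperiodic) signals.

The comparison features are the zero-lag Pearson **correlation matrix**, the
**lagged correlation / time-delay matrices** (extremal cross-correlation per
pair and the lag where it occurs, `tdm[k,l] = −τ*·TR`, positive when `l`
follows `k`), and the all-pairs **DTW distance matrix** computed by the
standard dynamic program
`C[k,j] = d[k,j] + min(C[k−1,j], C[k−1,j−1], C[k,j−1])`.

Downstream, cross-visit identification uses 1-nearest-neighbor matching with
cosine similarity scored by accuracy and Gorodkin's multi-class Matthews
correlation `R_K`; group classification uses PCA-reduced LDA/QDA, kernel
SVMs, an exact linear-programming sparse `l1`-SVM (hinge loss + `λ‖w‖₁`)
whose support maps back to salient ROI pairs, and a small
row/column-convolution CNN with optional per-class VAE augmentation.

## Worked example

```python
import numpy as np
from rsfi import (SyntheticParams, make_panel, planted_ordering, lead_matrix,
                  cyclicity_spectrum, recover_ordering, fingerprint_panel,
                  PreprocessConfig)

# one noisy cyclic scan with a known temporal ordering of 8 regions
probe = SyntheticParams(n_subjects=1, n_rois=8, n_time=300, noise_sd=0.3,
                        signature_strength=0.0, global_amp=0.0, seed=3)
scan = make_panel(probe).records[0].matrix
spectrum = cyclicity_spectrum(lead_matrix(scan, end_matched=True))
print("planted ordering:  ", planted_ordering(probe).tolist())
print("recovered ordering:", recover_ordering(spectrum).tolist())

# a 10-subject, two-visit cohort with stable subject signatures
cohort = SyntheticParams(n_subjects=10, n_rois=8, n_time=300,
                         signature_strength=0.6, seed=3)
panel = make_panel(cohort)
res = fingerprint_panel(panel, "lead", PreprocessConfig(filter_band=None))
print(f"cross-visit 1-NN accuracy: {res.mean_accuracy:.2f}, "
      f"R_K = {res.mean_rk:.2f}")
```

prints

```
planted ordering:   [0, 1, 2, 3, 4, 5, 6, 7]
recovered ordering: [1, 2, 3, 4, 5, 6, 7, 0]
cross-visit 1-NN accuracy: 0.90, R_K = 0.90
```

The recovered ordering matches the planted one (cyclic orders are defined up
to rotation, so `[1..7, 0]` equals `[0..7]`), and lead-matrix features
identify 9 of 10 subjects across visits a week of simulated drift apart.

## Command line

Every stage is also a CLI subcommand sharing one master `--seed`:

```sh
rsfi simulate --subjects 20 --seed 1 --out panel/
rsfi features --manifest panel/ --kind lead --band none --out features/
rsfi fingerprint --manifest panel/ --kind corr --out fp.tsv
rsfi report --manifest panel/ --out sweep.tsv   # feature x band x GSR grid
rsfi classify --manifest panel/ --feature lead --clf sparse-svm --out clf.tsv
rsfi embed --manifest panel/ --feature corr --method tsne --out embed.tsv
```

All outputs are plain tab-delimited text with YAML sidecars; a run with a
fixed seed is byte-reproducible.

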