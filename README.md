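# slowosc

Spectral analysis of intrinsic connectivity networks (ICNs) in
resting-state fMRI: group spatial ICA followed by band-limited
fractional ALFF in the infra-slow **slow-5** (0.01–0.027 Hz) and
**slow-4** (0.027–0.073 Hz) bands, with four-group statistics and a
synthetic cohort generator that makes the whole chain verifiable
without any real MRI data.

## Who this is for

Researchers studying how the spectral composition of spontaneous BOLD
oscillations differs between groups — e.g. healthy aging versus the
delayed (diaschisis) effects of ischemic stroke on the default-mode
network (DMN) and task-positive networks. The package implements the
full analysis chain as a tested library plus a thin CLI, and ships a
generator that plants known spatial networks with known band structure,
so every stage can be validated against ground truth.

## The method

1. **Preprocessing** — discard the first 10 volumes, despike against a
   running-median ± k·MAD envelope, linear detrend; subjects whose
   6-parameter motion track exceeds a 2-mm peak-to-peak range on any
   axis (rotations on a 50-mm radius) are excluded. Motion is
   summarised by the Euclidean norm (enorm) of frame-to-frame parameter
   differences.
2. **Group spatial ICA** — per-subject temporal PCA (default dimension
   1.5·k), temporal concatenation, group PCA to *k* components (default
   28), then natural-gradient **Infomax** ICA over voxels. Subject time
   courses and maps are recovered through **GICA back-reconstruction**:
   the group mixing matrix is partitioned per subject and lifted
   through each subject's retained PCA basis. Component reproducibility
   is assessed ICASSO-style (bootstrap + random restarts, clustering by
   spatial |r|), components are identified by greedy correlation
   against network templates, and kept only if their low-/high-
   frequency power ratio (0.01–0.1 Hz over 0.1 Hz–Nyquist) exceeds 50.
3. **Spectra and fALFF** — each back-reconstructed component time
   course is Fourier transformed; the one-sided amplitude spectrum
   |X(f)| is smoothed with a Gaussian kernel (σ = 2 Fourier bins). Band
   fALFF is the smoothed amplitude mass in a band over the mass in the
   full acquired range [0, Nyquist]:

       fALFF(band) = Σ_{f ∈ band} |X(f)| / Σ_{f ∈ [0, f_Nyq]} |X(f)|

   computed for slow-5, slow-4 and their union ("resting",
   0.01–0.073 Hz), plus the slow-5 share of the resting mass. Spectra
   are also resampled onto a uniform 0.009–0.060 Hz grid (34 bins of
   0.0015 Hz) for per-bin tests.
4. **Group statistics** — per-bin two-sample Student t-tests
   (uncorrected, optional Benjamini–Hochberg), one-way ANOVA with
   Tukey HSD (Tukey–Kramer for unequal n) on component fALFF, and
   pre-registered one-tailed contrasts. Component spectra are also
   combined into composite DMN (pDMN+aDMN+vDMN) and
   visual–sensorimotor components.

The synthetic generator plants five networks (three DMN subcomponents,
primary visual, sensorimotor) as Gaussian-blob spatial maps with
band-structured time courses, and encodes two group patterns: a global
slow-5 → slow-4 power reallocation at constant total low-frequency
power (late-stage stroke vs. age-matched controls) and a DMN-specific
slow-5/power decline with a task-positive slow-5 increase (aging). See
`docs/methods.md` for the generative model and its calibration.

## Worked example

```python
from slowosc import (GroupICA, GroupICAConfig, default_spec,
                     simulate_cohort, make_band_scheme)
from slowosc.preprocess import preprocess_scan
from slowosc.spectra import falff_table
from slowosc.stats import Contrast, contrast_report

spec = default_spec(seed=0, n_subjects_per_group={
    g: 3 for g in ("young", "old", "stroke_early", "stroke_late")})
scans, truth = simulate_cohort(spec)
kept = [preprocess_scan(s) for s in scans]

fit = GroupICA(kept, GroupICAConfig(n_components=8,
                                    subject_pca_dim=12, seed=0)).fit()
fit.match_templates(truth.maps)
print(fit.summary())
```

prints

```
Group spatial ICA (Infomax, GICA back-reconstruction)
  subjects: 12   voxels: 9600
  components: 8   subject PCA dim: 12
  variance explained: 65.1%
  IC01 -> visual   (r = +0.998)
  IC02 -> motor    (r = +0.999)
  IC05 -> aDMN     (r = +0.999)
  IC06 -> vDMN     (r = +0.999)
  IC07 -> pDMN     (r = +0.998)
```

All five planted networks are recovered with spatial correlations
≥ 0.998 against the ground-truth maps; the remaining three components
absorb noise (they fail the LF/HF robustness filter). Continuing,

```python
scheme = make_band_scheme(0.5 / 2.6)           # Nyquist of TR = 2.6 s
table = falff_table(fit.component_spectra(), scheme,
                    groups={s.subject_id: s.group for s in kept})
report = contrast_report(table, [Contrast("stroke_late", "old", "less")])
print(report["components"]["DMN"]["slow5"]["contrasts"]["stroke_late-old"])
```

gives

```
{'mean_a': 0.290, 'mean_b': 0.327, 'diff': -0.037, 't': -0.725,
 'p': 0.254, 'tails': 'one-tailed (less)', 'significant': False}
```

— the composite-DMN slow-5 fALFF is lower in the late-stroke group, as
planted, though 3 subjects per group is far too few for significance;
at the default cohort sizes (43/42/14/16) the effect is detected
reliably (see the acceptance run below).

The same chain is available from the shell:

```bash
slowosc simulate --out cohort/ --seed 1
slowosc run --out results/ --seed 1
```

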