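# sinusid

Forensic identification from the 3D shape of the maxillary sinuses.

When an unknown decedent must be identified, ante-mortem (AM) clinical
imaging can be compared with post-mortem (PM) imaging. The paranasal
sinuses are among the most individually distinctive skeletal structures, so
a natural identity test is: segment the sinus air space from both scans,
rigidly superimpose the two 3D surface models, and measure how far apart
the surfaces remain. Models from the *same* person differ only by
segmentation noise (fractions of a millimetre); models from *different*
people differ by genuine anatomy (millimetres). A fixed threshold on the
residual distance then separates matches from mismatches.

`sinusid` implements this pipeline end to end, together with a synthetic
cohort generator that reproduces the statistical regime of real repeat-CT
data, so every stage is testable without any patient scans:

1. **synthetic cohort** — per-subject sinus-like closed surfaces
   (deformed ellipsoids, ~30–40 mm, larger in males, mirrored left/right)
   acquired "twice" with small correlated repeat noise (`sinusid.cohort`);
2. **segmentation** — seeded gray-range region growing over a voxel volume
   plus marching-cubes surface extraction in mm (`sinusid.segmentation`);
3. **registration** — rigid ICP: exact point-to-surface correspondences
   alternated with closed-form Kabsch alignment (`sinusid.registration`);
4. **distance** — per-vertex point-to-surface distances, the RMS statistic
   and the green/red/blue chromatic map (`sinusid.distance`);
5. **experiment & statistics** — the balanced match/mismatch design, the
   1 mm identification rule, factorial summaries and a three-way
   sex × side × group ANOVA with eta-squared effect sizes
   (`sinusid.experiment`).

## The statistic

For AM reference vertices `p_1 … p_n` and the registered PM surface `S`,

    RMS = sqrt( (1/n) * sum_i  d(p_i, S)^2 )        [mm]

where `d(p, S)` is the exact distance from `p` to the nearest point on any
triangle of `S`. The identification rule is `match ⇔ RMS < 1.00 mm` (the
boundary counts as mismatch). Registration minimizes the same point-to-
surface objective; the ICP trace is recorded and is provably non-increasing.

## Worked example

```
$ python analysis/01_generate_cohort.py --n-per-sex 10 --seed 0
wrote 160 sinus models (10 subjects per sex, seed 0) to results/cohort
$ python analysis/02_run_experiment.py --n-per-sex 10 --seed 0
80 superimpositions in 53 s
match RMS range    0.11-0.21 mm
mismatch RMS range 1.35-2.21 mm
1 mm threshold classifies 100.0% of pairs correctly
table written to results/experiment.csv
$ python analysis/03_statistics.py
...
group effect: p = 5.01e-54 (significant at Bonferroni-corrected alpha 0.017);
eta^2 = 0.960
```

Reading: every same-subject superimposition lands well below 1 mm and every
different-subject one well above it, so the threshold classifies 100% of
pairs; the ANOVA attributes essentially all RMS variance to the
match/mismatch factor (eta² ≈ 0.96 here), with sex and side contributing
nothing meaningful — exactly the structure that makes the sinus usable as
an identifier.

The same stages are available as a CLI (`sinusid generate | segment |
superimpose | distance | experiment | anova | report`); each subcommand
writes a JSON run manifest with config, seeds and file digests.

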