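# dtialps

Diffusion-tensor analysis along the perivascular space (DTI-ALPS) for
glymphatic-system studies, as a tested, reproducible pipeline: simulate
diffusion-MRI cohorts with known ground truth, fit diffusion tensors,
compute left/right/average ALPS indices from template-space spherical ROIs,
summarize bilateral hippocampal diffusion metrics, and run the full
covariate-adjusted cohort statistics chain.

## Who this is for

Neuroimaging researchers who quantify glymphatic transport with the
ALPS index — for example in cohorts of type 2 diabetes with and without
mild cognitive impairment — and want (a) an auditable implementation of the
whole analysis from raw diffusion signals to adjusted p-values, and (b) a
phantom generator that lets every stage be validated against known truth.

## The statistic

At the body of the lateral ventricle, the perivascular space runs
left–right (the template x-axis), perpendicular to projection fibers
(inferior–superior, z) and association fibers (anterior–posterior, y).
With `dxx, dyy, dzz` the diagonal elements of the fitted diffusion tensor,
mean diffusivity along x inside a projection-fiber ROI (`Dxproj`) and an
association-fiber ROI (`Dxassoc`) is compared against the off-fiber,
non-perivascular diffusivities (`Dyproj`, `Dzassoc`):

```
ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)
```

Values near 1 mean no preferential diffusion along the perivascular axis;
higher values are read as better glymphatic transport. The index is
computed per hemisphere from four 5-mm spherical ROIs at fixed 1-mm
template coordinates — left projection (116,109,99), left association
(126,109,99), right projection (64,109,101), right association
(54,109,101) — and the bilateral average is reported alongside.

Tensors are fitted by weighted linear least squares on log-signals
(weights = squared predicted signal, one refinement pass) after restricting
to shells with b < 1000 s/mm² (an `--include-b1000` switch makes the cutoff
inclusive). FA, MD, AD and RD maps from the same fit are averaged over
atlas labels 37/38 for the bilateral hippocampi.

## Worked example

Simulate one healthy-control subject on the reduced test grid, write it as
NIfTI + FSL `bvals`/`bvecs`, and recompute its ALPS indices from the files:

```
$ dtialps simulate --group HC --seed 3 --out subj/
wrote subject phantom to subj

$ dtialps alps --dwi subj/dwi.nii.gz --bvals subj/bvals --bvecs subj/bvecs \
      --rois subj/rois.json --out subj/alps.csv
alps_left=2.3575 alps_right=1.1243 alps_mean=1.7409
```

This particular subject drew an unusually asymmetric pair of hemispheres;
its generating ground truth, stored in `subj/ground_truth.json`, is
left 2.3499 / right 1.1264 / average 1.7382 — recovered to within the
measurement noise of the SNR-20 acquisition (≈ 0.01–0.02 per index).

A full synthetic study — three groups, tensor fits, ALPS and hippocampal
metrics per subject, then the whole statistics roster — is one command:

```
$ dtialps run --smoke --seed 7 --out demo/
...
INFO dtialps stage=stats n=24
pipeline complete: 24 subjects → demo
```

which writes `cohort.csv` (one row per subject: covariates, ground truth,
and pipeline-recovered metrics), `stats.json` / `stats.md` (every analysis
as a uniform record: route taken, statistic, df, raw and BH-adjusted
p-values, effect estimates with 95% CIs), and `provenance.json`.

The preset calibration can be inspected directly:

```
$ dtialps calibrate --group HC --n 1000 --n-imaging 5 --seed 0
[HC] targets: left: 1.76±0.26  right: 1.59±0.21
[HC] ground truth left: mean=1.7483 sd=0.2512
[HC] ground truth right: mean=1.5910 sd=0.2152
[HC] pipeline measurement error (left, n=5): bias=+0.0019 sd=0.0190
```

i.e. the generator's ground-truth ALPS moments match the calibration
targets, and the imaging pipeline adds only ~0.02 of measurement noise per
subject at SNR 20 — small against the 0.2–0.26 between-subject spread.

## Real data

`dtialps fit`, `dtialps alps` and `dtialps hippo` accept user-supplied 4-D
NIfTI volumes with FSL-style gradient tables and integer label volumes.
Inputs must already be distortion-corrected, skull-stripped and spatially
normalized to the 1-mm template grid the ROI coordinates index; atlas files
are never bundled and are passed by path.
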