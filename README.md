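# hipmorph

Muscle morphometry from Dixon fat/water MRI: volumes, intramuscular fat
infiltration (MFI) profiles, segmentation agreement, and group statistics for
lateral-hip muscles (gluteus maximus, medius, minimus, tensor fasciae latae).

## The scientific problem

Hip-related pain in young athletes is associated with changes in the size and
fatty infiltration of the hip abductors. Quantifying this from MRI requires a
chain of measurements, each with room for silent error:

1. **Volume** of each segmented muscle: cross-sectional area per axial slice
   × slice thickness, summed along the muscle.
2. **MFI** per slice as the pooled fat fraction Σfat/(Σfat+Σwater) over the
   labelled voxels, and an **MFI profile** — the slice-wise series normalised
   to 101 nodes from the proximal (0%) to the distal (100%) end of the
   muscle, so muscles of different lengths and subjects can be compared
   node-for-node. Gluteus medius is additionally split into
   anterior/middle/posterior thirds and gluteus minimus into
   anterior/posterior halves along the anterior–posterior axis.
3. **Agreement and reliability**: Dice, Jaccard, conformity, TPR/TNR/PPV and
   volume ratio between segmentations; ICC(2,1) with a 95% CI, Bland–Altman
   limits of agreement, MAE/RMSE and prediction R² between repeated volume
   measurements.
4. **Group inference**: covariate-adjusted OLS (group + age + BMI + sex +
   sport, with a screened group×sex interaction) for volumes, and 1D
   statistical parametric mapping (node-wise two-sample t with a
   permutation-based family-wise max-|t| threshold; random-field theory as an
   alternative) for the 101-node MFI profiles.

Real Dixon studies rarely ship their images, so `hipmorph` includes a
**synthetic phantom and cohort generator** with analytic ground truth:
ellipsoid/tube muscles whose exact volumes and designed MFI profiles are
known, a boundary-flip "second rater", and study-scale cohorts
(180 symptomatic / 48 control by default) with known injected group effects
and deliberately confounded covariates. Every stage of the measurement and
inference chain is validated against that ground truth. See
[docs/methods.md](docs/methods.md) for the full model, conventions and
limitations.

## Worked example

From `examples/01_phantom_and_morphometry.py`: build a one-muscle ellipsoid
phantom (semi-axes 20×15×30 mm, designed linear MFI 0.1→0.3) and measure it.

```python
import numpy as np
from hipmorph import (MFIProfile, MuscleShape, PhantomSpec,
                      generate_phantom, mfi_profile, muscle_volume)

shape = MuscleShape(label=1, muscle="Gmed", side="L", primitive="ellipsoid",
                    center_mm=(36.0, 30.0, 45.0), semi_axes_mm=(20.0, 15.0, 30.0))
spec = PhantomSpec(grid_shape=(48, 40, 60), voxel_size_mm=(1.5, 1.5, 1.5),
                   muscles=[shape], mfi_profiles={1: MFIProfile("linear", (0.1, 0.3))})
dixon, mask = generate_phantom(spec)

rec = muscle_volume(mask, 1)            # 37567.1 mm^3 vs analytic 37699.1
prof = mfi_profile(dixon, mask, 1)      # 101 nodes, proximal -> distal
```

Running the script prints:

```
rasterized volume :   37567.1 mm^3
analytic volume   :   37699.1 mm^3
relative error    :   0.00350
profile nodes     : 101 (proximal 0% -> distal 100%)
MFI at 0/50/100%  : 0.100 0.200 0.300
max node error    : 1.11e-16
```

The 0.35% volume error is pure voxelisation at 1.5 mm (it halves again at
0.75 mm), and the profile machinery recovers the designed fat gradient to
machine precision on noise-free data.

The other examples exercise the rest of the package; each prints its numbers
with a line of interpretation:

* `examples/02_segmentation_agreement.py` — boundary-flip rater vs truth:
  Dice 0.9458, conformity 0.8853, volume ICC(2,1) 1.0000 [0.9787, 1.0000],
  Bland–Altman bias 131 mm³ [66, 196].
* `examples/03_cohort_statistics.py` — study-scale cohort with an injected
  Gmed effect of 23 858 mm³: adjusted estimate 22 673 mm³ [8 575, 36 772],
  p = 0.0017, 7.5% of the adjusted control mean; a null-effect SPM on MFI
  curves finds no supra-threshold cluster (max |t| = 1.88 < t* = 3.21).
* `examples/04_full_pipeline.py` — end-to-end run writing NIfTI images,
  agreement/reliability/volume/profile/regression/SPM tables and a digest
  manifest; byte-identical on rerun with the same config.

The same pipeline is available on the command line:

```bash
hipmorph run-all --seed 0 --out results/run0
hipmorph morphometry --fat fat.nii --water water.nii --mask mask.nii --out tables/
```

## Layout

```
src/hipmorph/     dixon_io, phantom, morphometry, agreement, cohort_stats,
                  pipeline, cli
examples/         four narrative scripts, one per capability
tests/            unit + property tests, plus test_acceptance.py
scripts/          acceptance.py (standalone reproduction script)
docs/methods.md   model, conventions, parameter rationale, limitations
```
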