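# mopet

Multi-level Otsu PET tumor segmentation (MO-PET) with the conventional
comparator methods, SUV imaging I/O, method-agreement statistics, and a
NEMA-IQ-style phantom simulator for ground-truth validation.

## What it does

- **MO-PET** (`mopet.otsu`): builds an SUV histogram inside an ellipsoidal
  volume of interest (VOI), finds the K-class threshold set minimizing the
  probability-weighted within-class variance (exhaustive-search optimum,
  computed by an equivalent dynamic program), and extracts the tumor mask as
  the in-VOI voxels at or above the topmost threshold, restricted to the
  26-connected component containing the SUV-max voxel. Default K=3,
  128 bins; K configurable 2–5.
- **Conventional comparators** (`mopet.conventional`): absolute-SUV
  thresholds (e.g. 2.0/2.5/3.0), percent-of-SUVmax thresholds
  (30/40/50/60%), and a generic gradient-shell method labeled
  `gradient (generic)` (an approximation of commercial gradient tools, not
  a replication).
- **Imaging I/O** (`mopet.io`): NIfTI volumes/masks (nibabel), body-weight
  SUV conversion with decay correction, DICOM PET series and RT Structure
  Set reading (optional `pydicom` extra), and even-odd voxel-center contour
  rasterization.
- **VOI geometry** (`mopet.voi`): ellipsoidal VOIs in world mm with optional
  ZYX Euler rotation; center-in-ellipsoid voxelization.
- **Agreement statistics** (`mopet.stats`): MTV/GTV ratio (mean ± SD),
  Spearman rank correlation (exact permutation p for n < 10, t
  approximation otherwise), ICC(A,1) with F-method 95% CI, and Bland-Altman
  bias ± SD with 95% limits of agreement.
- **Phantom simulation** (`mopet.phantom`): spheres at NEMA-IQ diameters on
  a uniform background with Gaussian PSF blur and intensity-proportional
  noise, plus a volume-recovery experiment grid across diameters,
  lesion-to-background ratios, seeds and methods.

## Test

```bash
python -m pytest -q tests/
```

## CLI

```bash
# generate a phantom (NIfTI + JSON spec + ground-truth masks)
mopet phantom --sphere 63 63 63 22 8 --psf-fwhm 6 --noise 0.1 -o phantom.nii.gz

# segment it with MO-PET inside an ellipsoidal VOI (world mm)
mopet segment phantom.nii.gz --method mo-pet -K 2 \
    --center 63 63 63 --semi-axes 24 24 24 -o mask.nii.gz

# other methods: --method absolute --threshold 2.5 | percent --fraction 0.4 | gradient
# run the phantom volume-recovery experiment grid
mopet recovery --diameters 17,22,28 --lbrs 4,8 --n-seeds 20 -o recovery.csv

# agreement statistics from a CSV of per-case volumes (cm^3)
mopet agree volumes.csv --reference-column gtv -o report.csv

# convert a PET DICOM series to a body-weight-SUV NIfTI (needs pydicom)
mopet suv /path/to/series -o suv.nii.gz
```

## Notes

- Volumes are 3-D arrays with an affine grid geometry (spacing/origin/
  direction, world mm); a voxel belongs to a region iff its center does —
  one inclusion rule used everywhere (VOIs, spheres, contours).
- MTV is mask voxel count × voxel volume, reported in cm³.
- The single-sphere phantoms are two-class scenes; the phantom validation
  therefore runs MO-PET with K=2. K=3 remains the default for clinical
  images (background / spill-over rim / tumor).
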