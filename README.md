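# glucest

Glutamate-weighted chemical exchange saturation transfer (GluCEST) MRI
analysis for small-animal brain studies, with a fully synthetic test bed.

GluCEST detects the labile amine protons of glutamate (~3 ppm downfield of
water) indirectly: a frequency-selective saturation pulse is applied over a
sweep of offsets, exchange transfers the saturation to water, and the
normalized water signal S(Δω)/S0 — the Z-spectrum — drops asymmetrically.
The contrast is the magnetization-transfer-ratio asymmetry at the labeling
offset,

    GluCEST (%) = 100 · (M(−3 ppm) − M(+3 ppm)) / M(−3 ppm),

computed per voxel after two corrections: the per-voxel water frequency
(B0) estimated from a low-power WASSR Z-spectrum, and the relative
transmit field (B1) from a dual-flip-angle pair via the double-angle
method.  Around this core the package provides voxelwise relaxometry
(T1 variable-TR, T2 multi-echo, ADC multi-b, FAIR-based cerebral blood
flow), a linear-combination 1H-MRS quantifier with water scaling, and
left/right hippocampal ROI statistics (Lilliefors normality screen +
independent t-test), i.e. everything needed to compare a stressed and a
control cohort.

Because real scanner data for such studies are rarely shared, every input
can be generated by the built-in digital phantom: Z-spectra are
forward-simulated by numerically evolving the two-pool Bloch–McConnell
equations under continuous-wave saturation, and all relaxometry series,
B1 pairs and spectra follow from the phantom's ground-truth parameter
maps.  Every analysis stage is therefore testable against known truth.

## Worked example

```python
from glucest.phantom import generate_cohort
from glucest.pipeline import run_pipeline

cohort = generate_cohort(
    n_per_group=12,
    group_contrast={"control": 5.02, "fst": 3.67},   # hippocampal GluCEST %
    between_animal_sd={"control": 0.44, "fst": 0.81},
    noise_sd=0.01, seed=42, shape=(64, 64),
    include_relaxometry=False, include_mrs=False)
result, maps = run_pipeline(cohort, include_relaxometry=False,
                            include_mrs=False)
print(result.summary())
t = result.tests["glucest"]
print(f"t = {t.statistic:.3f}, df = {t.df:.0f}, p = {t.p_value:.2g}")
```

prints

```
    metric    group      mean        sd   n
0  glucest  control  4.943602  0.454843  12
1  glucest      fst  4.033125  0.853104  12
t = 3.262, df = 22, p = 0.0036
```

The generator drew each animal's true hippocampal contrast from a normal
distribution around the group target (5.02 % vs 3.67 %), simulated the
saturation images with field inhomogeneity and 1 % noise, and the
pipeline recovered the group means through the full B0/B1-corrected
analysis; the equal-variance t-test then separates the groups.

The same chain is available from a shell:

```bash
glucest simulate --config sim.yaml --out cohort/ --seed 42
glucest stats cohort --manifest cohort/ --out stats/
glucest fit cest  --cest a/cest.nii.gz --wassr a/wassr.nii.gz \
                  --b1pair a/b1pair.nii.gz --out maps/
glucest fit relax --kind t2 --in a/t2.nii.gz --out maps/
glucest fit mrs   --spec a/mrs.csv --out metabolites.csv
```

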