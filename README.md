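# myelosurf

Surface-based T1w/T2w myeloarchitecture analysis for comparative primate
neuroanatomy: per-vertex myelin maps from MR volumes, gradient-ridge
areal parcellation, per-parcel areal metrics in native space, and
interspecies statistics — exercised end to end on synthetic cortical
phantoms with known ground truth.

## The problem

The ratio of T1-weighted to T2-weighted MR intensity is a non-invasive
proxy for intracortical myelin density.  Sharply myelinated regions such
as the MT+ complex and auditory cortex, and lightly myelinated islands
such as Brodmann area 7, stand out on a T1w/T2w map of the cortical
sheet, and the *gradient* of that map ridges along areal borders.
Comparing the sizes of such areas across species of very different brain
size requires relative quantities: each parcel's surface area and wedge
volume as a fraction of the hemisphere total.

The core quantities, for a white/pial surface pair with 1:1 vertex
correspondence:

- myelin map: `m_i = weighted mean of (T1w/T2w)(x)` along the white→pial
  segment of vertex `i`, Gaussian-weighted toward the mid-thickness
  (FWHM 1.8 mm for a night-monkey-sized brain), then corrected by
  subtracting the σ = 5 mm smoothed difference to a symmetrized group
  template;
- gradient magnitude `|∇m|` on the mid-thickness surface (tangent-plane
  least squares, pre-smoothing σ = 0.5 mm); ridges of `|∇m|` bound the
  parcels, grown from explicit seed vertices;
- per parcel: area `A = Σ vertex areas`, volume `V = Σ wedge volumes`,
  mean thickness; relative area `100·A/A_total` (%);
- interspecies inference: two-way ANOVA (species × parcel, Type III,
  sum-to-zero) over hemispheres, with per-parcel pairwise Welch t tests,
  Bonferroni-corrected across species pairs × parcels.

Everything upstream of these steps (scanning, registration, surface
reconstruction) is out of scope; a phantom generator supplies folded
surface pairs, myelin fields with configurable per-species areal
fractions, and T1w/T2w volumes whose ratio encodes the field, with
multiplicative low-frequency bias and additive noise.

## Worked example

```python
import myelosurf as ms

# three-species phantom population at desk scale (4 subjects/species)
cfg = ms.desk_config(seed=1)
res = ms.run_pipeline(cfg)

summary = res.summary.set_index(["species", "parcel"])
for sp in ("night_monkey", "macaque", "marmoset"):
    pct = 100 * summary.loc[(sp, "MT+"), "rel_area_mean"]
    sd = 100 * summary.loc[(sp, "MT+"), "rel_area_sd"]
    print(f"{sp:13s} MT+ relative area {pct:4.2f} +/- {sd:.2f} %")

inter = res.anova["rel_area"].anova.set_index("effect").loc["species:parcel"]
print(f"species x parcel interaction: F({inter.df1:.0f}, {inter.df2:.0f}) "
      f"= {inter.F:.1f}, p = {inter.p:.2e}")
```

prints

```
night_monkey  MT+ relative area 2.44 +/- 0.09 %
macaque       MT+ relative area 0.90 +/- 0.06 %
marmoset      MT+ relative area 1.14 +/- 0.10 %
species x parcel interaction: F(6, 84) = 2145.0, p = 1.17e-89
```

The phantom species were built with true MT+ area fractions of 2.4%,
0.9% and 1.2%: the pipeline — volumes → myelin maps → bias correction →
group parcellation → native-space metrics — recovers the group means to
within ~0.1 percentage points, and the species × parcel interaction is
overwhelmingly significant, reflecting that the MT+ expansion pattern
differs across parcels.

The same stages are available from the shell:

```sh
myelosurf run --config species.yaml --out out/ --seed 1
myelosurf map-myelin --t1w t1.nii --t2w t2.nii --white w.surf.gii \
    --pial p.surf.gii --fwhm 1.8 --template tmpl.shape.gii --out my.shape.gii
myelosurf parcellate --myelin my.shape.gii --white w.surf.gii \
    --pial p.surf.gii --seeds seeds.json --out labels.gii
```

Surfaces and per-vertex maps are GIFTI, volumes NIfTI-1, metric tables
TSV with a versioned header, and stats reports JSON.

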