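# ldics

Label-free quantification of lipid droplets (LDs) in third-harmonic-generation
(THG) microscopy images of fungal hyphae.

THG microscopy produces a signal at refractive-index interfaces, so lipid
droplets — sub-micron neutral-lipid organelles with a high refractive index —
appear as bright puncta inside an otherwise dim hypha, ringed by a bright cell
wall. This package implements the full quantification workflow for such
images, aimed at researchers studying fungal lipid metabolism (e.g. the
transient LD accumulation triggered by nitrogen starvation):

* **`ldics.synthetic`** — a hypha-image simulator (capsule-shaped hypha,
  Gaussian-profile wall ribbon, hard-disk droplets with truncated-normal
  diameters, Gaussian PSF, photon noise) with exact ground truth for every
  droplet, used to validate every stage.
* **`ldics.preprocess`** — hypha segmentation, and the iterated background
  subtraction that erases the cell wall: repeatedly subtract the mean
  intensity of the region outside the hypha and clip at zero (default 20
  iterations), plus manual-style wall cropping and out-of-hypha clearing.
* **`ldics.ics`** — Image Correlation Spectroscopy. The normalized
  fluctuation autocorrelation

      G(ξ, η) = ⟨δI(x, y) δI(x + ξ, y + η)⟩ / ⟨I⟩²,  δI = I − ⟨I⟩,

  is computed by FFT; the central profile (G curve) is fitted with a
  Lorentzian L(ξ) = G(0)·w²/(ξ² + w²) + offset, and the droplet number
  follows from

      N_LD = N_pix² / (r² π G(0)),  r = FWHM/2 = w,

  with N_pix the side of the 2ⁿ×2ⁿ frame and r in pixels. The mean droplet
  diameter is reported as FWHM × pixel size.
* **`ldics.psa`** — Particle Size Analysis: threshold → 8-connected
  components → per-particle area, equivalent diameter, centroid, circularity;
  the cross-validation method for ICS.
* **`ldics.colocalization`** — Pearson correlation and image
  cross-correlation spectroscopy (ICCS): the fraction of channel-a clusters
  interacting with channel b is the fitted amplitude ratio G_ab(0)/G_bb(0).
* **`ldics.reporting`** — batch runs over YAML configs, pooled diameter
  histograms (0.3 µm bins, normalized by total hypha area, with linear
  error propagation), and treated/control density ratios.

## Worked example

```python
from ldics.synthetic import SyntheticSpec, generate_hypha_image
from ldics.reporting import quantify_image

spec = SyntheticSpec(seed=7)            # control regime: 12 droplets,
image, truth = generate_hypha_image(spec)  # 1024 px at 0.1 µm/px
out = quantify_image(image)             # segment → subtract → ICS + PSA
```

This prints, via the result objects:

```
hypha area: 783.8 um^2 (truth 778.6)
truth: N=12, density=15.4e-3/um^2, mean diam=0.72
ICS: N=50.1, density=63.9e-3, diam=0.59 um, g0=759, w=2.96
PSA: N=12, density=15.3e-3, diam=0.76 um, thr=65.3
```

The segmented hypha area matches the geometric truth to < 1%, PSA recovers
the droplet census exactly at this density, and the ICS diameter (FWHM of
the fitted G curve) sits close to the true mean. The ICS *count* overshoots
at such sparse regimes — the count formula approximates the correlation area
of a compact blurred disk by π r² at the half-maximum radius, which is about
half its true value; see `docs/methods.md` for the quantitative analysis and
when ICS counts are reliable.

The same pipeline is scriptable from the shell:

```sh
ldics simulate --config spec.yaml --out sim/ --seed 5
ldics ics  --image sim/synthetic_thg.tif --pixel-size 0.1 --out ics.csv
ldics psa  --image sim/synthetic_thg.tif --pixel-size 0.1 --out psa.csv
ldics coloc --channel-a a.tif --channel-b b.tif --pixel-size 0.1 --out c.csv
ldics batch --config batch.yaml --out results.csv
```

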