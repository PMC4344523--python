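# Methods

This note documents the generative model behind `halofish.simdata`, the
estimators in the analysis pipeline, the main parameter choices with their
rationale, and the known limits of both.

## Generative model

### Nucleus geometry

A deproteinized nucleus is modeled as a solid spherical **core** of radius
3.5 µm centered in the field, rendered in the DAPI channel as a uniform
bright body (800 photons/voxel) over a faint floor (3 photons/voxel).
The default field is 40 z-planes at 0.2 µm spacing by 144 × 144 pixels at
0.16 µm — the acquisition geometry of a 40× widefield system with a 12-bit
camera. The 3.5 µm radius lets the core fit the 8 µm z-range with margin;
it is a modeling choice, not a measured value.

Chromosomal foci are placed uniformly inside the core sphere: one
centromere focus per chromosome copy (46 in G1, up to 92 in G2, with S phase
replicating a random 20–80% subset) and two telomere foci per chromosome
copy and strand. After denaturation the G- and C-strands of one chromosomal
telomere stay nearly coincident (0.05 µm jitter), which is what produces the
high core G/C colocalization the assay reports. Chromosomal telomere
lengths are log-normal with mean 40–150 kb per preset (ALT telomeres are
long and heterogeneous); centromere probe brightness is expressed in
telomere-bp equivalents (mean 3 kb) purely as a rendering convenience.

### ECTR populations

Per-nucleus ECTR molecule counts are negative-binomial: the total count has
mean `mean_G + mean_C` and dispersion *r* (default 4–5), and each molecule
is independently G-strand with probability `mean_G / (mean_G + mean_C)`.
The shared total reproduces the extreme cell-to-cell variability of ALT
lines (counts from under 20 to over 300 at GM847-like means) while the
per-molecule strand draw produces the observed excess of nuclei with more
G- than C-strand molecules. Molecule lengths are log-normal; the packaged
presets use log-SD 1.25–1.32, which puts the mean at 2–2.5× the median
(`exp(σ²/2)`) and reproduces the published length-bin fractions (<50 kb,
50–200 kb, >200 kb) for each line. The packaged presets (GM847, VA13,
U2OS) carry the published per-nucleus count means (126/95, 59/44, 21/14 for
G/C). Their group-level *content* fractions (ECTR share of total
telomere-repeat DNA) are **not** calibrated against the observed values;
chromosomal telomere lengths were chosen as realistic, not fitted.

ECTR molecules are placed in the Halo: direction uniform on the sphere,
distance from the core edge = 0.6 µm clearance + |N(0, 3.0 µm)|, redrawn
(bounded retries) if the position leaves the in-field margins — emulating
denaturation conditions tuned so molecules do not escape the field of view.
Cell-cycle phase scales the population: G2 nuclei draw `ectr_count_g2_fold`
(2.7–4.9 per preset) times more molecules with `ectr_length_g2_fold`
(1.226) longer length scale; S phase interpolates halfway.

### Optics and camera

Each molecule is a point emitter with expected photon count
`photons_per_bp × length_bp`, deposited trilinearly and blurred by a
separable 3D Gaussian PSF (σ = 0.35/0.12/0.12 µm in z/y/x — a widefield
approximation; the xy pixel size and PSF are not published for the original
system and are configurable). Readout adds Poisson shot noise on
signal + background (4 photons/voxel), a fixed 100 ADU camera offset,
Gaussian read noise (1 ADU), rounding, and clipping at 4095 (12-bit).

`photons_per_bp = 0.25` was chosen analytically so that the simulated
system sits at the assay's own operating point: the 810-bp standard then
has focus-scale SNR ≈ 5.6:1 and is detected essentially always (it defines
the minimum threshold), molecules of ~300 bp sit near SNR 2:1 (the assay's
quoted detection-limit regime), and a 200-kb molecule still peaks below
saturation. The dynamic-range ceiling is ~0.4 Mb per molecule; rarer,
longer molecules (mostly in the U2OS preset's tail) clip and are
under-sized, exactly as a 12-bit camera would.

Calibration slides scatter duplex plasmid foci (135 or 270 telomere
repeats = 810/1620 bp, emitting equally in both telomere channels, since
the insert carries both strands) on an empty field with ≥2 µm separation
and a 1.5 µm z-margin so the measurement aperture is never z-clipped.

## Analysis pipeline

**Deconvolution.** Richardson–Lucy against the Gaussian PSF model, 10
iterations by default. Because the PSF is separable and symmetric, each
iteration is two separable Gaussian filters; flux is conserved to well
under 1% and the uniform image is a fixed point. `iterations=0` is the
identity.

**Segmentation.** The core is the largest connected component of the
smoothed DAPI channel above a threshold found in two steps: Otsu on the log
intensities locates the bright body, and the boundary is then refined at
half-maximum between the body median and background median — for a blurred
step edge this recovers the true boundary (the plain Otsu cut sits partway
down the PSF skirt and overestimates volume by ~25%). The mask is 3D
hole-filled; the Halo is everything outside a 2-voxel guard dilation (the
guard absorbs PSF bleed from core chromatin). A stack with no sufficiently
large, sufficiently contrasted body raises a "no nucleus" error; a core
touching more than a quarter of the field border logs an off-center
warning.

**Detection.** Candidate spots are 3D local maxima of a
Laplacian-of-Gaussian response at the PSF scale. When a deconvolved stack
is available the response is computed on it (deconvolution resolves core
foci below the raw diffraction limit), and each candidate must pass a
significance gate on the *raw* image's PSF-matched filter (Gaussian-smoothed
amplitude ≥ 5 robust SD) — the matched statistic has ~2.5× the SNR of the
LoG response and its noise is well-behaved, so the gate rejects both plain
noise maxima and the speckle Richardson–Lucy amplifies out of shot noise.
Sub-resolution artifacts are handled deterministically: candidate peaks
within (0.5, 0.25, 0.25) µm of a stronger peak are fused (deconvolution
spike splitting; plateau duplicates from sources centered between voxels),
and peaks within 8 PSF-σ of a ≥100× stronger peak are discarded as
deconvolution ringing sidelobes, which sit out to ~7σ at ~0.1% relative
amplitude.

**Measurement.** Voxels are assigned by marker-based watershed on raw
intensity inside the union of fixed Mahalanobis-4.5σ PSF apertures around
the peaks. The fixed aperture is the load-bearing choice: it captures a
brightness-independent ≥99.8% of a spot's flux, so any capture shortfall
cancels in the calibration ratio and the intensity-to-length conversion
stays linear from 810 bp to 200 kb (an intensity-isophote mask would
capture a brightness-dependent fraction and bias the 1620-bp standard by
~+20%). Integrated intensity is the aperture/watershed sum minus a
per-z-plane background (median of the field margin, capped at the plane
median). Foci whose aperture crosses the xy border are flagged and excluded
from length estimates; apertures summing to less than one camera count are
discarded as ripple.

**Calibration.** Slope `mean(I_810)/810` (or a zero-intercept least-squares
line when both standards are fitted); threshold `mean(I_810)`; the 1620-bp
standard's relative residual is reported as a linearity diagnostic.
Calibration is per channel — Cy5 and rhodamine fluorophores cannot share a
slope. Standard-slide measurements drop detections dimmer than 2× the
null-aperture noise (a standards slide holds only bright plasmid foci, so
sub-noise detections are spurious). The focus-scale noise σ is the robust
SD of integrated intensity over randomly placed, focus-sized null apertures.

**Thresholding and metrics.** A focus passes if its integrated intensity is
≥ the 810-bp threshold (inclusive boundary). Centromere foci have no bp
calibration and instead pass at ≥3× the per-stack null-aperture noise.
Per-nucleus metrics count passing foci by strand and compartment; contents
sum estimated lengths; the ECTR fraction is computed on kb content
(`100 · halo/(halo+core)` per strand); strand biases use the symmetric
denominator `mean(G, C)` (bounded, antisymmetric under channel swap);
colocalization is greedy mutual-nearest-neighbor matching of G and C
centroids within 0.3 µm (of the order of the PSF width, standard
object-based practice), with fraction `pairs / mean(nG, nC)`.

**Cell cycle.** Nuclei are binned on core centromere counts against the
modal 2N count (taken as the most frequent observed count, ties toward the
smaller): ≤1.25× modal → G1, ≥1.75× modal → G2, else S. The symmetric
margins around the 2N and 4N expectations are a design choice and are
configurable. Group comparisons use Welch's unequal-variance t-test with
median/IQR descriptives; content-vs-centromere coupling uses OLS with a
95% slope CI.

## Problem sizes

The packaged verification runs use desk-scale experiment sizes: 120 foci
per calibration standard, 20 nuclei for the core telomere:centromere check,
60 ECTR-free nuclei for the false-positive bound, 60 nuclei per preset for
count-recovery, and 100 small random fields for the noise-free
detector-oracle comparison. At these sizes the standard error of a slide's
mean standard intensity is ~2%, and of a 20-nucleus mean ratio ~1–2%.

## What passing tests do and do not show

The simulator shares the real assay's structure (compartments, skewed
populations, optics, camera) but idealizes it: molecules are point sources
(a 200-kb molecule may in reality be an extended coil), the PSF is a
separable Gaussian without aberrations, hybridization efficiency is uniform
and implicit in `photons_per_bp`, there is no probe background speckle,
TERRA RNA, chromatin fibers protruding into the Halo, or slide-to-slide
variation. Recovery of generator parameters on these data therefore
validates the estimator pipeline — segmentation, detection, calibration,
statistics — not the chemistry; on real stacks the detector's
noise-adaptive cuts and the run-in-parallel calibration design carry the
weight. Known estimator biases at defaults: crowded core foci merge below
the optical resolution (the diploid tel:cen ratio reads ~1.9 rather than
2.0), Halo counts under-read truth by ~5–7% (sub-threshold molecules plus
merging), and per-molecule sizes above ~0.4 Mb clip.
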