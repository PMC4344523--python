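# halofish

Quantitative analysis and ground-truthed simulation of **Halo-FISH** imaging
of extrachromosomal telomere-repeat (ECTR) DNA.

## The problem

Cells that maintain telomeres by the Alternative Lengthening of Telomeres
(ALT) pathway carry large, highly variable amounts of extrachromosomal
telomere-repeat DNA. Halo-FISH separates this material from chromosomes in
single cells: nuclei embedded in agarose are deproteinized and denatured, so
chromosomal DNA stays in a compact, intensely DAPI-stained **nuclear core**
while extrachromosomal molecules diffuse outward into a surrounding
**Halo**. Strand-specific PNA probes (TelG for the TTAGGG strand, TelC for
the complementary strand, plus a pan-centromere probe) then label individual
molecules, which are imaged as 3D widefield z-stacks and counted and sized
per nucleus.

`halofish` implements the computational side of this assay for people who
want to analyze such acquisitions or to study the estimator itself:

- **simulation** (`halofish.simdata`): a forward model of the whole
  experiment — per-nucleus ECTR populations with over-dispersed counts and
  log-normally skewed lengths, chromosomal core telomere/centromere foci,
  cell-cycle state, point-source rendering through a Gaussian PSF with
  Poisson–Gaussian camera noise and 12-bit quantization, plus
  plasmid-standard calibration slides — all with full ground truth;
- **analysis**: Richardson–Lucy deconvolution (`preprocess`), DAPI core/Halo
  segmentation (`segmentation`), 3D LoG + watershed focus detection and
  object-based G/C colocalization (`foci`), quantitative-FISH
  intensity-to-length calibration from 135- and 270-repeat plasmid standards
  (`calibration`), and every per-nucleus and group statistic
  (`quantify`): counts, kb contents, ECTR fractions, telomere:centromere
  ratios, strand biases, centromere-count cell-cycle binning, Welch t-tests
  and content-vs-centromere regression.

The core quantitative conversion is the Q-FISH calibration: with plasmid
standards of known insert length (135 repeats = 810 bp, 270 repeats =
1620 bp of telomere sequence) processed in parallel, a zero-intercept model

    I = s · L

maps background-corrected integrated focus intensity *I* (ADU) to telomere
repeat length *L* (bp), with *s* fitted as `mean(I_810) / 810`. The mean
intensity of the 810-bp standard doubles as the minimum detection threshold
for calling ECTR molecules, and the focus-scale noise σ yields an
informational detection limit `snr · σ / s`.

## Worked example

```python
import halofish as hf
from halofish.pipeline import PipelineParams, simulate_and_calibrate, analyze_stack

config = hf.SimConfig(rng_seed=1)          # 40 z x 144 x 144, 12-bit
params = PipelineParams()                   # RL 10 iters, LoG detection

# calibrate on simulated 135/270-repeat plasmid slides
cal = simulate_and_calibrate(config, params, seed=3)
print(round(cal.slope("TelG"), 3), round(cal.min_threshold("TelG"), 1))

# one GM847-like ALT nucleus in G1, end to end
truth, stack = hf.simulate_nucleus(hf.GM847, "G1", config, seed=1)
metrics, foci = analyze_stack(stack, cal, params, truth.nucleus_id)
print(truth.ectr_count("G"), metrics.halo_count_G)
print(round(metrics.tel_cen_ratio_G, 2), round(metrics.coloc_fraction_halo, 3))
```

prints

```
0.239 193.3
130 121
1.88 0.028
```

meaning: the fitted slope is 0.239 ADU per bp with a 193.3 ADU minimum
threshold (the 810-bp standard's mean intensity); of 130 true G-strand ECTR
molecules placed in the Halo, 121 are detected and pass the threshold; the
nuclear core shows 1.88 single-strand telomere foci per centromere focus
(the diploid expectation is 2 — two telomeres per chromosome arm pair — less
a few percent of crowded core foci merged below the optical resolution);
and only 2.7% of Halo G foci colocalize with a C focus, the signature of
single-stranded, single-molecule ECTR foci.

A shell interface wraps the same pipeline:

```bash
halofish simulate --preset GM847 --n-nuclei 20 --seed 1 --out stacks/
halofish simulate-standards --n-foci 120 --seed 2 --out standards/
halofish calibrate --std810 standards/std810 --std1620 standards/std1620 --out cal.json
halofish analyze --in stacks/ --cal cal.json --out results/
halofish summarize --metrics results/per_nucleus.csv --out results/summary.csv
```

`analyze` writes `per_focus.csv`, `per_nucleus.csv`, `group_summary.csv` and
a `run_report.json` carrying the run's parameter hash for provenance.

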