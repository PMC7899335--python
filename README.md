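# glrkit

Quantification toolkit for fluorescence imaging and behavioral assays of
AMPA-type glutamate receptor (GLR-1) trafficking in *C. elegans*.

Studies of receptor trafficking in worm neurons quantify the same four
readouts over and over: synaptic puncta along the ventral nerve cord
(VNC), the surface vs total receptor pool from a dual SEP/mCherry tag,
local receptor insertion by dual-channel FRAP, and glutamatergic
behavior. These measurements are usually done with ad hoc ImageJ/Igor
macros that are hard to reproduce. glrkit packages them as a tested
library plus CLI, together with a synthetic-data generator with known
ground truth, so every stage can be validated end to end without any
microscope data.

## What it computes

**Puncta calling on line scans** (`glrkit.puncta`). A punctum is a
maximal run of pixels exceeding the background by *k*·σ (default 4
standard deviations, background by robust sigma clipping) that is at
least 0.3 µm wide. Per punctum: peak intensity (optionally normalized to
a same-day fluorescent-bead mean), full width at half maximum

&nbsp;&nbsp;&nbsp;&nbsp;FWHM = |x₂ − x₁| at I = bg + ½(I_peak − bg),

and per scan the density in puncta per 10 µm.

**Surface-fraction quantification** (`glrkit.dualreporter`). SEP
(superecliptic pHluorin) is quenched in acidic endosomes; mCherry is
pH-insensitive. Over a shared ROI, with per-channel thresholds
calibrated from control images, the thresholded integrated densities
give

&nbsp;&nbsp;&nbsp;&nbsp;ratio = SEP/mCherry = f + (1 − f)(1 − q),

where f is the surface fraction and q the quench efficiency; the module
inverts this to f̂ = (ratio/cal − (1 − q))/q, normalizes ratios to
same-day controls, and computes unthresholded soma totals.

**Dual FRAP** (`glrkit.frap`). Photobleaching darkens mCherry in both
compartments but SEP only at the surface (quenched SEP is bleach-
protected), so SEP recovery reports insertion from the internal pool.
The nested geometry (bleach = central 50 % of the image, quantification
ROI = central 50 % of the bleach) minimizes lateral-diffusion
contamination. ROI totals at 0, 2.5, 5 and 10 min are normalized to
pre-bleach and fitted with n(t) = n₀ + A(1 − e^{−kt}).

**Behavior** (`glrkit.behavior`). Nose-touch and optogenetic ASH
responses (per-worm response fractions), thrashing per 30 s, spontaneous
reversals per 5 min, and aldicarb paralysis time courses (fraction
paralyzed at 15-min checks, per plate of 20 worms).

**Statistics** (`glrkit.stats`). Student's/Welch's t, one-way ANOVA,
Tukey–Kramer HSD, Dunnett many-to-one comparisons (Monte-Carlo
multivariate-t critical values), and two-way repeated-measures
(split-plot) ANOVA — implemented from the sums of squares up and
cross-checked against independent references in the test suite.

**Synthetic data** (`glrkit.synthdata`). Generators for all of the
above with full ground-truth records (puncta geometry, surface fraction,
quench/bleach efficiencies, kinetic rates, behavioral probabilities),
byte-reproducible under a fixed seed.

## Worked example

```python
import numpy as np
from glrkit import synthdata, puncta

truth = synthdata.ScanTruth(
    length_um=60.0, background_mean=100.0, background_sd=5.0,
    puncta=((10.0, 800.0, 0.5), (20.0, 600.0, 0.5), (30.0, 700.0, 0.5)),
    bead_mean=250.0, seed=1)
scan = synthdata.gen_linescan(truth)
found = puncta.detect_puncta(scan, min_width_um=0.3, k_sd=4.0)
for p in found:
    print(f"center {p.center_um:5.1f} um  peak {p.peak_intensity:7.1f} AU"
          f"  norm {p.peak_intensity_norm:4.2f}  FWHM {p.fwhm_um:5.3f} um")
s = puncta.summarize(found, scan, normalize=True)
print(f"density {s.density_per_10um:.2f} per 10 um, mean FWHM {s.mean_fwhm_um:.3f} um")
```

prints

```
center  10.0 um  peak   896.7 AU  norm 3.59  FWHM 1.182 um
center  20.0 um  peak   709.1 AU  norm 2.84  FWHM 1.156 um
center  30.0 um  peak   797.0 AU  norm 3.19  FWHM 1.191 um
density 0.50 per 10 um, mean FWHM 1.177 um
```

Three puncta are recalled at their true positions; the measured widths
match the analytic Gaussian FWHM 2√(2 ln 2)·σ ≈ 1.177 µm, and the
normalized peaks are the peak heights divided by the 250 AU bead mean.

The same pipeline is available from the shell:

```
glrkit simulate --preset linescan --seed 1 --out-dir sim/
glrkit puncta --input sim/linescan.csv --out-dir analysis/
```

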