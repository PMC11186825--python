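# orgkit

Phase-resolved OCT optoretinography (ORG) analysis for the outer retina:
phase-restoring sub-pixel motion correction of complex B-scan time series,
layer segmentation, nanometre-scale optical-path-length (OPL) dynamics
between outer-retinal layers, unsupervised discovery and SVM classification
of photoreceptor (Type-I) and RPE (Type-II) signals, and downstream
quantification — subretinal-space composition, amplitude/latency/slope
metrics, en-face functional maps, and rhodopsin-bleach conversion.

It is written for researchers analysing stimulus-evoked retinal deformations
in rodent (or other) phase-resolved OCT recordings, and for anyone who wants
a fully synthetic, ground-truthed test bed for ORG signal-processing
pipelines: the `orgkit.synthetic` module generates complex speckle B-scan
series, repeated volumes and labelled phase traces with known layer
kinetics, bulk motion and noise, so every stage can be validated without
any instrument data.

## The method

Phase-resolved OCT measures axial motion interferometrically: a reflector
displaced by ΔOPL shifts the complex image phase by

```
Δφ = 4π · ΔOPL / λc            (reflection geometry, λc = 840 nm)
```

so nanometre displacements are resolvable far below the ~2 µm structural
resolution. Long recordings require bulk-motion correction that preserves
this phase. `orgkit` estimates sub-pixel displacements between repeated
B-scans by locating the peak of the upsampled cross-correlation map
(single-step DFT refinement) and corrects them by multiplying linear phase
ramps in the lateral spatial-frequency domain and in the spectral
(depth-conjugate) domain at the true carrier-offset frequencies — which
simultaneously removes the bulk phase offset `4π·dz/λc` that an
intensity-only shift would leave in every trace.

Per-pixel phase traces of the mixed OS+RPE layer are self-referenced against
the IS/OS band, unwrapped, converted to ΔOPL with an expansion-positive sign
convention, band-stop filtered against heartbeat/breathing artifacts, and
excluded when the pre-stimulus SD exceeds 60 mrad. For classification (and
only for classification) traces are low-pass filtered at 10 Hz, windowed to
−1.0…+3.5 s on a 5 ms grid, standardized, and compressed by PCA; the top two
principal components plus the normalized distance to Bruch's membrane form a
3-D spatiotemporal feature space. Low-density outliers are removed by a
coverage-radius rule (radius of the sphere covering 2% of the remaining
points, fence `Q3 + (Q3 − Q1)/5`), the rest are cut into three Ward-linkage
clusters, named Type-I / intermediate / Type-II by depth, and a standardized
Gaussian-kernel SVM trained on these labels classifies new recordings —
slower protocols are linearly interpolated to 5 ms and Gaussian-smoothed
first.

Structure-level signals follow by averaging labelled pixels: the subretinal
space (SRS) is composed by the telescoping identity
`SRS = Type-II + ΔOPL(IS/OS rel ELM)`, and stimulus strength converts to a
rhodopsin bleach fraction `F = 1 − exp(−Φ·t·P)` with photosensitivity
`P = 1.26 × 10⁻⁸ µm²`.

## Worked example

Simulate a prolonged (25 B-scans/s, 30 s) recording with a programmed
100 nm outer-segment elongation and the default slow SRS expansion, then run
the full pipeline — registration, segmentation, QC'd trace extraction,
unsupervised classification and quantification:

```python
import numpy as np
from dataclasses import replace
from orgkit import KineticsSpec, ProtocolSpec
from orgkit.synthetic import simulate_bscan_series
from orgkit.pipeline import analyze_bscan_series

kinetics = replace(KineticsSpec(), type_I_amp=100.0)  # programme a 100 nm OS response
protocol = ProtocolSpec(bscan_rate=25.0, duration=30.0, baseline=2.0)
series = simulate_bscan_series(kinetics=kinetics, protocol=protocol,
                               depth_px=160, lateral_px=64, seed=11)
result = analyze_bscan_series(series, seed=3)

labels = result["labels"]
print(f"traces retained after QC: {len(labels)}")
for name in ("type_I", "intermediate", "type_II", "outlier"):
    print(f"  {name:13s} {np.sum(labels == name)}")
m = result["metrics"]
print(f"OS  peak amplitude: {m['OS'].peak_amplitude:.1f} nm at {m['OS'].peak_latency:.2f} s")
print(f"SRS peak amplitude: {m['SRS'].peak_amplitude:.1f} nm at {m['SRS'].peak_latency:.1f} s")
print(f"SRS expansion slope (2-10 s): {m['SRS_slope'][0]:.1f} nm/s")
```

Output:

```
traces retained after QC: 640
  type_I        158
  intermediate  117
  type_II       229
  outlier       136
OS  peak amplitude: 88.2 nm at 0.48 s
SRS peak amplitude: 241.9 nm at 19.3 s
SRS expansion slope (2-10 s): 14.8 nm/s
```

The Type-I (OS tips) pixels sit anterior to the Type-II (RPE) pixels; the
recovered OS peak (88 nm vs the programmed 100 nm, the shortfall being PSF
cross-talk between adjacent bands plus notch-filter loss), its ~0.5 s
latency, and the SRS peak/slope (242 nm at 19 s, 14.8 nm/s vs a 14.7 nm/s
ground-truth fit over the same window) all track the programmed kinetics.

The same stages are available as a CLI:

```
orgkit --seed 5 simulate --out raw.h5 --kind bscan
orgkit register --input raw.h5 --out reg.h5
orgkit segment  --input reg.h5 --out layers.tsv
orgkit traces   --input reg.h5 --out traces.tsv
orgkit --seed 5 cluster --input traces.tsv --out labels.tsv --model-out model.joblib
orgkit quantify --input reg.h5 --out metrics.tsv
```

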