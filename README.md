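# frapfit

Simulation-based analysis of FRAP and iFRAP experiments (fluorescence
recovery after photobleaching / its photoconversion mirror image).

Conventional FRAP analysis fits closed-form recovery expressions that
assume idealised bleach profiles, effectively infinite fluorophore pools
and flat 2D geometries. In samples like an early zebrafish embryo or a
finite in vitro chamber those assumptions fail, and the estimated
diffusion coefficients can be off by hundreds of percent. `frapfit`
instead *simulates* the experiment: it reads the measured image series,
uses the first post-bleach frame as the initial condition of a
finite-element diffusion simulation in the real 2D/3D sample geometry,
and fits reaction-diffusion models to the measured recovery curves. It is
aimed at quantitative biologists measuring effective diffusivities of
secreted proteins, dextrans and photoconvertible probes in vitro and in
tissue.

## Model

Fluorophore concentration c(**x**, t) obeys the diffusion equation with
closed (no-flux) boundaries on the sample domain Ω:

    ∂c/∂t = D ∇²c  in Ω,     ∂c/∂n = 0  on ∂Ω,

with the initial condition bilinearly interpolated from the first
post-bleach image inside the field of view and set to a rim estimate
c_rim outside it. A single simulation at a reference diffusivity D_ref
serves every candidate D through self-similarity,
c(**x**, t, D) = c(**x**, (D/D_ref)·t, D_ref). Spatially uniform
production (k₂) and degradation (k₁) superpose analytically:

    c̄(t) = c̄_diff(t)·e^(−k₁t) + (1 − e^(−k₁t))·k₂/k₁.

Fitting minimises the sum of squared differences between simulated and
measured mean intensities over the bleached and slice ROIs (optionally on
a common equalised [0, 1] scale with per-ROI factors E_i) using
multi-start Nelder–Mead in log-parameter space. Competing kinetic models
(pure diffusion, +production, +degradation, +both) are ranked by
AIC/AICc with Akaike weights.

## Worked example

Generate a synthetic FRAP experiment with known ground truth
(D = 30 px²/s on a disc-shaped sample) and analyse it:

```python
from frapfit import synthetic as syn
from frapfit import FRAPModel, extract_curves, make_standard_rois
from frapfit.workflow import build_reference

truth = syn.SyntheticGroundTruth(D_true=30.0)
ds = syn.generate_frap_dataset(truth, frame_interval=1.0, n_frames=300)

rois = make_standard_rois(truth.center, r_slice=90, s_bleached=72)
curves = extract_curves(ds.stack, [rois["bleached"], rois["slice"]])
reference = build_reference(ds.stack.frames[0], truth.build_geometry(), rois)

result = FRAPModel(curves, reference, kinetics="diffusion").fit(starts=5)
print(result.summary())
```

```
FRAP reaction-diffusion fit
===========================
kinetic model:     diffusion
equalisation:      off
n observations:    600  (ROIs: bleached, slice)
fitted parameters: 1
starts converged:  5/5

D    = 30.0314 px^2/s
SSD  = 2.84188e-06
R^2  = bleached: 1.0000, slice: 1.0000, mean: 1.0000, product: 1.0000
```

The fitted D of 30.03 px²/s recovers the ground truth within 0.1%; the
R² values say both ROI curves are reproduced essentially exactly. With a
physical pixel size, `result.D_physical(pixel_size_um)` converts to
μm²/s.

A thin CLI covers the same pipeline from the shell:

```
frapfit synth --suite benchmark --out data/ --seed 1
frapfit fit --images frap.tif --config config.yaml --model d --starts 5
frapfit select fit_d.json fit_dp.json fit_dd.json fit_dpd.json
```

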