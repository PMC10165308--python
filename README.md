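# phantomforge

Tools for producing a **ground-truth validation phantom** for molecular
radiotherapy (MRT) dosimetry: printable anthropomorphic organ shells, a
Lu‑177 pharmacokinetic filling schedule, traceable dispensing plans with
gravimetric uncertainty bookkeeping, and verification reports comparing
the achieved fill against the model.

Validating an image-based dosimetry chain (SPECT/CT quantification →
time–activity fitting → absorbed dose) needs imaging data whose ground
truth is *known*. A physical phantom whose compartments are filled to
the activity concentrations a pharmacokinetic model predicts at each
clinical imaging timepoint provides exactly that. `phantomforge` covers
the desk side of building such a dataset:

1. **`phantomforge.phantom`** — labelled voxel phantoms: validation and
   raw/YAML I/O, a deterministic synthetic anatomy generator (elliptical
   body housing, liver with embedded 15.9 mL spherical tumour insert,
   spleen, two kidneys split into cortex and medulla), label merging
   (e.g. renal pelvis → medulla) and connected-component cleanup, and a
   ray-parity mesh voxelizer for round-trip checks and activity maps.
2. **`phantomforge.meshing`** — marching-cubes surface extraction,
   uniform-weight Laplacian smoothing, divergence-theorem volumes,
   outward shell extrusion (2 mm walls; 1 mm for the medullas),
   overlap resolution, scene assembly and binary/ASCII STL I/O.
3. **`phantomforge.pk`** — a linear compartment model
   `dA/dt = K·A`, `A(0) = (A₀, 0, …)` with A₀ = 7400 MBq, solved by
   classical fixed-step RK4 (ΔT = 1 min, 100 days), decay-corrected
   storage with the Lu‑177 half-life attached, concentration tables at
   the clinical timepoints T = 1, 4, 24, 40, 72, 144 h (medulla = ⅓ ×
   cortex concentration; background = rest-of-body), and time-integrated
   activities with an analytic mono-exponential tail.
4. **`phantomforge.metrology`** — the 110%/105% dispensing protocol with
   decay correction to scan start, gravimetric volumes with rectangular
   readability uncertainties (u = d/√12), quadrature propagation, and
   the concise `value(uncertainty)` notation (`2.00(6) MBq/mL`).
5. **`phantomforge.reporting`** — fill-fraction tables in concise
   notation, achieved-vs-model deviation reports (mean ± SD summary),
   per-compartment underfill ranges, and voxel activity-map export
   (NIfTI).

## Worked example

```python
from phantomforge import pk

model = pk.build_model()                       # 7400 MBq, default rates
schedule = pk.solve_rk4(model)                 # RK4, 1-min steps, 100 d
table = pk.concentrations_at(schedule, pk.DEFAULT_TIMEPOINTS_H)
print(table.round(4))
```

```
time_h        1.0     4.0     24.0    40.0    72.0    144.0
compartment
liver        0.0209  0.0662  0.1201  0.1054  0.0768  0.0373
spleen       0.0655  0.2074  0.3704  0.3203  0.2264  0.1029
tumour       0.6455  2.0631  4.0453  3.8270  3.2478  2.2001
cortex-L     0.2120  0.6688  1.1584  0.9723  0.6470  0.2587
cortex-R     0.2120  0.6688  1.1584  0.9723  0.6470  0.2587
medulla-L    0.0707  0.2229  0.3861  0.3241  0.2157  0.0862
medulla-R    0.0707  0.2229  0.3861  0.3241  0.2157  0.0862
background   0.1059  0.0671  0.0038  0.0009  0.0004  0.0002
```

Each column is an imaging timepoint (hours post administration), each
cell a decay-corrected activity concentration in MBq/mL that the
corresponding phantom compartment must contain at that scan. The
medulla rows are exactly one third of their cortex rows, the left and
right cortices share one concentration (one kinetic kidney compartment
split by volume), and the background row tracks the rest-of-body pool.
The shipped transfer rates are illustrative defaults — replace them
with fitted patient values via the config to model a real cohort.

Turning the T = 24 h column into a dispensing plan for the spleen:

```python
from phantomforge import metrology as met
from phantomforge.uvalue import UValue

stock = met.StockCalibration(UValue(120.0, 3.6, "MBq/mL"))
rec = met.plan_dispense(
    target_concentration_MBq_mL=0.3704, compartment_volume_mL=124.9,
    stock=stock, scan_time_h=24.0, half_life_h=pk.LU177_HALF_LIFE_H,
    dispense_time_h=0.0)
```

The plan draws 110% of the decay-corrected required activity
(`rec.draw_MBq` ≈ 56.5 MBq in `rec.stock_draw_mL` ≈ 0.47 mL), pre-dilutes
to 105% of the compartment volume and tops up to the on-model solution
volume (110%, ± 0.01 mL); dispensing exactly one compartment volume then
reproduces the target concentration at scan time identically — the
closed-loop identity the test suite checks to 1e-10.

The same pipeline is scriptable from the shell:

```sh
phantomforge synth --out phantom/            # synthetic voxel anatomy
phantomforge mesh --phantom phantom/ --organ liver --out stl/
phantomforge pk solve --out schedule.csv
phantomforge fill plan --scan-time 24 --stock-conc 120 --out plan.csv
phantomforge report fills                    # fill-fraction table + underfill
phantomforge export map --phantom phantom/ --time 24 --out truth.nii.gz
```

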