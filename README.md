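# nanonuc

Vapor-bubble nucleation thresholds for volatile perfluorocarbon
(perfluoropentane, PFP) nanodroplets confined by elastic tissue and driven
by focused ultrasound.

The package implements a modified classical nucleation theory (CNT) in
which the droplet's compressibility and the surrounding tissue's
elasticity act as two springs in series.  It provides:

- **`nanonuc.eos`** — Redlich–Kwong equation of state for the droplet
  liquid: isotherms, liquid-branch spinodal extraction, the empirical
  liquid-density and macroscopic-surface-tension correlations, and an
  optional Maxwell equal-area saturation-pressure construction.
- **`nanonuc.interfaces`** — pressure bookkeeping: Laplace pressure,
  Henry's-law dissolved-gas partial pressure, series (harmonic) modulus,
  elastic back-pressure, the metastability degree δ of the stretched
  liquid, and the metastability-scaled effective surface tension.
- **`nanonuc.energetics`** — the dimensionless nucleation-work landscape
  `w(X; γ) = 3X² − 2X³ + γX⁶`, its critical-radius / stable-critical-radius
  bifurcation (coalescence at γ = 27/256, energetic equilibrium at
  γ = 1/16), critical work, kinetic prefactor, nucleation rate and
  probability.
- **`nanonuc.threshold`** — the initial nucleation threshold (INT): the
  acoustic-tension magnitude at which the probability of nucleating the
  first bubble within τ = 1/(tau_divisor·f) reaches 50%, solved by
  bisection with a spinodal-bounded bracket; plus parameter sweeps
  (tissue modulus, droplet radius, interfacial tension, frequency,
  dissolved gas) and probability curves.
- **`nanonuc.fieldmap`** — a simplified *linear* axisymmetric focused-bowl
  pressure field (Rayleigh diffraction integral, power-law tissue
  attenuation) and extraction of achievable nucleation areas — the
  super-threshold region per droplet size.  Qualitative by design; it is
  not a nonlinear full-wave solver.
- **`nanonuc.cli` / `nanonuc.config`** — a `nanonuc` command-line tool,
  flat YAML configs with unit-suffixed keys (SI conversion happens only at
  this boundary), CSV/JSON artifacts and reproducibility manifests.

## CLI

```bash
nanonuc schema                                   # config keys, defaults, units
nanonuc spinodal --temps 294,302,310,343 -o spinodal.csv
nanonuc density --temps 310 -o density.csv
nanonuc work-curve --gamma 0.0625 -o work.csv    # minimum at X = 2
nanonuc threshold -o threshold.json              # defaults: 140 nm PFP, 5 MHz
nanonuc sweep --param R20_nm --values 50,100,140,200,500,1000 -o sweep.csv
nanonuc field --config scenario.yaml -o field.csv
nanonuc area --config scenario.yaml --diameters 100,200,300,400,500 -o area.json
```

Configs are flat YAML with unit-suffixed keys, e.g.

```yaml
R20_nm: 140
sigma2_mN_per_m: 56
K3_MPa: 0.4
f_MHz: 5
```

Unknown keys are a hard error.  Every command writes a JSON manifest next
to its output with the fully resolved configuration; re-running from a
manifest's config reproduces the outputs (the pipeline is deterministic —
no randomness anywhere).

## Library quick start

```python
from nanonuc import threshold, interfaces

res = threshold.solve_threshold(
    droplet=interfaces.DropletConfig(R20=140e-9, sigma2=56e-3),
    tissue=interfaces.TissueConfig(K3=0.4e6),
    f=5e6)
print(res.P_INT / 1e6, "MPa")   # ~5.0 MPa at the defaults
```

## Output column conventions

CSV artifacts use SI-suffixed column names: `T_K`, `V_m3_per_mol`, `P_Pa`,
`P_INT_Pa`, `sigma1_Npm`, `z_mm`/`r_mm`/`PNP_Pa` (field maps are exported
in millimetres for readability).  Floats are serialized with 9 significant
digits.

## Notes on scope

- The spinodal criterion is the liquid-branch local minimum of the
  isotherm (dP/dV = 0, d²P/dV² > 0); with the shipped PFP constants this
  reproduces the −5.26 MPa spinodal at 310 K.
- Saturation pressure is a user input per temperature; the package refuses
  to extrapolate the single 310 K preset across temperatures.
- The field mapper is linear and monochromatic; absolute focal dimensions
  from nonlinear simulations are out of scope.
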