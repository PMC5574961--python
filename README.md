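# sonokinetics

Quantitative analysis of the fluorescence kinetics of intercalating model
drugs (SYTOX Green, propidium iodide) after transient membrane
permeabilization — by ultrasound-activated microbubbles (sonoporation) or
by detergent. The package is aimed at researchers who monitor model-drug
uptake with time-lapse fluorescence microscopy or spectrofluorometry and
need to separate what the intensity time course says about *membrane
permeability* from what it says about intracellular diffusion, nuclear
accumulation, DNA binding and photobleaching.

## The problem

Intercalating dyes are nearly dark in solution and brighten several
hundred-fold when they bind nucleic acids. After sonoporation, the
intracellular fluorescence I(t) therefore reflects a chain of processes —
pore-local entry, cytosolic diffusion, nuclear import and intercalation —
not membrane transport alone, and it is further distorted by
photobleaching. The package models this chain mechanistically, generates
synthetic microscopy data with known ground truth, and estimates the
standard summary statistics used in the field:

* **Photobleaching rate constant** `k_pb`, from stained fixed cells:
  `I(t) = b + A·exp(−k_pb·t)`, with the duty-cycle model
  `k_pb(DC) = k_dark + k_laser·DC`.
* **Fluorescence rate constant** `k_f`, the apparent first-order rate of
  signal enhancement, from the two-compartment model (2CM)
  `I(t) = b + A·(1 − exp(−k_f·t))`, or from the three-compartment model
  (3CM) that adds a photobleached pool,
  `I(t) = b + A·k_f·(e^(−k_f·t) − e^(−k_pb·t)) / (k_pb − k_f)`,
  fitted with `k_pb` fixed to the fixed-cell calibration.
* Population summaries (median, 5–95 percentiles), fold ratios between
  conditions, and OLS regression of `k_f` on dye concentration.

The mechanistic core is a mass-conserving ODE over five states (free/bound
dye in cytosol and nucleus plus a bleached pool) driven by a time-dependent
membrane permeability — an exponentially resealing pore for sonoporation,
a constant permeability for detergent-treated monolayers. A 2-D
reaction–diffusion variant reproduces the single-cell picture: pore-local
entry, a cytosolic plateau within tens of seconds, and slow nuclear
accumulation lasting many minutes. See `docs/methods.md` for the model,
its assumptions and the packaged calibrations.

## Worked example

Simulate a FaDu cell exposed to ultrasound + microbubbles in 2 µM SYTOX
Green, recorded by fibered confocal microscopy (one frame per 30 s for
30 min), and fit the two-compartment model:

```python
from sonokinetics import simulate_condition, fit_trace, apparent_rate_preset

trace, states = simulate_condition("usmb_fadu", 2.0)   # 2 µM
fit = fit_trace(trace, "2cm")
print(f"fitted k_f : {fit.k_f * 1e3:.3f} x 10^-3 s^-1")
print(f"target k_f : {apparent_rate_preset('usmb_fadu', 2.0) * 1e3:.3f} x 10^-3 s^-1")
print(f"baseline   : {fit.baseline:.3f} a.u.")
print(f"amplitude  : {fit.amplitude:.3f} a.u.")
print(f"converged  : {fit.converged} ({fit.n_points} points)")
```

prints

```
fitted k_f : 0.400 x 10^-3 s^-1
target k_f : 0.400 x 10^-3 s^-1
baseline   : 2.912 a.u.
amplitude  : 8.001 a.u.
converged  : True (61 points)
```

The fitted rate is the apparent fluorescence rate constant at 2 µM — twice
the packaged 0.2×10⁻³ s⁻¹ µM⁻¹ concentration response, confirming the
preset calibration. The baseline is the free-dye signal internalized while
the pore was open; the amplitude is the nuclear-binding signal that grows
over the whole acquisition.

The same workflow is available from the shell:

```bash
sonokinetics simulate-traces --condition usmb_fadu --concentration 2 \
    --n-cells 20 --seed 1 --out traces.csv
sonokinetics fit --traces traces.csv --model 2cm --out fits.csv
sonokinetics analyze --fits fits.csv --out summary.json
```

and full preset experiments (`laser_dc`, `concentration_usmb`, `chem_perm`,
`cell_line`, `single_cell`) via `sonokinetics reproduce <preset>`, which
writes a Markdown report comparing each recovered quantity with its
packaged reference value and exits non-zero if any tolerance check fails.

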