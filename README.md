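# mockloop

A 0D (lumped-parameter) simulator of a CMR-compatible **mock circulatory
loop** — the bench rig used to validate computational hemodynamics of the
aortic arch against in-vitro phase-contrast MR flow measurements — together
with the validation statistics used for such comparisons.

It is aimed at cardiovascular modellers who want a desk-scale, fully
reproducible stand-in for the multi-scale (3D CFD + lumped network)
validation pipeline: the spatially resolved aortic domain is replaced by an
algebraic junction surrogate, so the whole system reduces to five ODEs that
integrate in about a second, while the network parameters, boundary
conditions and comparison statistics are retained.

## Model

Inlet flow Q_in(t) (pulsatile pump, half-sine systole) enters a massless
junction and splits over four branches j ∈ {innominate, carotid,
subclavian, descending aorta} through small internal resistances r_int,j.
Each branch carries a Windkessel compliance C_j and drains through a
calibrated non-linear tap plus tube resistance,

    ΔP_j = a_j·Q² + (b_j + R_j2)·Q ,

into a common node (compliance C_t) that returns through R_t to a constant
atrial head P_at = 8 mmHg. The node pressures obey

    C_j dp_j/dt = q_j − q_out,j ,
    C_t dp_c/dt = Σ_j q_out,j − (p_c − P_at)/R_t ,

integrated by explicit Euler at Δt = 1e-4 s over repeated cardiac cycles
until periodic (cycle-to-cycle pressure change < 0.1 mmHg). The shipped
parameter preset is the calibration of the physical circuit; the default
pump settings are cardiac output 5.48 L/min (TGA run) or 5.25 L/min
(control run), period 0.8 s. See `docs/methods.md` for the full model
description, numerical safeguards and limitations.

## Worked example

```python
import mockloop as ml

config = ml.default_network()                      # calibrated preset
wave = ml.generate_pump_waveform(ml.TGA_PUMP, 8000)  # 5.48 L/min, T = 0.8 s
result = ml.run_to_periodic(config, wave)

mmhg = 133.322
print(f"cycles to periodic : {result.cycles_run}")
print(f"mean p_aorta       : {result.p_aorta.mean()/mmhg:.1f} mmHg")
print(f"peak / min p_aorta : {result.p_aorta.max()/mmhg:.1f} / "
      f"{result.p_aorta.min()/mmhg:.1f} mmHg")
print("flow splits (%)    :", [f"{s:.1f}" for s in result.flow_split_percent()])
```

prints

```
cycles to periodic : 7
mean p_aorta       : 84.3 mmHg
peak / min p_aorta : 102.6 / 66.9 mmHg
flow splits (%)    : ['16.2', '10.6', '18.2', '55.0']
```

i.e. the loop settles at a mean aortic pressure of 84.3 mmHg with a
102.6/66.9 mmHg pulse, and the four outlets carry 16.2/10.6/18.2/55.0% of
the mean inlet flow (innominate/carotid/subclavian/descending aorta) —
close to the reference operating point of the bench comparison
(mean 85.7 mmHg, splits 15.7/10.3/17.8/55.1%).

The same pipeline is available from the shell:

```sh
mockloop waveform --co-lmin 5.48 --out wave.csv
mockloop simulate --waveform wave.csv --out sim.csv --report report.json
mockloop validate --sim sim.csv --measured measured.csv --report cmp.json
mockloop paper-stats --report stats.json   # recompute the published statistics
```

All artifacts are plain text (CSV time series, JSON configs/reports).

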