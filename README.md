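# azsim — calcium microdomains at the Drosophila NMJ active zone

Some active zones (AZs) of the Drosophila larval neuromuscular junction
carry a **T-bar**: a table-shaped electron-dense structure (a ~30 nm leg
topped by a ~140 nm roof) around which voltage-gated calcium channels
cluster. Because vesicle release probability depends superlinearly on the
calcium concentration near the release sites, the obvious question is
whether this structure *does* anything: does the T-bar, acting as a
diffusion obstacle, concentrate the calcium microdomain that forms during
an action potential?

`azsim` answers this in silico. It builds voxelized 3D anatomies of a
single AZ — with or without the T-bar, with clustered (70 nm) or dispersed
(140 nm) channel zones holding the same six N-type channels — and solves
the coupled diffusion–reaction system for free calcium and a mobile buffer

∂ₜ[Ca] = D_Ca Δ[Ca] − R,  ∂ₜ[B] = D_B Δ[B] − R,
R = k_on [B][Ca] − k_off([B]ₜₒₜ − [B]),

driven by a Goldman–Hodgkin–Katz channel flux gated by Borg-Graham-style
m²h kinetics, opposed by PMCA/NCX Hill pumps and a leak calibrated to hold
the 50 nM resting state exactly. Ring probes around the (virtual) T-bar
socket (radius R, height H) quantify the microdomain, and matched-peak
ratios compare the three anatomies. See `docs/methods.md` for the model,
numerics (exact fast-transform diffusion solves with a capacitance-matrix
obstacle correction) and parameter table.

This is an audience-of-modellers package: the library under `src/azsim/`
is the interface, the numbered scripts under `analysis/` run the study's
experiment sequence, and an `azsim` CLI wraps the common runs.

## Worked example

Compare the T-bar and no-T-bar anatomies (clustered channels in both)
through the first 40 Hz calcium peak on a desk-scale box — about a minute
on one core:

```python
import numpy as np
import azsim

results = {}
for name in ("tbar_clustered", "no_tbar_clustered"):
    cfg = azsim.make_preset(name, h=0.01).with_(
        t_end=6e-3,
        geometry=azsim.make_preset(name).geometry.with_(box_dims=(0.3, 0.3, 0.15)),
    )
    results[name] = azsim.run_scenario(cfg)

ts = results["tbar_clustered"].probe_series(0.03, 0.01)   # R = 30 nm, H = 10 nm
i = int(np.argmax(ts.values))
print(f"T-bar peak:   {ts.values[i]:.2f} uM at t = {ts.times[i]*1e3:.2f} ms "
      f"(baseline {ts.values[0]*1e3:.0f} nM)")
comp = azsim.scenario_ratios(results, 0.03, 0.01, peak_index=0)
print(f"no-T-bar peak: {comp.values['no_tbar_clustered']:.2f} uM")
print(f"T-bar excess near the membrane: {comp.percent_excess:.1f} %")
comp_roof = azsim.scenario_ratios(results, 0.03, 0.04, peak_index=0)
print(f"under-roof fold (H = 40 nm):    {comp_roof.fold['no_tbar_clustered']:.2f}x")
```

prints

```
T-bar peak:   18.30 uM at t = 4.19 ms (baseline 50 nM)
no-T-bar peak: 13.74 uM
T-bar excess near the membrane: 33.2 %
under-roof fold (H = 40 nm):    2.06x
```

Reading: a single action potential drives the ring-averaged concentration
30 nm from the socket axis from its 50 nM resting value to ~18 μM, peaking
4.2 ms after stimulus onset. The identical anatomy without the obstacle
peaks ~33% lower at the membrane, and the gap widens to about a factor two
just under the roof — the T-bar traps the microdomain where vesicles dock.
Dispersing the same six channels over a 140 nm disk (preset
`no_tbar_dispersed`) lowers the peak a further ~2× relative to the T-bar
case.

## Analysis scripts and CLI

```bash
python analysis/01_compare_scenarios.py    # three anatomies, full (R, H) ratio table
python analysis/02_frequency_sweep.py      # 20/40/80/100 Hz, later peaks
python analysis/03_vgcc_sweep.py           # 1–20 channels per AZ
python analysis/04_buffer_pump_sweep.py    # buffer/pumps on vs off
python analysis/05_grid_convergence.py     # nested-grid verification
```

Each script states its finding and writes CSV tables under `results/`.
The same experiments are available as `azsim run|compare|sweep-vgcc|
sweep-buffer|converge|probe` on the command line; single runs export probe
traces (CSV), run metadata (JSON), the exact config echo (YAML) and
optional VTK snapshots.

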