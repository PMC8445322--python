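# retroquant

Quantification of **intraluminal vesicle (ILV) retrofusion** from live-cell
time-lapses of a protease-cleavable GFP–CD63 reporter.

Multivesicular bodies (MVBs) carry reporter both on their limiting membrane
(LM) and on ILVs inside. Once a chemically induced protease is switched on,
only the cytosol-exposed LM pool can be cleaved (its GFP then accumulates in
the nucleus). Continued loss of endolysosomal GFP beyond the LM share
therefore requires *retrofusion* — ILVs fusing back with the LM and
re-exposing their cargo. This package implements the full quantitative chain
for that assay, for cell biologists analysing such movies and for anyone who
wants a tested, reproducible reference implementation:

1. **Segmentation** of each frame into endolysosomes (EL, far-red lysosome
   probe), nuclei (N, red marker), plasma membrane (PM, GFP) and cytosol,
   with first/last-frame thresholds linearly interpolated in between.
2. **Decay readouts**: the cytosol-background-subtracted, first-frame
   normalized EL median trace; its near-linear slope *A* over 90–360 min
   (per hour); the remaining fraction *R(t)*; condition-vs-control ratios.
3. **Kinetics**: a linear six-pool model of the reporter —
   LM pool `L`, dynamic (retrofusion-competent) ILV pool `I_dyn`, inert ILV
   pool `I_inert`, nuclear `N`, degraded `D`, secreted `S`:

   ```
   dL/dt       =  k_retro·I_dyn − k_cleave·L
   dI_dyn/dt   = −(k_retro + k_deg + k_sec)·I_dyn
   dI_inert/dt = −(k_deg + k_sec)·I_inert
   dN/dt       =  k_cleave·L        dD/dt = k_deg·(I_dyn+I_inert)
   dS/dt       =  k_sec·(I_dyn+I_inert)
   ```

   with observable `L + I_dyn + I_inert`, intraluminal fraction
   `f_ilv = ρ/(1+ρ)` from the ILV:LM abundance ratio ρ, and
   `k_deg = ln2/half-life`. Without retrofusion the observable plateaus at
   `f_ilv` (≈ 67 % at the immunogold-measured ρ = 2); with retrofusion the
   plateau drops to `f_ilv·(1−φ_dyn)`. Forward simulation is the exact
   matrix exponential; fitting is bounded multi-start least squares.
4. **Fate partition**: pulse-chase half-life, exosome share of the MVB pool,
   exosome GFP/CD63 ratio changes, immunogold ILV:LM summaries, and the
   lower bound on the ILV fraction that retrofused during the window.
5. **Synthetic data**: seeded generators for three-channel stacks and all
   side tables, with recorded ground truth, so every stage is testable
   without microscope data.

## Worked example

The numbered drivers under `analysis/` run the whole chain on simulated
movies (stacks go to `scratch/`, tables to `results/`):

```sh
python analysis/01_simulate_timelapse.py
python analysis/02_quantify_decay.py
python analysis/03_fit_kinetics.py
python analysis/04_fate_partition.py
```

which prints, among other lines:

```
        dimerizer: slope_A = -0.0812/h (rel ctrl 1.00), remaining_6h = 0.486
     no_dimerizer: slope_A = +0.0000/h (rel ctrl -0.00), remaining_6h = 1.000
 retro_attenuated: slope_A = -0.0701/h (rel ctrl 0.86), remaining_6h = 0.544
    k_cleave: fitted 0.00400 (generating 0.00400)
     k_retro: fitted 0.00400 (generating 0.00400)
 phi_dynamic: fitted 0.70017 (generating 0.70000)
no-retrofusion plateau at rho=2: 66.7% of initial EL signal
retrofusion lower bound: 7.8% of ILVs
```

Reading: the protease-on movie decays at slope −0.081/h and keeps 48.6 % of
its EL signal at 6 h; with the protease off the trace is flat (the control);
halving the retrofusion rate weakens the slope to 86 % of control. Fitting
the model to the quantified curve recovers the generating parameters, and
the fate arithmetic turns the measured scalars into per-pathway shares.

The same pipeline is exposed as a CLI (`retroquant simulate | quantify |
partition | all`) driven by a YAML config; every run writes back the
resolved configuration, seed included.

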