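# weplrange

**Inter-fraction proton range uncertainty from serial volumetric CT.**

Proton treatment plans are only as robust as the uncertainty model behind
them.  Between treatment fractions the patient's anatomy changes — setup
residuals after image guidance, organs moving relative to bone, weight
loss, filling — and every such change alters the water-equivalent path
length (WEPL) from the skin to the target, i.e. the proton range.
`weplrange` quantifies this *random* range error from daily volumetric
imaging of previously treated patients: it builds, per treatment site and
beam angle, the probability distribution of residual range changes that
robust optimisers and robustness analyses need as input.

For each patient course the package:

1. converts CT numbers to relative proton stopping power through a
   piecewise-linear calibration whose knots come from the Bethe–Bloch
   ratio
   `S_rel = (ρ_e/ρ_ew)·[ln(2 m_e c² β²/(I(1−β²)))−β²] / [ln(2 m_e c² β²/(I_w(1−β²)))−β²]`
   (I_w = 75 eV; the ratio is energy independent to <0.6 % over
   therapeutic energies, 0.238 % computed for the worst-case cortical-bone
   insert between 90 and 310 MeV);
2. ray-traces the effective depth `WEPL = Σ spᵢ·ℓᵢ` to every CTV pixel,
   in-plane toward the beam focus, with an exact Siddon-style grid walk;
3. registers each daily image into the reference frame with the rigid
   couch shift recorded clinically, correcting field-of-view truncation
   with a uniform-density body mask where needed;
4. forms per-fraction ΔWEPL distributions in the CTV against the first
   usable fraction (Δ>0 = undershoot risk, Δ<0 = overshoot risk); and
5. aggregates them into population statistics: overall mean, systematic
   Σ (SD of per-fraction means, image-weighted) and random σ (SD of all
   per-pixel deltas, data-point-weighted).

Because clinical serial CT is not publicly shareable, the package also
ships a ground-truthed synthetic module: 2D digital phantom courses with
setup error + recorded IGRT corrections, relative motion of femoral-head
surrogates, body-contour erosion and density fluctuations, with analytic
(m*, Σ*, σ_w*) ground truth that the full pipeline provably recovers.

## Worked example

Simulate a 20-fraction pelvis-like course in which the femoral-head
surrogates move relative to the CTV (SD 3 mm) on top of a 1 mm
post-correction setup residual, then analyse it for an anterior (0°) and
a lateral (90°) parallel beam:

```
$ cat motion.json
{"relative_insert_motion_sd": 3.0, "residual_after_igrt_sd": 1.0}

$ weplrange simulate --phantom prostate --motion motion.json \
      --fractions 20 --seed 7 --angles 0,90 --out demo
wrote 20-fraction course to demo

$ weplrange analyze --config demo/config.json
analysis written to demo/analysis

$ cat demo/analysis/population.csv
angle,mean_mm,sigma_mm,sd_mm,n_fractions,n_pixels
0,0.3184,0.9908,0.9795,20,9680
90,-0.5396,0.7770,3.4399,20,9680
All,-0.1106,0.9803,2.5651,40,19360
```

Reading the table: `sigma_mm` is the systematic component Σ (how much the
whole-fraction mean range change wanders from day to day) and `sd_mm` is
the random component σ (the spread of individual pixel range changes).
The lateral beam's σ of 3.44 mm dwarfs the anterior beam's 0.98 mm: the
90° rays cross the moving high-density discs, the 0° rays do not — the
beam-angle dependence that makes such priors worth measuring per site.
The output directory also contains per-fraction summaries
(`summaries.csv`), full percent-volume histograms (`histograms.csv`,
plus heat-map PNGs of ΔWEPL vs fraction), raw per-pixel deltas
(`samples.csv`) and a `run_log.json` that suffices to replay the
analysis byte for byte.

The same `analyze` entry point runs on real data: per-fraction NIfTI
volumes (HU), CTV/BODY masks on the planning grid, a
`fraction,dx_mm,dy_mm,dz_mm,rotation_deg,usable` shift CSV, and a config
JSON naming beam angles, source–axis distance, scanning-circle diameter
and calibration curve.  `weplrange calibrate` builds calibration curves
from insert measurements, `weplrange wepl` dumps raw effective-depth
maps, and `weplrange stats` re-aggregates population tables from
previously written per-fraction CSVs.

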