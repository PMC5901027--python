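# littplan

Automated trajectory planning for **laser interstitial thermal therapy
(LiTT)** of the mesial temporal lobe, the minimally invasive alternative to
open resection in drug-resistant mesial temporal lobe epilepsy.  The package
is aimed at researchers studying stereotactic planning algorithms: it
implements the full computer-assisted planning (CAP) loop — anatomical model
generation, safety-metric computation, feasibility filtering and ranking of
candidate trajectories, cylindrical ablation-zone volumetrics, and
manual-versus-automated cohort statistics — and ships a fully synthetic,
analytically ground-truthed head phantom so every stage is testable without
patient imaging.

## The model

Given a parcellated label volume (NIfTI + a `{label: role}` JSON map) the
planner:

1. **Target.**  Places the target at the amygdala centroid transformed 3 mm
   medially, 3 mm anteriorly and 3 mm inferiorly, aiming at the anterior
   amygdala surface while protecting the temporal stem and globus pallidus.
2. **Entries.**  Enumerates candidate entry points on prioritized entry
   gyri — inferior occipital, then middle occipital, then posterior middle
   temporal — on a deterministic world-space grid (default 2 mm pitch).
3. **Safety metrics.**  For each straight candidate `entry → target`:
   intracerebral length from the inner-skull crossing; drilling angle to the
   outer-skull normal; minimum distance and cumulative risk from critical
   structures (sulci as vasculature proxies), with pointwise risk

   `r(d) = 1` for `d ≤ 3 mm`, `r(d) = 0` for `d ≥ 10 mm`, linear between,

   and overall risk `R = ∫ r(d(s)) ds / 10 mm` over the intracerebral
   segment; contact with the eroded core of the amygdalohippocampal complex
   (AHC) as a fraction of its principal-axis extent; and minimum brainstem
   distance.
4. **Feasibility and ranking.**  Rejects candidates that cross the lateral
   ventricles (exclusion zone), come closer than the 3 mm planning safety
   margin to a critical structure, or exceed the 45° drilling-angle limit;
   ranks the survivors by
   `w_r·risk − w_a·AHC + w_l·length/150 + w_θ·angle/90` and returns the
   argmin, falling back to the next entry gyrus only when a role has no
   feasible candidate.
5. **Ablation model.**  Dilates the chosen trajectory into a flat-capped
   cylinder (default diameter 15 mm, device range 5–20 mm) from the tectal
   coronal plane to the target, intersects it with each ROI (amygdala,
   tectal-truncated hippocampus, entorhinal cortex, parahippocampal gyrus)
   and reports absolute/percentage ablation, the residual unablated depth of
   the mesial hippocampal head, and the grey-matter fraction of the cavity.

## Worked example

```sh
littplan phantom --out ph --side left --seed 3
littplan plan --volume ph/phantom.nii.gz --labelmap ph/labelmap.json --tectal-y -26 --out plan.json
```

prints (abridged)

```
"feasible": true,
"entry_role_used": "inferior_occipital",
"n_candidates_evaluated": 58,
"n_feasible": 41,
"rejection_tally": { "drilling_angle": 3, "ventricle": 14 }
```

— the planner found a feasible posteroinferior corridor through the
inferior occipital gyrus; 14 candidates were discarded for crossing the
occipital horn of the lateral ventricle.  Metrics for the winning
trajectory:

```sh
littplan metrics --volume ph/phantom.nii.gz --labelmap ph/labelmap.json \
    --entry -42.5,-69.5,-3.5 --target -23,11,-21 --tectal-y -26
```

```
"intracerebral_length": 85.1,   # mm from inner-skull crossing to target
"drilling_angle": 16.2,         # degrees off the outer-skull normal
"min_critical_distance": 7.98,  # mm; > 3 mm safety margin, hence feasible
"overall_risk": 0.24,           # low: the path stays clear of the sulci
"ahc_center_proportion": 0.92,  # the path cannulates the AHC long axis
"ventricle_hit": false
```

and the expected ablation volumetrics:

```sh
littplan ablate --volume ph/phantom.nii.gz --labelmap ph/labelmap.json \
    --entry -42.5,-69.5,-3.5 --target -23,11,-21 --tectal-y -26 --out report.tsv
```

```
role                    anatomical_volume_mm3  ablated_volume_mm3  percent_ablated
amygdala                1648.00                1168.00             70.87
hippocampus             2303.00                2291.00             99.48
ahc                     3951.00                3459.00             87.55
entorhinal_cortex       723.00                 115.00              15.91
parahippocampal_gyrus   3093.00                69.00               2.23
total                   7767.00                3643.00             46.90
```

The 15 mm cylinder ablates most of the AHC while sparing the
parahippocampal gyrus; on this phantom 53% of the modelled cavity is grey
matter.  Anatomical variants that close the posteroinferior corridor
(`--variant deep_collateral_sulcus` or `enlarged_occipital_horn`) force the
planner to fall back to a middle occipital entry.

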