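# memkit

Structural and mechanical analysis of planar lipid bilayers, with a
synthetic-bilayer generator that makes every estimator testable against a
known ground truth.

## What problem this addresses

Bilayer simulations of biological membranes (plasma-membrane- and
myelin-like mixtures of phospholipids, sphingomyelin, galactosylceramide
and cholesterol) are characterized by a standard set of observables: area
per lipid, thickness from the phosphate peaks of the density profile,
carbon-tail order parameters, cholesterol tilt, hydrogen bonds, leaflet
interdigitation, water penetration, and the mechanical moduli that govern
stretching and bending.  `memkit` implements this whole observable set as a
tested Python library for anyone analyzing planar-bilayer configurations
(multi-frame GRO or PDB) and the scalar time series (projected area,
surface tension) that mechanical analyses consume.

Because trajectory data for such studies are rarely deposited, the package
ships a first-class synthetic generator: it draws bilayer configurations
and scalar ensembles whose *statistics* are prescribed — not molecular
dynamics — so every estimator can be validated by parameter recovery.

## The core quantities

With the bilayer normal along z and projected area `A = Lx·Ly`:

- **Areal strain** — `ε_A = A/A₀ − 1`, with `A₀` the mean area at zero
  tension.
- **Area compressibility modulus, two routes** —
  `K_A = (∂γ/∂ε_A)_T = k_B·T·⟨A⟩_eq / ⟨δA²⟩_eq`.
  The regression route splits each constant-tension production series into
  4 blocks, averages γ and ε_A per block, and takes the OLS slope (its SE
  is the SE of K_A; fits with r² < 0.9 are flagged).  The fluctuation route
  evaluates the right-hand side on the equilibrium area series, with a
  4-block jackknife SE.
- **Bending modulus** (polymer-brush relation) —
  `K_c = K_A·(h − h₀)²/24`, `h` the phosphate-peak thickness, `h₀ = 1 nm`
  (valid for PC bilayers in the liquid phase).
- **Order parameter** — `S_C = ½⟨3·cos²θᵢ − 1⟩`, where θᵢ is the angle
  between the axis through the C(i−1) and C(i+1) carbons and the bilayer
  normal; 1 = fully aligned, 0 = isotropic, −0.5 = perpendicular.
- **Hydrogen bonds** — geometric criteria, donor–acceptor distance
  ≤ 0.35 nm and donor–hydrogen–acceptor angle ≥ 135° (both inclusive).
- **Interdigitation** — leaflet mass overlap
  `λ = ∫4ρ_u ρ_l dz / ∫(ρ_u + ρ_l)² dz ∈ [0, 1]`.
- **Water penetration** — per-(x, y)-bin probability of observing a water
  in the hydrophobic center; the 0.31 nm bin is the cube holding one water
  at the bulk density 33.36 nm⁻³.

All lengths are nm, tensions and K_A mN/m, K_c Joule, temperatures Kelvin.

## Worked example

Generate a reference-like bilayer (100 lipids per leaflet at 0.49 nm² per
lipid, 35/35/30 POPC/POPE/CHOL, thickness 4 nm) together with an
equilibrium area ensemble generated at K_A = 457 mN/m, then analyze it:

```python
from memkit.cli_pipeline import validate_config, run_pipeline

cfg = validate_config({
    "seed": 7,
    "generate": {
        "n_lipids_per_leaflet": 100, "target_apl": 0.49,
        "target_thickness": 4.0, "n_frames": 4,
        "area_series": {"K_A_true": 457.0, "mean_area": 49.0,
                        "temperature": 310.0, "n": 100_000},
    },
}, out="run")
outputs = run_pipeline(cfg)
```

`run/structure.json` then contains

```json
{
 "area_per_lipid_box_nm2": 0.49,
 "area_per_lipid_voronoi_nm2": 0.4899999999999999,
 "cholesterol_tilt_mean_deg": 20.05,
 "cholesterol_tilt_sd_deg": 9.10,
 "interdigitation_overlap": 0.0,
 "thickness_nm": 4.0,
 "thickness_single_peak": false
}
```

and `run/mechanics.json` reports the fluctuation-route modulus

```json
"k_a_fluctuation": {"k_a_mN_m": 458.55, "stderr_mN_m": 2.40}
```

Reading the numbers: the box route (`Lx·Ly / 100`) and the periodic
Voronoi tessellation agree exactly at 0.49 nm², as the partition property
demands; the thickness estimator recovers the 4 nm phosphate-plane
separation; the cholesterol tilt spread (9.1°) matches the generator's 10°
draw within sampling error; and the fluctuation estimator recovers the
generative modulus 457 mN/m within its jackknife error.  The same
functionality is available from the shell via `memkit generate`,
`memkit analyze-structure`, `memkit analyze-interactions`,
`memkit analyze-mechanics` and `memkit report`.

To analyze existing files instead, point the config's `inputs` section at
a (multi-frame) GRO/PDB configuration, a topology YAML and scalar CSVs
(`time_ns,area_nm2,tension_mN_m,temperature_K`).

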