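# Methods

This note records the models, parameter choices and numerical decisions
behind `hemopk`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Kinetic model

A single well-stirred plasma compartment of volume `V` holds three state
variables, all in μmol/L heme (binding-site) equivalents: unbound Hb,
unbound Hp binding capacity, and the Hb:Hp complex.

```
d[Hb]/dt   = In_Hb(t)/V − k_on·[Hb]·[Hp] − k_el_free·[Hb]
d[Hp]/dt   = In_Hp(t)/V − k_on·[Hb]·[Hp]
d[HbHp]/dt = k_on·[Hb]·[Hp] − E([HbHp])
```

with `E(c) = k_el_complex·c` (first-order) or `vmax·c/(km + c)`
(Michaelis–Menten, a saturable macrophage route). A fourth state
accumulates eliminated heme so that mass balance can be asserted at any
time to integrator tolerance.

Assumptions, and why:

* **Binding is irreversible** (`k_off = 0`). Hb:Hp affinity is of
  femtomolar order — effectively covalent on the 60 h horizon — and the
  analysis chain never needs a dissociation term. One equation set serves
  dimeric and multimeric Hp, whose in-vivo kinetics are indistinguishable;
  the phenotype only changes the chromatographic forward model.
* **Hp is counted in binding-site equivalents**, so 1:1 heme
  stoichiometry collapses binding to a single bimolecular term. The
  gram→μmol conversion (62.06 μmol/g) is chosen so 4 g Hp binds exactly
  4 g Hb, matching the 1:1 gram dosing of the study design; it is
  configurable.
* **Unbound Hb leaves plasma by one lumped first-order process**
  (renal filtration plus extravasation). The large apparent Vc of unbound
  Hb is *not* modelled as a physical compartment; it emerges in the NCA
  because rapid binding caps the observable free Cmax far below dose/V.
* **Glucocorticoid (prednisone) pre-treatment is modelled solely as an
  elevated basal Hp pool.** The in-vivo data show no PK effect of the
  glucocorticoid beyond Hp availability, so no other parameter changes.
  Endogenous Hp synthesis and turnover are neglected over 60 h.
* **Noise** is multiplicative lognormal (mean-one), default CV 10%, a
  standard proportional-error model for chromatographic/spectral assays.
  Post-dose values below the LOQ (default 1 μmol/L) are reported missing,
  never zero; the t = 0 baseline is exactly zero for exogenous analytes.

### Reference parameter values

The seven-arm reference design (4 g Hb, ± 4 g Hp, ± prednisone) uses one
shared kinetic parameter set, calibrated once so the simulated groups
reproduce the magnitudes observed in the dog study (total-Hb Cmax
≈ 350 μmol/L; bound-complex Cmax ≈ 300–400 μmol/L, t½ ≈ 12 h, Vc near
plasma volume; unbound Cmax ≈ 20–80 μmol/L with sub-hour half-life):

| parameter | default | unit | rationale |
|---|---|---|---|
| `plasma_volume_L` | 0.6 | L | beagle ≈ 11 kg at ~55 ml plasma/kg |
| `basal_hp_uM` (untreated) | 150 | μmol/L eq | high constitutive dog Hp (≈ 2.4 g/L) |
| `basal_hp_uM` (prednisone) | 360 | μmol/L eq | strong acute-phase induction (≈ 5.8 g/L) |
| `k_on` | 1.0 | L/(μmol·h) | fast capture: binding completes within minutes, as observed |
| `k_el_free` | 2.0 | 1/h | unbound disappearance t½ ≈ 20 min |
| `k_el_complex` | 0.058 | 1/h | complex terminal t½ = ln2/k ≈ 12 h |
| `vmax`, `km` | 30, 50 | μmol/(L·h), μmol/L | saturable-mode alternative; at Cmax ≫ km it yields the observed two-phase bound decay |
| `noise_cv`, `loq_uM` | 0.10, 1.0 | —, μmol/L | typical assay precision and quantification floor |

The 4 g Hb dose is 248.22 μmol heme (tetramer MW 64 458 g/mol, 4 hemes),
both constants configurable.

A consequence of irreversible fast binding worth stating: in arms where
total Hp (basal + infused) exceeds the heme dose, unbound Hb falls below
the LOQ within one or two samples of the Hp infusion, so unbound NCA
parameters are estimable only in the near-stoichiometric (prednisone,
no-exogenous-Hp) arms. This mirrors the real study, where the fully
Hp-covered arm reported no measurable unbound Hb at all; the intermediate
persistence of unbound Hb seen in some in-vivo arms (half-lives up to
~1 h) likely reflects binding heterogeneity that a single bimolecular
constant cannot reproduce, and is emulated only qualitatively.

What passing simulator-based tests do **not** show: fidelity to any real
dog's physiology (no organ compartments, no allometry, no Hp turnover),
nor the mechanistic cause of the two-phase bound decay — the saturable
clearance mode is one admissible mechanism, not a claim.

## Measurement chain

**Spectral speciation.** Blank correction subtracts the interpolated
pre-dose plasma spectrum pointwise (small negatives from noise pass
through). Speciation solves `A(λ) = Σ_s ε_s(λ)·c_s·path` by non-negative
least squares over a 500–650 nm window — the Q-band region that
distinguishes ferrous, ferric and hemichrome heme. Non-negativity is
imposed because negative concentrations are unphysical. The packaged
extinction table is **synthetic**: smooth Gaussian-mixture curves anchored
at literature single-wavelength millimolar coefficients of each species
(oxy 542/577 nm, aquo-met 500/630 nm, hemichrome 535/565 nm) on a 1 nm
grid over 450–700 nm. Every property the package relies on
(forward/inverse round trip, scaling equivariance, window behaviour) is
invariant to the exact curve shapes; a laboratory table can be swapped in
from CSV. A four-species mode (oxy and deoxy separated) is selectable.
The fit rejects windows where the extinction matrix condition number
exceeds 1e8.

**SEC partition.** Peaks are integrated inside fixed windows with a
linear baseline connecting the window endpoints; negative net areas clip
to zero. Retention structure of the forward model: free Hb 20.7 min;
dog complex 17.7 min; human dimeric complex 17.2 min (0.5 min earlier);
human multimeric complex an equal-weight pair at 14.7/15.1 min with wider
peaks (σ 0.55 vs 0.25 min). Default windows: free 19.7–21.7 min; bound
16.2–18.7 min (dog/dimeric); bound 12.0–17.0 min (multimeric) — the
multimeric window extends to 17 min, past the nominal 12–16 band, so the
broad components' right tail is fully integrated; with the window cut at
16 the endpoint-baseline correction alone would bias the free fraction by
more than half a percentage point. Window edges are configurable. Free
and complexed heme are assigned the same molar A405 response, which the
percent formulas implicitly assume. The partition multiplies percent free
by spectral total heme, so free + bound equals the total by construction
(one floating-point rounding).

## Non-compartmental analysis

* **Terminal-point selection** is a best-adjusted-r² search over the last
  3–8 quantifiable points (ties toward more points), the standard
  automated λz rule; a fixed point count can be forced. Rising terminal
  data are flagged, not extrapolated.
* **t½ = ln2·Vc/CL** (equivalently ln2·AUC₀₋∞/Cmax) is the primary
  half-life, honouring the study's reporting convention; the conventional
  ln2/k is carried as a diagnostic. The two coincide only for a true
  mono-exponential profile.
* Below-LOQ values are missing for both Clast and the slope; leading
  zeros at t = 0 are retained for the AUC; gaps are spanned by a single
  trapezoid.
* Group tables report mean ± SEM (sd/√n, ddof = 1); with n = 1 the SEM is
  missing. Note that a mean of per-subject ratios (e.g. mean CLᵢ) is not
  the ratio of means — the package aggregates per-subject parameters, as
  the study did.
* Known discretization bias, quantified by the recovery tests: on the
  22-point schedule a k = 0.2/h profile carries ≈ 1.5% trapezoidal AUC
  overestimate (hence CL low by the same) and ≈ 3% Cmax underestimate
  from the unsampled end-of-infusion peak (hence Vc high); both are
  inherent to the schedule, not estimation errors.

## Endocytosis quantification

Segmentation is intentionally minimal and auditable: Otsu global
threshold on the nuclear channel → connected components → area filter
(30–1000 px at the synthetic scale). Touching nuclei are not split; the
generator guarantees separation and clumped real data are out of scope.
The cell region is the nucleus expanded radially by 8 px (configurable),
capturing the perinuclear compartment where internalized complex
accumulates; the per-cell statistic is the mean green intensity over that
region minus a scalar per-experiment background (estimated from no-probe
control samples over their segmented cell regions), floored at zero.

The synthetic generator places non-overlapping disk nuclei and paints
each cell's probe signal into the perinuclear ring, scaling the ring
amplitude so that the *region mean* equals the recorded true per-cell
intensity — making generator truth and pipeline measurand identical by
construction. It emulates separated, evenly illuminated, single-plane
fields; it does not emulate cell clumping, illumination gradients,
z-stacks or photobleaching, so passing tests certify the measurement
arithmetic, not robustness to those artifacts.

## Pipeline and reproducibility

All randomness flows from explicit integer seeds: study seed → per-subject
seeds (seed + index); the CLI and `run_study` re-seed arms with spaced
offsets. Stiff integration uses BDF with rtol 1e-8 / atol 1e-12, split at
infusion switch times so no discontinuity is stepped over; schedule values
are read off a dense solution grid (≥ 40 points/h). Simulated
concentrations are clipped at zero before noise. The full-chain vs bypass
comparison (NCA on measured vs simulated concentrations, noiseless) is the
standing guard against measurement-stage bias; censoring is disabled there
because a sample exactly at the LOQ could otherwise flip between paths.
Study outputs are flat CSVs plus a JSON manifest (config hash, seed,
version, paths, timestamps).

Problem sizes used by the shipped tests and the acceptance script — six
subjects per simulated arm (four in the total-heme arms), 100 synthetic
image fields, 1000 random profiles for the oracle checks — match the
study's group sizes where applicable and keep every run deterministic.

## Known limitations

* No physiologically-based distribution, species scaling, or Hp
  glycosylation/phenotype biochemistry; prednisone dose–response is not
  modelled (only its endpoint, the raised Hp pool).
* The λz selection rule is a reasonable default, not a bit-for-bit
  reproduction of any commercial NCA tool.
* Overlapping SEC peaks are not deconvolved; window integration assumes
  the phenotype's peaks stay inside their windows.
* The extinction table is a synthetic stand-in (above); absolute
  speciation accuracy on real spectra depends on supplying measured
  coefficients.
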