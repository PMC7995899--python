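# Methods

## The kinetic model

Iodine biokinetics are modelled as a linear, first-order compartment system.
The shipped systemic model has 30 compartments and 48 nonzero transfer
coefficients (day⁻¹): the alimentary tract (oral cavity, fast/slow
oesophagus, stomach, small intestine and its wall, three colon segments),
blood iodide and blood organic iodine, the thyroid iodide and organic
pools, salivary glands and stomach wall (secretion loops back into the
gut), kidneys (a urinary-path pool and an organic pool), liver (iodide and
organic), distributed "other tissue" iodide and organic pools of different
turnover, red-cell iodide, the urinary bladder content, and urine and
faeces sinks. Oral administration starts in the oral cavity; intravenous
administration starts in blood iodide.

Radioactive decay couples chain members (parent → progeny at
branching × λ_parent, in nuclei units) into a block lower-triangular system
dy/dt = M y. Progeny without a registered model of their own occupy the same
compartments and transfer with the parent's coefficients — a deliberate
simplification, adequate because the only progeny of dosimetric interest
here (Xe-131m, 1.18% branch) contributes under one percent of thyroid dose;
the interface accepts progeny-specific models. Chains truncate at a 15-min
half-life by default: shorter-lived members are taken to decay where they
are created.

### Provenance of the coefficient set

The four thyroid transfer coefficients and the model's topology follow the
published systemic iodine model description; alimentary-tract transit rates
are the standard adult values (stomach 20.57 d⁻¹, small intestine 6 d⁻¹,
colon segments 2 d⁻¹, fractional absorption 0.99, bladder voiding 12 d⁻¹).
The remaining systemic rates could not be transcribed verbatim and are a
physiologically motivated reconstruction, which is why the data file is
named `icrp_iodine_adult_synthetic.tsv`. Two calibrations were performed
once, as part of constructing the data file, and never revisited:

* the renal clearance of blood iodide was root-found to 12.008 d⁻¹
  (physiological range) so the normal variant reproduces the documented 26%
  24-h oral thyroid uptake of I-131;
* the low/high variants' blood→thyroid coefficients were root-found to
  3.912 and 11.905 d⁻¹ for their documented 16% and 36% 24-h uptakes (the
  variants differ from normal *only* in this coefficient).

The patient-refit ratios the acceptance script reports (thyroid-TIAC ratio
1.447, whole-body-decay ratio 1.867) were **not** calibration targets; they
emerge from the reconstructed physiology. The blocked-thyroid variant is
derived at build time by zeroing organification rather than stored, since
it differs from normal in that single coefficient.

## Solver

The solution uses `scipy`'s scaling-and-squaring matrix exponential, one
propagator per distinct time step, rather than eigendecomposition: the
biokinetic matrices are stiff (rates from 0.0077 to ~12 000 d⁻¹) and
near-defective (measured eigenvector condition numbers ~1e16). Activities
are reported as fractions of administered activity; solver round-off below
−1e-9 raises a warning, and small negatives are clamped to zero.
Time-integrated activity coefficients are computed analytically from
−M x = y₀ (x is the integral of the state to infinity) and reported in
hours; a trapezoid-quadrature cross-check on a dense grid is part of the
test suite (agreement to 1e-4 relative). A decay-free "stable tracer" mode
exists for conservation testing; its time integrals diverge and requesting
them raises a diagnostic pointing at decay.

Internal time unit: days (matching day⁻¹ coefficients). User-facing times
and TIACs: hours (TIACs print as MBq·h/MBq). The conversion lives in one
module (`iodose.units`).

## Fitting

The cost is the unweighted sum of squared residuals in fraction space
between model RIU(tᵢ) and the measured points (1/σ² weighting is opt-in).
Free parameters are any subset of the four thyroid coefficients — only the
two inorganic ones when the thyroid is blocked — with default bounds
[1e-3, 1e3] day⁻¹, generously covering the reference range 0.0077–95.

Optimisation is multi-start bounded least squares in log10-parameter space:
the normal/low/high reference sets first, then seeded log-uniform draws
(default 8 starts, deterministic per seed). Each start runs a conditioning
pre-stage on *relative* residuals — without it the optimiser stalls on
near-zero uptake curves where absolute residuals are flat — followed by a
polish on the reported absolute-residual objective. A start that exhausts
its evaluation budget with an essentially exact fit counts as converged;
only starts that error out or go non-finite are failures, and a fit
error is raised only if every start fails.

Identifiability: a noise-free four-point schedule pins the RIU curve but
not all four coefficients (the landscape has an exact ridge). The thyroid
TIAC is the identified, reported headline — the recovery studies in the
test suite show TIAC recovery within 2% for ≥95% of log-uniform coefficient
draws (noise-free) and a cohort bias under 5% at 5% multiplicative noise
(200 replicates). One-point fits are permitted with a logged warning, a
late (~4 day) point being the most informative choice.

## Synthetic patients

`generate_synthetic_patient` emulates the clinical pre-therapeutic
protocol: 3–4 probe measurements between a few hours and ~8 days (the
recovery studies use 5, 24, 48 and 120 h; the worked example uses
3, 24, 48, 120 h), with multiplicative Gaussian noise
riu·(1 + ε), ε ~ N(0, cv²), clamped to [0, 1]; cv = 0.05 is the default
noise level for studies, representative of probe counting and positioning
reproducibility. What it does *not* emulate: systematic calibration bias
between time points, patient motion/geometry changes, background and
scatter corrections, or inter-patient variation in the non-thyroid
physiology (the reconstruction's fixed rates). Passing recovery tests
therefore demonstrate statistical identifiability under the stated noise
model, not robustness to structural model error.

## Dosimetry

S values are consumed in mGy/(MBq·h) so absorbed dose is literally
TIAC × S summed over sources and chain members; a units declaration is
required in the table header and mismatches are rejected. The shipped
`svalues_i131_synthetic.csv` is a synthetic fixture (self-dose particle
terms = mean electron energy per decay over reference organ mass; photon
cross terms from assumed absorbed fractions); it exercises the pipeline and
is not phantom Monte-Carlo output. `compose_s_value` builds S rows from an
emission spectrum and a SAF grid with interpolation linear in log-energy;
emission energies outside the grid raise rather than clamp.

Mass correction of thyroid self-irradiation scales photons by
(M_ref/M_pat)^⅔ and particles by M_ref/M_pat from the reference 23.4 g
(male) / 19.5 g (female); it applies only to self-dose rows and is exact
at the reference mass.

Effective dose uses the standard tissue weighting factors (thyroid 0.04,
weights summing to 1); remainder tissues enter as the arithmetic mean of
the available remainder organs; missing organs contribute zero with a
warning. The thyroid-zeroed variant removes the thyroid term without
renormalising — so E(w_thyroid=0) = E − 0.04·(sex-averaged thyroid dose)
identically. Radiation weights are 1 for photons and electrons, kept
explicit should other emission classes ever be added.

The activity prescription A_a = D·M/(Ē·∫RIU dt) is the only dimensionally
coherent reading of the pre-therapeutic formula; units are enforced (Gy,
kg, J, hours→seconds, result MBq). The default Ē for I-131 is the electron
(beta + conversion) energy per decay from the registry, 3.18e-14 J
(~0.198 MeV); photons mostly escape a thyroid-sized volume.

## Nuclide data

The registry ships I-131 (with Xe-131m), I-123, I-124 and I-125 with
half-lives, branchings and *condensed* emission spectra (aggregated lines)
transcribed from standard decay-data compilations — adequate for the Ē
constant and fixture dosimetry, not for spectroscopy. The delimited-text
format is documented in the file header so users can register further
isotopes.

## Known limitations

* The systemic coefficient file is a labelled reconstruction, not a
  verbatim transcription; absolute non-thyroid TIACs inherit its
  uncertainty even though the thyroid behaviour is pinned by calibration
  and by the patient fit.
* Only the adult model ships; other age classes raise a clean error and
  can be supplied as model files.
* No Bayesian uncertainty on fitted coefficients; the multi-start spread
  is diagnostic only.
* Progeny share the parent's kinetics unless a progeny model is supplied;
  fine for Xe-131m, wrong for chemically dissimilar progeny of other
  iodine isotopes.
* The fixture S table covers five target organs and two nuclides; effective
  doses computed from it are pipeline demonstrations, not risk estimates.
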