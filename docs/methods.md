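# Methods

## The measurement model

2-picolylamine (2PA, C₆H₈N₂) condenses with a carboxyl group to an
amide, losing one water.  The derivative's protonated precursor is
therefore

    m/z(precursor) = M(analyte) + M(tag) − M(H₂O) + m(H⁺)
                   = M(analyte) + 91.0655 Da   (light channel)

with monoisotopic masses throughout (the atomic mass table is pinned in
`chem.py`; D = 2.0141018 Da).  The heavy tag 2PA-d6 carries six
carbon-bound deuteriums (the exchangeable amine hydrogens stay light),
shifting the precursor by 6 × (m(D) − m(H)) = 6.0377 Da.  Precursors
are reported at one decimal with half-away-from-zero rounding, the
convention of printed method tables; full precision is kept internally.

Amide cleavage under collision-induced dissociation releases the
picolylamine fragment with the charge: *m/z* 109 ([2PA+H]⁺) for light,
115 ([2PA-d6+H]⁺) for heavy derivatives.  Analytes deuterated on the
carbons α to the carboxyl (the d5/d7 internal standards) transfer a
deuteron instead, raising the fragment one mass unit (*m/z* 110 on the
light channel).  The trigger is modeled simply as
`deuterium_count > 0`, which is exact for the bundled standards; the
same deuteron rule is applied on the heavy channel for symmetry,
although no bundled analyte exercises it.

Several rows of the published method table cannot be reproduced by any
single mass convention (they differ from the monoisotopic value by
0.1–0.2, e.g. lauric printed 291.1 vs computed 291.2, oleic 373.1 vs
373.3, and the bile-acid block); these are treated as transcription
errors.  The test suite asserts only the arithmetically consistent
subset and the two exact structural invariants (the 6.0377 Da channel
spacing and the 91.0655 Da derivatization offset, both to ±0.001 Da).

## What the simulator emulates — and what it does not

Each transition yields a trace on a 0.5 s grid spanning the expected
retention time ± 2.5 retention windows (flanks are needed for baseline
estimation).  A trace is

    intensity(t) = baseline + amount · R · b · ε · shape(t) · s(t) + noise(t)

* `shape` — unit-area Gaussian (σ = 3 s default) or exponentially
  modified Gaussian for tailing peaks; published chromatograms show but
  do not parameterize peak shapes, so σ is a free, per-analyte
  overridable default.
* `R` — response factor, 10⁴ integrated counts per amount unit, giving
  apex S/N ≈ 650 at defaults (a comfortably quantifiable channel).
* `b` — heavy-channel isotope-effect bias, lognormal around 1 with
  σ = 0.05, fixed per analyte and seed.  Measured 1:1 ratios deviate
  from 1 by up to tens of percent in practice without a stated
  magnitude; 5% reproduces that scale of deviation.
* `ε` — optional per-trace multiplicative response noise (`area_cv`),
  off by default for differential runs and 5% for calibration runs,
  representing level-to-level preparation variability.
* `s(t)` — ion suppression, shared by all channels at the same instant:
  2–5 Gaussian matrix bands of width 60–120 s (the chromatographic
  timescale of co-eluting matrix components — much slower than the 3 s
  analyte peaks), normalized and scaled to a random depth of at most
  0.6, so the factor stays within (0.4, 1].  The smoothness is what
  makes the heavy/light ratio matrix-insensitive even with the 0.3 s
  heavy retention shift: the residual ratio error is bounded by
  |d ln s/dt| × 0.3 s ≲ 1%.  The detector baseline (10 counts) is not
  suppressed.
* `noise` — additive white Gaussian (2 counts), plus an optional slow
  sinusoidal baseline drift (off by default).
* heavy retention shift — 0.3 s by default: derivative pairs co-elute
  almost exactly, and the small nonzero value exercises the pairing
  tolerance.

Every draw comes from a sub-stream seeded by (config seed, stable
string key), so outputs are bit-reproducible and independent of
generation order.

The 4-group × 3-matrix study simulates *pooled* samples per group
(group sizes N = 4/4/3/5 are carried as metadata) measured as technical
triplicates against the SPF reference channel — pooling removes
biological variance by construction, matching the pooled-sample design
the workflow targets.  The bundled template configures the qualitative
biology of a germ-free × renal-failure experiment (microbiota-dependent
bile acids absent in germ-free plasma, SCFAs and secondary bile acids
absent in germ-free feces, intestinal fatty acids and
indole-3-acetic acid reduced, glycine conjugates elevated without
bacterial deconjugation), with every configured effect at ≥ 1.5-fold so
it is resolvable at triplicate precision.  Not modeled: full-scan
spectra, isotope envelopes beyond the single 6 Da shift, chimeric
transitions, carryover, injection-order drift, and per-animal
biological variance.  Passing tests therefore demonstrate the
correctness of the measurement chain under these idealized conditions,
not instrument-level robustness.

## Peak processing choices

Vendor auto-integration parameters are unknowable, so the module fixes
a fully specified algorithm: Savitzky–Golay (order 2, 7 points)
smoothing for apex/bound finding only; baseline and noise from the
flanks outside the retention window as median and 1.4826 × MAD;
trapezoidal integration of the *raw* baseline-subtracted signal;
detection at S/N ≥ 3 (a module convention for ND, not an instrument
rule).  Integration bounds are where the smoothed signal falls to 1%
of the apex height (or the window edge).  A 5% cutoff — the other
common convention — truncates 1.44% of a Gaussian's area at ±2.45σ and
cannot meet a 1% single-channel accuracy target; the 1% cutoff
(±3.03σ) loses only 0.24%.  The threshold is a parameter
(`bound_fraction`) for users who prefer the wider convention.  Ratios
are computed from areas, not heights, and co-eluting pairs are
truncated identically, so the ratio is insensitive to the cutoff.
Pairing tolerance defaults to 0.1 min.

## Quantification conventions

* Calibration: weighted least squares of response ratio (analyte
  area / internal-standard area) on concentration with weights 1/x —
  the standard choice when response variance grows with concentration —
  or unweighted on request.  1/x², sometimes seen elsewhere, is not
  offered.  The reported r is the unweighted Pearson correlation of the
  level data.  Any ≥ 2 distinct levels fit; curves below 5 levels are
  flagged non-reportable.  Default series use 7 levels across two
  decades; 9-level series are equally supported.
* Sample SD uses the n−1 denominator throughout.
* Accuracy (RE) is the spiked-recovery form
  ((found − endogenous)/spiked − 1) × 100; precision (RSD) is
  100 × SD/mean.  Both are scale-invariant where defined.
* Group ratios come in two routes that must agree: the ratio of mean
  absolute concentrations (with group SDs propagated in quadrature on
  the relative scale) and the mean heavy/light ratio of a pooled
  differential run.  In the noiseless limit both reduce to the amount
  ratio and coincide exactly; the acceptance suite verifies this
  identity and their agreement under 5% noise.

## Differential layer

Two-sided pooled-variance Student's t-tests on technical triplicates;
zero pooled variance is handled by convention (p = 1 for equal means,
p = 0 otherwise, flagged degenerate).  Stars follow the strict
thresholds p < 0.05/0.01/0.001.  No multiple-testing correction is
applied in the primary columns — the comparison layer mirrors
per-analyte testing practice — but a Benjamini–Hochberg q-value column
is appended as clearly supplementary output.  Non-detected cells are
never imputed as zero: they are excluded from testing and routed to
explicit fold-change statuses (`absent-in-b`, `emergent-in-b`,
`absent-both`).  Pathway classification is a deterministic registry:
cholic and chenodeoxycholic acid are host primary bile acids, the
remaining unconjugated panel bile acids are microbiota-transformed
secondary species, glycine conjugates are host conjugation products,
SCFAs and indole-3-acetic acid are microbial products, and long-chain
fatty acids are classified by chain class with mixed origin (host
synthesis modulated by microbial desaturation/elongation).

## Numerical and I/O notes

* Time is seconds internally, minutes at I/O boundaries (method tables
  and mzML print minutes).
* mzML chromatogram lists are written with lxml (64-bit uncompressed
  arrays, id = `"<analyte>|<channel>"`) and read by a namespace-aware
  reader that also accepts 32-bit and zlib-compressed arrays and
  second-valued time axes.  The CSV dialect
  (`transition_id,time_s,intensity`) stores `repr` floats, so its
  round trip is bit-exact.
* Detection applies a 10⁻⁶-relative height floor so float residue from
  the smoother on flat traces can never register as a peak.
* Problem sizes in the test and acceptance suites (50-seed ratio sweep,
  200-seed calibration sweep, 120 suppression profiles, one full
  4 × 3 × 40 study) were chosen so the whole battery completes in well
  under a minute while keeping Monte-Carlo pass criteria comfortably
  away from their thresholds.

## Known limitations

* Retention times are fixture data; nothing is predicted from
  structure, and isomer pairs are distinguished only by their
  configured retention times.
* The isotope-effect bias is a static per-analyte response factor; real
  deuterium effects also shift retention slightly, which is only
  captured as the constant 0.3 s channel offset.
* The ND rule (S/N ≥ 3) is a convention; published non-detects may
  reflect different vendor criteria.
* Collision energies and S-lens voltages are pass-through metadata,
  never computed.
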