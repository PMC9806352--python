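# Methods

## The quantification model

vespaquant quantifies a venom proteome from gel-band-resolved label-free
mass-spectrometry data.  The measurement model has two levels:

1. **Within a band**, the spectral AUC of a protein is proportional to its
   share of the band's protein mass (up to multiplicative noise).  AUCs
   from different bands are not comparable because each band is a separate
   digestion and injection.
2. **Across bands**, the densitometric area of a band in the stained lane
   is proportional to the band's share of the total loaded protein.

The composition estimate multiplies the within-band AUC fraction of each
protein by its band's densitometric proportion and sums over bands:

    percent(X) = 100 · Σₙ fracₙ(X) · pₙ,   fracₙ(X) = AUCₙ(X) / Σ_toxins AUCₙ

Both fractions are closed (sum to one per band; proportions sum to one
over analysed bands), so the output sums to 100% exactly whenever every
analysed band contains at least one toxin identification.  Non-toxin and
contaminant identifications are excluded from numerator *and*
denominator: the composition is of the toxin proteome.

Assumptions worth stating: staining response is linear in protein mass
and uniform across proteins; AUC response within a band is linear in
mass share; the excised bands capture the quantifiable venom (proportions
are normalised over analysed bands only, not the whole lane — the
convention under which published compositions total ≈100%).

## Quality filtering

Identifications are retained when score ≥ `min_score` (default 50 on the
−10·log₁₀ p scale), unique peptides ≥ `min_unique_peptides` (default 1),
and the accession is not a contaminant (exact accessions or prefixes such
as `CRAP_`; decoys use `DECOY_`).  Thresholds are inclusive.  The search
FDR (0.1% regime) is an upstream search-engine setting, not an export
column; a standard target-decoy estimator is provided so the regime can
be verified on simulated data carrying planted decoys.  The unique-peptide
rule is applied per band: each band's identification stands alone.

## Densitometry

Bands are half-open intervals `[start, end)` on the migration axis, so
adjacent bands partition cleanly.  Baseline correction subtracts a
valley-to-valley straight line through the profile values at the band
edges (the simplest defensible default for stained gel lanes; clipped at
zero).  Areas are trapezoidal integrals — exact for the piecewise-linear
signal a sampled profile represents, hence invariant under refinement of
the sampling grid.  Users who quantified bands in external gel software
can supply a band-area table instead of a profile.

## Transcriptome side and the translation index

Counts are converted to TPM, `tpm_i = 10⁶·(cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ)` with ℓ the
effective length; family percentages are computed over toxin-annotated
transcripts only, mirroring the proteome's "all toxin hits" denominator
so the two percentage scales are directly comparable.  The translation
index of a family is proteome % / transcriptome %; it is undefined
(flagged, NaN) when the family has zero transcriptome share.

**Compositional closure.** Because both sides are forced to total 100%,
planting a translation efficiency τ_f in the generator yields a realised
index of τ_f · Σ_g π_g/τ_g, not τ_f itself: boosting one family's
efficiency deflates every family's transcriptome share through the common
denominator.  The two coincide as the perturbed families' total proteome
share approaches zero.  This is a property of ratios of closed
compositions, not an implementation artefact, and it caps how literally
any index value should be read when the perturbed family is abundant.

## Assay arithmetic

* **Turbidity reduction units**: one TRU ≡ a 50% turbidity reduction,
  prorated linearly (reduction% / 50); activity = TRU / (mg · min).  The
  prorating convention is ours — the unit definition fixes only the 50%
  point — and is recorded in output metadata.  Sample turbidity above
  control reports zero activity with a warning.
* **Standard-curve specific activity**: ordinary least squares of
  absorbance on analyte nmol over all provided points; inversion gives
  nmol = (A − intercept)/slope, activity in nmol·mg⁻¹·min⁻¹.
  Extrapolation beyond the fitted range is permitted but warned about,
  as are negative inferred amounts.  Activities are reported per mg.
* **Relative haemolysis**: percent of the detergent positive control
  (100% lysis), blank-corrected by default (uncorrected mode via flag);
  not clipped, so super-control values remain visible.
* **Clotting delay**: absolute delay and fold change against control
  plasma; wells with no clot inside the instrument window are treated as
  right-censored at the window limit, and delay/fold are reported as
  lower bounds.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs from
one `SyntheticTruth`:

* **Composition.** Default: a 14-family hornet-venom-like toxin proteome
  (CAP 26.1%, PLA1 21.9%, trypsin 19.0%, hyaluronidase 15.2%, …), two
  proteins per family (28 toxin proteins in 14 groups, the granularity of
  a typical hornet venom proteome).  Family shares are split among
  members by a Dirichlet(2) draw.
* **Migration.** Molecular weights are log-uniform on 10–100 kDa; lane
  position is linear in log₁₀(MW), descending, as on an SDS-PAGE gel
  (constants are configuration, not science).  Each protein contributes a
  Gaussian peak (SD 1 lane unit) whose area is its mass share; peaks
  closer than four widths share a band, and band edges extend 3.5 widths
  or to the gap midpoint.  Both the sampled profile and the analytic band
  areas are emitted; the analytic route is exact, while profile
  integration loses tail mass across the edges of closely spaced bands
  (percent-level leakage when gaps fall below ~7 peak widths) — a
  faithful rendition of why densitometry of overlapping bands is hard.
* **Noise.** Spectral AUCs and per-transcript TPMs carry multiplicative
  log-normal noise with log-SD `noise_sd_log` (default 0.2, a typical
  between-band variation for label-free intensities).  True-hit scores
  are drawn from N(85, 8), decoys from N(25, 10) (both floored at zero),
  so true hits overwhelmingly pass the default filters and decoys
  overwhelmingly fail; the separation is configurable.  The count of
  hits passing the default thresholds is recorded at generation time,
  independently of the filtering module.
* **Transcriptome.** Family TPM ∝ π_f/τ_f with default efficiencies
  τ = 9 (CAP), 3 (DPP), 2 (hyaluronidase), 0.85 (PLA1), 1 elsewhere —
  the qualitative over-/under-translation pattern of vespid venom glands
  — four transcripts per family, plus ten non-toxin (housekeeping)
  transcripts absorbing 35% of total TPM, standing in for the abundant
  physiological transcripts (e.g. arginine kinase) that never appear in
  the venom.  Expected counts are back-computed from TPM at a 20 M read
  depth, so TPM recomputation from counts is self-consistent.

All randomness flows from one `numpy` generator seeded by the truth's
single seed, with a fixed draw order, so a truth regenerates its dataset
byte-identically.

What the generator does **not** emulate: peptide-level effects (missed
cleavages, ionisation bias), protein-dependent stain response, band
smiling/curvature, chimeric or mis-assembled transcripts, and biological
replicate variation.  Passing recovery tests therefore demonstrate the
pipeline's correctness under the stated measurement model, not
robustness to those real-data pathologies.

## Numerical choices

* Percentages are kept at full double precision internally; display
  rounds to two decimals with no post-rounding renormalisation (a printed
  table may total 100.01).
* Compensated summation (`math.fsum`) is used for totals and
  conservation checks.
* Zero-toxin bands (positive proportion, no surviving toxin hit) follow a
  policy: `renormalise` (default — proportions rescaled over toxin-bearing
  bands, keeping the total at 100%) or `error` for auditing.
* Degenerate inputs (all-zero lane, zero total AUC in a band, no toxin
  transcripts, zero-slope standard curve) raise dedicated errors rather
  than returning NaNs; the CLI maps format/validation errors to exit
  code 2 and policy/degenerate-data errors to 3.
* Duplicate (band, accession) rows in search exports are merged by
  summing AUC (protein-group splits), keeping the maximum score and
  unique-peptide count.

## Problem sizes

The test suite and acceptance checks run on datasets of 12–14 families ×
2 proteins (≈60 spectral hits, ≈8 bands, ≈66 transcripts), with 20-seed
replication for recovery statistics and 200 random micro-instances for
the brute-force oracle comparison — sizes at which every check completes
in seconds while exercising all code paths.
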