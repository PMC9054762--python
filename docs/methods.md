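# Methods

## Scope and model

The package quantifies helix-forming polyalanine stretches inside
intrinsically disordered regions (IDRs) and supports the two companion
analyses used when comparing disordered paralogs: amino-acid composition
differences, and NMR secondary-chemical-shift helicity. External predictors
(disorder, helix propensity, prion-likeness, shift-based structure
populations) are *inputs*, consumed as plain tabular tracks; the package
never recomputes them.

### IDR segmentation

A disorder track (one value in [0, 1] per residue) is binarized at a cutoff
(default 0.5, **inclusive**: value ≥ cutoff is disordered). IDRs are the
maximal disordered runs **strictly longer** than `min_length` (default 40,
so 41 residues is the minimal passing case). Runs separated by even a
single ordered residue are not merged. Both boundary conventions are
configuration: the cutoff because pre-binarized 0/1 tracks should pass
through unchanged, the strict length bound because "longer than 40" is read
literally, with the inclusive reading one flag away.

### Stretch scoring

Scores come from a versioned per-amino-acid table with non-negative
weights. The shipped default (`data/polyala_scores.yaml`, version 1.0) sets
A = 0.5 and gives the other helix-promoting residues M = 0.3, L = 0.3,
Q = 0.2; everything else is 0. These are tentative propensity weights, not
fitted constants — every test constructs its own explicit table, so no
result in the test suite depends on the default's values.

A *stretch* is a maximal run of residues with positive weight; its score is
the plain sum of weights, and the per-IDR scalar is the maximum stretch
score (0 if none). Two consequences define the measure's behavior:

* the score grows linearly with homorepeat length, so an 8-alanine tract
  at weight 0.5 scores 4.0;
* any zero-weighted residue breaks the run, so the same tract interrupted
  at its middle scores 2.0 — continuity matters, not just composition.

Because weights are non-negative and zero residues terminate windows, the
maximum stretch sum equals the maximum over all contiguous windows of
positively weighted residues; the test suite checks this equivalence
against an O(n²) all-windows oracle. Non-canonical letters (X, B, Z, U)
weigh 0 and therefore act as breakers — conservative, since they are
unscorable.

An alternative aggregation (e.g. length-normalized) can be swapped in by
replacing `max_polyala_score`; nothing else reads stretch internals.

### Helix elements

Independently of scoring, an IDR "contains an α-helical element" when some
run of at least `min_run` = 5 consecutive residues has predicted helix
propensity **strictly above** 0.8 (of 1.0). Both the strictness and the
constants are configuration (`HelixElementConfig`).

### Prevalence and the resampling null

Prevalence is the fraction of IDRs whose score is **strictly greater** than
each threshold (defaults 1.5, 2.0, 2.5) or that contain a helix element.
Denominators are IDR counts; a protein-level variant
(`protein_prevalence_statistic`) counts proteins owning at least one
passing IDR, since resampling draws proteins, not IDRs. An empty IDR set
yields flagged-undefined fractions (None), never silent zeros.

The null draws k = 100 subsets of `subset_size` proteins from the reference
population without replacement (independently across draws), pools each
subset's IDRs, and records the statistic. Mean and sample SD (k − 1
denominator) summarize the 100 draws. The default subset sizes 1542 and
689 are the sizes of the curated RNA-binding-protein census and its
mRNA-binding subset, the sets these nulls are meant to calibrate (the
census text also quotes 692 mRBPs; 689 is the size used for resampling and
is the default here). Observed sets are summarized as
(observed − mean)/SD plus the empirical quantile among the 100 draws; when
the null is degenerate (SD = 0) the displacement is reported as ±inf/0 with
an explicit flag. No p-value machinery beyond the quantile is attempted.

### Composition differences

Compositions are pooled over all sequences of a set; non-canonical letters
are counted separately and excluded from the 20-letter denominator.
Differences (fraction A − fraction B) are emitted with letters sorted from
most to least prion-promoting; the ordering is shipped as configuration
(`data/prion_order.yaml`, sourced from prion-domain enrichment statistics)
because it is used only for display, never computed from. A letter with
fewer than 10 occurrences in *either* set is masked (flagged, still
reported) — the conservative reading, since rarity in one set already makes
its difference unreliable.

### NMR secondary shifts

Secondary shifts are Δδ = δ_obs − δ_rc per backbone atom (H, N, Cα, Cβ,
C′) against a static random-coil table (`data/random_coil_shifts.tsv`,
literature-style values for disordered reference peptides at ~pH 6.5,
25 °C; glycine has no Cβ, proline no amide H). Correction schemes
(neighbor, temperature, pH) are deliberately not implemented — a corrected
table can be loaded through the same `RandomCoilTable.from_tsv` hook.
Missing assignments stay missing (NaN) end to end.

The helicity index ΔδCα − ΔδCβ cancels any constant carbon-referencing
offset exactly; the suite asserts this invariance to machine precision.
Variant-vs-wildtype differences are computed through an explicit
`VariantMap` built from the construct design (declared deleted ranges) —
never from alignment, because deletions are known exactly. Residues
immediately flanking a deletion are flagged `near_deletion`, since
truncation-site perturbations are expected and discounted. Amide
differences are reported separately as ΔδH and ΔδN; a combined CSP norm
exists as a convenience but feeds no analysis.

Fractional helix population is estimated as
p̂ = mean(ΔδCα − ΔδCβ over a window) / 3.3 ppm, where 3.3 = 2.8 − (−0.5)
is the full-helix amplitude of the packaged offsets (Cα +2.8, Cβ −0.5,
C′ +1.8, H −0.25, N −1.5 ppm). These amplitudes are configuration
(`FULL_HELIX_OFFSETS`) and are shared by the shift simulator, so recovery
tests are exact in the noiseless limit by construction. Construct ranking
sorts by mean index over a window, grouping constructs whose means differ
by less than a tolerance (default 0.05 ppm, roughly twice the propagated
noise of a 9-residue window at 0.02 ppm carbon noise) into equivalence
tiers.

## Synthetic data: what it emulates, what it does not

`gen_proteome` produces proteins of uniform random composition over the 20
canonical letters (uniform keeps planted-signal arithmetic exact; a
UniProt-like composition can be passed in principle by editing sequences,
but the generator itself stays uniform), each with probability
`idr_fraction` (default 1) of one IDR of 45–90 residues. Disordered
positions get values ~ U(0.6, 1.0) and ordered ones ~ U(0.0, 0.4), leaving
a margin around the 0.5 cutoff; an `adversarial` mode instead straddles the
cutoff for boundary testing. With probability `planted_stretch_rate`, an
8-alanine tract (configurable length) is written inside the IDR with
matching high helix-track values (U(0.85, 1.0)); with probability
`interruption_rate` its middle residue becomes a valine. The truth table
records every plant. Protein lengths default to U(120, 300) residues —
short of real proteome scale but long enough to hold the largest IDR.

Caveats a passing test does **not** speak to: real proteomes have biased
composition (more background alanines → more spurious short stretches),
multiple IDRs per protein, disorder scores correlated along the chain, and
predictor errors correlated with sequence content. The generator models
none of these; it validates the *statistics machinery* (segmentation,
scoring, resampling calibration, determinism), not predictor fidelity.
One visible consequence: background residues flanking a plant are
occasionally alanine, so a planted 8-tract can legitimately score above
4.0 — truth-table comparisons account for this.

`gen_shift_set` implements observed = random-coil + p·(full-helix offset)
inside the helical span + Gaussian noise per atom (defaults 0.05 ppm
carbons/nitrogen, 0.01 ppm protons), with optional random assignment
dropout. It is a one-population two-state model; real exchange-broadened
spectra, nearest-neighbor corrections and β/PPII contributions are out of
scope.

## Numerical choices

* All randomness flows through `numpy.random.default_rng(seed)`; same seed,
  same bytes. Resampling draws use one generator across the k draws.
* A null whose k draws all coincide reports SD exactly 0 (guarding the
  degenerate-flag logic against floating-point residue), and a zero-SD
  comparison reports displacement 0 when the observed value equals the null
  mean within `np.isclose`.
* Duplicate shift rows with equal values are tolerated; conflicting values
  are errors. Atoms outside the backbone five are skipped with a warning.
* Coordinates are 1-based inclusive at every interface; the segment TSV
  carries a header line stating the convention since BED-style files are
  usually 0-based half-open.

## Problem sizes

The calibration studies run on 10,000-protein synthetic proteomes with
k = 100 draws at subset sizes 1542 and 689, and helix-population recovery
uses 200 Monte-Carlo shift sets per planted population on a 23-residue
construct with a 9-residue helical span; oracle-equivalence checks use
1,000 random instances per primitive (500 in the acceptance script). These
sizes give standard errors comfortably below the tolerances asserted
(e.g. binomial SE ≈ 0.012 at π = 0.3, n = 1542) while the whole suite runs
in seconds.

## Known limitations

* The default score table's values are tentative by design; conclusions
  that depend on absolute score magnitudes (rather than threshold
  orderings) should re-derive weights for their own system.
* The prevalence machinery assumes IDR scores are exchangeable across
  proteins within a set; paralog families contribute correlated IDRs.
* The random-coil table ships without condition corrections; absolute Δδ
  values for real data at other pH/temperature will carry small offsets —
  the ΔδCα − ΔδCβ index and all difference profiles are insensitive to the
  constant part of such offsets, which is why they are the primary outputs.
* NMR-STAR support covers the minimal `_Atom_chem_shift` loop layout, not
  the full STAR grammar.
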