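# Methods

This note documents the models behind `cftrace`, the parameter defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Error model

Sequencing substitutions at the few-per-mille level are the dominant source
of non-reference signal at circulating-tumour-DNA allele fractions, so every
calling statistic conditions on an empirically estimated substitution model
rather than a nominal quality score. `estimate_confusion_matrix` tallies
observed vs reference base at every usable site of a sample's alignments and
row-normalises with an additive pseudocount (default 1) into per-quality-bin
4×4 matrices P(observed | true).

Choices:

- **Truth proxy.** The reference base, at sites outside a caller-supplied
  exclusion set (germline variants, candidate positions). Sites that look
  like unlisted variants are additionally skipped: a non-reference base on
  more than one read at allele fraction ≥ 0.2, or two or more distinct
  multiply-observed non-reference bases. The fraction cut keeps coincident
  double sequencing errors in the tally (skipping them would bias the
  estimate downward) while excluding real polymorphisms.
- **Read filtering.** Mapping quality ≥ 20; no duplicates, secondary or
  supplementary alignments; the 5 outermost aligned bases of each read are
  ignored (end-of-read artefact suppression).
- **Quality bins.** [0–19], [20–29], [30+]. Bins without observations carry
  no information and default to the error-free row.
- A zero-usable-site estimation raises instead of silently returning the
  pseudocount prior.

On simulated data with a uniform injected rate the estimate converges to the
injected matrix; the suite checks < 5% relative error on the total
off-diagonal mass at ~5×10⁶ tallied bases.

## Stage 1: candidate scan and scoring

A pileup column becomes a candidate iff a single alternate base not in the
germline genotype is carried by ≥ 3 high-quality reads, and total depth lies
within [0.25, 2] × the genome-wide median (columns outside the band are
ignored, never emitted). "High quality" means base quality ≥ 20, mapping
quality ≥ 20, primary non-duplicate alignment, > 5 bp from the read end.
At multi-allelic columns only the best-supported alternate is scored; the
condition is recorded as a `multiallelic` filter label.

Scoring per candidate (k alternate among n high-quality reads, error rate
*e* taken from the column's modal quality bin):

- **Frequentist:** exact upper binomial tail P(K ≥ k | n, e), computed via
  the regularised incomplete beta function (equal to the direct summation;
  the suite asserts equality against brute-force enumeration for all
  n ≤ 20). If e is below 10⁻⁶ the candidate is flagged
  `error-model-floor`, since the tail then reflects the pseudocount more
  than data.
- **Bayesian:** H0, all alternate reads are errors (per-read probability
  e_ref→alt); H1, a somatic allele at fraction f is present, per-read
  alternate probability f·(1−e_alt→ref) + (1−f)·e_ref→alt, f marginalised
  uniformly over the grid {0.01, …, 0.50}. Posterior odds combine the
  marginal likelihood ratio with a somatic prior of 10⁻⁴ per site — roughly
  an order of magnitude above the per-base burden of a heavily mutated
  cutaneous melanoma genome, deliberately permissive because stage 2
  provides an independent check. `f_hat` is the grid argmax of the H1
  likelihood.

Final calls require p ≤ 10⁻⁶ **and** posterior ≥ 0.95. With the default
error rate (0.1%) and ~100× depth these thresholds bind at k ≈ 4, slightly
above the 3-read candidate floor; at a 5% VAF and 100× this yields the
intended behaviour that WGS sits right at its detection limit, while a
tumour-free genome of 1.5×10⁵ sites yields zero calls (both are asserted in
the acceptance tests, with sensitivity ≥ 0.9 measured on the post-relapse
simulated composition whose ≥ 5%-VAF variants sit at 8–10%).

Coordinates are 1-based inclusive everywhere user-facing (VCF convention);
BED input is 0-based half-open; internal arrays are 0-based and never
serialised.

## Stage 2: haplotype verification

For each stage-1 call:

1. **Background haplotype.** Per-position majority consensus of the
   alternate-supporting *molecules* (both mates of an alternate-carrying
   fragment) over ± w = 30 bp; ties resolve to the reference base,
   uncovered positions fall back to the reference, the centre is forced to
   the alternate. Phased germline hets carried by the supporting reads are
   therefore retained in the haplotype.
2. **k-mer support.** The haplotype's variant-spanning 31-mers are
   canonicalised (min of k-mer and reverse complement), making verification
   strand symmetric. Support is the number of distinct molecules containing
   at least one spanning k-mer — molecules, not reads, so overlapping mates
   are not double-counted. Defaults: `min_support` 3 (mirrors the candidate
   floor), `germline_tolerance` 0.
3. **Local assembly.** A de Bruijn graph over the window reads (both
   orientations), nodes below abundance 2 dropped, unitigs read off
   deterministically from sorted node order. The variant-centred k-length
   core of the haplotype should appear in a contig (or intact in ≥ 2
   reads). A silent assembly condemns the candidate **only when support is
   ample** (≥ 2×`min_support`): with exactly 3 supporting molecules the
   graph often cannot tile the core at abundance 2 even for a perfectly
   consistent variant, and thin-but-consistent evidence is already vouched
   for by the spanning k-mers.
4. **Divergence guard.** The consensus of the supporting molecules is
   compared with the reference across their full insert span; positions
   where ≥ 2 concordant reads outvote the rest and disagree with the
   reference (excluding the candidate and known germline variants) count as
   background mismatches. ≥ 2 such mismatches ⇒ `assembly_artefact`. A true
   somatic SNV lies on a reference-like background; reads mismapped from a
   3%-diverged paralog carry ~5–10 divergent positions across a ~330 bp
   span and are flagged in 100/100 seeded replicates of the acceptance
   experiment. The molecule-level span matters: single reads alone cover
   only ±99 bp around the variant and miss sparse divergence.

Verdict precedence: `germline_contaminated` (any germline molecule carries a
spanning k-mer beyond tolerance) → `insufficient` (support < 3) →
`assembly_artefact` → `verified`. A tolerance > 0 is allowed but should be
paired with a binomial test against the germline error rate; the default
keeps it at zero.

## Mutational signatures

Every SNV maps to one of 96 classes (pyrimidine convention:
5′-base [C|T > alt] 3′-base, purine-centred contexts reverse-complemented).
Strand attribution follows transcription-coupled-repair logic: if the
pyrimidine of the substitution lies on the coding (sense) strand of the
single overlapping gene the event is "untranscribed-strand", on the template
strand "transcribed"; variants under genes on both strands are "ambiguous"
and excluded from strand counts (kept in the 96-class spectrum); intergenic
variants form their own stratum.

- **Strand bias:** exact two-sided binomial test of untranscribed vs
  transcribed counts at p₀ = 0.5, aggregated to the 6 substitution types;
  empty types give p = 1.
- **Between-sample comparison:** per type, a 2×2 table (type count vs rest)
  across the two spectra, two-sided Fisher exact test,
  Benjamini–Hochberg adjusted across the 6 types (that granularity matches
  how base-pair substitution classes are usually reported; the test uses
  raw counts vs totals, not depth-normalised rates). Relative change is
  (p₂ − p₁)/p₁.

The Fisher p-values and BH q-values are asserted against hypergeometric
summation and a from-the-definition step-up oracle respectively.

## Longitudinal tracking

`build_vaf_matrix` assembles per-timepoint (alt, depth) observations into a
variant × timepoint matrix with union semantics (a variant missing from one
timepoint's calls becomes an undetected zero with its depth retained).
Detection requires alt ≥ 3 reads **and** VAF ≥ 0.002 — the 3-read floor
carried over from the caller, at amplicon-like depth.

- **Subclone clustering:** agglomerative, Euclidean distance on VAF rows,
  average linkage, cut at k = 2 by default. Rows are sorted
  lexicographically by variant key before linkage so the result is
  invariant to input order.
- **Progression rule:** a variant *rises* at timepoint t if it is detected
  with VAF ≥ 0.01 after being undetected at both (r = 2) immediately
  preceding timepoints; progression is called at the earliest sampling day
  where ≥ 25% of tracked variants rise. The rule trace records every
  evaluation. Lead time = imaging day − call day. On the default
  relapse-trajectory scenario this calls day 119 against imaging day 207:
  88 days of lead.
- **Sample similarity:** Pearson correlation over shared variants per
  sample pair (timepoints plus optional external profiles such as a tumour
  biopsy); pairs with < 2 shared variants or zero variance yield NaN, never
  a silent 0.
- **Depth planning:** X = κ/(α·f) with α ∈ (0,1] the library efficiency and
  κ ≥ 1 the read-count scaling efficiency (PCR duplication and coverage
  dispersion); exposed as an invertible parameter tuple.

## Simulator

The generator produces exactly the structure the analysis assumes, which is
what makes the end-to-end tests meaningful — and bounds what they show.

- **Fragments:** lengths from a discretised normal (mode 167 bp, sd 25 bp)
  multiplied by 1 + 0.3·cos(2π(L−167)/10) and renormalised, truncated at
  30 bp. The mode and the 10 bp sub-peak period are the canonical plasma
  cfDNA values; the sd and amplitude are pinned package choices (they are
  not published quantities). Fragments are placed uniformly; both 100 bp
  mates are emitted, so a position's read depth counts overlapping mates
  twice, and `mean_depth` is calibrated accordingly (observed depth within
  5% at ≥ 100 kb).
- **Truth:** germline hets uniform at 8×10⁻⁴ per base; somatic SNVs drawn
  per 96-class signature weights with sites sampled from matching
  trinucleotide contexts on either strand. The default UV-dominated
  signature puts 0.8 mass on C>T with 5′-pyrimidine contexts weighted
  three-fold. Each variant belongs to a variant group (truncal or private
  to a subclone); expected VAF = 0.5 × Σ carrier tumour fractions.
- **Scenario defaults.** The relapse trajectory samples days
  {−7, 0, 17, 42, 70, 100, 119, 150, 280, 343}: subclone A (driver) at
  fraction 0.10 pre-treatment, 0 on therapy, rising linearly from 0.02
  (day 119) to 0.16 (day 343); subclone B mirrors A scaled by 0.7 and
  collapses to half its day-280 value at the last draw; the imaging
  progression date is fixed at day 207. Driver VAF is thus 5% before
  treatment and 8% at the final draw. Single-timepoint "snapshot"
  compositions (pre-treatment and post-relapse) serve read-level
  simulation; the parameter-recovery experiment uses the post-relapse
  snapshot, whose tumour fraction (~0.20 total) matches the sample in which
  genome-wide calling is actually attempted in this design.
- **Reads:** per-fragment allele draws (somatic with probability equal to
  the expected VAF, germline hets at 0.5), substitution errors drawn from
  the configured confusion matrix, constant Q30 base qualities and mapping
  quality 60, read groups per sample. One master seed; per-sample
  substreams by fixed offsets; identical configurations produce
  byte-identical SAM output.
- **Timecourses:** expected-VAF tables are deterministic; observation
  counts at panel depth (default 5000×) are either the rounded expectation
  (deterministic mode) or binomial draws (noisy mode).

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real plasma data: GC- and mappability-dependent
coverage bias, indels/SVs/CNVs, strand-specific or context-dependent error
processes (e.g. oxidative or deamination artefacts), quality-score
miscalibration, mapping ambiguity (reads are placed at their true positions;
the divergence guard is exercised by explicit read misassignment), tumour
fraction drift within a draw, and fragment-size differences between tumour
and normal cfDNA.

## Numerical conventions and degenerate inputs

Likelihoods are computed in log space (`logaddexp` marginalisation);
binomial tails via the incomplete beta; per-read probabilities clipped to
[10⁻¹², 1−10⁻¹²] only inside the Bayesian H1 mixture. Consensus ties resolve
to the reference base; cluster tie-breaks are fixed by lexicographic row
order; empty k-mer graphs, zero-total spectra, all-undetected matrices and
zero-usable-site estimations all raise or return explicit "no call" values
rather than defaults. Problem sizes in the test suite (40–300 kb genomes,
100× cfDNA, 34× germline, 600 planted variants) were chosen as the smallest
at which the binomial statistics of the recovery experiments are stable.

## Known limitations

- The caller is SNV-only by design; indel support would require a different
  error model and gapped haplotype construction.
- The error model is quality-binned but not context-stratified; a
  trinucleotide-context matrix is the natural extension.
- The divergence guard assumes the paralog is absent from the germline
  read set at the locus; a paralog present in both samples manifests as
  `germline_contaminated` instead.
- `required_depth` treats detection as a deterministic threshold; it does
  not model the binomial sampling of alternate reads at depth X.
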