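# Methods

This note documents the models, rules and numerical choices behind
`crisprselect`, in the spirit of a methods supplement: what each component
assumes, which parameters matter, and what the synthetic data does and does
not establish about real experiments.

## Coordinates and sequence model

All coordinates are 0-based, half-open internally; reports and CLI output
are 1-based inclusive. Sequences are restricted to concrete A/C/G/T bases
(IUPAC ambiguity codes are rejected) because every designer rule is defined
on concrete bases. A locus carries a single coding frame as an ordered list
of `(start, end, frame_offset)` segments plus a gene strand; translation
concatenates the segments in gene orientation, skips `frame_offset` leading
bases, and drops a trailing partial codon, so partial loci translate
cleanly. Only same-length edited sequences can be translated against a
locus's segments — sufficient for checking WT′ synonymy, which is always a
single-nucleotide substitution.

## Cassette designer

**Cas9 model.** SpCas9 with an NGG PAM and a blunt cut 3 nt 5′ of the PAM
(between protospacer positions 17 and 18). These are configuration
constants (`design.CUT_OFFSET_FROM_PAM`).

**Guide rule.** Every base changed by the knock-in (variant, and by default
also WT′) must fall in the PAM's GG or within the 10 PAM-proximal
protospacer nucleotides (seed offsets 1–10), so the knock-in destroys
re-cutting. A base landing on the PAM's N does not count as a disruption:
only the GG confers recognition. Candidates are ranked by |variant distance
to cut| (knock-in efficiency decays with distance), then smallest seed
offset, then plus strand, then position — a total order, so design is
deterministic.

**Joint disruption.** By default the WT′ search requires the WT′ to disrupt
the chosen guide on its own (`require_joint_disruption=True`): both repair
outcomes must be protected from re-cutting, since re-cutting of either
template would distort the ratio. A variant-only mode is available.

**Off-target screen.** An exhaustive scan of user-supplied sequences for
20-mer+NGG sites within a mismatch budget (default 3). Sites with a broken
GG are not Cas9 substrates and are not reported; the guide passes when
every minimal-mismatch hit carries ≥ 1 mismatch in the seed. The screen is
desk-scale by design — genome-wide scoring is out of scope, and the
reference set is explicit input.

**WT′ search.** Single-nucleotide synonymous substitutions at the variant
position or within 3 nt of it, ranked by distance (0, 1, 2, 3) and then by
the usage frequency of the resulting codon, descending. Three screens:

* *synonymy* — translated protein must be unchanged;
* *splice motifs* — a candidate is rejected if it raises a donor or
  acceptor motif score above threshold (donor 0.80, acceptor 0.85 on a 0–1
  scale) at any window where the unedited sequence scored below it, on
  either strand. The screen is a deliberately simple position-frequency
  model (9-nt donor MAG|GTRAGT with invariant GT; 15-nt acceptor =
  polypyrimidine tract + invariant AG): it replaces interactive web-tool
  screening with something reproducible and overridable
  (`splice_allow_positions`);
* *rare codons* — the resulting codon must have usage ≥ 5 per thousand in
  the bundled human table (configurable threshold and table), so the
  normalization edit does not itself slow translation.

For splice-site variants (`splice_mode="exon_offset"`) WT′ candidates are
instead drawn from coding positions near the exon boundary closest to the
variant, since the variant itself sits in sequence where a synonymous edit
is undefined.

**ssODNs.** Both templates get symmetric 45-nt homology arms around their
own edit. Polarity follows the asymmetric-donor rule: when the nearest
edited base is more than 4 bp from the cut, edits left of the break get a
sense oligo and edits right of it an antisense oligo; at ≤ 4 bp polarity is
immaterial and defaults to sense — a deterministic choice where the
underlying rule is indifferent. The two templates are verified to agree at
every shared genomic position outside the edit sites.

**Primers.** Primers of 18–25 nt must anneal entirely outside the union
footprint of both ssODNs, with the near edge 40–120 nt away, product length
230–350 bp, GC 35–65%, and a GC-content melting-temperature rule
(64.9 + 41·(GC−16.4)/N) within 44–68 °C. Among valid pairs the smallest
summed offset wins, ties broken by GC balance — again a total order.
Thermodynamic (nearest-neighbor) design is explicitly out of scope.

## Read classification

**Alignment.** Global alignment with affine gaps (match +2, mismatch −1,
gap open −6, extend −0.5) via Biopython's PairwiseAligner, with all gaps
post-normalized to their leftmost equivalent placement so gap-position ties
are deterministic. Equal-length reads at ≥ 90% identity take a
substitution-only fast path; reads below 60% alignment identity are flagged
unalignable and counted as OTHER. Within `quantify_sample`, identical
(sequence, quality) records are classified once and cached.

**Decision order.** (1) Reads shorter than 50 nt or with mean quality below
20 are DISCARDED. (2) Any InDel overlapping the quantification window
(default: the ssODN-covered region — edits outside it cannot derive from
the templates) makes the read an InDel allele, *regardless* of point edits:
a knock-in read carrying an InDel is an InDel allele, consistent with the
observation that InDels at the target site destroy the tested residue. The
net coding-length change of window-overlapping InDels decides frameshift
(mod 3 ≠ 0) vs in-frame; InDels confined to sequence without a defined
frame count as in-frame ("non-coding InDel"). (3) Otherwise the read is
matched against the expected window haplotypes — WT, variant knock-in, WT′
knock-in, and (when the two edits do not share positions) the double
knock-in (MIXED_KI, quantified separately and excluded from ratios). Bases
below quality 10, or removed by alignment gaps, act as wildcards; a fully
unreadable edit window defaults to WT. Substitutions away from the edit
sites are ignored by default (sequencing-error tolerance; a strict mode
reclassifies any window substitution as OTHER). Haplotype matching rather
than per-edit present/absent logic is what makes same-position variant/WT′
pairs classify correctly.

**Absolute cell numbers.** `genome_equivalents = gdna_ng × 1000 / 6.0 pg`;
the per-category estimate is equivalents × read frequency, i.e. read
frequency is treated as a per-cell frequency. The alternative allele-count
reading (2 × equivalents × frequency) is exposed as `allele_count` so the
assumption is visible. `cells` uses raw equivalents (linear in mass and
frequency); `cells_printed` uses equivalents rounded to the nearest
thousand, matching how such numbers are usually quoted.

## Selection analysis

Ratios are plain read-count quotients; a zero WT′ count flags the ratio
undefined rather than producing an infinity. 95% CIs use a normal
approximation on the log ratio with a half-count correction. Normalization
divides each replicate's later-point ratio by that replicate's baseline
ratio; replicates without a usable baseline are excluded with a warning.
Paired t-tests are two-tailed and run on the linear-scale folds by default
(matching the plotted quantity); a log-scale option is provided and
recommended for strongly skewed ratios. Zero-variance difference vectors
are flagged instead of producing an undefined p-value.

**Frameshift control.** Per point: fold > 1.4 → enriched; fold < 0.7 →
depleted; inside the band, "validated neutral" requires the frameshift:WT′
control fold < 0.67 (selection pressure was present and detectable);
otherwise "inconclusive" — the guard against calling a variant neutral in
an assay without selection pressure. The band and threshold are explicit
parameters.

**Depth guidance.** The recommended depth solves
`N = (z_{1−α/2} + z_power)² · (3 + 1/φ) / (f · r · ln²φ)` — a normal
approximation for the two-sided test of log fold change = ln φ against 0,
with Var(log fold) = 1/v₁ + 1/w₁ + 1/v₂ + 1/w₂ evaluated at expected counts
(baseline variant = baseline WT′ = later WT′ = N·f, later variant = N·f·φ),
divided across r replicates. It is a guideline-grade calculation, labelled
as such, and paired with an independent Monte-Carlo power simulation
(`simulate_power`) that the test suite checks agrees within 5 percentage
points. The recommendation is monotone in f and, for φ ∈ [0.1, 10], in the
effect size; below φ ≈ 0.1 the 1/φ variance term makes the curve flatten —
a real feature of count ratios, not an artifact.

## Simulator

The generator's defaults are the study-like regime: 50,000 cells, per-allele
cut probability 0.9, conditional outcome distribution (given a cut) of
unedited 0.25, variant knock-in 0.094, WT′ knock-in 0.094, frameshift InDel
0.470, in-frame InDel 0.092. This yields marginal knock-in allele
frequencies of ~8.5% per template and a frameshift:knock-in ratio of ~5:1,
the pattern reported for efficiently edited diploid lines. Timepoints
default to days 2 and 12 with a passage to 50,000 cells on day 7; template
mass 100 ng, depth 30,000 reads, substitution error 0.3% per base.

Modeling choices and their consequences:

* *allele independence* — each allele is cut and resolved independently,
  so biallelic correlations beyond the cut probability are absent. An
  explicit joint table over category pairs can be supplied to reproduce an
  observed single-cell zygosity structure exactly.
* *class-level growth* — each cell belongs to one fitness class (precedence
  variant > WT′ > frameshift > in-frame > unedited) and grows
  exponentially in expectation, with multinomial resampling only at
  passaging. Closed-form oracle: the expected variant:WT′ ratio fold
  between t₁ and t₂ is (w_variant/w_WT′)^(t₂−t₁). Cells carrying both a
  variant and a WT′ allele are assigned the variant's fitness, which biases
  the *allele-level* fold slightly toward 1 (≈ +7% at default knock-in
  frequencies for a 5-fold depletion). The recovery tests account for this
  rather than hiding it: it is a property of the assay, not a bug.
* *sequencing* — two-stage multinomial sampling (allele pool of
  2 × genome equivalents molecules, then reads), uniform substitution
  errors, constant Phred qualities matching the error rate. No PCR bias,
  no chimeras, no quality profiles, no paired-end structure. Passing
  round-trip tests therefore demonstrates correctness of the arithmetic
  and classification logic under idealized noise, not robustness to
  amplification artifacts.
* *determinism* — the seed is mandatory; the same seed yields byte-identical
  FASTQ. Replicates derive child seeds via `SeedSequence.spawn`.

## Test and script problem sizes

The test battery uses 20 designer fixtures on 2 kb loci, a 60-nt toy
amplicon for the exhaustive (≤ 2-edit) classifier enumeration, round-trip
simulations of 3 replicates × 2 timepoints at 30,000 reads, stoichiometry
sweeps (initial ratios 0.06–12.5) at 20,000 reads, and 10,000-draw
Monte-Carlo power checks — sizes at which binomial sampling error is small
relative to the tested tolerances while the whole suite runs in a couple of
minutes on one CPU. Deletion+insertion edit pairs are excluded from the
classifier enumeration because they restore the read length, making the
indel-vs-substitution representation genuinely alignment-dependent.

## Known limitations

* The splice screen is a motif heuristic, not a full splicing model;
  borderline candidates should be checked externally and whitelisted.
* Off-target screening is restricted to supplied sequences; no genome-wide
  search or cutting-efficiency scores.
* The classifier assumes pre-merged single-end reads spanning the amplicon.
* Multi-variant multiplex cassettes and >2 ploidy are unsupported.
* Depth guidance models read counts as independent binomials; UMI-free PCR
  duplicates and overdispersion in real libraries argue for treating the
  recommendation as a lower bound.
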