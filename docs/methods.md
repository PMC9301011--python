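# Methods

## Quantification model

Each sample contributes two fragment libraries: IP (antibody-enriched) and
input. All per-sample peak sets are merged into one catalogue by unioning
overlapping-or-touching intervals per chromosome, so every peak is
quantified in every library. For a peak of length L nt:

- MFPKM = ip_count × 10⁹ / (L × N_IP)
- IFPKM = input_count × 10⁹ / (L × N_input)
- methylation level = MFPKM / IFPKM

with N the total mapped fragments of the library (not in-peak totals; the
normalization mirrors FPKM, where the denominator is library size). Library
totals and peak length cancel in ways the tests pin down exactly: the level
is invariant to peak length (L cancels) and, at pseudocount zero, to uniform
library rescaling.

**Pseudocount.** The paper-style ratio is undefined when IFPKM = 0. The
`pseudocount` parameter is expressed in fragment-count units and converted
to FPKM units per cell, ε = pseudocount × 10⁹/(L·N); the default of 1 is the
normalized weight of a single fragment. Because ε carries the same 1/L as
the FPKM itself, peak-length invariance of the level survives the
pseudocount exactly; invariance to uniform library rescaling is exact only
at pseudocount 0 (the offset shrinks as libraries grow, which is the
intended behaviour of a one-fragment floor). The unshifted ratio is reported
alongside wherever IFPKM > 0, and peaks with any non-positive level are
excluded (and counted) before correlations.

**Similarity.** Pearson correlation of log₂ levels across peaks, all sample
pairs. Zero-variance samples yield NaN correlations rather than a silent
number.

## Peak calling

A deliberately simple, transparent enrichment caller stands where a
dedicated MeRIP peak caller would sit in a production pipeline: windows of
200 nt advance in 50-nt steps; each window's IP fragment count m is tested
one-sidedly against Binomial(N_IP, max(m_input, 0.5)/N_input); windows pass
at BH-adjusted q ≤ 0.05, fold ≥ 2 and m ≥ 10, and surviving windows merge
into peaks. The half-count floor on the input proportion keeps the
expectation defined in zero-coverage windows. The defaults match the
fragment scale of the libraries (100–300 nt): enriched windows are a few
steps wide, so merged peaks land at 200–450 nt.

## Differential calls

Group means are arithmetic means of levels (not log levels) across the
samples of each condition. The classification is fold-change-only with an
inclusive boundary: fold = mean_B/mean_A, up iff fold ≥ 1.5, down iff
fold ≤ 1/1.5. No variance test is applied — the criterion is a threshold,
so per-group replicate SDs are carried in the output for transparency, and
the label-swap symmetry (A↔B exchanges up↔down exactly) is a tested
invariant. Non-finite folds (possible at pseudocount 0) are flagged
`excluded`, never dropped silently. Gene-level rollups deduplicate peaks per
gene; a gene carrying both up and down peaks appears in both lists with a
flag.

## Annotation, metagene, motifs

Annotation applies a fixed priority order at the peak midpoint:
5′UTR > 3′UTR > CDS > TSS > TTS > intron > intergenic (windows ±1 kb around
TSS/TTS; ties between genes break toward the smaller gene id). Midpoint
assignment is deterministic and total — every peak gets exactly one
category — at the cost of ignoring partial overlaps; an overlap-weighted
mode was considered and rejected to keep category counts reproducible under
small coordinate shifts. For bar-chart-style summaries the fine categories
collapse to exonic / intronic / 3′UTR / intergenic.

The metagene profile maps peak midpoints onto a composite transcript axis
(5′UTR | CDS | 3′UTR, 50 bins per segment by default), using one
representative transcript per gene (the longest) and normalizing each
position by its segment length. Bin masses sum to 1. Because each segment is
stretched to equal visual width, a uniform distribution over the mature
transcript shows per-segment mass proportional to true segment lengths —
this is a tested property, and the reason segment masses rather than bin
heights should be compared across annotations.

Motif work is confirmatory, not discovery: stated IUPAC motifs (RRACH and
its canonical instance GGACU) are scanned directly (U≡T, overlapping hits
reported); enrichment in peak vs background sequences is a one-sided
hypergeometric test on per-sequence presence/absence with BH across motifs.
The same exact test drives gene-list over-representation. Note that for a
5-mer as degenerate as RRACH, presence/absence saturates in windows beyond
~300 nt (a random 300-mer contains RRACH with probability ≈ 0.97), so
enrichment tests are only informative with short, site-centred sequences.

## Assay calculators

- **2^−ΔΔCt**: replicate Ct values are averaged before ΔCt; amplification
  efficiency is fixed at 2 by default and exposed as a parameter. Per-group
  summaries exponentiate the mean ΔΔCt (a geometric mean of per-sample
  values), so the calibrator group summarizes to exactly 1; an arithmetic
  mean would exceed 1 by Jensen's inequality.
- **MeRIP-qPCR**: IP/input ratio 2^−(Ct_IP − Ct_input) per (sample, gene),
  normalized to the same sample's housekeeping-gene ratio; a %input column
  is optional. The normalizer's self-enrichment is identically 1.
- **Decay**: y = e^(−kt) fitted by least squares on ln y (closed form, no
  optimizer; a nonlinear one-phase fit would differ only under strong
  heteroscedasticity). Points with y ≤ 0 are excluded and reported; < 3
  usable points or k ≤ 10⁻⁹/h → not estimable; t½ = ln2/k; R² on the log
  scale. No plateau term: chases normalized to 0 h decay toward zero.
- **LC-MS/MS**: per-nucleoside OLS calibration of area against
  concentration; sample areas outside the calibrated range warn; inferred
  A concentration ≤ 0 is an error, negative m⁶A clamps to 0 with a warning;
  ratio = conc(m⁶A)/conc(A).

## Synthetic data generator

The generator emulates the structure of the motivating experimental design:
two conditions × two replicates, paired IP/input libraries of 100–300 nt
fragments, m⁶A sites on RRACH 5-mers biased toward CDS and 3′UTR (segment
weights 1:4:4), and a subset of sites differing ≥1.5-fold between
conditions.

- **Genome/genes**: random sequence; per-gene 5′UTR/CDS/3′UTR lengths
  default to 150/900/450 nt (single-exon by default; a multi-exon option
  inserts 200–500 nt introns); both strands; every transcript is guaranteed
  an RRACH (one is injected in the rare sequence lacking it).
- **Sites**: one per gene by default, enrichment β (default 8) over a
  150-nt window centred on the site — the fragment scale; condition fold φ
  multiplies the IP rate in condition B. Class labels derive from φ and the
  1.5 threshold and are exactly recomputable from the truth table.
- **Fragments**: input fragment positions are uniform over expressed
  transcripts; IP centres are drawn from the flat+window density. Exactly
  `depth` fragments per library (default 10⁵), lengths uniform in
  [100, 300].
- **Noise**: gamma-Poisson per gene (marginally negative binomial; shape
  `dispersion`, default 10). The gamma expression factor is drawn once per
  sample and shared between that sample's IP and input libraries, because
  replicate-to-replicate expression variability is a property of the
  sample's RNA, not of the library prep. The IP/input level therefore
  carries only counting noise, which is the implicit assumption of a
  fold-change-only differential criterion; modelling the gamma independently
  per library would make a 1.5-fold threshold meaningless at any depth.
- **Seeding**: one master seed; child seeds are spawned per
  (condition, replicate, library) via `numpy` seed sequences, so outputs
  are byte-identical across runs and libraries are independent.

What the simulator does **not** model — and hence what passing tests do not
demonstrate about real data: spliced fragments, base-call errors,
antibody off-target binding, GC/mappability bias, transcript-isoform
mixtures, and a calibrated match to any real study's depth or dispersion
(the depths here are desk-scale). One systematic effect it does reproduce is
composition bias: because IP library size is fixed, adding methylation mass
in one condition slightly deflates all that condition's levels (the same
effect library-size normalization has in differential expression), so
estimated folds are mildly compressed toward it — visible as planted fold 3
recovering as ≈2.4, still comfortably beyond the 1.5 threshold.

## Problem sizes

The validation study runs 200 genes × 1 site (50 up at φ=3, 50 down at
φ=1/3, 100 unchanged), β = 8, 10⁵ fragments × 8 libraries; it completes in
well under a minute and is the scale at which the recovery targets
(per-class sensitivity ≥ 0.9, FDR ≤ 0.1) are asserted. Oracle-based checks
(merge vs boolean mask, motif scan vs regex, hypergeometric vs exact
enumeration) run at 10³–10⁴ element scale.

## Known limitations

- The window caller is a stand-in with simple statistics; it under-segments
  closely spaced sites (< ~300 nt) into one peak.
- Midpoint annotation misattributes peaks that straddle feature boundaries.
- The fold-change criterion has no error control; FDR in the validation is
  controlled by simulation design (adequate depth), not by the statistic.
- The metagene uses peak midpoints and one transcript per gene; it is not a
  read-coverage-weighted profile.
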