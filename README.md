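# meriplite

Quantification of m⁶A RNA methylation from MeRIP-seq experiments, and the
arithmetic behind the companion bench assays.

MeRIP-seq (methylated-RNA immunoprecipitation sequencing) profiles
N6-methyladenosine by sequencing two libraries per sample: an IP library
enriched for m⁶A-containing RNA fragments and an input library of the same
fragmented RNA without enrichment. `meriplite` takes per-library fragment
alignments (BED), gene models (GTF) and a sample sheet, and produces merged
peak catalogues, per-peak methylation levels, sample-similarity matrices,
differential-methylation calls between condition groups (e.g. offspring of
specific-pathogen-free vs germ-free dams), peak annotation, metagene
profiles and motif statistics. It is written for analysts who want the
quantification pipeline to be small, inspectable and testable against
planted ground truth — a seeded synthetic-data generator is a first-class
part of the package.

## The model

For each merged peak of length *L* and each sample, fragment counts are
normalized per library:

    MFPKM = ip_count    × 10⁹ / (L × N_IP)
    IFPKM = input_count × 10⁹ / (L × N_input)

where *N* is the total number of mapped fragments in that library. The
methylation level of the peak is

    level = MFPKM / IFPKM

(optionally with a one-fragment pseudocount in each library; *L* cancels in
the ratio). Sample similarity is the Pearson correlation of log₂ levels
across peaks. For two condition groups A and B, a peak with group-mean
levels m_A and m_B is called **up** when m_B / m_A ≥ 1.5, **down** when
m_B / m_A ≤ 1/1.5, and unchanged otherwise — a fold-change-only criterion
with an inclusive boundary.

Around this core the package provides: a sliding-window binomial
enrichment caller (IP count tested against the input-implied expectation,
BH-corrected), interval merging across samples, largest-overlap fragment
counting, midpoint-priority feature annotation
(5′UTR > 3′UTR > CDS > TSS > TTS > intron > intergenic), a binned metagene
over the normalized 5′UTR|CDS|3′UTR axis, IUPAC motif scanning (RRACH,
GGACU) with exact hypergeometric enrichment, hypergeometric
over-representation of gene lists, and the assay calculators: 2^−ΔΔCt
relative expression, MeRIP-qPCR IP/input enrichment normalized to GAPDH,
first-order mRNA half-life (t½ = ln2/k) from actinomycin-D chases, and the
LC-MS/MS m⁶A/A nucleoside ratio from linear standard curves.

## Worked example

```python
from meriplite import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="run", n_genes=100, depth=50_000,
                     fraction_up=0.25, fraction_down=0.25, fold=3.0, seed=2)
summary = run_pipeline(cfg)
print(summary["differential"])
print(summary["recovery"])
```

prints

```
{'up': 25, 'down': 24, 'unchanged': 49, 'excluded': 0}
{'site_peak_match_rate': 0.97, 'up_sensitivity': 1.0, 'up_fdr': 0.0,
 'down_sensitivity': 0.96, 'down_fdr': 0.0}
```

One hundred m⁶A sites were planted on RRACH 5-mers (25 threefold up in the
second condition, 25 threefold down, 50 unchanged) and fragment libraries
were simulated at 50,000 fragments each. The pipeline recalled 25 up and 24
down peaks; against the planted truth all up sites and 24/25 down sites were
recovered, with no false calls in either class. The same stages are
available as a thin CLI (`meriplite simulate | callpeaks | merge | quantify |
diff | annotate | metagene | motif | ora | ddct | merip-qpcr | decay |
lcms-ratio | run`), and `examples/` holds one short narrative script per
capability.

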