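"""Synthetic MeRIP-seq data with known ground truth.

The generator emulates the structure of a paired IP/input methylation
profiling experiment: a toy genome with 5'UTR/CDS/3'UTR gene models, m6A
sites planted on RRACH 5-mers with a positional bias toward the CDS and
3'UTR, and fragment libraries of 100-300 nt whose IP coverage is enriched by
a factor beta over a window centred on each site (times the condition fold
phi in the second condition).

Counting noise is gamma-Poisson (marginally negative binomial, ``size``
shape parameter): each sample draws one gamma expression factor per gene
that is shared between its paired IP and input libraries, so the IP/input
ratio carries only multinomial counting noise — replicate variability in
expression is a property of the sample's RNA, not of the library prep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel, GenomicInterval
from .motifs import scan_motif

logger = logging.getLogger(__name__)

FRAGMENT_LENGTH_RANGE = (100, 300)  # nt, per the library prep being emulated
DEFAULT_ENRICHMENT_WINDOW = 150  # nt over which beta applies, fragment scale
DEFAULT_SEGMENT_WEIGHTS = {"5'UTR": 1.0, "CDS": 4.0, "3'UTR": 4.0}
FOLD_THRESHOLD = 1.5  # class labels in the truth table follow this

_BASES = np.array(list("ACGT"))


@dataclass
class FragmentSet:
    """One sequencing library: genomic fragment intervals plus its total."""

    sample_id: str
    library_kind: str  # "IP" or "input"
    fragments: pd.DataFrame  # columns: chrom, start, end, strand
    library_total: int

    def __post_init__(self) -> None:
        if self.library_kind not in ("IP", "input"):
            raise ValueError(f"library_kind must be IP or input, got {self.library_kind!r}")
        if self.library_total != len(self.fragments):
            raise ValueError("library_total must equal the number of fragments")

    def to_bed(self, path: str) -> None:
        df = self.fragments
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": [f"{self.sample_id}_{self.library_kind}_{i}" for i in range(len(df))],
                "score": 0,
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed_fragments(path: str, sample_id: str, library_kind: str) -> FragmentSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    frags = df[["chrom", "start", "end", "strand"]].reset_index(drop=True)
    return FragmentSet(sample_id, library_kind, frags, len(frags))


@dataclass
class SimTruth:
    """Planted m6A sites with their enrichments and condition folds."""

    sites: pd.DataFrame  # site_id, gene_id, chrom, pos, tpos, motif, beta, phi, class
    genes: list[GeneModel] = field(default_factory=list)
    genome: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        self.sites.drop(columns=["tpos"]).to_csv(path, sep="\t", index=False)


def _classify_phi(phi: float, threshold: float = FOLD_THRESHOLD) -> str:
    if phi >= threshold:
        return "up"
    if phi <= 1.0 / threshold:
        return "down"
    return "unchanged"


def _resolve_length(spec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_genome(
    n_genes: int,
    length_params: dict | None = None,
    seed: int = 0,
    gap: int = 500,
    n_chroms: int = 1,
    exons_per_gene: int = 1,
    intron_length: tuple[int, int] = (200, 500),
    minus_strand_fraction: float = 0.5,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate a toy genome and gene models with UTR/CDS architecture.

    ``length_params`` maps segment names (``utr5``, ``cds``, ``utr3``) to a
    fixed int or an inclusive (lo, hi) range.  Every transcript is guaranteed
    to contain at least one RRACH occurrence (a GGACT is injected if the
    random sequence happens to lack one).  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = {"utr5": 150, "cds": 900, "utr3": 450}
    params.update(length_params or {})
    for k, v in params.items():
        lo = v if isinstance(v, int) else v[0]
        if lo < 1:
            raise ValueError(f"{k} length must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_seqs: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(n_chroms)}
    cursors = {c: 0 for c in chrom_seqs}
    genes: list[GeneModel] = []

    for i in range(n_genes):
        chrom = f"chr{(i % n_chroms) + 1}"
        utr5 = _resolve_length(params["utr5"], rng)
        cds = _resolve_length(params["cds"], rng)
        utr3 = _resolve_length(params["utr3"], rng)
        mature = utr5 + cds + utr3

        tseq = "".join(rng.choice(_BASES, size=mature))
        if not scan_motif(tseq, "RRACH"):
            pos = int(rng.integers(0, mature - 5 + 1))
            tseq = tseq[:pos] + "GGACT" + tseq[pos + 5 :]

        strand = "-" if rng.random() < minus_strand_fraction else "+"
        gseq = tseq if strand == "+" else _revcomp(tseq)

        # split the genomic-orientation sequence into exons with introns
        n_ex = max(1, exons_per_gene)
        start = cursors[chrom] + gap
        pieces, exons, pos0 = [], [], start
        bounds = sorted(rng.choice(np.arange(1, mature), size=n_ex - 1, replace=False)) if n_ex > 1 else []
        seg_edges = [0, *map(int, bounds), mature]
        for j in range(n_ex):
            seg = gseq[seg_edges[j] : seg_edges[j + 1]]
            exons.append(GenomicInterval(chrom, pos0, pos0 + len(seg)))
            pieces.append(seg)
            if j < n_ex - 1:
                ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
                pieces.append("".join(rng.choice(_BASES, size=ilen)))
                pos0 += len(seg) + ilen
            else:
                pos0 += len(seg)

        chrom_seqs[chrom].append("".join(rng.choice(_BASES, size=gap)))
        chrom_seqs[chrom].append("".join(pieces))
        cursors[chrom] = pos0

        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=utr5,
                cds_end=utr5 + cds,
            )
        )

    genome = {}
    for chrom, parts in chrom_seqs.items():
        parts.append("".join(rng.choice(_BASES, size=gap)))
        genome[chrom] = "".join(parts)
    return genes, genome


def _revcomp(seq: str) -> str:
    from .genes import reverse_complement

    return reverse_complement(seq)


def plant_m6a_sites(
    genes: list[GeneModel],
    genome: dict[str, str],
    sites_per_gene: int = 1,
    beta_range: tuple[float, float] = (8.0, 8.0),
    fraction_up: float = 0.0,
    fraction_down: float = 0.0,
    fold: float = 3.0,
    segment_weights: dict[str, float] | None = None,
    min_separation: int = 300,
    seed: int = 0,
) -> SimTruth:
    """Place m6A sites on RRACH positions, biased toward CDS and 3'UTR.

    Class allocation is deterministic: of the n placed sites,
    ``round(fraction_up * n)`` are labelled up (phi = fold),
    ``round(fraction_down * n)`` down (phi = 1/fold), the rest unchanged
    (phi = 1).  Genes without an RRACH match are skipped with a warning.
    """
    if fraction_up + fraction_down > 1:
        raise ValueError("fraction_up + fraction_down must be <= 1")
    if fold <= 0:
        raise ValueError("fold must be positive")
    weights = dict(DEFAULT_SEGMENT_WEIGHTS)
    weights.update(segment_weights or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    records = []
    for gene in genes:
        tseq = gene.transcript_sequence(genome)
        starts = scan_motif(tseq, "RRACH")
        # the methylated A is the third base of RRACH
        a_pos = [s + 2 for s in starts]
        if not a_pos:
            logger.warning("gene %s has no RRACH site; skipped", gene.gene_id)
            continue
        w = np.array([weights.get(gene.segment_of(t), 0.0) for t in a_pos], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(a_pos))
        chosen: list[int] = []
        nz = np.flatnonzero(w)
        probs = w[nz] / w[nz].sum()
        # weighted draw without replacement, enforcing a minimum spacing so
        # planted peaks stay resolvable at fragment scale
        pool = [int(nz[j]) for j in rng.choice(len(nz), size=len(nz), replace=False, p=probs)]
        for idx in pool:
            t = a_pos[idx]
            if all(abs(t - c) >= min_separation for c in chosen):
                chosen.append(t)
            if len(chosen) == sites_per_gene:
                break
        for t in chosen:
            records.append(
                {
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "pos": gene.transcript_to_genomic(t),
                    "tpos": t,
                    "motif": tseq[t - 2 : t + 3],
                    "beta": float(rng.uniform(*beta_range)),
                }
            )

    n = len(records)
    n_up = int(round(fraction_up * n))
    n_down = int(round(fraction_down * n))
    perm = rng.permutation(n)
    phi = np.ones(n)
    phi[perm[:n_up]] = fold
    phi[perm[n_up : n_up + n_down]] = 1.0 / fold

    sites = pd.DataFrame.from_records(records)
    if n:
        sites["phi"] = phi
        sites["class"] = [_classify_phi(p) for p in phi]
        sites.insert(0, "site_id", [f"site{i + 1:04d}" for i in range(n)])
    else:
        sites = pd.DataFrame(
            columns=["site_id", "gene_id", "chrom", "pos", "tpos", "motif", "beta", "phi", "class"]
        )
    return SimTruth(sites=sites, genes=list(genes), genome=genome)


def simulate_fragments(
    truth: SimTruth,
    conditions: tuple[str, str] = ("SPF", "GF"),
    replicates: int = 2,
    depth: int = 100_000,
    dispersion: float = 10.0,
    enrichment_window: int = DEFAULT_ENRICHMENT_WINDOW,
    fragment_length_range: tuple[int, int] = FRAGMENT_LENGTH_RANGE,
    seed: int = 0,
) -> dict[tuple[str, str], FragmentSet]:
    """Draw paired IP and input fragment libraries for each sample.

    Input fragments land uniformly over expressed transcripts; IP fragment
    centres are drawn from a per-transcript density that is flat except in a
    ``enrichment_window`` around each planted site, where the rate is
    multiplied by beta (condition A) or beta * phi (condition B).  Exactly
    ``depth`` fragments are drawn per library.

    Returns a dict keyed by (sample_id, library_kind); sample ids are
    "<condition>_r<k>".
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(conditions) != 2:
        raise ValueError("exactly two condition names are required")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    genes = truth.genes
    n_genes = len(genes)
    lengths = np.array([g.mature_length for g in genes])
    half_w = enrichment_window // 2

    # per-gene IP position weights for each condition
    site_by_gene: dict[str, list[tuple[int, float, float]]] = {}
    for r in truth.sites.itertuples():
        site_by_gene.setdefault(r.gene_id, []).append((int(r.tpos), float(r.beta), float(r.phi)))

    dens: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for ci, cond in enumerate(conditions):
        for g, L in zip(genes, lengths):
            w = np.ones(L)
            for tpos, beta, phi in site_by_gene.get(g.gene_id, []):
                mult = beta * phi if ci == 1 else beta
                lo, hi = max(0, tpos - half_w), min(L, tpos + half_w)
                w[lo:hi] = np.maximum(w[lo:hi], mult)
            dens[cond].append(w)

    out: dict[tuple[str, str], FragmentSet] = {}
    for ci, cond in enumerate(conditions):
        for rep in range(1, replicates + 1):
            sample = f"{cond}_r{rep}"
            # deterministic child seeds per (condition, replicate, purpose)
            base = np.random.SeedSequence([seed, ci, rep])
            kids = base.spawn(3)
            rng_expr = np.random.default_rng(kids[0])
            expr = rng_expr.gamma(shape=dispersion, scale=1.0 / dispersion, size=n_genes)

            for kind, kid in (("input", kids[1]), ("IP", kids[2])):
                rng = np.random.default_rng(kid)
                if kind == "input":
                    gene_w = expr * lengths
                else:
                    gene_w = expr * np.array([d.sum() for d in dens[cond]])
                counts = rng.multinomial(depth, gene_w / gene_w.sum())
                rows = []
                for gi, (g, c) in enumerate(zip(genes, counts)):
                    if c == 0:
                        continue
                    L = lengths[gi]
                    flo, fhi = fragment_length_range
                    flen = rng.integers(flo, min(fhi, L) + 1, size=c)
                    if kind == "input":
                        centers = rng.integers(0, L, size=c)
                    else:
                        d = dens[cond][gi]
                        centers = rng.choice(L, size=c, p=d / d.sum())
                    t_start = np.clip(centers - flen // 2, 0, L - flen)
                    t_end = t_start + flen
                    g0 = np.array([g.transcript_to_genomic(int(t)) for t in t_start])
                    g1 = np.array([g.transcript_to_genomic(int(t) - 1) for t in t_end])
                    lo = np.minimum(g0, g1)
                    hi = np.maximum(g0, g1) + 1
                    rows.append(
                        pd.DataFrame(
                            {"chrom": g.chrom, "start": lo, "end": hi, "strand": g.strand}
                        )
                    )
                frags = (
                    pd.concat(rows, ignore_index=True)
                    if rows
                    else pd.DataFrame(columns=["chrom", "start", "end", "strand"])
                )
                frags = frags.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
                    drop=True
                )
                out[(sample, kind)] = FragmentSet(sample, kind, frags, len(frags))
    return out


def sample_sheet(libraries: dict[tuple[str, str], FragmentSet], conditions: tuple[str, str]) -> pd.DataFrame:
    """Tidy sample sheet (sample_id, condition) for the simulated design."""
    rows = []
    for (sample, kind) in libraries:
        if kind == "IP":
            cond = sample.rsplit("_r", 1)[0]
            rows.append({"sample_id": sample, "condition": cond})
    return pd.DataFrame(rows)
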