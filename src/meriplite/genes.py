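"""Gene models and coordinate arithmetic.

Transcript architecture is kept deliberately simple: each gene carries one
(representative) transcript made of sorted, non-overlapping exons plus a CDS
span given in *transcript* coordinates.  From these the 5'UTR, CDS and 3'UTR
segments are derived.  Genomic coordinates are 0-based half-open throughout
the library; GTF output converts to the 1-based closed convention of that
format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene with a single representative transcript.

    ``exons`` are sorted by genomic start and non-overlapping.  ``cds_start``
    and ``cds_end`` delimit the CDS in transcript coordinates (0-based
    half-open over the mature, spliced transcript).  For minus-strand genes
    transcript coordinate 0 is the genomically *rightmost* exonic base.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    _exon_offsets: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        if not (0 <= self.cds_start < self.cds_end <= self.mature_length):
            raise ValueError(
                f"CDS span [{self.cds_start}, {self.cds_end}) outside mature "
                f"transcript of length {self.mature_length} in {self.gene_id}"
            )
        # cumulative exonic length preceding each exon, in genomic order
        off, acc = [], 0
        for e in self.exons:
            off.append(acc)
            acc += len(e)
        self._exon_offsets = off

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr3_length(self) -> int:
        return self.mature_length - self.cds_end

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    # -- coordinate maps ---------------------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Transcript coordinate of genomic position ``pos``.

        Returns None for intronic or flanking positions.
        """
        for e, off in zip(self.exons, self._exon_offsets):
            if e.start <= pos < e.end:
                t_plus = off + (pos - e.start)
                if self.strand == "+":
                    return t_plus
                return self.mature_length - 1 - t_plus
        return None

    def transcript_to_genomic(self, t: int) -> int:
        """Genomic position of transcript coordinate ``t`` (0-based)."""
        if not 0 <= t < self.mature_length:
            raise ValueError(f"transcript coordinate {t} outside [0, {self.mature_length})")
        t_plus = t if self.strand == "+" else self.mature_length - 1 - t
        for e, off in zip(self.exons, self._exon_offsets):
            if off <= t_plus < off + len(e):
                return e.start + (t_plus - off)
        raise AssertionError("unreachable")

    def segment_of(self, t: int) -> str:
        """Which transcript segment (5'UTR / CDS / 3'UTR) position ``t`` is in."""
        if t < self.cds_start:
            return "5'UTR"
        if t < self.cds_end:
            return "CDS"
        return "3'UTR"

    def transcript_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][e.start : e.end] for e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- FASTA / GTF round trips ------------------------------------------------


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(path, as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def _segment_intervals(gene: GeneModel, t0: int, t1: int) -> list[tuple[int, int]]:
    """Genomic intervals covered by transcript span [t0, t1)."""
    out = []
    cur_start = None
    prev = None
    for t in range(t0, t1):
        g = gene.transcript_to_genomic(t)
        if prev is not None and g == prev + (1 if gene.strand == "+" else -1):
            prev = g
            continue
        if prev is not None:
            out.append((cur_start, prev))
        cur_start, prev = g, g
    if prev is not None:
        out.append((cur_start, prev))
    return [(min(a, b), max(a, b) + 1) for a, b in out]


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "meriplite") -> None:
    """Write gene/transcript/exon/CDS/UTR features (1-based closed coords)."""
    rows = []

    def add(gene: GeneModel, feat: str, start: int, end: int) -> None:
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
        rows.append(
            "\t".join(
                [gene.chrom, source, feat, str(start + 1), str(end), ".", gene.strand, ".", attrs]
            )
        )

    for g in genes:
        add(g, "gene", g.start, g.end)
        add(g, "transcript", g.start, g.end)
        for e in g.exons:
            add(g, "exon", e.start, e.end)
        for feat, t0, t1 in [
            ("five_prime_utr", 0, g.cds_start),
            ("CDS", g.cds_start, g.cds_end),
            ("three_prime_utr", g.cds_end, g.mature_length),
        ]:
            if t1 > t0:
                for s, e in _segment_intervals(g, t0, t1):
                    add(g, feat, s, e)
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def read_gtf(path: str) -> list[GeneModel]:
    """Rebuild GeneModel objects from a GTF written by :func:`write_gtf`."""
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]+)"')
    genes = []
    for gid, grp in df.groupby("gene_id", sort=False):
        exon_rows = grp[grp["feature"] == "exon"]
        exons = [
            GenomicInterval(r.chrom, int(r.start) - 1, int(r.end))
            for r in exon_rows.itertuples()
        ]
        strand = grp["strand"].iloc[0]
        chrom = grp["chrom"].iloc[0]
        cds_rows = grp[grp["feature"] == "CDS"]
        utr5 = grp[grp["feature"] == "five_prime_utr"]
        utr5_len = int((utr5["end"] - (utr5["start"] - 1)).sum())
        cds_len = int((cds_rows["end"] - (cds_rows["start"] - 1)).sum())
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=utr5_len,
                cds_end=utr5_len + cds_len,
            )
        )
    return genes
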