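"""Peak-to-gene annotation and metagene profiling.

Each peak is assigned one genomic feature category by applying a fixed
priority order at the peak midpoint (5'UTR > 3'UTR > CDS-exon > TSS > TTS >
intron > intergenic by default).  The metagene profile maps peak midpoints
to a composite transcript axis — 5'UTR | CDS | 3'UTR, each segment length-
normalized into ``bins_per_segment`` bins — using one representative
(the longest) transcript per gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genes import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY = ("5'UTR", "3'UTR", "CDS", "TSS", "TTS", "intron", "intergenic")
SEGMENTS = ("5'UTR", "CDS", "3'UTR")


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def _categories_at(pos: int, gene: GeneModel, tss_tts_window: int) -> set[str]:
    cats: set[str] = set()
    t = gene.genomic_to_transcript(pos)
    if t is not None:
        cats.add(gene.segment_of(t))
    elif gene.start <= pos < gene.end:
        cats.add("intron")
    tss = gene.start if gene.strand == "+" else gene.end - 1
    tts = gene.end - 1 if gene.strand == "+" else gene.start
    if abs(pos - tss) <= tss_tts_window:
        cats.add("TSS")
    if abs(pos - tts) <= tss_tts_window:
        cats.add("TTS")
    return cats


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    tss_tts_window: int = 1000,
) -> pd.DataFrame:
    """One category and (unless intergenic) one gene per peak.

    The peak midpoint decides: among genes whose span (plus the TSS/TTS
    window) covers it, categories are collected and the highest-priority one
    wins; gene ties break toward the smaller gene_id.  Midpoints in no gene
    are intergenic, with the nearest gene on the same chromosome recorded
    when one exists.
    """
    known_chroms = {g.chrom for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for pk in peaks.itertuples():
        if pk.chrom not in known_chroms:
            raise ValueError(f"peak {pk.name} on unknown chromosome {pk.chrom}")
        mid = _midpoint(pk.start, pk.end)
        best_cat, best_gene = "intergenic", None
        for gene in by_chrom[pk.chrom]:
            if not (gene.start - tss_tts_window <= mid < gene.end + tss_tts_window):
                continue
            for cat in _categories_at(mid, gene, tss_tts_window):
                if priority.index(cat) < priority.index(best_cat):
                    best_cat, best_gene = cat, gene.gene_id
        if best_gene is None:
            near = min(
                by_chrom[pk.chrom],
                key=lambda g: (min(abs(mid - g.start), abs(mid - g.end)), g.gene_id),
                default=None,
            )
            nearest = near.gene_id if near is not None else None
        else:
            nearest = best_gene
        rows.append(
            {
                "peak_id": pk.name,
                "category": best_cat,
                "gene_id": best_gene,
                "nearest_gene": nearest,
                "midpoint": mid,
            }
        )
    return pd.DataFrame(rows)


def category_summary(annotation: pd.DataFrame, collapse: bool = True) -> pd.Series:
    """Fraction of peaks per category (Fig-style bar chart input).

    With ``collapse`` the fine categories fold into exonic / intronic /
    3'UTR / intergenic: 5'UTR, CDS, TSS and TTS all report as exonic.
    """
    cats = annotation["category"]
    if collapse:
        mapping = {
            "5'UTR": "exonic",
            "CDS": "exonic",
            "TSS": "exonic",
            "TTS": "exonic",
            "3'UTR": "3'UTR",
            "intron": "intronic",
            "intergenic": "intergenic",
        }
        cats = cats.map(mapping)
    frac = cats.value_counts(normalize=True)
    return frac


def metagene_profile(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    bins_per_segment: int = 50,
) -> pd.DataFrame:
    """Peak-midpoint density over the normalized 5'UTR|CDS|3'UTR axis.

    Only peaks whose midpoint falls in an exon of an annotated gene
    contribute.  Each contributing peak adds mass 1/n to the bin holding its
    normalized segment position, so the densities sum to 1.  Transcripts
    lacking a UTR simply contribute to the segments they have (logged).
    """
    if bins_per_segment < 1:
        raise ValueError("bins_per_segment must be >= 1")
    # one representative transcript per gene: the longest mature transcript
    rep: dict[str, GeneModel] = {}
    for g in genes:
        cur = rep.get(g.gene_id)
        if cur is None or g.mature_length > cur.mature_length:
            rep[g.gene_id] = g
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in rep.values():
        by_chrom.setdefault(g.chrom, []).append(g)

    counts = np.zeros(3 * bins_per_segment)
    n_used = 0
    for pk in peaks.itertuples():
        mid = _midpoint(pk.start, pk.end)
        for gene in by_chrom.get(pk.chrom, []):
            t = gene.genomic_to_transcript(mid)
            if t is None:
                continue
            seg = gene.segment_of(t)
            seg_len = {
                "5'UTR": gene.utr5_length,
                "CDS": gene.cds_length,
                "3'UTR": gene.utr3_length,
            }[seg]
            seg_off = {"5'UTR": 0, "CDS": gene.cds_start, "3'UTR": gene.cds_end}[seg]
            if seg_len == 0:
                logger.info("gene %s lacks a %s; peak kept in adjacent segment", gene.gene_id, seg)
                continue
            frac = (t - seg_off) / seg_len
            b = min(int(frac * bins_per_segment), bins_per_segment - 1)
            counts[SEGMENTS.index(seg) * bins_per_segment + b] += 1
            n_used += 1
            break
    density = counts / counts.sum() if counts.sum() else counts
    seg_col = [s for s in SEGMENTS for _ in range(bins_per_segment)]
    pos = [(i + 0.5) / bins_per_segment for _ in SEGMENTS for i in range(bins_per_segment)]
    return pd.DataFrame(
        {"segment": seg_col, "segment_position": pos, "density": density}
    )


def segment_mass(profile: pd.DataFrame) -> dict[str, float]:
    return profile.groupby("segment", sort=False)["density"].sum().to_dict()


def peak_gene_map(annotation: pd.DataFrame) -> dict[str, str | None]:
    return dict(zip(annotation["peak_id"], annotation["gene_id"]))
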