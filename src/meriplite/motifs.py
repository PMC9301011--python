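"""IUPAC motif scanning and exact enrichment statistics.

The m6A consensus is RRACH (R = A/G, H = A/C/U); GGACU is its canonical
instance.  Scanning is confirmatory — stated motifs are matched directly
against sequences, with U and T treated as the same base — and enrichment of
a motif in peak sequences over background sequences is assessed with a
one-sided hypergeometric test on per-sequence presence/absence, adjusted
with Benjamini-Hochberg when several motifs are tested together.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


def bh_adjust(pvalues) -> "pd.Series | list[float]":
    """Benjamini-Hochberg adjusted q-values (delegates to statsmodels)."""
    return multipletests(list(pvalues), method="fdr_bh")[1]


def _motif_sets(motif: str) -> list[frozenset]:
    sets = []
    for code in motif.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}")
        sets.append(frozenset(IUPAC[code]))
    return sets


def scan_motif(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions of ``motif``.

    ``sequence`` may contain U or T (equivalent); N in the sequence matches
    nothing except the N code.
    """
    sets = _motif_sets(motif)
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    k = len(sets)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


def motif_enrichment(
    peak_seqs: list[str],
    background_seqs: list[str],
    motifs: str | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of motifs in peaks.

    Presence/absence is scored per sequence; the population is the pooled
    peak + background set, successes are sequences containing the motif, and
    the draw is the peak set.  Returns one row per motif with k/n, K/N, the
    exact upper-tail p-value, and BH-adjusted q across the tested motifs.
    """
    if not peak_seqs or not background_seqs:
        raise ValueError("peak and background sequence sets must be non-empty")
    if isinstance(motifs, str):
        motifs = [motifs]
    rows = []
    n = len(peak_seqs)
    N = n + len(background_seqs)
    for motif in motifs:
        k = sum(bool(scan_motif(s, motif)) for s in peak_seqs)
        K = k + sum(bool(scan_motif(s, motif)) for s in background_seqs)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"motif": motif, "peak_hits": k, "peak_n": n, "pool_hits": K, "pool_n": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def ora_enrichment(
    gene_list: list[str] | set[str],
    gene_sets: dict[str, set[str] | list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene sets.

    Gene sets are intersected with the universe first; p is the one-sided
    upper tail, q the BH adjustment across sets.  Sorted by p.
    """
    universe = set(universe)
    hits = set(gene_list) & universe
    if not hits or not universe:
        raise ValueError("gene list and universe must be non-empty")
    if not set(gene_list) <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe)
        k = len(set(members) & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set": name, "overlap": k, "set_size": K, "list_size": n, "universe": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
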