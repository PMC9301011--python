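"""Differential methylation by the fold-change criterion.

Peaks whose group-B mean methylation level is at least ``threshold`` times
the group-A mean are "up"; those at most 1/threshold times are "down"; the
rest are "unchanged".  The boundary is inclusive (fold-change >= 1.5 is up)
and the default threshold is 1.5.  The criterion is threshold-based only —
no variance test is applied — so the per-group replicate standard deviation
is carried in the output for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import MethylationLevelMatrix

DEFAULT_FOLD = 1.5


def group_mean_levels(
    m: MethylationLevelMatrix | pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Arithmetic mean (and SD) of levels per peak within each group.

    ``groups`` maps every sample to its condition label.  Returns a frame
    with columns ``mean_<g>`` and ``sd_<g>`` per group.
    """
    levels = m.level if isinstance(m, MethylationLevelMatrix) else m
    if levels is None:
        raise ValueError("levels not computed")
    missing = set(levels.columns) - set(groups)
    if missing:
        raise ValueError(f"samples missing from the group map: {sorted(missing)}")
    out = {}
    for g in dict.fromkeys(groups.values()):  # preserve insertion order
        cols = [s for s in levels.columns if groups[s] == g]
        if not cols:
            continue
        out[f"mean_{g}"] = levels[cols].mean(axis=1)
        out[f"sd_{g}"] = levels[cols].std(axis=1, ddof=1) if len(cols) > 1 else 0.0
    return pd.DataFrame(out, index=levels.index)


def classify_differential(
    means: pd.DataFrame,
    group_a: str,
    group_b: str,
    threshold: float = DEFAULT_FOLD,
) -> pd.DataFrame:
    """Trichotomous up/down/unchanged classification of fold = B/A.

    Peaks with a non-finite fold (e.g. zero group-A mean without a
    pseudocount) are flagged ``excluded`` rather than silently dropped.
    """
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    a = means[f"mean_{group_a}"]
    b = means[f"mean_{group_b}"]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = b / a
    cls = np.where(
        ~np.isfinite(fold),
        "excluded",
        np.where(fold >= threshold, "up", np.where(fold <= 1.0 / threshold, "down", "unchanged")),
    )
    return pd.DataFrame(
        {
            "mean_A": a,
            "mean_B": b,
            "fold": fold,
            "class": cls,
        },
        index=means.index,
    )


def class_counts(calls: pd.DataFrame) -> dict[str, int]:
    c = calls["class"].value_counts().to_dict()
    return {k: int(c.get(k, 0)) for k in ("up", "down", "unchanged", "excluded")}


def peaks_to_genes(calls: pd.DataFrame, peak_to_gene: dict[str, str | None]) -> pd.DataFrame:
    """De-duplicated per-gene summary of up/down methylated peaks.

    ``peak_to_gene`` maps peak names to gene ids (None for intergenic peaks,
    which are reported under the pseudo-gene ``<intergenic>``).  A gene with
    both up and down peaks appears with ``both=True``.
    """
    rows: dict[str, dict] = {}
    for peak, row in calls.iterrows():
        if row["class"] not in ("up", "down"):
            continue
        gene = peak_to_gene.get(peak) or "<intergenic>"
        rec = rows.setdefault(gene, {"gene_id": gene, "up_peaks": 0, "down_peaks": 0})
        rec[f"{row['class']}_peaks"] += 1
    out = pd.DataFrame(rows.values(), columns=["gene_id", "up_peaks", "down_peaks"])
    if len(out):
        out["both"] = (out["up_peaks"] > 0) & (out["down_peaks"] > 0)
    else:
        out["both"] = pd.Series(dtype=bool)
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def gene_lists(gene_table: pd.DataFrame) -> dict[str, list[str]]:
    """Up/down gene lists (a both-gene appears in both lists)."""
    real = gene_table[gene_table["gene_id"] != "<intergenic>"]
    return {
        "up": sorted(real.loc[real["up_peaks"] > 0, "gene_id"]),
        "down": sorted(real.loc[real["down_peaks"] > 0, "gene_id"]),
    }
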