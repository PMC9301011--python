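"""End-to-end orchestration: simulate -> peaks -> levels -> differential ->
annotation -> metagene -> motif (-> ORA), from one declarative config.

Every stage writes its table into the run directory and the whole run is
summarized in ``summary.json`` (peak counts, class counts, category
fractions, correlation block means, parameters and seed), so two runs with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import differential as diff
from . import motifs
from . import peaks as pk
from . import quantify as qt
from .genes import read_fasta, read_gtf, write_fasta, write_gtf
from .io import load_libraries, read_gmt, read_sample_sheet
from .simulate import plant_m6a_sites, simulate_fragments, simulate_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative run configuration; round-trips losslessly through YAML."""

    outdir: str = "run"
    seed: int = 0
    # simulation (used when sample_sheet is None)
    simulate: bool = True
    n_genes: int = 200
    sites_per_gene: int = 1
    beta: float = 8.0
    fraction_up: float = 0.25
    fraction_down: float = 0.25
    fold: float = 3.0
    depth: int = 100_000
    dispersion: float = 10.0
    replicates: int = 2
    conditions: tuple[str, str] = ("SPF", "GF")
    # real-data inputs (used when simulate is False)
    sample_sheet: str | None = None
    annotation_gtf: str | None = None
    genome_fasta: str | None = None
    gene_sets_gmt: str | None = None
    # analysis parameters
    caller_window: int = 200
    caller_step: int = 50
    caller_min_fold: float = 2.0
    caller_min_count: int = 10
    caller_fdr: float = 0.05
    pseudocount: float = 1.0
    fold_threshold: float = 1.5
    bins_per_segment: int = 50
    motifs: tuple[str, ...] = ("RRACH", "GGACU")

    def validate(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not self.simulate:
            for p in (self.sample_sheet, self.annotation_gtf, self.genome_fasta):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input path missing: {p}")
        if self.gene_sets_gmt is not None and not Path(self.gene_sets_gmt).exists():
            raise FileNotFoundError(self.gene_sets_gmt)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["motifs"] = list(self.motifs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "motifs" in d:
            d["motifs"] = tuple(d["motifs"])
        return cls(**d)


def _background_sequences(peaks: pd.DataFrame, genome: dict[str, str], seed: int) -> list[str]:
    """Length-matched random windows from the same chromosomes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    out = []
    for r in peaks.itertuples():
        L = r.end - r.start
        size = len(genome[r.chrom])
        s = int(rng.integers(0, max(size - L, 1)))
        out.append(genome[r.chrom][s : s + L])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "parameters": asdict(config), "stages": {}}
    t_all = time.time()

    def stage(name):
        logger.info("stage %s", name)
        summary["stages"][name] = {"t_start": round(time.time() - t_all, 2)}
        return time.time()

    try:
        # -- inputs ---------------------------------------------------------
        t0 = stage("inputs")
        if config.simulate:
            genes, genome = simulate_genome(config.n_genes, seed=config.seed)
            truth = plant_m6a_sites(
                genes,
                genome,
                sites_per_gene=config.sites_per_gene,
                beta_range=(config.beta, config.beta),
                fraction_up=config.fraction_up,
                fraction_down=config.fraction_down,
                fold=config.fold,
                seed=config.seed,
            )
            libraries = simulate_fragments(
                truth,
                conditions=config.conditions,
                replicates=config.replicates,
                depth=config.depth,
                dispersion=config.dispersion,
                seed=config.seed,
            )
            groups = {
                f"{c}_r{k}": c
                for c in config.conditions
                for k in range(1, config.replicates + 1)
            }
            write_fasta(genome, str(outdir / "genome.fa"))
            write_gtf(genes, str(outdir / "genes.gtf"))
            truth.to_tsv(str(outdir / "truth.tsv"))
            for (s, kind), lib in libraries.items():
                lib.to_bed(str(outdir / f"{s}_{kind}.bed"))
        else:
            sheet = read_sample_sheet(config.sample_sheet)
            libraries = load_libraries(sheet)
            groups = dict(zip(sheet["sample_id"], sheet["condition"]))
            genes = read_gtf(config.annotation_gtf)
            genome = read_fasta(config.genome_fasta)
            truth = None
        chrom_sizes = {c: len(s) for c, s in genome.items()}

        # -- per-sample peak calling and merging -----------------------------
        stage("callpeaks")
        samples = sorted({s for (s, kind) in libraries if kind == "IP"})
        per_sample = {}
        for s in samples:
            per_sample[s] = pk.call_peaks_window(
                libraries[(s, "IP")],
                libraries[(s, "input")],
                window=config.caller_window,
                step=config.caller_step,
                min_fold=config.caller_min_fold,
                min_count=config.caller_min_count,
                fdr=config.caller_fdr,
                chrom_sizes=chrom_sizes,
            )
            pk.write_peaks_bed(per_sample[s], str(outdir / f"{s}_peaks.bed"))
        stage("merge")
        merged = pk.merge_peaks(per_sample.values())
        pk.write_peaks_bed(merged, str(outdir / "merged_peaks.bed"))
        summary["peaks"] = {
            "per_sample": {s: int(len(p)) for s, p in per_sample.items()},
            "merged": int(len(merged)),
        }

        # -- quantification ---------------------------------------------------
        stage("quantify")
        counts = qt.count_matrix(merged, libraries)
        levels = qt.methylation_level(
            qt.compute_normalized_counts(counts), pseudocount=config.pseudocount
        )
        levels.level.to_csv(outdir / "levels.tsv", sep="\t")
        stage("similarity")
        corr, n_excl = qt.sample_similarity(levels)
        corr.to_csv(outdir / "sample_correlation.tsv", sep="\t")
        cond_of = groups
        within, cross = [], []
        for i, a in enumerate(corr.index):
            for b in corr.columns[i + 1 :]:
                (within if cond_of[a] == cond_of[b] else cross).append(float(corr.loc[a, b]))
        summary["similarity"] = {
            "excluded_peaks": n_excl,
            "mean_within_condition_r": float(np.mean(within)) if within else None,
            "mean_cross_condition_r": float(np.mean(cross)) if cross else None,
        }

        # -- differential -----------------------------------------------------
        stage("differential")
        means = diff.group_mean_levels(levels, groups)
        calls = diff.classify_differential(
            means, config.conditions[0], config.conditions[1], threshold=config.fold_threshold
        )
        calls.to_csv(outdir / "differential.tsv", sep="\t")
        summary["differential"] = diff.class_counts(calls)

        # -- annotation / metagene -------------------------------------------
        stage("annotate")
        annotation = ann.annotate_peaks(merged, genes)
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        summary["categories"] = {
            k: round(float(v), 4) for k, v in ann.category_summary(annotation).items()
        }
        gene_table = diff.peaks_to_genes(calls, ann.peak_gene_map(annotation))
        gene_table.to_csv(outdir / "differential_genes.tsv", sep="\t", index=False)
        lists = diff.gene_lists(gene_table)
        summary["genes"] = {"up": len(lists["up"]), "down": len(lists["down"])}

        stage("metagene")
        profile = ann.metagene_profile(merged, genes, bins_per_segment=config.bins_per_segment)
        profile.to_csv(outdir / "metagene.tsv", sep="\t", index=False)
        summary["metagene_segment_mass"] = {
            k: round(float(v), 4) for k, v in ann.segment_mass(profile).items()
        }

        # -- motif -----------------------------------------------------------
        stage("motif")
        peak_seqs = [genome[r.chrom][r.start : r.end] for r in merged.itertuples()]
        if peak_seqs:
            bg = _background_sequences(merged, genome, config.seed)
            motif_res = motifs.motif_enrichment(peak_seqs, bg, list(config.motifs))
            motif_res.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
            summary["motif"] = {
                r["motif"]: {"p": float(r["p"]), "q": float(r["q"])}
                for _, r in motif_res.iterrows()
            }

        # -- ORA (optional) ---------------------------------------------------
        if config.gene_sets_gmt is not None:
            stage("ora")
            sets = read_gmt(config.gene_sets_gmt)
            universe = {g.gene_id for g in genes}
            if lists["up"]:
                ora = motifs.ora_enrichment(lists["up"], sets, universe)
                ora.to_csv(outdir / "ora_up.tsv", sep="\t", index=False)
                summary["ora_top_set"] = str(ora.iloc[0]["gene_set"]) if len(ora) else None

        # -- truth-based evaluation (simulation runs only) ---------------------
        if truth is not None and len(truth.sites):
            stage("evaluate")
            summary["recovery"] = evaluate_against_truth(calls, merged, truth.sites)

    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        failed = list(summary["stages"])[-1] if summary["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t_all, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def evaluate_against_truth(
    calls: pd.DataFrame, merged: pd.DataFrame, sites: pd.DataFrame
) -> dict:
    """Per-class sensitivity and FDR of peak calls against planted sites.

    Each planted site is matched to the merged peak containing its genomic
    position (if any); sensitivity of a class is the fraction of its sites
    whose peak carries that call, FDR the fraction of peaks with that call
    whose matched site (if any) is of a different class.
    """
    peak_of_site = {}
    by_chrom = {c: g.sort_values("start") for c, g in merged.groupby("chrom")}
    for r in sites.itertuples():
        grp = by_chrom.get(r.chrom)
        if grp is None:
            continue
        hit = grp[(grp["start"] <= r.pos) & (r.pos < grp["end"])]
        if len(hit):
            peak_of_site[r.site_id] = hit.iloc[0]["name"]
    site_class = dict(zip(sites["site_id"], sites["class"]))
    truth_of_peak: dict[str, str] = {}
    for sid, pname in peak_of_site.items():
        truth_of_peak[pname] = site_class[sid]

    out = {"site_peak_match_rate": round(len(peak_of_site) / len(sites), 4)}
    for cls in ("up", "down"):
        n_sites = int((sites["class"] == cls).sum())
        tp = sum(
            1
            for sid, pname in peak_of_site.items()
            if site_class[sid] == cls and calls.loc[pname, "class"] == cls
        )
        called = calls[calls["class"] == cls].index
        fp = sum(1 for pname in called if truth_of_peak.get(pname) != cls)
        out[f"{cls}_sensitivity"] = round(tp / n_sites, 4) if n_sites else None
        out[f"{cls}_fdr"] = round(fp / len(called), 4) if len(called) else 0.0
    return out
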