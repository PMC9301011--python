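"""Readers and writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

import pandas as pd

from .simulate import FragmentSet, read_bed_fragments

SAMPLE_SHEET_COLUMNS = ["sample_id", "condition", "ip_path", "input_path"]


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str) -> None:
    df[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def load_libraries(sheet: pd.DataFrame) -> dict[tuple[str, str], FragmentSet]:
    libs = {}
    for r in sheet.itertuples():
        libs[(r.sample_id, "IP")] = read_bed_fragments(r.ip_path, r.sample_id, "IP")
        libs[(r.sample_id, "input")] = read_bed_fragments(r.input_path, r.sample_id, "input")
    return libs


def read_gmt(path: str) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str] | list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, name, *sorted(members)]) + "\n")
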