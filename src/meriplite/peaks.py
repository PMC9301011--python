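"""Peak calling, merging and fragment counting.

The caller is a sliding-window binomial test of IP counts against the
expectation implied by the input library: a window with ``m`` IP fragments is
tested one-sidedly against Binomial(N_IP, input_m / N_input), windows are
filtered on minimum fold enrichment and count, BH-adjusted across windows,
and surviving windows are merged into peaks.  Per-sample peak sets are then
unioned across samples ("peaks identified in all samples were merged") so
one consistent peak catalogue is quantified in every library.

Peaks are plain DataFrames with columns ``chrom, start, end, name`` (plus
``samples`` after merging); coordinates are 0-based half-open as in BED.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .simulate import FragmentSet

PEAK_COLUMNS = ["chrom", "start", "end", "name"]


def _validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    if (peaks["end"] <= peaks["start"]).any():
        bad = peaks[peaks["end"] <= peaks["start"]].iloc[0]
        raise ValueError(f"malformed interval [{bad['start']}, {bad['end']}) on {bad['chrom']}")
    return peaks


def _window_counts(starts: np.ndarray, ends: np.ndarray, w_starts: np.ndarray, w_ends: np.ndarray) -> np.ndarray:
    """Number of fragments overlapping each window, by sorted searchsorted.

    A fragment [s, e) overlaps window [a, b) iff s < b and e > a.
    """
    s_sorted = np.sort(starts)
    e_sorted = np.sort(ends)
    return np.searchsorted(s_sorted, w_ends, side="left") - np.searchsorted(
        e_sorted, w_starts, side="right"
    )


def call_peaks_window(
    ip: FragmentSet,
    input_lib: FragmentSet,
    window: int = 200,
    step: int = 50,
    min_fold: float = 2.0,
    min_count: int = 10,
    fdr: float = 0.05,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window binomial enrichment caller for one IP/input pair."""
    if input_lib.library_total == 0:
        raise ValueError("input library is empty; enrichment expectation undefined")
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")

    n_ip = ip.library_total
    n_in = input_lib.library_total
    out = []
    ip_by = dict(tuple(ip.fragments.groupby("chrom", sort=False)))
    in_by = dict(tuple(input_lib.fragments.groupby("chrom", sort=False)))
    chroms = chrom_sizes or {
        c: int(max(df["end"].max() for df in (ip_by.get(c), in_by.get(c)) if df is not None))
        for c in set(ip_by) | set(in_by)
    }

    for chrom in sorted(chroms):
        size = chroms[chrom]
        w_starts = np.arange(0, max(size - window, 0) + step, step)
        w_ends = np.minimum(w_starts + window, size)
        ip_df = ip_by.get(chrom)
        in_df = in_by.get(chrom)
        m_ip = (
            _window_counts(ip_df["start"].to_numpy(), ip_df["end"].to_numpy(), w_starts, w_ends)
            if ip_df is not None
            else np.zeros(len(w_starts), dtype=int)
        )
        m_in = (
            _window_counts(in_df["start"].to_numpy(), in_df["end"].to_numpy(), w_starts, w_ends)
            if in_df is not None
            else np.zeros(len(w_starts), dtype=int)
        )
        # expected IP proportion from the input library; half-count floor so
        # windows with zero input coverage still have a defined expectation
        p0 = np.maximum(m_in, 0.5) / n_in
        fold = (m_ip / n_ip) / p0
        pvals = binom.sf(m_ip - 1, n_ip, p0)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": w_starts,
                    "end": w_ends,
                    "ip_count": m_ip,
                    "input_count": m_in,
                    "fold": fold,
                    "p": pvals,
                }
            )
        )

    windows = pd.concat(out, ignore_index=True)
    if windows.empty or int(windows["ip_count"].sum()) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    windows["q"] = multipletests(windows["p"], method="fdr_bh")[1]
    keep = windows[
        (windows["q"] <= fdr) & (windows["fold"] >= min_fold) & (windows["ip_count"] >= min_count)
    ]
    if keep.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    merged = merge_peaks([keep[["chrom", "start", "end"]]])
    merged["name"] = [f"{ip.sample_id}_peak{i + 1}" for i in range(len(merged))]
    return merged[PEAK_COLUMNS]


def merge_peaks(peak_sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union of overlapping-or-touching intervals across peak sets.

    Provenance: if input frames carry a ``name`` column prefixed by a sample
    id, the merged ``samples`` column lists contributing inputs.  Output is
    sorted by (chrom, start) and renamed peak1..peakN.
    """
    frames = []
    for i, df in enumerate(peak_sets):
        if df is None or len(df) == 0:
            continue
        d = df[["chrom", "start", "end"]].copy()
        d["source"] = df["name"].str.rsplit("_peak", n=1).str[0] if "name" in df else f"set{i}"
        frames.append(_validate_peaks(d))
    if not frames:
        return pd.DataFrame(columns=[*PEAK_COLUMNS, "samples"])
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        cur_s = cur_e = None
        sources: set = set()
        for r in grp.itertuples():
            if cur_s is None:
                cur_s, cur_e, sources = r.start, r.end, {r.source}
            elif r.start <= cur_e:  # overlap or touch
                cur_e = max(cur_e, r.end)
                sources.add(r.source)
            else:
                rows.append((chrom, cur_s, cur_e, ",".join(sorted(sources))))
                cur_s, cur_e, sources = r.start, r.end, {r.source}
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, ",".join(sorted(sources))))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "samples"])
    out.insert(3, "name", [f"peak{i + 1}" for i in range(len(out))])
    return out


def count_fragments(
    peaks: pd.DataFrame,
    library: FragmentSet,
    mode: str = "single",
) -> tuple[pd.Series, int]:
    """Fragments per peak plus the library total (all mapped fragments).

    A fragment counts toward a peak when they overlap by >= 1 nt.  Under the
    default ``single`` mode a fragment overlapping several peaks is assigned
    once, to the peak with the largest overlap (leftmost peak on ties);
    ``all`` counts it in every overlapped peak.  Peaks must be
    non-overlapping per chromosome in ``single`` mode — merge first.
    """
    if mode not in ("single", "all"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    peaks = _validate_peaks(peaks)
    counts = pd.Series(0, index=peaks["name"].to_numpy(), dtype=int)

    for chrom, pk in peaks.groupby("chrom", sort=False):
        pk = pk.sort_values("start", kind="mergesort")
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        if mode == "single" and (ps[1:] < pe[:-1]).any():
            raise ValueError("overlapping peaks under single-assignment counting; merge first")
        names = pk["name"].to_numpy()
        fr = library.fragments[library.fragments["chrom"] == chrom]
        if fr.empty:
            continue
        fs = fr["start"].to_numpy()
        fe = fr["end"].to_numpy()
        # candidate peak index range for each fragment
        lo = np.searchsorted(pe, fs, side="right")
        hi = np.searchsorted(ps, fe, side="left")
        n_cand = hi - lo
        one = n_cand == 1
        if mode == "all":
            for i in np.nonzero(n_cand >= 1)[0]:
                for j in range(lo[i], hi[i]):
                    counts[names[j]] += 1
            continue
        # common case: exactly one candidate peak
        idx, cnt = np.unique(lo[one], return_counts=True)
        for j, c in zip(idx, cnt):
            counts[names[j]] += int(c)
        # fragments spanning several peaks: largest overlap, leftmost on ties
        for i in np.nonzero(n_cand > 1)[0]:
            js = np.arange(lo[i], hi[i])
            ov = np.minimum(fe[i], pe[js]) - np.maximum(fs[i], ps[js])
            counts[names[js[int(np.argmax(ov))]]] += 1
    return counts, library.library_total


def write_peaks_bed(peaks: pd.DataFrame, path: str) -> None:
    df = peaks.copy()
    df["score"] = 0
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_peaks_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :4]
    df.columns = PEAK_COLUMNS
    return _validate_peaks(df)
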