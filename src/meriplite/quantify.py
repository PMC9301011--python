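"""Per-peak normalized fragment counts and methylation levels.

For each merged peak of length L, the IP library's normalized count is

    MFPKM = ip_count * 1e9 / (L * N_IP)

and the input library's is

    IFPKM = input_count * 1e9 / (L * N_input),

where N is the total number of mapped fragments in that library (not only
in-peak fragments).  The per-peak methylation level is MFPKM / IFPKM; with a
pseudocount eps the level is (MFPKM + eps_M) / (IFPKM + eps_I) where each
eps is by default the normalized value of a single fragment in that library
(1e9 / (L * N)), so peak length still cancels exactly in the ratio.

Sample similarity is the Pearson correlation of log2 levels across peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import count_fragments
from .simulate import FragmentSet

SCALE = 1e9


@dataclass
class PeakCountMatrix:
    """Per-peak IP and input fragment counts with library totals."""

    ip_counts: pd.DataFrame  # peaks x samples
    input_counts: pd.DataFrame
    ip_totals: pd.Series  # per sample
    input_totals: pd.Series
    peak_lengths: pd.Series  # per peak

    def __post_init__(self) -> None:
        if (self.peak_lengths < 1).any():
            raise ValueError("peak lengths must be >= 1")
        if (self.ip_totals < 1).any() or (self.input_totals < 1).any():
            raise ValueError("library totals must be >= 1")

    @property
    def samples(self) -> list[str]:
        return list(self.ip_counts.columns)


@dataclass
class MethylationLevelMatrix:
    """MFPKM, IFPKM and (once computed) the per-peak methylation level."""

    mfpkm: pd.DataFrame
    ifpkm: pd.DataFrame
    peak_lengths: pd.Series
    ip_totals: pd.Series
    input_totals: pd.Series
    level: pd.DataFrame | None = None
    raw_ratio: pd.DataFrame | None = None


def count_matrix(
    peaks: pd.DataFrame,
    libraries: dict[tuple[str, str], FragmentSet],
    mode: str = "single",
) -> PeakCountMatrix:
    """Count every sample's IP and input libraries over one merged peak set."""
    samples = sorted({s for (s, kind) in libraries if kind == "IP"})
    ip_c, in_c, ip_t, in_t = {}, {}, {}, {}
    for s in samples:
        c, t = count_fragments(peaks, libraries[(s, "IP")], mode=mode)
        ip_c[s], ip_t[s] = c, t
        c, t = count_fragments(peaks, libraries[(s, "input")], mode=mode)
        in_c[s], in_t[s] = c, t
    lengths = pd.Series(
        (peaks["end"] - peaks["start"]).to_numpy(), index=peaks["name"].to_numpy()
    )
    return PeakCountMatrix(
        ip_counts=pd.DataFrame(ip_c),
        input_counts=pd.DataFrame(in_c),
        ip_totals=pd.Series(ip_t),
        input_totals=pd.Series(in_t),
        peak_lengths=lengths,
    )


def compute_normalized_counts(counts: PeakCountMatrix) -> MethylationLevelMatrix:
    """Fill MFPKM and IFPKM from raw counts, lengths and library totals."""
    L = counts.peak_lengths.to_numpy()[:, None]
    mf = counts.ip_counts * SCALE / (L * counts.ip_totals.to_numpy()[None, :])
    inf = counts.input_counts * SCALE / (L * counts.input_totals.to_numpy()[None, :])
    return MethylationLevelMatrix(
        mfpkm=mf,
        ifpkm=inf,
        peak_lengths=counts.peak_lengths,
        ip_totals=counts.ip_totals,
        input_totals=counts.input_totals,
    )


def methylation_level(
    m: MethylationLevelMatrix, pseudocount: float | None = None
) -> MethylationLevelMatrix:
    """Fill the per-peak methylation level MFPKM / IFPKM.

    ``pseudocount`` is in fragment-count units: the additive offsets are
    its normalized value in each library, pseudocount * 1e9 / (L * N).  The
    default of 1 is the normalized weight of a single fragment; 0 gives the
    raw ratio (infinite where IFPKM is 0).  The unshifted ratio is kept in
    ``raw_ratio`` wherever IFPKM > 0.
    """
    if pseudocount is None:
        pseudocount = 1.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    L = m.peak_lengths.to_numpy()[:, None]
    eps_m = pseudocount * SCALE / (L * m.ip_totals.to_numpy()[None, :])
    eps_i = pseudocount * SCALE / (L * m.input_totals.to_numpy()[None, :])
    m.level = (m.mfpkm + eps_m) / (m.ifpkm + eps_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        m.raw_ratio = m.mfpkm / m.ifpkm.where(m.ifpkm > 0)
    return m


def sample_similarity(m: MethylationLevelMatrix) -> tuple[pd.DataFrame, int]:
    """Pearson correlation matrix of log2 methylation levels.

    Peaks whose level is non-finite or non-positive in any sample are
    excluded; the number excluded is returned alongside.  Samples with zero
    variance after filtering get NaN correlations (flagged undefined).
    """
    if m.level is None:
        raise ValueError("levels not computed; call methylation_level first")
    if m.level.shape[1] < 2:
        raise ValueError("need at least two samples")
    lv = m.level
    ok = np.isfinite(lv).all(axis=1) & (lv > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    log_lv = np.log2(lv[ok])
    if log_lv.shape[0] < 3:
        raise ValueError("fewer than 3 peaks usable for correlation")
    sd = log_lv.std(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        corr_np = np.corrcoef(log_lv.to_numpy().T)
    corr_np[sd == 0, :] = np.nan
    corr_np[:, sd == 0] = np.nan
    np.fill_diagonal(corr_np, 1.0)
    corr = pd.DataFrame(corr_np, index=lv.columns, columns=lv.columns)
    return corr, n_excluded
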