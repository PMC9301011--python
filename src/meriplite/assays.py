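"""Assay-level calculators: qPCR, MeRIP-qPCR, mRNA decay and LC-MS/MS.

These implement the arithmetic behind four bench assays:

* relative expression by the 2^-ddCt method (replicates averaged, target Ct
  normalized to a reference gene, then to a calibrator group);
* m6A enrichment by MeRIP-qPCR, the IP/input ratio 2^-(Ct_IP - Ct_input)
  normalized to a housekeeping gene such as GAPDH in the same sample;
* first-order mRNA decay under transcription inhibition, fit on the log
  scale, with half-life t1/2 = ln 2 / k;
* the m6A/A nucleoside ratio from LC-MS peak areas via linear standard
  curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

LN2 = float(np.log(2.0))


# -- 2^-ddCt ----------------------------------------------------------------


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression per sample x gene by the ddCt method.

    ``table`` columns: sample_id, group, gene, ct (one row per replicate;
    replicates are averaged before dCt).  dCt = Ct_target - Ct_reference per
    sample; ddCt = dCt - mean dCt over the calibrator group's samples;
    relative expression = efficiency^-ddCt.  The per-group summary uses the
    geometric mean (efficiency^-(group mean ddCt)) so the calibrator group
    summarizes to exactly 1.
    """
    need = {"sample_id", "group", "gene", "ct"}
    if not need <= set(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(need)}")
    ct = table.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    ref = ct[ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    missing = set(targets["sample_id"]) - set(ref.index)
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} not measured in sample(s) {sorted(missing)}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()
    cal = targets[targets["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    cal_mean = cal.groupby("gene")["dct"].mean()
    targets["ddct"] = targets["dct"] - cal_mean.loc[targets["gene"]].to_numpy()
    targets["rel_expr"] = efficiency ** (-targets["ddct"])
    return targets.reset_index(drop=True)


def group_expression_summary(ddct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per group x gene: geometric-mean relative expression."""
    g = ddct_table.groupby(["group", "gene"], as_index=False)["ddct"].mean()
    g["rel_expr"] = efficiency ** (-g["ddct"])
    return g


# -- MeRIP-qPCR -------------------------------------------------------------


def merip_qpcr_enrichment(
    table: pd.DataFrame,
    normalizer_gene: str = "GAPDH",
    percent_input: bool = False,
) -> pd.DataFrame:
    """Relative m6A enrichment per gene per sample.

    ``table`` columns: sample_id, gene, library_kind (IP/input), ct.  The
    IP/input ratio per (sample, gene) is 2^-(Ct_IP - Ct_input); the reported
    enrichment divides it by the normalizer gene's ratio in the same sample.
    With ``percent_input`` the unnormalized ratio is also reported as a
    percentage of input.
    """
    need = {"sample_id", "gene", "library_kind", "ct"}
    if not need <= set(table.columns):
        raise ValueError(f"MeRIP-qPCR table must have columns {sorted(need)}")
    ct = table.groupby(["sample_id", "gene", "library_kind"], as_index=False)["ct"].mean()
    wide = ct.pivot_table(index=["sample_id", "gene"], columns="library_kind", values="ct")
    if "IP" not in wide or "input" not in wide or wide[["IP", "input"]].isna().any().any():
        bad = wide[wide.reindex(columns=["IP", "input"]).isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing IP or input Ct for {bad}")
    wide = wide.reset_index()
    wide["ratio"] = 2.0 ** (-(wide["IP"] - wide["input"]))
    norm = wide[wide["gene"] == normalizer_gene].set_index("sample_id")["ratio"]
    missing = set(wide["sample_id"]) - set(norm.index)
    if missing:
        raise ValueError(f"normalizer {normalizer_gene!r} missing in sample(s) {sorted(missing)}")
    wide["enrichment"] = wide["ratio"].to_numpy() / norm.loc[wide["sample_id"]].to_numpy()
    if percent_input:
        wide["percent_input"] = 100.0 * wide["ratio"]
    return wide


# -- mRNA decay -------------------------------------------------------------


@dataclass
class DecayFit:
    """First-order decay fit: rate k (per hour), half-life and log-scale R2."""

    gene: str
    k: float
    half_life: float  # hours; inf when not estimable
    r_squared: float
    n_points: int
    estimable: bool
    note: str = ""


def fit_decay(
    timepoints: np.ndarray | list[float],
    expression: np.ndarray | list[float],
    gene: str = "",
    k_tolerance: float = 1e-9,
) -> DecayFit:
    """Fit y = exp(-k t) by least squares on ln y.

    Expression must already be normalized to the reference gene and to the
    0 h timepoint (so y(0) ~ 1).  Points with y <= 0 are excluded and
    counted in the note; fewer than 3 usable points, or a non-positive rate
    estimate, yields a not-estimable fit.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(expression, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and expression must have equal length")
    ok = y > 0
    n_dropped = int((~ok).sum())
    note = f"{n_dropped} non-positive point(s) excluded" if n_dropped else ""
    t, y = t[ok], y[ok]
    if len(t) < 3:
        return DecayFit(gene, np.nan, np.inf, np.nan, len(t), False, note or "fewer than 3 usable points")
    res = linregress(t, np.log(y))
    k = -res.slope
    r2 = float(res.rvalue**2)
    if k <= k_tolerance:
        return DecayFit(gene, float(k), np.inf, r2, len(t), False, (note + "; " if note else "") + "no decay")
    return DecayFit(gene, float(k), LN2 / float(k), r2, len(t), True, note)


def fit_decay_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every gene in a tidy (gene, time_h, expression) table."""
    fits = [
        fit_decay(grp["time_h"].to_numpy(), grp["expression"].to_numpy(), gene=g)
        for g, grp in table.groupby("gene", sort=True)
    ]
    return pd.DataFrame([vars(f) for f in fits])


# -- LC-MS/MS ---------------------------------------------------------------


def _calibrate(areas: np.ndarray, concs: np.ndarray, sample_area: float, label: str) -> float:
    if len(areas) < 2:
        raise ValueError(f"need >= 2 calibration points for {label}")
    res = linregress(concs, areas)
    if res.slope <= 0:
        raise ValueError(f"non-positive calibration slope for {label}")
    if not (min(areas) <= sample_area <= max(areas)):
        warnings.warn(
            f"{label} sample area {sample_area} outside calibration range "
            f"[{min(areas)}, {max(areas)}]",
            stacklevel=3,
        )
    return (sample_area - res.intercept) / res.slope


def m6a_ratio_lcms(
    sample_areas: dict[str, float],
    standards: dict[str, pd.DataFrame],
) -> dict[str, float]:
    """m6A/A ratio from LC-MS peak areas via linear standard curves.

    ``standards`` maps nucleoside name ("m6A", "A") to a frame with columns
    ``concentration`` and ``area``; concentrations are inferred by ordinary
    least squares (area vs concentration) and the ratio is conc(m6A) /
    conc(A).  A negative inferred m6A concentration is clamped to zero (with
    a warning); a non-positive A concentration is an error.
    """
    concs = {}
    for nuc in ("m6A", "A"):
        if nuc not in standards or nuc not in sample_areas:
            raise ValueError(f"standards and sample area required for {nuc}")
        std = standards[nuc]
        concs[nuc] = _calibrate(
            std["area"].to_numpy(dtype=float),
            std["concentration"].to_numpy(dtype=float),
            float(sample_areas[nuc]),
            nuc,
        )
    if concs["A"] <= 0:
        raise ValueError(f"inferred A concentration non-positive ({concs['A']:.4g})")
    if concs["m6A"] < 0:
        warnings.warn("inferred m6A concentration negative; clamped to 0", stacklevel=2)
        concs["m6A"] = 0.0
    return {"conc_m6A": concs["m6A"], "conc_A": concs["A"], "ratio": concs["m6A"] / concs["A"]}
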