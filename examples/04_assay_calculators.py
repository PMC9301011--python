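"""The four assay calculators on small worked inputs.

Relative expression (2^-ddCt), MeRIP-qPCR enrichment, mRNA half-life under
transcription inhibition, and the LC-MS m6A/A nucleoside ratio.
"""

import numpy as np
import pandas as pd

from meriplite import delta_delta_ct, fit_decay, m6a_ratio_lcms, merip_qpcr_enrichment

# 2^-ddCt: target amplifies one cycle earlier in the treated sample
ct = pd.DataFrame(
    {
        "sample_id": ["t1", "t1", "c1", "c1"],
        "group": ["treated", "treated", "control", "control"],
        "gene": ["Wnt4", "GAPDH", "Wnt4", "GAPDH"],
        "ct": [20.0, 15.0, 21.0, 15.0],
    }
)
res = delta_delta_ct(ct, reference_gene="GAPDH", calibrator_group="control")
print("ddCt fold change (treated vs control):",
      float(res.loc[res["sample_id"] == "t1", "rel_expr"].iloc[0]))
# 2.0 = one cycle earlier doubles the estimated starting template.

# MeRIP-qPCR: target IP/input ratio double the housekeeping ratio
merip = pd.DataFrame(
    {
        "sample_id": ["s1"] * 4,
        "gene": ["Wnt4", "Wnt4", "GAPDH", "GAPDH"],
        "library_kind": ["IP", "input", "IP", "input"],
        "ct": [24.0, 20.0, 25.0, 20.0],
    }
)
out = merip_qpcr_enrichment(merip, normalizer_gene="GAPDH")
print("m6A enrichment of Wnt4 over GAPDH:",
      float(out.loc[out["gene"] == "Wnt4", "enrichment"].iloc[0]))

# half-life from an actinomycin-D chase at 0/2/4/8 h
fit = fit_decay([0, 2, 4, 8], [1, 0.5, 0.25, 0.0625])
print(f"decay rate k = {fit.k:.4f}/h, half-life = {fit.half_life:.2f} h, R2 = {fit.r_squared:.3f}")

# LC-MS: linear standard curves, then the concentration ratio
conc = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
standards = {
    "m6A": pd.DataFrame({"concentration": conc, "area": 2.0 * conc}),
    "A": pd.DataFrame({"concentration": conc, "area": 2.0 * conc}),
}
lcms = m6a_ratio_lcms({"m6A": 4.0, "A": 8.0}, standards)
print("m6A/A ratio:", round(lcms["ratio"], 4))
# conc(m6A)=2, conc(A)=4 under the slope-2 curves -> ratio 0.5.
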