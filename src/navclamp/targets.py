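"""Published whole-cell and cut-open-oocyte group measurements used as
calibration targets and for the comparison tables.

Midpoints in mV; currents in pA (HEK) or nA; percentages relative to the
cell's maximum peak transient amplitude; charges in nC; the gating-pore
slope in nA per nC.
"""

from __future__ import annotations

REPORTED = {
    "WT": {
        "act_v_half_mV": -26.50,
        "inact_v_half_mV": -65.01,
        "persistent_pct": 0.57,
        "resurgent_pct": 2.39,
        "persistent_pA": -44.97,
        "resurgent_pA": -178.40,
        "max_peak_pA": -8750.0,
        "max_peak_density_pA_pF": -550.0,
        "qmax_nC": 0.85,
    },
    "R1882Q": {
        "act_v_half_mV": -24.77,
        "inact_v_half_mV": -57.34,
        "persistent_pct": 1.15,
        "resurgent_pct": 3.35,
        "persistent_pA": -100.80,
        "resurgent_pA": -284.80,
        "max_peak_pA": -8750.0,   # not different from WT
    },
    "R853Q": {
        "act_v_half_mV": -25.11,
        "inact_v_half_mV": -71.46,
        "persistent_pct": 0.26,
        "resurgent_pct": 1.55,
        "persistent_pA": -12.78,
        "resurgent_pA": -61.33,
        "max_peak_pA": -3820.0,
        "max_peak_density_pA_pF": -280.0,
        "qmax_nC": 0.44,
        "gp_slope_nA_per_nC": -118.0,
        "gp_pearson_r": -0.974,
        "gp_r2_adj": 0.943,
    },
}

ENDOGENOUS_PEAK_PA = -207.1
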