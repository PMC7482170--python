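"""Published per-strain mutation-rate table used as pipeline input.

Reported genome-wide mutation rates for gamma-irradiated Arabidopsis:
the wild-type control (1000 Gy) and the NHEJ-deficient AtKu70-/- and
AtLig4-/- mutants (100 Gy), as mean +/- SE per base pair on the 1e-8
scale over the seven event categories. "ND" entries (not detected) are
stored as 0. These numbers serve as inputs for desk-scale consistency
checks (per-Gy conversion, type fractions, fold changes) and for
parameterizing the synthetic strain profiles.
"""

from __future__ import annotations

import pandas as pd

GENOME_LENGTH_BP = 119_146_348

CATEGORIES = ["SBS", "Del1", "Ins1", "DelGE2", "InsGE2", "Complex", "SV"]

STRAIN_DOSES_GY = {"WT": 1000.0, "AtKu70": 100.0, "AtLig4": 100.0}

N_PLANTS = {"WT": 8, "AtKu70": 10, "AtLig4": 9}

# mean per-bp rates, 1e-8 scale
RATE_PER_BP_X1E8 = pd.DataFrame(
    {
        "SBS": [30.27, 4.02, 5.21],
        "Del1": [6.98, 0.34, 0.19],
        "Ins1": [1.67, 0.17, 0.0],
        "DelGE2": [6.28, 4.27, 4.84],
        "InsGE2": [0.56, 0.5, 0.19],
        "Complex": [3.21, 1.42, 1.12],
        "SV": [0.14, 0.0, 0.09],
        "Total": [49.10, 10.71, 11.62],
    },
    index=["WT", "AtKu70", "AtLig4"],
)

# standard errors, same scale
SE_PER_BP_X1E8 = pd.DataFrame(
    {
        "SBS": [3.36, 0.46, 0.95],
        "Del1": [1.20, 0.14, 0.12],
        "Ins1": [0.89, 0.11, 0.0],
        "DelGE2": [0.74, 0.55, 0.91],
        "InsGE2": [0.28, 0.19, 0.12],
        "Complex": [0.40, 0.25, 0.28],
        "SV": [0.14, 0.0, 0.09],
        "Total": [4.36, 0.61, 1.97],
    },
    index=["WT", "AtKu70", "AtLig4"],
)


def per_gy_table() -> pd.DataFrame:
    """Per-Gy rates (1e-10 scale) derived from the per-bp table.

    rate/bp/Gy = rate/bp divided by dose; the 1e-8 -> 1e-10 scale shift
    absorbs a factor of 100, so at 100 Gy the printed numbers coincide.
    """
    doses = pd.Series(STRAIN_DOSES_GY)
    return RATE_PER_BP_X1E8.mul(100.0 / doses, axis=0)


def fraction_table() -> pd.DataFrame:
    """Each category's share of the strain total (mutation-type pie)."""
    return RATE_PER_BP_X1E8[CATEGORIES].div(
        RATE_PER_BP_X1E8["Total"], axis=0
    )
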