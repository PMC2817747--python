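"""Bundled reference tables for the analysis.

`normal_breast_variability_panel` is the published 18-gene reference panel of
expression variability in healthy breast tissue (bilateral
reduction-mammaplasty donors, qPCR on median-centered log2 values): per gene
the overall standard deviation across all tissue specimens and the
decomposition of that SD into between-women, within-breast (slice) and
between-breasts-within-woman shares.  It serves as input for summary
statistics and for deriving control-referenced thresholds (e.g. the WFDC2
over-expression cutoff of mean + 3 x 2.73 = 8.19).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["normal_breast_variability_panel"]

# gene, overall SD, share between women (%), share within breast (%),
# share between breasts of the same woman (%)
_PANEL = [
    ("ASPN", 0.88, 75, 21, 3),
    ("CAV1", 0.89, 60, 38, 2),
    ("CFB", 0.74, 46, 46, 8),
    ("COL1A2", 1.13, 76, 15, 10),
    ("CTGF", 1.07, 67, 28, 6),
    ("GATA3", 1.61, 60, 36, 4),
    ("LETMD1", 0.46, 79, 11, 9),
    ("MGST1", 0.94, 59, 37, 4),
    ("LYZ", 1.08, 66, 23, 8),
    ("MMP2", 0.63, 50, 39, 10),
    ("MUC1", 2.34, 62, 34, 4),
    ("SPARC", 0.71, 74, 22, 3),
    ("SUMF2", 0.39, 55, 35, 7),
    ("TIMP1", 0.69, 65, 26, 9),
    ("TIMP2", 0.49, 63, 29, 7),
    ("TIMP3", 0.60, 67, 30, 3),
    ("WFDC2", 2.73, 61, 35, 4),
    ("YWHAZ", 0.37, 64, 30, 5),
]


def normal_breast_variability_panel() -> pd.DataFrame:
    """The 18-gene normal-breast variability panel.

    Returns a DataFrame with columns ``gene``, ``overall_sd`` and the
    component-SD shares ``share_women``, ``share_slice``, ``share_breast`` as
    fractions in [0, 1] (the printed percentages divided by 100).
    """
    frame = pd.DataFrame(
        _PANEL,
        columns=["gene", "overall_sd", "pct_women", "pct_slice", "pct_breast"],
    )
    for comp in ("women", "slice", "breast"):
        frame[f"share_{comp}"] = frame[f"pct_{comp}"] / 100.0
    return frame[["gene", "overall_sd", "share_women", "share_slice", "share_breast"]]
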