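"""Published statistics of the released florbetapir amyloid-network template.

The released template retained 17 replicable amyloid-beta networks out of 40
split-half matched component pairs; the remaining 23 pairs were excluded as
sub-threshold (pair correlation < 0.4), ventricular, white-matter, brain-edge
or reference-region (cerebellar) components.  For each retained network the
table below lists the split-half pair correlation, the network label, and
the age-association statistics (standardized beta and BH-FDR q) computed on
the florbetaben (FBB, n=173) and florbetapir (FBP, n=296) cohorts.  Rows
whose age association was negative are marked ``x-neg`` in the printed table;
their q entries are stored as NaN here and the sign lives in the beta column.

These printed values serve as worked-example inputs for the screening and
bookkeeping operations; nothing downstream re-estimates them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "template_table",
    "EXCLUSION_TALLY",
    "N_MATCHED_PAIRS",
    "N_RETAINED",
    "COHORT_SIZES",
]

#: split-half bookkeeping of the released template: 40 matched pairs in,
#: 17 networks retained, 23 excluded by reason
N_MATCHED_PAIRS = 40
N_RETAINED = 17
EXCLUSION_TALLY = {
    "below_threshold": 13,
    "ventricle": 4,
    "white_matter": 2,
    "edge": 2,
    "reference_region": 2,
}

COHORT_SIZES = {"FBP": 296, "FBP_group_A": 148, "FBP_group_B": 148, "FBB": 173}

_ROWS = [
    # corr, label, beta_fbb, q_fbb, beta_fbp, q_fbp  (None == x-neg)
    (0.50, "AU1", 0.17, 3.9e-2, -0.078, None),
    (0.45, "AU2", 0.302, 2.7e-4, 0.051, 0.46),
    (0.67, "SM1", 0.118, 0.15, -0.002, None),
    (0.54, "SM2", 0.169, 3.9e-2, 0.143, 3.1e-2),
    (0.52, "SM3", -0.061, None, -0.164, None),
    (0.71, "VIS1", 0.203, 1.8e-2, 0.151, 3.1e-2),
    (0.73, "VIS2", 0.057, 0.53, 0.204, 2.1e-3),
    (0.68, "VIS3", 0.026, 0.73, -0.049, None),
    (0.57, "VIS4", 0.32, 1.3e-4, 0.147, 3.1e-2),
    (0.53, "VIS5", 0.177, 3.7e-2, 0.040, 0.55),
    (0.52, "CC1", 0.428, 6.6e-8, 0.234, 5.1e-4),
    (0.62, "CC2", 0.151, 6.4e-2, 0.062, 0.39),
    (0.51, "CC3", -0.061, None, 0.118, 7.8e-2),
    (0.66, "DM1", 0.039, 0.66, 0.002, 0.97),
    (0.53, "DM2", 0.268, 1.4e-3, -0.010, None),
    (0.54, "DM3", 0.234, 5.9e-3, 0.072, 0.34),
    (0.54, "DM4", 0.183, 3.4e-2, -0.011, None),
]


def template_table() -> pd.DataFrame:
    """The published per-network statistics as a DataFrame.

    Columns: ``pair_correlation``, ``label``, ``beta_fbb``, ``q_fbb``,
    ``beta_fbp``, ``q_fbp``.  NaN q means the row was screened ``x-neg`` for
    that tracer.
    """
    frame = pd.DataFrame(
        _ROWS,
        columns=[
            "pair_correlation",
            "label",
            "beta_fbb",
            "q_fbb",
            "beta_fbp",
            "q_fbp",
        ],
    )
    return frame.astype(
        {
            "pair_correlation": float,
            "beta_fbb": float,
            "q_fbb": float,
            "beta_fbp": float,
            "q_fbp": float,
        }
    )


def tracer_frame(tracer: str) -> pd.DataFrame:
    """Association-style frame (unit, beta, q) for one tracer (FBB or FBP)."""
    t = tracer.lower()
    if t not in ("fbb", "fbp"):
        raise ValueError("tracer must be 'FBB' or 'FBP'")
    table = template_table()
    frame = pd.DataFrame(
        {
            "unit": table["label"],
            "beta": table[f"beta_{t}"],
            "q": table[f"q_{t}"],
        }
    )
    # NaN q rows are the printed x-neg entries; their beta is negative, so
    # screening reproduces the printed status from the sign alone.
    assert np.all(frame.loc[frame["q"].isna(), "beta"] < 0)
    return frame
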