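"""Disease-progression outcome: percent cartilage-volume change at 24 months.

Two sign conventions coexist in the literature: the loss formula
``(baseline − followup)/baseline × 100`` (loss positive) and the signed
change ``(followup − baseline)/baseline × 100`` (loss negative).  Reported
cohort tables use negative values for loss, so ``signed_change`` is the
default; the two conventions are exact negatives of each other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tables import validate_volumes

__all__ = ["percent_volume_change", "build_progression_table", "CONVENTIONS"]

CONVENTIONS = ("signed_change", "paper_loss")


def percent_volume_change(
    baseline, followup, convention: str = "signed_change"
):
    """Percent volume change between baseline and follow-up.

    Accepts scalars or arrays.  ``signed_change`` returns negative values
    for loss; ``paper_loss`` returns the literal loss formula (positive for
    loss).  Invariant to common rescaling of both volumes.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if (baseline <= 0).any():
        raise ValueError("baseline volume must be > 0")
    if (followup < 0).any():
        raise ValueError("follow-up volume must be >= 0")
    if convention == "signed_change":
        out = (followup - baseline) / baseline * 100.0
    elif convention == "paper_loss":
        out = (baseline - followup) / baseline * 100.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return out if out.ndim else float(out)


def build_progression_table(
    volumes: pd.DataFrame, convention: str = "signed_change"
) -> pd.DataFrame:
    """One progression row per (subject, compartment).

    The resulting ``pct_change`` column is the regression outcome of the
    ratio screen.
    """
    validate_volumes(volumes)
    out = volumes[["subject_id", "compartment"]].copy()
    out["pct_change"] = percent_volume_change(
        volumes["volume_baseline"].to_numpy(),
        volumes["volume_24m"].to_numpy(),
        convention,
    )
    return out
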