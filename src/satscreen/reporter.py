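"""Reporter-activity and immunoblot-band normalisation utilities.

These mirror the bench quantifications used to phenotype rebuilt mutants:
beta-galactosidase reporter activity is the plate-reader Vmax normalised to
culture OD600; stress induction is summarised as the treated/untreated
activity ratio; crosslinking band intensities are normalised by the lane's
total protein signal and expressed as fold of the wild-type lane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "normalize_activity",
    "treatment_fold_change",
    "normalize_band",
    "ReporterMeasurement",
    "BandQuant",
    "summarize_replicates",
    "normalize_activity_table",
    "normalize_band_table",
]


def normalize_activity(vmax: float, od600: float) -> float:
    """Reporter activity: Vmax normalised to OD600."""
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return vmax / od600


def treatment_fold_change(activity_treated: float, activity_untreated: float) -> float:
    """Induction ratio of treated over untreated reporter activity."""
    if activity_untreated <= 0:
        raise ValueError("untreated activity must be positive")
    return activity_treated / activity_untreated


def normalize_band(
    band_intensity: float, total_protein_signal: float, wt_normalized: float
) -> float:
    """Band intensity / total protein signal, as fold of the WT lane."""
    if total_protein_signal <= 0:
        raise ValueError("total protein signal must be positive")
    if wt_normalized <= 0:
        raise ValueError("WT normalised intensity must be positive")
    return (band_intensity / total_protein_signal) / wt_normalized


@dataclass(frozen=True)
class ReporterMeasurement:
    strain_id: str
    vmax: float
    od600: float
    treatment: str = "none"  # e.g. "PMB 0.75ug/mL 40min"

    @property
    def activity(self) -> float:
        return normalize_activity(self.vmax, self.od600)


@dataclass(frozen=True)
class BandQuant:
    lane_id: str
    band_intensity: float
    total_protein_signal: float

    @property
    def normalized(self) -> float:
        if self.total_protein_signal <= 0:
            raise ValueError("total protein signal must be positive")
        return self.band_intensity / self.total_protein_signal


def summarize_replicates(values, spread: str = "sd") -> tuple[float, float]:
    """Mean and spread (sample SD by default, SEM on request) of replicates."""
    values = list(values)
    n = len(values)
    if n == 0:
        raise ValueError("no replicate values")
    mean = sum(values) / n
    if n == 1:
        return mean, math.nan
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    if spread == "sd":
        return mean, sd
    if spread == "sem":
        return mean, sd / math.sqrt(n)
    raise ValueError(f"unknown spread: {spread!r}")


def normalize_activity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add an ``activity`` column (Vmax/OD600) to a measurement table.

    Expects columns ``strain_id``, ``replicate``, ``vmax``, ``od600`` and
    optionally ``treatment``.
    """
    out = df.copy()
    if (out["od600"] <= 0).any():
        raise ValueError("OD600 must be positive")
    out["activity"] = out["vmax"] / out["od600"]
    return out


def normalize_band_table(df: pd.DataFrame, wt_lane: str) -> pd.DataFrame:
    """Normalise band intensities and express them as fold of the WT lane.

    Expects columns ``lane_id``, ``band_intensity``, ``total_protein_signal``.
    The WT lane's ``fold_of_wt`` is 1 by construction.
    """
    out = df.copy()
    if (out["total_protein_signal"] <= 0).any():
        raise ValueError("total protein signal must be positive")
    out["normalized"] = out["band_intensity"] / out["total_protein_signal"]
    wt_rows = out.loc[out["lane_id"] == wt_lane, "normalized"]
    if wt_rows.empty:
        raise ValueError(f"WT lane {wt_lane!r} not found")
    wt_norm = float(wt_rows.mean())
    if wt_norm <= 0:
        raise ValueError("WT normalised intensity must be positive")
    out["fold_of_wt"] = out["normalized"] / wt_norm
    return out
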