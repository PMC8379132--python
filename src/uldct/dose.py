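"""Radiation-dose accounting for CT and projection radiography.

Effective dose is estimated with region-specific conversion factors:
``E = k_CT × DLP`` for CT (adult pelvis, k = 0.013 mSv/mGy·cm) and
``E = k_DR × DAP`` for radiographs (k = 0.00029 mSv/mGy·cm²). Protocol
comparison reports percent reduction ``100·(1 − new/ref)`` and fold
reduction ``ref/new``. Report helpers round half away from zero to the
conventional printed precision (2 decimals for mSv, 1 for percent/fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ArgumentError, DivisionError

__all__ = [
    "K_CT_PELVIS",
    "K_DR_PELVIS",
    "DoseRecord",
    "effective_dose_ct",
    "effective_dose_dr",
    "dose_reduction",
    "dlp_from_ctdi",
    "round_half_away",
    "read_dose_csv",
]

K_CT_PELVIS = 0.013  # mSv per mGy*cm, adult pelvis
K_DR_PELVIS = 0.00029  # mSv per mGy*cm^2, pelvic radiograph


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (matches printed dose tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class DoseRecord:
    """One exam's dose-report scalars and the derived effective dose."""

    modality: str  # "ct" or "dr"
    effective_dose_msv: float
    k_factor: float
    ctdi_vol_mgy: float | None = None
    dlp_mgy_cm: float | None = None
    dap_mgy_cm2: float | None = None
    scan_length_mm: float | None = None


def effective_dose_ct(dlp_mgy_cm: float, k: float = K_CT_PELVIS) -> float:
    """Effective dose (mSv) from a CT dose-length product (mGy·cm)."""
    if dlp_mgy_cm < 0:
        raise ArgumentError("DLP must be non-negative")
    return dlp_mgy_cm * k


def effective_dose_dr(dap_mgy_cm2: float, k: float = K_DR_PELVIS) -> float:
    """Effective dose (mSv) from a radiograph dose-area product (mGy·cm²)."""
    if dap_mgy_cm2 < 0:
        raise ArgumentError("DAP must be non-negative")
    return dap_mgy_cm2 * k


def dose_reduction(dose_ref_msv: float, dose_new_msv: float) -> tuple[float, float]:
    """Percent and fold reduction of ``dose_new`` relative to ``dose_ref``,
    each rounded to 1 decimal."""
    if dose_ref_msv <= 0 or dose_new_msv <= 0:
        raise DivisionError("doses must be positive for a reduction ratio")
    percent = 100.0 * (1.0 - dose_new_msv / dose_ref_msv)
    fold = dose_ref_msv / dose_new_msv
    return round_half_away(percent, 1), round_half_away(fold, 1)


def dlp_from_ctdi(ctdi_vol_mgy: float, scan_length_mm: float) -> float:
    """DLP (mGy·cm) = CTDIvol (mGy) × scan length (cm)."""
    if ctdi_vol_mgy < 0 or scan_length_mm < 0:
        raise ArgumentError("inputs must be non-negative")
    return ctdi_vol_mgy * scan_length_mm / 10.0


def ct_record(dlp_mgy_cm: float, ctdi_vol_mgy=None, scan_length_mm=None, k: float = K_CT_PELVIS) -> DoseRecord:
    return DoseRecord(
        modality="ct",
        effective_dose_msv=effective_dose_ct(dlp_mgy_cm, k),
        k_factor=k,
        ctdi_vol_mgy=ctdi_vol_mgy,
        dlp_mgy_cm=dlp_mgy_cm,
        scan_length_mm=scan_length_mm,
    )


def dr_record(dap_mgy_cm2: float, k: float = K_DR_PELVIS) -> DoseRecord:
    return DoseRecord(
        modality="dr",
        effective_dose_msv=effective_dose_dr(dap_mgy_cm2, k),
        k_factor=k,
        dap_mgy_cm2=dap_mgy_cm2,
    )


def read_dose_csv(path) -> pd.DataFrame:
    """Read a dose-report CSV (columns: modality, plus dlp_mgy_cm /
    ctdi_vol_mgy / scan_length_mm for CT or dap_mgy_cm2 for DR) and append
    an effective_dose_msv column."""
    df = pd.read_csv(path)
    if "modality" not in df.columns:
        raise ArgumentError("dose CSV needs a 'modality' column (ct/dr)")
    doses = []
    for _, row in df.iterrows():
        if row["modality"] == "ct":
            doses.append(effective_dose_ct(float(row["dlp_mgy_cm"])))
        elif row["modality"] == "dr":
            doses.append(effective_dose_dr(float(row["dap_mgy_cm2"])))
        else:
            raise ArgumentError(f"unknown modality {row['modality']!r}")
    out = df.copy()
    out["effective_dose_msv"] = doses
    return out
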