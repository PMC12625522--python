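"""Clinical instrument scoring: NPI-NH subsyndromes, SPPB, dementia severity.

* NPI-NH: 12 neuropsychiatric symptom items, each scored frequency x severity
  (0-12), clustered into four subsyndromes — agitation (agitation/aggression +
  disinhibition + irritability, 0-36), psychosis (delusions + hallucinations,
  0-24), affective (depression + anxiety, 0-24) and apathy (the apathy item,
  0-12) — plus a 0-144 total.
* SPPB: balance, 4-m gait and repeated chair-stand sub-tests each 0-4, summed
  to 0-12; a sub-test attempted but not completed scores 0.
* Severity staging: DSM-5 diagnosis first, then CDR sum-of-boxes bands for
  dementia cases (4.5-9.0 mild, 9.5-15.5 moderate, 16.0-18.0 severe). Residents
  without dementia — with or without mild cognitive impairment — form a single
  combined group.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("actipat")

__all__ = [
    "NPI_ITEM_NAMES",
    "NPIItems",
    "NPISubsyndromes",
    "SPPBScore",
    "SeverityGroup",
    "ClinicalValidationError",
    "npi_subsyndromes",
    "sppb_total",
    "severity_group",
    "read_clinical_csv",
    "score_clinical_table",
]

NPI_ITEM_NAMES: tuple[str, ...] = (
    "delusions",
    "hallucinations",
    "agitation_aggression",
    "depression",
    "anxiety",
    "euphoria",
    "apathy",
    "disinhibition",
    "irritability",
    "aberrant_motor",
    "nighttime_behavior",
    "appetite_eating",
)

_AGITATION_ITEMS = ("agitation_aggression", "disinhibition", "irritability")
_PSYCHOSIS_ITEMS = ("delusions", "hallucinations")
_AFFECTIVE_ITEMS = ("depression", "anxiety")


class ClinicalValidationError(ValueError):
    """A clinical score is outside its instrument's valid range."""


@dataclass(frozen=True)
class NPIItems:
    """The twelve NPI-NH item scores (each frequency x severity, 0-12)."""

    delusions: int = 0
    hallucinations: int = 0
    agitation_aggression: int = 0
    depression: int = 0
    anxiety: int = 0
    euphoria: int = 0
    apathy: int = 0
    disinhibition: int = 0
    irritability: int = 0
    aberrant_motor: int = 0
    nighttime_behavior: int = 0
    appetite_eating: int = 0

    def __post_init__(self) -> None:
        for name in NPI_ITEM_NAMES:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 12):
                raise ClinicalValidationError(
                    f"NPI item {name!r} must be an integer in [0, 12], got {v!r}"
                )

    @classmethod
    def from_frequency_severity(cls, freq: dict[str, int], sev: dict[str, int]) -> "NPIItems":
        """Build items from separate frequency (0-4) and severity (0-3) ratings."""
        scores = {}
        for name in NPI_ITEM_NAMES:
            f, s = freq[name], sev[name]
            if not 0 <= f <= 4:
                raise ClinicalValidationError(f"NPI frequency {name!r} outside [0, 4]")
            if not 0 <= s <= 3:
                raise ClinicalValidationError(f"NPI severity {name!r} outside [0, 3]")
            scores[name] = int(f) * int(s)
        return cls(**scores)


@dataclass(frozen=True)
class NPISubsyndromes:
    """Clustered NPI-NH scores; higher means more severe symptoms."""

    agitation: int  # 0-36
    psychosis: int  # 0-24
    affective: int  # 0-24
    apathy: int  # 0-12
    total: int  # 0-144


def npi_subsyndromes(items: NPIItems) -> NPISubsyndromes:
    """Cluster the 12 items into the four subsyndromes plus the total."""
    return NPISubsyndromes(
        agitation=sum(getattr(items, n) for n in _AGITATION_ITEMS),
        psychosis=sum(getattr(items, n) for n in _PSYCHOSIS_ITEMS),
        affective=sum(getattr(items, n) for n in _AFFECTIVE_ITEMS),
        apathy=items.apathy,
        total=sum(getattr(items, n) for n in NPI_ITEM_NAMES),
    )


@dataclass(frozen=True)
class SPPBScore:
    balance: int
    gait: int
    chair: int
    attempted: tuple[bool, bool, bool] = (True, True, True)

    @property
    def total(self) -> int:
        return self.balance + self.gait + self.chair


def sppb_total(
    balance: int | None,
    gait: int | None,
    chair: int | None,
    attempted: tuple[bool, bool, bool] = (True, True, True),
) -> SPPBScore:
    """Sum the three SPPB sub-tests into the 0-12 total.

    A sub-test passed as ``None`` means the resident attempted it but could
    not perform it; it scores 0, keeping non-ambulant residents in the
    analysis rather than excluding them.
    """
    subs = []
    for name, v in zip(("balance", "gait", "chair"), (balance, gait, chair)):
        if v is None:
            subs.append(0)
            continue
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
            raise ClinicalValidationError(
                f"SPPB {name} must be an integer in [0, 4] or None, got {v!r}"
            )
        subs.append(int(v))
    return SPPBScore(subs[0], subs[1], subs[2], attempted=attempted)


class SeverityGroup(enum.IntEnum):
    """Cognitive-impairment/dementia severity groups (ordinal 1-4)."""

    NOCI_MCI = 1
    MILD_DEMENTIA = 2
    MODERATE_DEMENTIA = 3
    SEVERE_DEMENTIA = 4


def severity_group(
    has_dementia: bool,
    has_mci: bool = False,
    cdr_sob: float | None = None,
    *,
    very_mild_policy: str = "mild",
) -> SeverityGroup:
    """Stage a resident from DSM-5 diagnosis flags and CDR sum-of-boxes.

    Non-dementia residents (including those with mild cognitive impairment)
    fall in the combined no-impairment/MCI group. Dementia cases are banded on
    CDR sum-of-boxes: 4.5-9.0 mild, 9.5-15.5 moderate, 16.0-18.0 severe.

    A dementia diagnosis with CDR-SOB in the 0.5-4.0 "questionable to very
    mild" band sits outside the four named groups; by default it is staged as
    mild dementia (the DSM-5 diagnosis dominates), with a warning.
    ``very_mild_policy='noci_mci'`` assigns it to the combined group instead.
    """
    if not has_dementia:
        return SeverityGroup.NOCI_MCI
    if cdr_sob is None:
        raise ClinicalValidationError("cdr_sob is required for dementia cases")
    if not (0.0 <= cdr_sob <= 18.0) or round(cdr_sob * 2) != cdr_sob * 2:
        raise ClinicalValidationError(
            f"cdr_sob must lie on the 0.5-step grid in [0, 18], got {cdr_sob!r}"
        )
    if cdr_sob >= 16.0:
        return SeverityGroup.SEVERE_DEMENTIA
    if cdr_sob >= 9.5:
        return SeverityGroup.MODERATE_DEMENTIA
    if cdr_sob >= 4.5:
        return SeverityGroup.MILD_DEMENTIA
    if very_mild_policy == "noci_mci":
        return SeverityGroup.NOCI_MCI
    logger.warning(
        "dementia diagnosis with CDR-SOB %.1f (questionable/very-mild band); "
        "staged as mild dementia",
        cdr_sob,
    )
    return SeverityGroup.MILD_DEMENTIA


def read_clinical_csv(path) -> pd.DataFrame:
    """Read the participant clinical table (one row per participant)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ClinicalValidationError(f"{path}: missing participant_id column")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ClinicalValidationError(f"{path}: duplicate participant {dup}")
    return df


def score_clinical_table(df: pd.DataFrame, *, very_mild_policy: str = "mild") -> pd.DataFrame:
    """Score a raw clinical table into analysis covariates.

    Accepts either twelve ``npi_<item>`` product columns or twenty-four
    ``npi_<item>_freq`` / ``npi_<item>_sev`` columns (multiplied on ingest).
    SPPB sub-test columns may hold NA for attempted-but-unable (scored 0).
    Returns a frame with participant_id, npi subsyndromes, npi_total,
    sppb_total, severity (ordinal 1-4) plus passed-through covariates.
    """
    out = pd.DataFrame({"participant_id": df["participant_id"]})
    if f"npi_{NPI_ITEM_NAMES[0]}" in df.columns:
        items_df = pd.DataFrame(
            {n: df[f"npi_{n}"].astype(int) for n in NPI_ITEM_NAMES}
        )
    elif f"npi_{NPI_ITEM_NAMES[0]}_freq" in df.columns:
        items_df = pd.DataFrame(
            {
                n: (df[f"npi_{n}_freq"].astype(int) * df[f"npi_{n}_sev"].astype(int))
                for n in NPI_ITEM_NAMES
            }
        )
    else:
        raise ClinicalValidationError(
            "clinical table needs npi_<item> or npi_<item>_freq/_sev columns"
        )
    subs = [
        npi_subsyndromes(NPIItems(**{n: int(r[n]) for n in NPI_ITEM_NAMES}))
        for r in items_df.to_dict("records")
    ]
    out["npi_agitation"] = [s.agitation for s in subs]
    out["npi_psychosis"] = [s.psychosis for s in subs]
    out["npi_affective"] = [s.affective for s in subs]
    out["npi_apathy"] = [s.apathy for s in subs]
    out["npi_total"] = [s.total for s in subs]

    def _sub(v):
        return None if pd.isna(v) else int(v)

    out["sppb_total"] = [
        sppb_total(_sub(r.sppb_balance), _sub(r.sppb_gait), _sub(r.sppb_chair)).total
        for r in df.itertuples()
    ]
    out["severity"] = [
        int(
            severity_group(
                bool(r.dx_dementia),
                bool(getattr(r, "dx_mci", False)),
                None if pd.isna(getattr(r, "cdr_sob", np.nan)) else float(r.cdr_sob),
                very_mild_policy=very_mild_policy,
            )
        )
        for r in df.itertuples()
    ]
    for col in ("age", "sex", "bmi"):
        if col in df.columns:
            out[col] = df[col].to_numpy()
    return out
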