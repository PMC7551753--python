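"""Canonical catalogs: physiological variables, disease codes, plausible ranges.

The 17 physiological variables (PVs) and 24 grouped disease codes form the
default universe of every operation in this package.  Each PV carries a
built-in plausible-physiology entry (generation mean/sd, canonical unit,
plausible range) that the synthetic generator and the ETL cleaner share.
All of it is overridable at call sites; the tables here are defaults, not
clinical claims.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical PV abbreviations, in fixed catalog order.  This order defines
#: feature-column layout and the deterministic tie-break used in rankings.
PV_CATALOG: tuple[str, ...] = (
    "SpO2",   # oxygen saturation
    "CRR",    # capillary refill rate (0 = normal, 1 = abnormal)
    "FiO2",   # fraction inspired oxygen
    "GCST",   # Glasgow coma scale total
    "GCSE",   # Glasgow coma scale eye opening
    "GCSM",   # Glasgow coma scale motor response
    "GCSV",   # Glasgow coma scale verbal response
    "PH",     # blood pH
    "Weight",
    "TEMP",   # temperature, Celsius
    "SBP",    # systolic blood pressure
    "RR",     # respiratory rate
    "MBP",    # mean blood pressure
    "Ht",     # height
    "HR",     # heart rate
    "Glu",    # glucose
    "DBP",    # diastolic blood pressure
)

#: The 24 grouped disease codes, D1..D24.
DISEASE_CATALOG: tuple[str, ...] = tuple(f"D{i}" for i in range(1, 25))


@dataclass(frozen=True)
class PVProfile:
    """Default generation and cleaning profile for one PV.

    ``mean``/``sd`` parameterize the synthetic generator; ``lo``/``hi`` is
    the plausible range used by the cleaner (values outside are outliers);
    ``unit`` is the canonical unit after cleaning.  ``binary`` marks
    categorical 0/1 variables (CRR), generated by thresholding the latent.
    """

    mean: float
    sd: float
    lo: float
    hi: float
    unit: str
    binary: bool = False


#: Built-in plausible-physiology table.  Values are deliberately generic;
#: override via ``SyntheticConfig.physiology`` or the ETL range table.
PHYSIOLOGY: dict[str, PVProfile] = {
    "SpO2":   PVProfile(97.0, 2.5, 0.0, 100.0, "%"),
    "CRR":    PVProfile(0.0, 1.0, 0.0, 1.0, "", binary=True),
    "FiO2":   PVProfile(0.5, 0.2, 0.2, 1.0, ""),
    "GCST":   PVProfile(11.0, 3.0, 3.0, 15.0, ""),
    "GCSE":   PVProfile(3.0, 1.0, 1.0, 4.0, ""),
    "GCSM":   PVProfile(5.0, 1.2, 1.0, 6.0, ""),
    "GCSV":   PVProfile(3.5, 1.2, 1.0, 5.0, ""),
    "PH":     PVProfile(7.4, 0.07, 6.3, 8.0, ""),
    "Weight": PVProfile(80.0, 18.0, 20.0, 300.0, "kg"),
    "TEMP":   PVProfile(37.0, 0.7, 25.0, 45.0, "C"),
    "SBP":    PVProfile(120.0, 20.0, 30.0, 250.0, "mmHg"),
    "RR":     PVProfile(19.0, 5.0, 0.0, 80.0, "insp/min"),
    "MBP":    PVProfile(85.0, 15.0, 20.0, 200.0, "mmHg"),
    "Ht":     PVProfile(170.0, 10.0, 100.0, 230.0, "cm"),
    "HR":     PVProfile(85.0, 15.0, 0.0, 300.0, "bpm"),
    "Glu":    PVProfile(130.0, 45.0, 20.0, 1000.0, "mg/dL"),
    "DBP":    PVProfile(70.0, 12.0, 20.0, 150.0, "mmHg"),
}


def default_range_table() -> dict[str, tuple[float, float]]:
    """Plausible [lo, hi] range per PV for outlier removal."""
    return {pv: (p.lo, p.hi) for pv, p in PHYSIOLOGY.items()}


def canonical_units() -> dict[str, str]:
    return {pv: p.unit for pv, p in PHYSIOLOGY.items()}
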