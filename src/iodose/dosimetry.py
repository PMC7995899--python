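"""Organ dosimetry: S values, mass correction, absorbed and effective dose,
and administered-activity planning.

The dose to a target region is the sum over source regions of the
time-integrated activity (TIAC, MBq·h per MBq administered) times the
S value S(target ← source), the mean absorbed dose to the target per
nuclear transformation in the source.  S values are *consumed* from tables
(standardised here to mGy per MBq·h so that dose = TIAC × S directly) or
composed from an emission spectrum and a specific-absorbed-fraction (SAF)
table as S = Σ_i Δ_i · Φ(E_i) with Δ_i = E_i·Y_i the energy yield of the
i-th transition.

Thyroid self-irradiation can be rescaled from the reference phantom mass
(23.4 g male, 19.5 g female) to the patient's: photons scale with
(M_ref/M_pat)^(2/3), charged particles with M_ref/M_pat.

The effective dose is the tissue-weighted, sex-averaged sum of organ doses;
a second bookkeeping with the thyroid weight set to zero (without
renormalising the remaining weights) serves as a risk indicator for
non-target tissues when the thyroid is deliberately ablated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .nuclides import ELECTRON, PHOTON, EmissionSpectrum, get_nuclide
from .units import SECONDS_PER_HOUR

logger = logging.getLogger(__name__)

S_UNITS = "mGy/(MBq.h)"
SAF_UNITS = "1/kg"

#: reference phantom thyroid masses, kg
REFERENCE_THYROID_MASS_KG = {"male": 0.0234, "female": 0.0195}

#: ICRP 2007 tissue weighting factors.  "remainder" (0.12) is shared by the
#: remainder tissues; the remainder dose here is the arithmetic mean of the
#: available remainder organs.
TISSUE_WEIGHTS = {
    "red_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach_wall": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "urinary_bladder_wall": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
    "remainder": 0.12,
}

REMAINDER_ORGANS = (
    "adrenals", "extrathoracic_region", "gall_bladder", "heart", "kidneys",
    "lymphatic_nodes", "muscle", "oral_mucosa", "pancreas", "prostate",
    "small_intestine_wall", "spleen", "thymus", "uterus",
)

#: radiation weighting factors; photons and electrons both 1, kept explicit.
RADIATION_WEIGHTS = {PHOTON: 1.0, ELECTRON: 1.0}


@dataclass(frozen=True)
class TissueWeights:
    w_t: dict[str, float]
    w_r: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.w_t.values()) or any(
            v < 0 for v in self.w_r.values()
        ):
            raise ValidationError("weighting factors must be >= 0")
        total = sum(self.w_t.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"tissue weights must sum to 1 before any modification, got {total}"
            )


DEFAULT_WEIGHTS = TissueWeights(dict(TISSUE_WEIGHTS), dict(RADIATION_WEIGHTS))


# ---------------------------------------------------------------------------
# S-value and SAF tables


_S_COLUMNS = ["nuclide", "source", "target", "sex", "s_photon", "s_particle"]


class SValueTable:
    """Rows of S(target ← source) split into photon and particle parts,
    in mGy per MBq·h, keyed by (nuclide, source, target, sex)."""

    def __init__(self, frame: pd.DataFrame, masses_kg: dict[str, float] | None = None):
        missing = set(_S_COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"S-value table missing columns {sorted(missing)}")
        if (frame[["s_photon", "s_particle"]] < 0).any().any():
            raise ValidationError("S components must be >= 0")
        if frame.duplicated(subset=["nuclide", "source", "target", "sex"]).any():
            raise ValidationError("duplicate (nuclide, source, target, sex) S rows")
        self.frame = frame.reset_index(drop=True)
        self.masses_kg = dict(masses_kg or REFERENCE_THYROID_MASS_KG)

    @classmethod
    def from_csv(cls, path) -> "SValueTable":
        units = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "units:" in line:
                    units = line.split("units:", 1)[1].strip()
        if units != S_UNITS:
            raise ValidationError(
                f"S-value table {path} must declare '# units: {S_UNITS}' "
                f"in its header (found: {units!r})"
            )
        frame = pd.read_csv(path, comment="#")
        return cls(frame)

    def rows_for(self, nuclide: str, sex: str) -> pd.DataFrame:
        return self.frame[
            (self.frame["nuclide"] == nuclide) & (self.frame["sex"] == sex)
        ]

    def targets(self) -> list[str]:
        return sorted(self.frame["target"].unique())

    def with_rows(self, frame: pd.DataFrame) -> "SValueTable":
        return SValueTable(frame, self.masses_kg)


class SAFTable:
    """Specific absorbed fractions Φ(target ← source, E) per kg on an energy
    grid, per radiation class (and optionally sex)."""

    _COLUMNS = ["source", "target", "radiation_class", "energy_mev", "phi_per_kg"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self._COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"SAF table missing columns {sorted(missing)}")
        if (frame["phi_per_kg"] < 0).any():
            raise ValidationError("SAF values must be >= 0")
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "SAFTable":
        return cls(pd.read_csv(path, comment="#"))

    def grid(self, source: str, target: str, radiation_class: str):
        rows = self.frame[
            (self.frame["source"] == source)
            & (self.frame["target"] == target)
            & (self.frame["radiation_class"] == radiation_class)
        ].sort_values("energy_mev")
        if rows.empty:
            raise ConfigurationError(
                f"SAF table has no ({radiation_class}) grid for {target} <- {source}"
            )
        e = rows["energy_mev"].to_numpy(dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValidationError(
                f"SAF energy grid for {target} <- {source} must be strictly increasing"
            )
        return e, rows["phi_per_kg"].to_numpy(dtype=float)


#: conversion: (Gy per transformation) -> (mGy per MBq·h)
_GY_PER_DECAY_TO_MGY_PER_MBQ_H = 1e6 * SECONDS_PER_HOUR * 1e3


def compose_s_value(
    spectrum: EmissionSpectrum,
    saf: SAFTable,
    source: str,
    target: str,
    *,
    nuclide: str = "",
    sex: str = "both",
) -> dict:
    """S(target ← source) = Σ_i Δ_i · Φ(E_i), photon and particle parts
    accumulated separately.

    Φ is evaluated by interpolation linear in log-energy; an emission energy
    outside the tabulated grid raises (no silent clamping).
    """
    parts = {PHOTON: 0.0, ELECTRON: 0.0}
    for t in spectrum.transitions:
        e_grid, phi = saf.grid(source, target, t.radiation_class)
        if not (e_grid[0] <= t.energy_mev <= e_grid[-1]):
            raise ValidationError(
                f"emission energy {t.energy_mev} MeV outside SAF grid "
                f"[{e_grid[0]}, {e_grid[-1]}] for {target} <- {source} "
                f"({t.radiation_class}); extend the table"
            )
        phi_e = float(np.interp(np.log(t.energy_mev), np.log(e_grid), phi))
        parts[t.radiation_class] += t.energy_yield_j * phi_e  # Gy per decay
    return {
        "nuclide": nuclide,
        "source": source,
        "target": target,
        "sex": sex,
        "s_photon": parts[PHOTON] * _GY_PER_DECAY_TO_MGY_PER_MBQ_H,
        "s_particle": parts[ELECTRON] * _GY_PER_DECAY_TO_MGY_PER_MBQ_H,
    }


def mass_correct_self_dose(row, m_pat_kg: float, m_ref_kg: float | None = None):
    """Rescale a self-irradiation S row to a patient organ mass.

    Photons scale with (M_ref/M_pat)^(2/3); particles with M_ref/M_pat.
    ``row`` is a mapping with source/target/sex/s_photon/s_particle.
    """
    if row["source"] != row["target"]:
        raise ValidationError(
            "mass correction applies to self-irradiation rows only "
            f"(got {row['target']} <- {row['source']})"
        )
    if not m_pat_kg > 0:
        raise ValidationError("patient mass must be > 0")
    if m_ref_kg is None:
        try:
            m_ref_kg = REFERENCE_THYROID_MASS_KG[row["sex"]]
        except KeyError:
            raise ValidationError(
                f"no reference mass for sex {row['sex']!r}; pass m_ref_kg"
            ) from None
    ratio = m_ref_kg / m_pat_kg
    out = dict(row)
    out["s_photon"] = row["s_photon"] * ratio ** (2.0 / 3.0)
    out["s_particle"] = row["s_particle"] * ratio
    return out


def mass_corrected_table(
    svalues: SValueTable, organ: str, m_pat_kg: float
) -> SValueTable:
    """Apply the self-dose mass correction to every ``organ <- organ`` row."""
    frame = svalues.frame.copy()
    mask = (frame["source"] == organ) & (frame["target"] == organ)
    for i in frame.index[mask]:
        corrected = mass_correct_self_dose(frame.loc[i].to_dict(), m_pat_kg)
        frame.loc[i, ["s_photon", "s_particle"]] = (
            corrected["s_photon"],
            corrected["s_particle"],
        )
    return svalues.with_rows(frame)


# ---------------------------------------------------------------------------
# absorbed and effective dose


@dataclass(frozen=True)
class DoseResult:
    """Per-organ absorbed-dose coefficients and effective doses.

    ``by_nuclide``: target × (sex, nuclide) absorbed dose, mGy/MBq.
    Effective doses are mSv/MBq.
    """

    by_nuclide: pd.DataFrame
    effective_dose: float | None = None
    effective_dose_no_thyroid: float | None = None

    def organ_doses(self, sex: str) -> pd.Series:
        """Total (all chain members) absorbed dose per organ, mGy/MBq."""
        cols = [c for c in self.by_nuclide.columns if c[0] == sex]
        if not cols:
            raise ConfigurationError(f"no dose computed for sex {sex!r}")
        return self.by_nuclide[cols].sum(axis=1)


def absorbed_dose(
    tiacs,
    svalues: SValueTable,
    *,
    sexes: tuple[str, ...] = ("male", "female"),
    targets: list[str] | None = None,
) -> DoseResult:
    """D(target) = Σ_sources TIAC(source) · (S_photon + S_particle),
    summed per chain member; mGy per MBq administered.

    Source regions without S rows contribute zero with a logged warning.
    """
    targets = targets or svalues.targets()
    members = list(tiacs.table.columns)
    in_body_regions = sorted(
        {c.region for c in tiacs.model.compartments if c.in_body}
    )
    data: dict[tuple[str, str], pd.Series] = {}
    warned: set[tuple[str, str]] = set()
    for sex in sexes:
        for member in members:
            rows = svalues.rows_for(member, sex)
            covered = set(rows["source"])
            doses = {}
            for target in targets:
                total = 0.0
                trows = rows[rows["target"] == target].set_index("source")
                for source in in_body_regions:
                    t_h = tiacs.region_hours(source, member)
                    if t_h == 0.0:
                        continue
                    if source in trows.index:
                        s = trows.loc[source]
                        total += t_h * float(s["s_photon"] + s["s_particle"])
                    elif source not in covered and (member, source) not in warned:
                        warned.add((member, source))
                        logger.warning(
                            "no S rows for source %r (nuclide %s); it "
                            "contributes zero dose", source, member,
                        )
                doses[target] = total
            data[(sex, member)] = pd.Series(doses)
    frame = pd.DataFrame(data)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["sex", "nuclide"])
    return DoseResult(by_nuclide=frame)


def effective_dose(
    dose_male: pd.Series,
    dose_female: pd.Series,
    weights: TissueWeights = DEFAULT_WEIGHTS,
    *,
    zero_thyroid: bool = False,
) -> float:
    """Sex-averaged, tissue-weighted effective dose, mSv per MBq.

    ``zero_thyroid`` sets w_T(thyroid) = 0 without renormalising the other
    weights.  Organs absent from the input contribute zero (warning logged);
    remainder tissues enter as the arithmetic mean of those available.
    """
    organs = set(dose_male.index) | set(dose_female.index)

    def sex_avg(organ: str) -> float:
        return 0.5 * (float(dose_male.get(organ, 0.0)) + float(dose_female.get(organ, 0.0)))

    e = 0.0
    for tissue, w in weights.w_t.items():
        if tissue == "remainder":
            avail = [o for o in REMAINDER_ORGANS if o in organs]
            if avail:
                e += w * float(np.mean([sex_avg(o) for o in avail]))
            continue
        if zero_thyroid and tissue == "thyroid":
            continue
        if tissue not in organs:
            logger.warning(
                "tissue %r has weight %g but no dose value; contributes zero",
                tissue, w,
            )
            continue
        e += w * sex_avg(tissue)
    # photon/electron radiation weights are 1; kept explicit for generality
    assert all(v == 1.0 for v in weights.w_r.values())
    return e


# ---------------------------------------------------------------------------
# EANM administered-activity planning


@dataclass(frozen=True)
class PlanInputs:
    """Inputs of the pre-therapeutic activity prescription."""

    prescribed_dose_gy: float  # mean absorbed dose to the thyroid, Gy
    thyroid_mass_kg: float
    mean_energy_j: float  # mean energy deposited in thyroid per decay, J
    riu_integral_h: float  # ∫ RIU(t) dt, hours (thyroid TIAC)

    def __post_init__(self):
        for name in ("prescribed_dose_gy", "thyroid_mass_kg", "mean_energy_j"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.riu_integral_h > 0:
            raise ValidationError("RIU time integral must be > 0")


def administered_activity(plan: PlanInputs) -> float:
    """Activity to administer, MBq:  A = D·M / (Ē · ∫RIU dt).

    D in Gy (= J/kg), M in kg, Ē in J and the RIU integral in hours, so the
    denominator converts to seconds and the quotient is in Bq.
    """
    a_bq = (plan.prescribed_dose_gy * plan.thyroid_mass_kg) / (
        plan.mean_energy_j * plan.riu_integral_h * SECONDS_PER_HOUR
    )
    return a_bq / 1e6


def mean_energy_per_decay_j(nuclide: str = "I-131", radiation_class: str = ELECTRON) -> float:
    """Mean emitted energy per decay from the registry spectrum (joule).

    For I-131 thyroid planning the locally absorbed energy is, to a good
    approximation, the electron (beta + conversion) energy; photons mostly
    escape a thyroid-sized volume.
    """
    return get_nuclide(nuclide).emissions.energy_per_decay_j(radiation_class)


def scale_to_administration(dose, activity_mbq: float):
    """Organ dose (mGy) for an administered activity (MBq).

    ``dose`` may be a scalar coefficient, a Series of per-organ
    coefficients, or a :class:`DoseResult` (scales the per-nuclide table).
    """
    if activity_mbq < 0:
        raise ValidationError("administered activity must be >= 0")
    if isinstance(dose, DoseResult):
        return dose.by_nuclide * activity_mbq
    return dose * activity_mbq
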