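"""Readers, writers, configuration and the end-to-end pipeline.

The measurement CSV dialect: comma-separated with a header row
``time_h,riu_fraction[,sigma_rel]``; decimal points; comment lines start
with ``#``.  Reports are versioned JSON (schema v1) or markdown; both are
byte-stable for identical inputs and seeds (no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd
import yaml

from .dosimetry import DoseResult, SValueTable, mean_energy_per_decay_j
from .errors import ValidationError
from .fitting import PARAMETER_NAMES, UptakeMeasurement
from .model import ThyroidUptakeModel, ThyroidUptakeResults, default_svalue_table

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _package_version() -> str:
    try:
        return metadata.version("iodose")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_measurements(path) -> list[UptakeMeasurement]:
    """Read the measurement CSV dialect into validated measurements.

    Rows are sorted by time (stable); duplicate time points and uptake
    fractions outside [0, 1] raise with the offending row number.
    """
    frame = pd.read_csv(path, comment="#")
    required = {"time_h", "riu_fraction"}
    if not required <= set(frame.columns):
        raise ValidationError(
            f"{path}: header must contain {sorted(required)}, got {list(frame.columns)}"
        )
    if frame.empty:
        raise ValidationError(f"{path}: no measurement rows")
    measurements = []
    for i, row in frame.iterrows():
        rownum = i + 2  # header is row 1
        riu = float(row["riu_fraction"])
        if not 0.0 <= riu <= 1.0:
            raise ValidationError(
                f"{path} row {rownum}: riu_fraction {riu} outside [0, 1]"
            )
        t = float(row["time_h"])
        if not t > 0:
            raise ValidationError(f"{path} row {rownum}: time_h must be > 0")
        sigma = row.get("sigma_rel")
        sigma = None if sigma is None or pd.isna(sigma) else float(sigma)
        measurements.append(UptakeMeasurement(t, riu, sigma))
    times = [m.time_h for m in measurements]
    if len(set(times)) != len(times):
        dupes = sorted({t for t in times if times.count(t) > 1})
        raise ValidationError(f"{path}: duplicate time points {dupes}")
    return sorted(measurements, key=lambda m: m.time_h)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's inputs: identifier, measurements and the two
    patient-specific parameters (uptake data and thyroid mass)."""

    identifier: str
    measurements: tuple[UptakeMeasurement, ...]
    thyroid_mass_g: float | None = None
    sex: str = "both"
    route: str = "oral"
    nuclide: str = "I-131"
    variant: str = "normal"

    def __post_init__(self):
        if not self.identifier:
            raise ValidationError("patient identifier must be nonempty")
        if self.thyroid_mass_g is not None and not self.thyroid_mass_g > 0:
            raise ValidationError("thyroid mass must be > 0 when given")
        if self.sex not in ("male", "female", "both"):
            raise ValidationError(f"sex must be male/female/both, got {self.sex!r}")


def read_patient(csv_path, config: "PipelineConfig | None" = None) -> PatientRecord:
    """Measurement CSV -> validated patient record (config supplies the rest)."""
    config = config or PipelineConfig()
    return PatientRecord(
        identifier=config.patient_id or Path(csv_path).stem,
        measurements=tuple(read_measurements(csv_path)),
        thyroid_mass_g=config.thyroid_mass_g,
        sex=config.sex,
        route=config.route,
        nuclide=config.nuclide,
        variant=config.variant,
    )


@dataclass
class PipelineConfig:
    """Settings of one reproducible run; YAML-loadable, CLI flags override."""

    patient_id: str | None = None
    variant: str = "normal"
    route: str = "oral"
    nuclide: str = "I-131"
    blocked: bool = False
    free: tuple[str, ...] = PARAMETER_NAMES
    n_starts: int = 8
    seed: int = 0
    weighted: bool = False
    sex: str = "both"
    thyroid_mass_g: float | None = None
    prescribed_dose_gy: float | None = None
    administered_activity_mbq: float | None = None
    svalue_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "free" in raw:
            raw["free"] = tuple(raw["free"])
        return cls(**raw)


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run used and produced; every number traces back to an
    input echoed here or to a pipeline stage."""

    patient: PatientRecord
    config: PipelineConfig
    results: ThyroidUptakeResults
    dose: DoseResult
    plan_activity_mbq: float | None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        res = self.results
        tiacs = res.tiacs()
        doses = {
            sex: {
                organ: float(v)
                for organ, v in self.dose.organ_doses(sex).items()
            }
            for sex in ("male", "female")
        }
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "software_version": _package_version(),
            "inputs": {
                "patient": {
                    "identifier": self.patient.identifier,
                    "sex": self.patient.sex,
                    "thyroid_mass_g": self.patient.thyroid_mass_g,
                    "measurements": [asdict(m) for m in self.patient.measurements],
                },
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.config).items()
                },
            },
            "fit": {
                "coefficients_per_day": res.coefficients.as_dict(),
                "cost": res.cost,
                "converged": res.converged,
                "n_starts_used": res.fit_result.n_starts_used,
                "residuals": [float(r) for r in res.resid],
            },
            "tiac_h": {
                "thyroid": res.thyroid_tiac_h,
                "by_region": {
                    region: float(tiacs.table.loc[region].sum())
                    for region in tiacs.sources()
                },
                "whole_body_decay_fraction": res.whole_body_decay_fraction,
            },
            "dose": {
                "organ_mGy_per_MBq": doses,
                "effective_mSv_per_MBq": self.dose.effective_dose,
                "effective_no_thyroid_mSv_per_MBq": self.dose.effective_dose_no_thyroid,
            },
            "plan": {"administered_activity_MBq": self.plan_activity_mbq},
            "warnings": list(self.warnings),
        }


def run_pipeline(patient: PatientRecord, config: PipelineConfig) -> ReportBundle:
    """fit -> TIAC -> absorbed/effective dose -> activity plan, one bundle.

    Mass correction applies when the patient's thyroid mass is given
    (otherwise doses use the reference mass, with a warning); the activity
    plan runs when a prescribed dose and mass are both present.
    """
    warnings_: list[str] = []
    model = ThyroidUptakeModel(
        patient.measurements,
        variant=patient.variant,
        route=patient.route,
        nuclide=patient.nuclide,
        blocked=config.blocked,
        free=config.free,
        weighted=config.weighted,
    )
    results = model.fit(n_starts=config.n_starts, seed=config.seed)
    warnings_.extend(results.fit_result.warnings_)

    svalues = (
        SValueTable.from_csv(config.svalue_csv)
        if config.svalue_csv
        else default_svalue_table()
    )
    if patient.thyroid_mass_g is None:
        msg = "no patient thyroid mass; doses use the reference phantom mass"
        logger.warning(msg)
        warnings_.append(msg)
    dose = results.dose(svalues, thyroid_mass_g=patient.thyroid_mass_g)

    plan_activity = None
    if config.prescribed_dose_gy is not None:
        if patient.thyroid_mass_g is None:
            raise ValidationError(
                "activity planning needs the patient thyroid mass"
            )
        plan_activity = results.administered_activity(
            config.prescribed_dose_gy,
            patient.thyroid_mass_g,
            mean_energy_j=mean_energy_per_decay_j(patient.nuclide),
        )
    return ReportBundle(
        patient=patient,
        config=config,
        results=results,
        dose=dose,
        plan_activity_mbq=plan_activity,
        warnings=tuple(warnings_),
    )


def _markdown_table(headers: list[str], rows: list[list]) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    out = ["| " + " | ".join(headers) + " |",
           "|" + "|".join(" --- " for _ in headers) + "|"]
    for row in rows:
        out.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(out)


def render_markdown(bundle: ReportBundle) -> str:
    d = bundle.to_dict()
    res = d["fit"]
    lines = [
        f"# Radioiodine dose report — patient {bundle.patient.identifier}",
        "",
        f"Software version {d['software_version']}, report schema v{d['schema_version']}, "
        f"seed {bundle.config.seed}.",
        "",
        "## Fitted thyroid transfer coefficients (day^-1)",
        "",
        _markdown_table(
            ["coefficient", "value"],
            [[k, v] for k, v in res["coefficients_per_day"].items()],
        ),
        "",
        f"Cost (sum of squared residuals): {res['cost']:.3e}; "
        f"converged: {res['converged']}.",
        "",
        "## Summary",
        "",
        _markdown_table(
            ["Thyroid TIAC [h]", "E [mSv/MBq]", "E(w_thyroid=0) [mSv/MBq]"]
            + [f"{o} [mGy/MBq]" for o in sorted(d["dose"]["organ_mGy_per_MBq"]["female"])],
            [
                [
                    d["tiac_h"]["thyroid"],
                    d["dose"]["effective_mSv_per_MBq"],
                    d["dose"]["effective_no_thyroid_mSv_per_MBq"],
                ]
                + [
                    d["dose"]["organ_mGy_per_MBq"]["female"][o]
                    for o in sorted(d["dose"]["organ_mGy_per_MBq"]["female"])
                ]
            ],
        ),
        "",
        "## Plan",
        "",
        f"Administered activity: "
        f"{d['plan']['administered_activity_MBq'] or 'not requested'}"
        + (" MBq" if d["plan"]["administered_activity_MBq"] else ""),
        "",
    ]
    if d["warnings"]:
        lines += ["## Warnings", ""] + [f"- {w}" for w in d["warnings"]] + [""]
    return "\n".join(lines)


def write_report(bundle: ReportBundle, path, format: str = "json") -> Path:
    """Serialise a bundle; identical inputs and seed give identical bytes."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(bundle.to_dict(), indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        path.write_text(render_markdown(bundle))
    else:
        raise ValidationError(f"unknown report format {format!r} (json|markdown)")
    return path


def read_report(path) -> dict:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: unsupported report schema {data.get('schema_version')}"
        )
    return data
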