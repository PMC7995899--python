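"""Model/Results interface for patient-specific radioiodine dosimetry.

:class:`ThyroidUptakeModel` is built from a patient's fractional thyroid
uptake measurements (a DataFrame, CSV file or list of measurements) plus the
modelling choices (uptake variant, administration route, nuclide, blocked
thyroid, free parameters).  Its :meth:`~ThyroidUptakeModel.fit` returns a
:class:`ThyroidUptakeResults` carrying the fitted thyroid transfer
coefficients, the residuals and cost, the derived time-integrated activity
coefficients, and methods for organ dosimetry, activity planning, a
statsmodels-style ``summary()`` and plotting.

    >>> model = ThyroidUptakeModel.from_csv("patient.csv")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> res.administered_activity(prescribed_dose_gy=150.0, thyroid_mass_g=30)
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import numpy as np
import pandas as pd

from . import fitting
from .compartments import CompartmentModel, ThyroidCoefficients
from .dosimetry import (
    DEFAULT_WEIGHTS,
    DoseResult,
    PlanInputs,
    SValueTable,
    absorbed_dose,
    administered_activity,
    effective_dose,
    mass_corrected_table,
    mean_energy_per_decay_j,
)
from .errors import ValidationError
from .fitting import FitSpec, UptakeMeasurement
from .kinetics import TIACTable, tiac, whole_body_decays


def default_svalue_table() -> SValueTable:
    """The shipped synthetic fixture S-value table (I-131 + Xe-131m)."""
    ref = resources.files("iodose.data").joinpath("svalues_i131_synthetic.csv")
    with resources.as_file(ref) as p:
        return SValueTable.from_csv(p)


class ThyroidUptakeModel:
    """Systemic iodine model with patient-adjustable thyroid kinetics.

    Parameters
    ----------
    measurements
        Sequence of :class:`UptakeMeasurement` (time in hours since
        administration, fractional uptake, optional relative sigma).
    variant, route, nuclide, blocked, free, bounds, weighted
        Fitting context; see :class:`iodose.fitting.FitSpec`.
    """

    def __init__(
        self,
        measurements,
        *,
        variant: str = "normal",
        route: str = "oral",
        nuclide: str = "I-131",
        blocked: bool = False,
        free: tuple[str, ...] = fitting.PARAMETER_NAMES,
        bounds: dict | None = None,
        weighted: bool = False,
    ):
        self.measurements = tuple(
            m if isinstance(m, UptakeMeasurement) else UptakeMeasurement(*m)
            for m in measurements
        )
        self.spec = FitSpec(
            free_parameters=tuple(free),
            bounds=bounds or {},
            route=route,
            nuclide=nuclide,
            variant=variant,
            blocked=blocked,
            weighted=weighted,
        )

    # -- constructors --------------------------------------------------

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ThyroidUptakeModel":
        """Build from a frame with columns ``time_h``, ``riu_fraction``
        (optionally ``sigma_rel``)."""
        required = {"time_h", "riu_fraction"}
        if not required <= set(frame.columns):
            raise ValidationError(
                f"measurement frame needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        ms = []
        for row in frame.itertuples(index=False):
            sigma = getattr(row, "sigma_rel", None)
            sigma = None if sigma is None or pd.isna(sigma) else float(sigma)
            ms.append(UptakeMeasurement(float(row.time_h), float(row.riu_fraction), sigma))
        return cls(ms, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ThyroidUptakeModel":
        from .io import read_measurements  # local import to avoid cycle

        return cls(read_measurements(path), **kwargs)

    # -- fitting -------------------------------------------------------

    def fit(self, *, n_starts: int = 8, seed: int = 0) -> "ThyroidUptakeResults":
        spec = replace(self.spec, n_starts=n_starts, seed=seed)
        result = fitting.fit(self.measurements, spec)
        return ThyroidUptakeResults(self, result)

    def simulate(self, coeffs: ThyroidCoefficients, times_h) -> np.ndarray:
        """RIU(t) curve for a given coefficient set in this model's context."""
        ev = fitting._RIUEvaluator(
            self.spec.base_model(), self.spec.nuclide, self.spec.route
        )
        times = np.atleast_1d(np.asarray(times_h, dtype=float))
        order = np.argsort(times)
        out = np.empty_like(times)
        out[order] = ev.riu(coeffs.as_dict(), times[order])
        return out


class ThyroidUptakeResults:
    """Estimates and derived dosimetric quantities of a fitted uptake model."""

    def __init__(self, model: ThyroidUptakeModel, fit_result: fitting.FitResult):
        self.model = model
        self.fit_result = fit_result
        self._tiacs: TIACTable | None = None

    # -- estimates -----------------------------------------------------

    @property
    def coefficients(self) -> ThyroidCoefficients:
        return self.fit_result.coefficients

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients.as_dict(), name="day^-1")

    @property
    def cost(self) -> float:
        return self.fit_result.cost

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def resid(self) -> np.ndarray:
        return self.fit_result.residuals

    @property
    def fittedvalues(self) -> np.ndarray:
        obs = np.array([m.riu for m in self.fit_result.measurements])
        return obs + self.fit_result.residuals

    @property
    def fitted_model(self) -> CompartmentModel:
        return self.fit_result.model

    # -- kinetics ------------------------------------------------------

    def tiacs(self) -> TIACTable:
        if self._tiacs is None:
            self._tiacs = tiac(
                self.fitted_model, self.model.spec.nuclide, self.model.spec.route
            )
        return self._tiacs

    @property
    def thyroid_tiac_h(self) -> float:
        return self.tiacs().thyroid_h

    @property
    def whole_body_decay_fraction(self) -> float:
        return whole_body_decays(
            self.fitted_model, self.model.spec.nuclide, self.model.spec.route
        )

    # -- dosimetry -----------------------------------------------------

    def dose(
        self,
        svalues: SValueTable | None = None,
        *,
        thyroid_mass_g: float | None = None,
        weights=DEFAULT_WEIGHTS,
    ) -> DoseResult:
        """Organ absorbed-dose coefficients (mGy/MBq) and effective doses
        (mSv/MBq), optionally with the thyroid self-dose mass-corrected to
        the patient's thyroid mass."""
        svalues = svalues or default_svalue_table()
        if thyroid_mass_g is not None:
            if not thyroid_mass_g > 0:
                raise ValidationError("thyroid mass must be > 0 g")
            svalues = mass_corrected_table(svalues, "thyroid", thyroid_mass_g / 1e3)
        result = absorbed_dose(self.tiacs(), svalues)
        e = effective_dose(
            result.organ_doses("male"), result.organ_doses("female"), weights
        )
        e0 = effective_dose(
            result.organ_doses("male"),
            result.organ_doses("female"),
            weights,
            zero_thyroid=True,
        )
        return DoseResult(
            by_nuclide=result.by_nuclide,
            effective_dose=e,
            effective_dose_no_thyroid=e0,
        )

    def administered_activity(
        self,
        prescribed_dose_gy: float,
        thyroid_mass_g: float,
        mean_energy_j: float | None = None,
    ) -> float:
        """EANM activity prescription A = D·M/(Ē·∫RIU dt), MBq."""
        plan = PlanInputs(
            prescribed_dose_gy=prescribed_dose_gy,
            thyroid_mass_kg=thyroid_mass_g / 1e3,
            mean_energy_j=mean_energy_j
            or mean_energy_per_decay_j(self.model.spec.nuclide),
            riu_integral_h=self.thyroid_tiac_h,
        )
        return administered_activity(plan)

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "        Thyroid Uptake Model Results",
            "=" * 52,
            f"{'Nuclide:':<22}{spec.nuclide:>30}",
            f"{'Route:':<22}{spec.route:>30}",
            f"{'Starting variant:':<22}{str(spec.variant):>30}",
            f"{'Blocked thyroid:':<22}{str(spec.blocked):>30}",
            f"{'Measurements:':<22}{len(self.fit_result.measurements):>30}",
            f"{'Free parameters:':<22}{len(spec.free_parameters):>30}",
            f"{'Starts used:':<22}{self.fit_result.n_starts_used:>30}",
            f"{'Converged:':<22}{str(self.converged):>30}",
            f"{'Cost (SSR):':<22}{self.cost:>30.3e}",
            "-" * 52,
            f"{'coefficient':<28}{'day^-1':>12}",
        ]
        for name, value in self.coefficients.as_dict().items():
            lines.append(f"{name:<28}{value:>12.4g}")
        lines += [
            "-" * 52,
            f"{'Thyroid TIAC [h]:':<28}{self.thyroid_tiac_h:>12.1f}",
            f"{'In-body decay fraction:':<28}{self.whole_body_decay_fraction:>12.3f}",
            "=" * 52,
            "Individual coefficients can trade off along the fit",
            "ridge; the thyroid TIAC is the identified quantity.",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured points and fitted RIU(t) curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.fit_result.fitted_curve
        ax.plot(curve["time_h"], curve["riu"], label="fitted model")
        t = [m.time_h for m in self.fit_result.measurements]
        y = [m.riu for m in self.fit_result.measurements]
        ax.plot(t, y, "o", label="measured")
        ax.set_xlabel("time after administration [h]")
        ax.set_ylabel("fractional thyroid uptake RIU(t)")
        ax.legend()
        return ax
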