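"""Linear kinetics: time-activity curves, RIU, TIACs and whole-body decays.

The compartment transfers, physical decay and progeny ingrowth together form
a first-order linear ODE system.  It is solved exactly (matrix exponential
with scaling-and-squaring, robust to the near-defective spectra these
stiff biokinetic matrices can have), never by step-wise integration; the
time-integrated activity coefficients come from a direct linear solve of
``-M x = y0`` (the integral of the state to infinity).

State bookkeeping is done in *nuclei* normalised to the administered parent
activity; reported quantities are activity fractions (multiplying member
``k`` by λ_k/λ_parent), so a unit administered activity of the parent maps
to activity fraction 1 at the route entry at t = 0.

Internal time unit: days.  User-facing times and TIACs: hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve as linsolve

from .compartments import CompartmentModel
from .errors import ConfigurationError, DataIntegrityError, ValidationError
from .nuclides import Nuclide, build_decay_chain
from .units import days_to_hours, hours_to_days

__all__ = [
    "StateMatrix",
    "ActivityCurves",
    "TIACTable",
    "assemble_matrix",
    "solve_activities",
    "riu",
    "tiac",
    "tiac_by_quadrature",
    "whole_body_decays",
]


@dataclass(frozen=True)
class StateMatrix:
    """Assembled block system over (compartment × chain member)."""

    matrix: np.ndarray  # (n*m, n*m), day^-1, nuclei units
    y0: np.ndarray  # initial nuclei (unit administered parent activity)
    model: CompartmentModel
    chain: tuple[tuple[Nuclide, float], ...]
    route: str
    include_decay: bool

    @property
    def n_compartments(self) -> int:
        return self.model.n_compartments

    @property
    def n_members(self) -> int:
        return len(self.chain)

    def member_symbols(self) -> list[str]:
        return [nuc.symbol for nuc, _ in self.chain]

    def activity_scale(self) -> np.ndarray:
        """Per-member factor converting nuclei to activity fractions."""
        lam_parent = self.chain[0][0].decay_constant
        if not self.include_decay:
            return np.ones(self.n_members)
        return np.array(
            [nuc.decay_constant / lam_parent for nuc, _ in self.chain]
        )


def assemble_matrix(
    model: CompartmentModel,
    chain: list[tuple[Nuclide, float]],
    route: str,
    *,
    include_decay: bool = True,
    progeny_models: dict[str, CompartmentModel] | None = None,
) -> StateMatrix:
    """Build the block state matrix for a decay chain on a model.

    Progeny occupy the same compartment census as the parent and, unless a
    progeny-specific model is supplied in ``progeny_models``, transfer with
    the parent's coefficients (a stated simplification: untraced progeny
    decay where they are created or where parent kinetics carry them).
    """
    if not chain:
        raise ValidationError("decay chain must be nonempty")
    if route not in model.route_entry:
        raise ConfigurationError(
            f"route {route!r} not supported by model {model.name!r} "
            f"(supported: {sorted(model.route_entry)})"
        )
    if not include_decay and len(chain) > 1:
        raise ValidationError(
            "decay-off (stable tracer) mode is only meaningful for a "
            "single-member chain"
        )
    n = model.n_compartments
    m = len(chain)
    symbols = [nuc.symbol for nuc, _ in chain]
    M = np.zeros((n * m, n * m))
    for k, (nuc, _cum) in enumerate(chain):
        member_model = (progeny_models or {}).get(nuc.symbol, model)
        if member_model.names != model.names:
            raise DataIntegrityError(
                f"progeny model for {nuc.symbol} must share the parent "
                "model's compartment census"
            )
        T = member_model.transfer_matrix()
        block = slice(k * n, (k + 1) * n)
        lam = nuc.decay_constant if include_decay else 0.0
        M[block, block] = T - lam * np.eye(n)
        # ingrowth from any earlier chain member that lists this nuclide
        for j in range(k):
            parent_nuc = chain[j][0]
            branching = dict(parent_nuc.progeny).get(nuc.symbol, 0.0)
            if branching > 0:
                pblock = slice(j * n, (j + 1) * n)
                M[block, pblock] += branching * parent_nuc.decay_constant * np.eye(n)
    if not np.all(np.isfinite(M)):
        raise ValidationError("non-finite transfer coefficient in model")
    y0 = np.zeros(n * m)
    y0[model.index(model.route_entry[route])] = 1.0
    return StateMatrix(M, y0, model, tuple(chain), route, include_decay)


@dataclass(frozen=True)
class ActivityCurves:
    """Activity fractions per (chain member, compartment) on a time grid."""

    times_h: np.ndarray
    activities: np.ndarray  # (n_members, n_compartments, n_times)
    model: CompartmentModel
    member_symbols: tuple[str, ...]
    includes_physical_decay: bool

    def fraction(self, compartment: str, member: str | None = None) -> np.ndarray:
        i = self.model.index(compartment)
        if member is None:
            member = self.member_symbols[0]
        k = self.member_symbols.index(member)
        return self.activities[k, i, :]

    def region_fraction(self, region: str, member: str | None = None) -> np.ndarray:
        comps = self.model.regions().get(region, [])
        if not comps:
            raise ConfigurationError(f"model has no region {region!r}")
        return sum(self.fraction(c, member) for c in comps)

    def total_in_body(self, member: str | None = None) -> np.ndarray:
        return sum(self.fraction(c, member) for c in self.model.in_body_names())

    def total_everywhere(self, member: str | None = None) -> np.ndarray:
        return sum(self.fraction(c.name, member) for c in self.model.compartments)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: time_h, compartment, chain_member, fraction."""
        records = []
        for k, sym in enumerate(self.member_symbols):
            for i, comp in enumerate(self.model.names):
                for t, a in zip(self.times_h, self.activities[k, i, :]):
                    records.append((float(t), comp, sym, float(a)))
        return pd.DataFrame(
            records, columns=["time_h", "compartment", "chain_member", "fraction"]
        )


def solve_activities(state: StateMatrix, times_h) -> ActivityCurves:
    """Exact solution of the linear system at the requested times (hours).

    Times must be non-negative and sorted; the solution propagates with one
    matrix exponential per distinct time step.
    """
    times_h = np.atleast_1d(np.asarray(times_h, dtype=float))
    if times_h.size == 0:
        raise ValidationError("times must be nonempty")
    if np.any(times_h < 0) or np.any(np.diff(times_h) < 0):
        raise ValidationError("times must be >= 0 and sorted ascending")
    times_d = hours_to_days(times_h)
    n, m = state.n_compartments, state.n_members
    out = np.empty((m * n, times_h.size))
    y = state.y0.copy()
    prev_t = 0.0
    propagators: dict[float, np.ndarray] = {}
    for col, t in enumerate(times_d):
        dt = t - prev_t
        if dt > 0:
            P = propagators.get(dt)
            if P is None:
                P = expm(state.matrix * dt)
                propagators[dt] = P
            y = P @ y
        prev_t = t
        out[:, col] = y
    scale = state.activity_scale()
    acts = out.reshape(m, n, times_h.size) * scale[:, None, None]
    negmin = acts.min()
    if negmin < -1e-9:
        warnings.warn(
            f"solver produced activity {negmin:.3e} below tolerance; clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    acts = np.clip(acts, 0.0, None)
    return ActivityCurves(
        times_h=times_h,
        activities=acts,
        model=state.model,
        member_symbols=tuple(state.member_symbols()),
        includes_physical_decay=state.include_decay,
    )


def riu(
    model: CompartmentModel,
    nuclide: str = "I-131",
    route: str = "oral",
    times_h=(24.0,),
    *,
    registry=None,
) -> np.ndarray:
    """Fractional thyroid uptake RIU(t): iodide + organic thyroid activity
    of the *parent* nuclide as a fraction of administered activity, physical
    decay included (no decay correction)."""
    chain = build_decay_chain(nuclide, registry=registry)[:1]
    state = assemble_matrix(model, chain, route)
    curves = solve_activities(state, times_h)
    return curves.region_fraction("thyroid", member=nuclide)


@dataclass(frozen=True)
class TIACTable:
    """Time-integrated activity coefficients in hours (MBq·h per MBq
    administered), per source region and chain member."""

    table: pd.DataFrame  # index: region, columns: member symbols, values: hours
    by_compartment: pd.DataFrame  # index: compartment
    model: CompartmentModel
    route: str
    parent: str

    def region_hours(self, region: str, member: str | None = None) -> float:
        member = member or self.parent
        try:
            return float(self.table.loc[region, member])
        except KeyError:
            raise ConfigurationError(
                f"no TIAC for region {region!r} / member {member!r}"
            ) from None

    @property
    def thyroid_h(self) -> float:
        return self.region_hours("thyroid")

    def total_in_body_h(self, member: str | None = None) -> float:
        member = member or self.parent
        in_body_regions = {
            c.region for c in self.model.compartments if c.in_body
        }
        return float(
            self.table.loc[self.table.index.isin(in_body_regions), member].sum()
        )

    def sources(self) -> list[str]:
        return list(self.table.index)


def _integrated_nuclei(state: StateMatrix) -> np.ndarray:
    """∫0^∞ y(t) dt (days) by direct linear solve of -M x = y0."""
    try:
        x = linsolve(-state.matrix, state.y0)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "time-integrated activity requires a decaying (or fully "
            "excreted) system; enable physical decay"
        ) from exc
    if not np.all(np.isfinite(x)) or np.any(x < -1e-9):
        raise ValidationError(
            "singular or unstable system: time integrals do not converge; "
            "enable physical decay"
        )
    return np.clip(x, 0.0, None)


def tiac(
    model: CompartmentModel,
    nuclide: str = "I-131",
    route: str = "oral",
    *,
    registry=None,
    progeny_models=None,
) -> TIACTable:
    """Analytic TIACs (hours) per source region and chain member."""
    chain = build_decay_chain(nuclide, registry=registry)
    state = assemble_matrix(model, chain, route, progeny_models=progeny_models)
    x = _integrated_nuclei(state)  # nuclei-days
    n, m = state.n_compartments, state.n_members
    scale = state.activity_scale()
    per_comp = days_to_hours(x.reshape(m, n) * scale[:, None]).T  # (n, m)
    symbols = state.member_symbols()
    by_comp = pd.DataFrame(per_comp, index=model.names, columns=symbols)
    regions = pd.Series({c.name: c.region for c in model.compartments})
    by_region = by_comp.groupby(regions).sum()
    return TIACTable(
        table=by_region,
        by_compartment=by_comp,
        model=model,
        route=route,
        parent=symbols[0],
    )


def tiac_by_quadrature(
    model: CompartmentModel,
    nuclide: str = "I-131",
    route: str = "oral",
    *,
    region: str = "thyroid",
    t_max_h: float = 24.0 * 400,
    n_points: int = 20000,
    registry=None,
) -> float:
    """Trapezoid cross-check of the analytic TIAC on a dense grid (hours).

    Test oracle; deliberately independent of the linear-solve path."""
    chain = build_decay_chain(nuclide, registry=registry)
    state = assemble_matrix(model, chain, route)
    times = np.linspace(0.0, t_max_h, n_points)
    curves = solve_activities(state, times)
    y = curves.region_fraction(region, member=nuclide)
    return float(np.trapezoid(y, times))


def whole_body_decays(
    model: CompartmentModel,
    nuclide: str = "I-131",
    route: str = "oral",
    *,
    member: str | None = None,
    registry=None,
) -> float:
    """Fraction of administered nuclei of ``member`` (default: the parent)
    that decay inside the body: λ · Σ over in-body compartments of the
    time-integrated activity."""
    chain = build_decay_chain(nuclide, registry=registry)
    state = assemble_matrix(model, chain, route)
    member = member or nuclide
    symbols = state.member_symbols()
    if member not in symbols:
        raise ConfigurationError(f"{member!r} is not in the decay chain of {nuclide}")
    k = symbols.index(member)
    x = _integrated_nuclei(state)  # nuclei-days
    n = state.n_compartments
    lam_member = chain[k][0].decay_constant
    in_body = np.array([c.in_body for c in model.compartments])
    nuclei_days = x[k * n : (k + 1) * n][in_body].sum()
    # y is in units of administered parent nuclei, so λ_member · ∫y dt is
    # directly the fraction of administered nuclei decaying in the body
    return float(lam_member * nuclei_days)
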