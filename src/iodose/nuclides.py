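"""Nuclide registry: decay constants, decay chains and emission spectra.

The registry ships the four nuclear-medicine iodine isotopes (I-131, I-123,
I-124, I-125) together with their radioactive progeny; the file format (see
``data/nuclides.txt``) is a documented, extensible delimited-text format so
users can register further iodine isotopes without touching code.

Energies are stored in MeV in the data file and exposed in joule (the unit
the energy-yield product Δ_i = E_i · Y_i enters dosimetry with) as well as
MeV for readability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import DataIntegrityError, UnknownNuclideError, ValidationError
from .units import HOURS_PER_DAY, LN2, MEV_TO_J

#: Default chain truncation: progeny shorter-lived than 15 minutes are
#: treated as decaying where their parent sits.
DEFAULT_MIN_HALF_LIFE_DAYS = 15.0 / 60.0 / HOURS_PER_DAY

PHOTON = "photon"
ELECTRON = "electron"


@dataclass(frozen=True)
class Transition:
    """One (possibly aggregated) emission line."""

    radiation_class: str  # "photon" or "electron"
    energy_mev: float
    yield_per_decay: float

    @property
    def energy_j(self) -> float:
        return self.energy_mev * MEV_TO_J

    @property
    def energy_yield_j(self) -> float:
        """Δ = E·Y, joule per nuclear transformation."""
        return self.energy_j * self.yield_per_decay


@dataclass(frozen=True)
class EmissionSpectrum:
    transitions: tuple[Transition, ...]

    def energy_per_decay_j(self, radiation_class: str | None = None) -> float:
        """Total emitted energy per decay (joule), optionally per class."""
        return sum(
            t.energy_yield_j
            for t in self.transitions
            if radiation_class is None or t.radiation_class == radiation_class
        )


@dataclass(frozen=True)
class Nuclide:
    symbol: str
    half_life_days: float  # math.inf for stable
    progeny: tuple[tuple[str, float], ...]  # (symbol, branching fraction)
    emissions: EmissionSpectrum = field(default_factory=lambda: EmissionSpectrum(()))

    @property
    def stable(self) -> bool:
        return math.isinf(self.half_life_days)

    @property
    def decay_constant(self) -> float:
        """λ = ln2 / T½ in day^-1; 0 for stable nuclides."""
        if self.stable:
            return 0.0
        return LN2 / self.half_life_days


class NuclideRegistry:
    """Parsed registry; normally accessed through the module-level helpers."""

    def __init__(self, nuclides: dict[str, Nuclide]):
        self._nuclides = dict(nuclides)

    @classmethod
    def from_file(cls, path) -> "NuclideRegistry":
        half_lives: dict[str, float] = {}
        progeny: dict[str, list[tuple[str, float]]] = {}
        emissions: dict[str, list[Transition]] = {}
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "N":
                    _, symbol, hl = fields
                    half_lives[symbol] = (
                        math.inf if hl == "stable" else float(hl)
                    )
                elif tag == "P":
                    _, parent, daughter, frac = fields
                    progeny.setdefault(parent, []).append((daughter, float(frac)))
                elif tag == "E":
                    _, symbol, rclass, energy, yld = fields
                    if rclass not in (PHOTON, ELECTRON):
                        raise ValueError(f"bad radiation class {rclass!r}")
                    emissions.setdefault(symbol, []).append(
                        Transition(rclass, float(energy), float(yld))
                    )
                else:
                    raise ValueError(f"unknown record tag {tag!r}")
            except (ValueError, TypeError) as exc:
                raise DataIntegrityError(
                    f"{path}:{lineno}: malformed registry record {raw!r}: {exc}"
                ) from exc

        nuclides = {}
        for symbol, hl in half_lives.items():
            if not hl > 0:
                raise DataIntegrityError(f"{symbol}: half-life must be positive")
            branches = tuple(progeny.get(symbol, ()))
            total = sum(f for _, f in branches)
            if any(not 0.0 <= f <= 1.0 for _, f in branches) or total > 1.0 + 1e-9:
                raise DataIntegrityError(
                    f"{symbol}: branching fractions must lie in [0,1] and sum to <= 1"
                )
            for daughter, _ in branches:
                if daughter not in half_lives:
                    raise DataIntegrityError(
                        f"{symbol}: progeny {daughter!r} has no registry entry"
                    )
            spec = EmissionSpectrum(tuple(emissions.get(symbol, ())))
            if any(t.yield_per_decay < 0 for t in spec.transitions):
                raise DataIntegrityError(f"{symbol}: negative emission yield")
            nuclides[symbol] = Nuclide(symbol, hl, branches, spec)
        return cls(nuclides)

    def symbols(self) -> list[str]:
        return sorted(self._nuclides)

    def get(self, symbol: str) -> Nuclide:
        try:
            return self._nuclides[symbol]
        except KeyError:
            raise UnknownNuclideError(symbol, self.symbols()) from None

    def extend_from_file(self, path) -> "NuclideRegistry":
        """Return a new registry with user records merged over the shipped ones."""
        extra = NuclideRegistry.from_file(path)
        merged = dict(self._nuclides)
        merged.update(extra._nuclides)
        return NuclideRegistry(merged)


_default_registry: NuclideRegistry | None = None


def default_registry() -> NuclideRegistry:
    global _default_registry
    if _default_registry is None:
        with resources.as_file(
            resources.files("iodose.data").joinpath("nuclides.txt")
        ) as p:
            _default_registry = NuclideRegistry.from_file(p)
    return _default_registry


def get_nuclide(symbol: str, registry: NuclideRegistry | None = None) -> Nuclide:
    """Look up a fully populated nuclide record by symbol (e.g. ``"I-131"``)."""
    reg = registry or default_registry()
    return reg.get(symbol)


def build_decay_chain(
    symbol: str,
    min_half_life_days: float = DEFAULT_MIN_HALF_LIFE_DAYS,
    registry: NuclideRegistry | None = None,
) -> list[tuple[Nuclide, float]]:
    """Radioactive decay chain starting at ``symbol``.

    Returns ``[(nuclide, cumulative branching), ...]`` with the parent first
    (cumulative branching 1).  Stable members end the chain and are excluded
    (they contribute no decays).  Radioactive members with half-life below
    ``min_half_life_days`` are truncated: their decays are attributed to the
    parent's compartment, a stated simplification appropriate for short-lived
    progeny.
    """
    reg = registry or default_registry()
    parent = reg.get(symbol)
    if parent.stable:
        raise ValidationError(f"{symbol} is stable; no decay chain to build")

    chain: list[tuple[Nuclide, float]] = []
    seen_on_path: set[str] = set()

    def visit(nuc: Nuclide, cum: float, path: set[str]) -> None:
        if nuc.symbol in path:
            raise DataIntegrityError(
                f"cyclic decay chain involving {nuc.symbol}"
            )
        if nuc.stable:
            return
        if nuc is not parent and nuc.half_life_days < min_half_life_days:
            return  # truncated: decays attributed upstream
        for existing in chain:
            if existing[0].symbol == nuc.symbol:
                raise DataIntegrityError(
                    f"decay chain revisits {nuc.symbol}; converging chains "
                    "are not supported by the registry format"
                )
        chain.append((nuc, cum))
        for daughter_symbol, frac in nuc.progeny:
            visit(reg.get(daughter_symbol), cum * frac, path | {nuc.symbol})

    visit(parent, 1.0, seen_on_path)
    return chain
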