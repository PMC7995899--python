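"""Compartment models for systemic iodine.

Two model families ship with the package:

* the ICRP-style systemic iodine model — 30 named compartments (alimentary
  tract, blood iodide/organic, the two thyroid pools, secretory organs,
  kidneys, liver, distributed "other tissue" pools, bladder and the urine
  and faeces excretion sinks) connected by 48 first-order transfer
  coefficients, with normal / low / high uptake variants and a blocked
  thyroid mode that zeroes organification;
* the EANM pre-therapeutic two-compartment model (blood pool supporting a
  thyroid compartment, with renal and hormonal excretion).

Only the four coefficients governing thyroid iodide/iodine handling are
patient-adjustable in the systemic model; everything else is reference
physiology.  Models are value objects: modification helpers return new
instances and never mutate the original.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    UnsupportedModelError,
    ValidationError,
)

ORAL = "oral"
INTRAVENOUS = "intravenous"

#: The four patient-adjustable transfer arrows of the systemic model.
THYROID_TRANSFER_KEYS = {
    "blood_to_thyroid_iodide": ("blood_iodide", "thyroid_iodide"),
    "thyroid_iodide_to_blood": ("thyroid_iodide", "blood_iodide"),
    "thyroid_iodide_to_organic": ("thyroid_iodide", "thyroid_organic"),
    "organic_to_blood": ("thyroid_organic", "blood_organic"),
}

UPTAKE_CLASSES = ("normal", "low", "high", "blocked")
AGE_CLASSES = ("adult", "15y", "10y", "5y", "1y", "100d")


@dataclass(frozen=True)
class ThyroidCoefficients:
    """The four thyroid transfer coefficients, day^-1."""

    blood_to_thyroid_iodide: float
    thyroid_iodide_to_blood: float
    thyroid_iodide_to_organic: float
    organic_to_blood: float

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"thyroid coefficient {name} must be finite and >= 0, got {value}"
                )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in THYROID_TRANSFER_KEYS}


@dataclass(frozen=True)
class ModelVariant:
    uptake_class: str = "normal"
    age_class: str = "adult"

    def __post_init__(self):
        if self.uptake_class not in UPTAKE_CLASSES:
            raise ValidationError(
                f"uptake_class must be one of {UPTAKE_CLASSES}, got {self.uptake_class!r}"
            )
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )


@dataclass(frozen=True)
class EANMParameters:
    """Rate constants of the EANM two-compartment model, day^-1."""

    k_t: float  # blood pool -> thyroid uptake
    k_r: float  # blood pool -> urine (renal clearance)
    k_h: float  # thyroid -> excreted hormone

    def __post_init__(self):
        for name in ("k_t", "k_r", "k_h"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class Compartment:
    name: str
    region: str  # source-region label used by dosimetry
    in_body: bool  # False for excretion sinks


@dataclass(frozen=True)
class CompartmentModel:
    """Named compartments plus a non-negative transfer-coefficient map.

    ``transfers[(a, b)]`` is the first-order rate (day^-1) from compartment
    ``a`` to ``b``; ``route_entry`` maps administration routes to the entry
    compartment.
    """

    name: str
    compartments: tuple[Compartment, ...]
    transfers: dict[tuple[str, str], float]
    route_entry: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise DataIntegrityError(f"{self.name}: duplicate compartment names")
        known = set(names)
        for (a, b), k in self.transfers.items():
            if a not in known or b not in known:
                raise DataIntegrityError(
                    f"{self.name}: transfer {a}->{b} references unknown compartment"
                )
            if a == b:
                raise DataIntegrityError(f"{self.name}: self-transfer {a}->{a}")
            if not np.isfinite(k) or k < 0:
                raise ValidationError(
                    f"{self.name}: transfer coefficient {a}->{b} must be >= 0, got {k}"
                )
        for route, entry in self.route_entry.items():
            if entry not in known:
                raise DataIntegrityError(
                    f"{self.name}: route {route!r} enters unknown compartment {entry!r}"
                )

    # -- introspection -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"{self.name}: no compartment {name!r}"
            ) from None

    def compartment(self, name: str) -> Compartment:
        return self.compartments[self.index(name)]

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def n_transfers(self) -> int:
        """Number of nonzero transfer coefficients."""
        return sum(1 for k in self.transfers.values() if k > 0)

    def in_body_names(self) -> list[str]:
        return [c.name for c in self.compartments if c.in_body]

    def regions(self) -> dict[str, list[str]]:
        """Source-region label -> compartment names carrying it."""
        out: dict[str, list[str]] = {}
        for c in self.compartments:
            out.setdefault(c.region, []).append(c.name)
        return out

    def transfer_matrix(self) -> np.ndarray:
        """Transfer-only rate matrix T with T[i, j] = k(j -> i) and
        T[j, j] = -(total outflow of j).  Column sums are <= 0 for in-body
        compartments (material is conserved or leaves to a sink column)."""
        n = self.n_compartments
        idx = {c.name: i for i, c in enumerate(self.compartments)}
        T = np.zeros((n, n))
        for (a, b), k in self.transfers.items():
            T[idx[b], idx[a]] += k
            T[idx[a], idx[a]] -= k
        return T

    def reachable_from(self, route: str) -> set[str]:
        if route not in self.route_entry:
            raise ConfigurationError(
                f"{self.name}: route {route!r} not supported "
                f"(supported: {sorted(self.route_entry)})"
            )
        adjacency: dict[str, set[str]] = {}
        for (a, b), k in self.transfers.items():
            if k > 0:
                adjacency.setdefault(a, set()).add(b)
        seen = {self.route_entry[route]}
        stack = [self.route_entry[route]]
        while stack:
            for nxt in adjacency.get(stack.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    # -- thyroid coefficient handling ---------------------------------

    def thyroid_coefficients(self) -> ThyroidCoefficients:
        try:
            return ThyroidCoefficients(
                **{
                    name: self.transfers.get(key, 0.0)
                    for name, key in THYROID_TRANSFER_KEYS.items()
                }
            )
        except ValidationError:  # pragma: no cover - shipped data is valid
            raise

    def with_thyroid_coefficients(
        self, coeffs: ThyroidCoefficients
    ) -> "CompartmentModel":
        """Return a copy with the four thyroid coefficients replaced."""
        for key in THYROID_TRANSFER_KEYS.values():
            if key[0] not in self.names or key[1] not in self.names:
                raise ConfigurationError(
                    f"{self.name}: not a systemic iodine model; cannot set "
                    "thyroid coefficients"
                )
        transfers = dict(self.transfers)
        for name, key in THYROID_TRANSFER_KEYS.items():
            transfers[key] = getattr(coeffs, name)
        return replace(self, transfers=transfers)


def set_thyroid_coefficients(
    model: CompartmentModel, coeffs: ThyroidCoefficients
) -> CompartmentModel:
    """Functional alias for :meth:`CompartmentModel.with_thyroid_coefficients`."""
    return model.with_thyroid_coefficients(coeffs)


# ---------------------------------------------------------------------------
# model definition file parsing


def _parse_model_file(path) -> tuple[list[Compartment], dict[str, dict], dict]:
    """Parse the delimited-text model definition format.

    Records (tab-separated):
      ``C name region in_body`` — compartment census;
      ``T variant from to k_per_day`` — one transfer arrow of one variant.
    """
    compartments: list[Compartment] = []
    variants: dict[str, dict[tuple[str, str], float]] = {}
    meta: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line and "=" not in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta.setdefault(key.strip(), value.strip())
            continue
        fields = line.split("\t")
        try:
            if fields[0] == "C":
                _, name, region, in_body = fields
                compartments.append(Compartment(name, region, in_body == "1"))
            elif fields[0] == "T":
                _, variant, src, dst, k = fields
                key = (src, dst)
                table = variants.setdefault(variant, {})
                if key in table:
                    raise ValueError(f"duplicate transfer {src}->{dst}")
                table[key] = float(k)
            else:
                raise ValueError(f"unknown record tag {fields[0]!r}")
        except (ValueError, TypeError) as exc:
            raise DataIntegrityError(
                f"{path}:{lineno}: malformed model record {raw!r}: {exc}"
            ) from exc
    return compartments, variants, meta


def load_model_file(path, variant_name: str, *, model_name: str | None = None) -> CompartmentModel:
    """Load one variant of a model definition file (shipped or user-supplied)."""
    compartments, variants, meta = _parse_model_file(path)
    if variant_name not in variants:
        raise UnsupportedModelError(
            f"{path}: no variant {variant_name!r} (available: {sorted(variants)})"
        )
    return CompartmentModel(
        name=model_name or f"{Path(path).stem}:{variant_name}",
        compartments=tuple(compartments),
        transfers=variants[variant_name],
        route_entry={ORAL: "oral_cavity", INTRAVENOUS: "blood_iodide"},
        metadata=dict(meta, variant=variant_name, source=str(path)),
    )


_SYSTEMIC_DATA = "icrp_iodine_adult_synthetic.tsv"


def build_icrp_iodine_model(
    variant: ModelVariant | str = ModelVariant(), *, data_path=None
) -> CompartmentModel:
    """Construct the systemic iodine model for the requested variant.

    Normal, low and high uptake variants differ only in the blood-to-thyroid
    iodide transfer coefficient; ``blocked`` is the normal model with the
    iodide-to-organic (organification) coefficient forced to zero.  Only the
    adult age class ships; other age classes raise
    :class:`UnsupportedModelError`.
    """
    if isinstance(variant, str):
        variant = ModelVariant(uptake_class=variant)
    if variant.age_class != "adult":
        raise UnsupportedModelError(
            f"no coefficient data shipped for age class {variant.age_class!r}; "
            "supply a model definition file for non-adult ages"
        )
    if data_path is None:
        ref = resources.files("iodose.data").joinpath(_SYSTEMIC_DATA)
        with resources.as_file(ref) as p:
            return _build_systemic(p, variant)
    return _build_systemic(data_path, variant)


def _build_systemic(path, variant: ModelVariant) -> CompartmentModel:
    file_variant = "normal" if variant.uptake_class == "blocked" else variant.uptake_class
    model = load_model_file(
        path,
        file_variant,
        model_name=f"icrp-iodine-{variant.age_class}-{variant.uptake_class}",
    )
    model = replace(
        model, metadata=dict(model.metadata, uptake_class=variant.uptake_class,
                             age_class=variant.age_class)
    )
    if variant.uptake_class == "blocked":
        coeffs = replace(model.thyroid_coefficients(), thyroid_iodide_to_organic=0.0)
        model = model.with_thyroid_coefficients(coeffs)
    return model


def build_eanm_model(params: EANMParameters) -> CompartmentModel:
    """The EANM two-compartment model: blood pool + thyroid, intravenous entry.

    Hormone excretion (k_h) routes thyroid activity to an out-of-body sink
    rather than back to blood: with three rate constants and the recommended
    three-point measurement schedule, a recirculating topology would leave
    the fit underdetermined.
    """
    compartments = (
        Compartment("blood_pool", "blood", True),
        Compartment("thyroid", "thyroid", True),
        Compartment("urine", "urine", False),
        Compartment("excreted_hormone", "excreta", False),
    )
    transfers = {
        ("blood_pool", "thyroid"): params.k_t,
        ("blood_pool", "urine"): params.k_r,
        ("thyroid", "excreted_hormone"): params.k_h,
    }
    return CompartmentModel(
        name="eanm-two-compartment",
        compartments=compartments,
        transfers=transfers,
        route_entry={INTRAVENOUS: "blood_pool"},
        metadata={"family": "eanm"},
    )
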