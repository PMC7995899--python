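import numpy as np
import pytest

from iodose import (
    ThyroidCoefficients,
    build_icrp_iodine_model,
)
from iodose.compartments import Compartment, CompartmentModel, INTRAVENOUS

#: the reference normal-uptake thyroid coefficients (day^-1)
NORMAL_COEFFS = ThyroidCoefficients(7.3, 36.0, 95.0, 0.0077)
#: patient-specific fitted set of the worked hyperthyroid example
PATIENT1_COEFFS = ThyroidCoefficients(55.0, 12.0, 8.9, 0.083)

FOUR_POINT_SCHEDULE_H = [5.0, 24.0, 48.0, 120.0]


@pytest.fixture(scope="session")
def normal_model():
    return build_icrp_iodine_model("normal")


@pytest.fixture(scope="session")
def patient1_model(normal_model):
    return normal_model.with_thyroid_coefficients(PATIENT1_COEFFS)


def random_linear_model(rng: np.random.Generator, n: int = 5) -> CompartmentModel:
    """Random connected n-compartment model plus one excretion sink."""
    names = [f"c{i}" for i in range(n)]
    comps = [Compartment(name, "other", True) for name in names]
    comps.append(Compartment("sink", "urine", False))
    transfers = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.5:
                transfers[(names[i], names[j])] = float(rng.uniform(0.05, 5.0))
    # guarantee connectivity and an excretion path
    for i in range(n - 1):
        transfers.setdefault((names[i], names[i + 1]), float(rng.uniform(0.05, 5.0)))
    transfers[(names[n - 1], "sink")] = float(rng.uniform(0.05, 2.0))
    return CompartmentModel(
        name="random",
        compartments=tuple(comps),
        transfers=transfers,
        route_entry={INTRAVENOUS: names[0]},
    )


def rk4(matrix: np.ndarray, y0: np.ndarray, t_end: float, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta integration of y' = M y.

    Independent oracle for the matrix-exponential solver."""
    y = y0.astype(float).copy()
    steps = int(round(t_end / dt))
    for _ in range(steps):
        k1 = matrix @ y
        k2 = matrix @ (y + 0.5 * dt * k1)
        k3 = matrix @ (y + 0.5 * dt * k2)
        k4 = matrix @ (y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
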