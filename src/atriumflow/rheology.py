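"""Blood constitutive models and dimensionless-number helpers.

Blood is treated as a generalized-Newtonian fluid whose apparent viscosity
follows the Bird-Carreau law

    mu(gamma) = mu_inf + (mu0 - mu_inf) * [1 + (lambda*gamma)^2]^((n-1)/2)

interpolating between a low-shear plateau ``mu0`` and a high-shear plateau
``mu_inf`` with time constant ``lambda`` and power-law index ``n``.  A
constant-viscosity Newtonian comparator is available through the same
interface so that solver and metric code never branches on the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import constants as C

__all__ = [
    "FluidProperties",
    "ReynoldsRecord",
    "apparent_viscosity",
    "reynolds_number",
    "laminar_check",
]


@dataclass(frozen=True)
class FluidProperties:
    """Density plus rheology parameters of the working fluid.

    Parameters
    ----------
    rho : float
        Mass density [kg/m^3].
    mu0, mu_inf : float
        Low- and high-shear viscosity plateaus [Pa s]; ``mu0 >= mu_inf > 0``.
    lambda_t : float
        Carreau time constant [s].
    n_index : float
        Power-law index, ``0 < n <= 1`` (shear-thinning for n < 1).
    model : {"bird_carreau", "newtonian"}
    mu_newt : float
        Constant viscosity used when ``model == "newtonian"`` [Pa s].
    """

    rho: float = C.BLOOD_DENSITY
    mu0: float = C.CARREAU_MU0
    mu_inf: float = C.CARREAU_MU_INF
    lambda_t: float = C.CARREAU_LAMBDA
    n_index: float = C.CARREAU_N
    model: str = "bird_carreau"
    mu_newt: float = C.NEWTONIAN_MU

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValueError(
                f"need mu0 >= mu_inf > 0, got mu0={self.mu0}, mu_inf={self.mu_inf}"
            )
        if self.lambda_t < 0:
            raise ValueError(f"lambda_t must be non-negative, got {self.lambda_t}")
        if not (0 < self.n_index <= 1):
            raise ValueError(f"n_index must lie in (0, 1], got {self.n_index}")
        if self.model not in ("bird_carreau", "newtonian"):
            raise ValueError(f"unknown rheology model {self.model!r}")
        if self.model == "newtonian" and self.mu_newt <= 0:
            raise ValueError(f"mu_newt must be positive, got {self.mu_newt}")

    @classmethod
    def newtonian(cls, mu: float = C.NEWTONIAN_MU, rho: float = C.BLOOD_DENSITY) -> "FluidProperties":
        """Constant-viscosity comparator with the same density."""
        return cls(rho=rho, model="newtonian", mu_newt=mu)


@dataclass
class ReynoldsRecord:
    """Boundary Reynolds-number summary over one cardiac cycle.

    ``U`` and ``mu_used`` are the time- and patch-averaged velocity magnitude
    and apparent viscosity; min/mean/max come from the time-varying Reynolds
    series built with the patch-averaged quantities.
    """

    boundary_name: str
    U: float
    D: float
    mu_used: float
    re_min: float
    re_mean: float
    re_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.re_min <= self.re_mean <= self.re_max):
            raise ValueError(
                f"need 0 <= re_min <= re_mean <= re_max, got "
                f"({self.re_min}, {self.re_mean}, {self.re_max})"
            )


def apparent_viscosity(gamma_dot, props: FluidProperties | None = None):
    """Apparent viscosity [Pa s] at shear rate ``gamma_dot`` [1/s].

    Accepts scalars or arrays.  For the Bird-Carreau model the result is
    bounded by the two plateaus; for the Newtonian model it is the constant
    ``mu_newt`` broadcast to the input shape.
    """
    if props is None:
        props = FluidProperties()
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    if props.model == "newtonian":
        out = np.full_like(g, props.mu_newt)
    else:
        out = props.mu_inf + (props.mu0 - props.mu_inf) * (
            1.0 + (props.lambda_t * g) ** 2
        ) ** ((props.n_index - 1.0) / 2.0)
    if np.isscalar(gamma_dot) or np.ndim(gamma_dot) == 0:
        return float(out)
    return out


def reynolds_number(rho: float, U: float, D: float, mu: float) -> float:
    """Reynolds number Re = rho * U * D / mu for a boundary of diameter D."""
    if rho <= 0:
        raise ValueError(f"density must be positive, got {rho}")
    if U < 0:
        raise ValueError(f"velocity must be non-negative, got {U}")
    if D <= 0:
        raise ValueError(f"diameter must be positive, got {D}")
    if mu <= 0:
        raise ValueError(f"viscosity must be positive, got {mu}")
    return rho * U * D / mu


def laminar_check(
    re_values: Sequence[float] | Iterable[float],
    names: Sequence[str] | None = None,
    threshold: float = C.LAMINAR_RE_THRESHOLD,
) -> tuple[bool, list[str]]:
    """Check a set of boundary Reynolds numbers against the laminar criterion.

    Returns ``(laminar, warnings)`` where ``laminar`` is True iff every value
    is strictly below ``threshold`` and ``warnings`` names each exceedance.
    """
    values = [float(v) for v in re_values]
    if not values:
        raise ValueError("laminar_check requires at least one Reynolds number")
    if names is not None and len(names) != len(values):
        raise ValueError("names must match re_values in length")
    warnings: list[str] = []
    for i, re in enumerate(values):
        if re >= threshold:
            label = names[i] if names is not None else f"boundary {i}"
            warnings.append(
                f"{label}: Re = {re:g} >= {threshold:g}; laminar assumption questionable"
            )
    return (len(warnings) == 0), warnings


def viscosity_table(
    gamma_min: float = 1e-2,
    gamma_max: float = 1e4,
    n_points: int = 200,
    props: FluidProperties | None = None,
):
    """Log-spaced shear-rate sweep of the configured model and the Newtonian
    comparator, for plotting.  Returns a pandas DataFrame with columns
    ``gamma_dot``, ``mu``, ``mu_newtonian``.
    """
    import pandas as pd

    if props is None:
        props = FluidProperties()
    g = np.logspace(math.log10(gamma_min), math.log10(gamma_max), n_points)
    return pd.DataFrame(
        {
            "gamma_dot": g,
            "mu": apparent_viscosity(g, props),
            "mu_newtonian": np.full(n_points, props.mu_newt),
        }
    )
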