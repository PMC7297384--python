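"""Microscopic two-site binding models and the equilibrium non-identifiability manifold.

Two mechanisms produce identical equilibrium dose-response curves:

* **NC** — one receptor with two *identical* sites and a cooperativity factor
  ``omega`` multiplying the second association rate (``omega < 1`` is negative
  cooperativity).
* **IB** — one receptor with two *independent, different* sites with their own
  association/dissociation rates.

At equilibrium only the dissociation constants matter.  An NC model
``(K, omega)`` with ``omega < 1`` has an IB counterpart ``(K10, K01)`` with the
same dose-response curve, obtained from::

    K**2 / omega = K10 * K01          (geometric condition)
    K / omega    = (K10 + K01) / 2    (arithmetic condition)

whose roots are ``K10, K01 = (K/omega) * (1 ± sqrt(1 - omega))``.  For
``omega > 1`` the roots are complex, so positive cooperativity has no IB
counterpart and the identifiability problem disappears.

Concentration units are abstract throughout the package: all rates and doses
are interpreted relative to an arbitrary reference concentration and time unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NCParams",
    "IBParams",
    "IdentifiabilityError",
    "theta_eq_ib",
    "theta_eq_nc",
    "nc_to_ib",
    "ib_to_nc",
    "params_from_json",
]


class IdentifiabilityError(ValueError):
    """Raised when an NC parameter set has no IB counterpart (omega > 1)."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class NCParams:
    """Negative-cooperativity model: identical sites.

    Parameters
    ----------
    k : float
        Association rate of the first binding (1/(concentration·time)).
    l : float
        Dissociation rate of each site (1/time).
    omega : float
        Dimensionless cooperativity factor on the second association rate;
        ``omega < 1`` slows the second binding (negative cooperativity),
        ``omega = 1`` reduces to identical independent sites.
    """

    k: float
    l: float
    omega: float

    def __post_init__(self) -> None:
        _require_positive(k=self.k, l=self.l, omega=self.omega)

    @property
    def K(self) -> float:
        """Dissociation constant of the first binding, l/k."""
        return self.l / self.k

    def to_json(self) -> str:
        return json.dumps(
            {"model": "NC", "k": self.k, "l": self.l, "omega": self.omega}
        )


@dataclass(frozen=True)
class IBParams:
    """Independent-binding model: two different, non-interacting sites.

    Site labels 10 and 01 are interchangeable (swapping them gives an
    equivalent model); rates are ``k10, k01`` (association,
    1/(concentration·time)) and ``l10, l01`` (dissociation, 1/time).
    """

    k10: float
    k01: float
    l10: float
    l01: float

    def __post_init__(self) -> None:
        _require_positive(k10=self.k10, k01=self.k01, l10=self.l10, l01=self.l01)

    @property
    def K10(self) -> float:
        return self.l10 / self.k10

    @property
    def K01(self) -> float:
        return self.l01 / self.k01

    @property
    def ratio(self) -> float:
        """Association-rate ratio k10/k01, the control parameter of the
        early-time dynamic range in this model."""
        return self.k10 / self.k01

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "IB",
                "k10": self.k10,
                "k01": self.k01,
                "l10": self.l10,
                "l01": self.l01,
            }
        )


def params_from_json(text: str) -> NCParams | IBParams:
    """Deserialize a parameter set written by ``to_json``."""
    obj = json.loads(text)
    tag = obj.pop("model", None)
    if tag == "NC":
        return NCParams(**obj)
    if tag == "IB":
        return IBParams(**obj)
    raise ValueError(f"unknown model tag {tag!r}")


def theta_eq_ib(L, K10: float, K01: float):
    """Equilibrium occupied-site fraction of the IB model.

    theta = (L/(K10+L) + L/(K01+L)) / 2 — the average of two Langmuir
    isotherms, one per independent site.
    """
    _require_positive(K10=K10, K01=K01)
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    out = 0.5 * (L / (K10 + L) + L / (K01 + L))
    return out if out.ndim else float(out)


def theta_eq_nc(L, K: float, omega: float):
    """Equilibrium occupied-site fraction of the NC model.

    theta = (K*L + omega*L**2) / (K**2 + 2*K*L + omega*L**2).
    """
    _require_positive(K=K, omega=omega)
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    out = (K * L + omega * L**2) / (K**2 + 2 * K * L + omega * L**2)
    return out if out.ndim else float(out)


def nc_to_ib(K: float, omega: float) -> tuple[float, float]:
    """Map NC dissociation parameters to the IB pair with the same
    equilibrium curve.

    Returns ``(K10, K01)`` with ``K10 >= K01`` (the manifold's reflection
    symmetry under site swap is resolved canonically).  Raises
    :class:`IdentifiabilityError` for ``omega > 1``: the roots are complex, so
    positively cooperative curves cannot be mimicked by independent sites.
    """
    _require_positive(K=K, omega=omega)
    if omega > 1:
        raise IdentifiabilityError(
            f"omega={omega} > 1: complex roots, no IB counterpart"
        )
    s = np.sqrt(1.0 - omega)
    K10 = (K / omega) * (1.0 + s)
    K01 = (K / omega) * (1.0 - s)
    return float(K10), float(K01)


def ib_to_nc(K10: float, K01: float) -> tuple[float, float]:
    """Map IB dissociation constants to the equivalent NC ``(K, omega)``.

    K = harmonic-type mean 2*K10*K01/(K10+K01); omega = 4*K10*K01/(K10+K01)**2.
    By AM-GM, omega <= 1 always (equality iff K10 == K01): every IB model has
    an *effective* cooperativity factor in the negative-cooperativity range.
    """
    _require_positive(K10=K10, K01=K01)
    s = K10 + K01
    K = 2.0 * K10 * K01 / s
    omega = 4.0 * K10 * K01 / s**2
    return float(K), float(omega)
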