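"""Kinetic rate constants, unit conventions, and concentration rescaling.

The aggregation models are written in terms of five rate constants and an
initial monomer concentration (molar-hour units by default):

``k_n``
    primary nucleation.  Two conventions coexist: the closed in vitro model
    uses a constant heterogeneous source term ``2 k_n`` (units M h^-1), while
    the in vivo models use homogeneous nucleation ``k_n m^2`` (units
    M^-1 h^-1).  A :class:`KineticParameters` instance carries a
    ``kn_convention`` tag so that rescaling applies the correct power of the
    concentration scale.
``k_plus``
    filament elongation (M^-1 h^-1).
``k_2``
    monomer-dependent secondary nucleation (M^-2 h^-1).
``K_m`` / ``K_M``
    Michaelis-Menten-type saturation constants (M^2) for secondary
    nucleation, with respect to monomer concentration (in vitro) or total
    aggregate mass (in vivo).  They are equal unless explicitly overridden.
``m_0``
    monomer concentration (M).

Because the molar-scale rates span ~25 orders of magnitude, all default
fixtures work in micromolar-hour units, i.e. the Table-style molar values
rescaled by ``c = 1e6``.  Every quantity with pure rate units (critical
clearance, halftimes) is invariant under this rescaling.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "KineticParameters",
    "ab42_hepes_parameters",
    "rescale_parameters",
    "validate_parameters",
    "load_parameters",
    "save_parameters",
    "InvalidParameterError",
]

#: Conventions for the primary nucleation rate constant.
KN_INVITRO = "invitro"  # constant source 2*k_n, k_n in concentration/time
KN_HOMOGENEOUS = "homogeneous"  # source k_n*m^2, k_n in 1/(concentration*time)


class InvalidParameterError(ValueError):
    """Raised for structurally invalid parameter values or files."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and concentrations for the aggregation models.

    Attributes
    ----------
    k_n, k_plus, k_2 : float
        Primary nucleation, elongation and secondary nucleation rates.
    K_m, K_M : float
        Monomer- and mass-saturation constants for secondary nucleation.
        ``K_M`` defaults to ``K_m``.
    m_0 : float
        Monomer concentration.
    conc_scale : float
        Dimensionless factor by which concentrations have been rescaled
        relative to molar units (1.0 = molar).
    kn_convention : str
        ``"invitro"`` (constant source) or ``"homogeneous"`` (k_n m^2).
    """

    k_n: float
    k_plus: float
    k_2: float
    K_m: float
    K_M: float | None = None
    m_0: float = 3e-6
    conc_scale: float = 1.0
    kn_convention: str = KN_INVITRO

    def __post_init__(self) -> None:
        if self.K_M is None:
            object.__setattr__(self, "K_M", self.K_m)
        if self.kn_convention not in (KN_INVITRO, KN_HOMOGENEOUS):
            raise InvalidParameterError(
                f"unknown kn_convention {self.kn_convention!r}"
            )

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def with_convention(self, convention: str) -> "KineticParameters":
        """Reinterpret k_n under a different nucleation convention.

        The numeric value is kept; only the tag changes.  The two conventions
        assign different units to k_n, so this is a deliberate act by the
        caller (typically when moving Table-style in vitro parameters into an
        in vivo model).
        """
        return self.replace(kn_convention=convention)


#: A beta 42 in HEPES buffer, molar-hour units.
_AB42_HEPES_MOLAR = dict(
    k_n=1.6e-11,
    k_2=2.1e14,
    K_m=2.3e-17,
    k_plus=1e10,
    m_0=3e-6,
)


def ab42_hepes_parameters(scaled: bool = True) -> KineticParameters:
    """Reference Aβ42 (HEPES buffer) parameter set.

    Parameters
    ----------
    scaled : bool
        If True (default), return the micromolar-hour version (concentration
        scale ``c = 1e6``), in which k_2 = 210, k_plus = 1e4,
        K_m = K_M = 2.3e-5 and m_0 = 3.  If False, return raw molar values.
    """
    p = KineticParameters(**_AB42_HEPES_MOLAR)
    return rescale_parameters(p, 1e6) if scaled else p


def rescale_parameters(params: KineticParameters, c: float) -> KineticParameters:
    """Re-express parameters in concentration units scaled by ``c``.

    Every concentration variable x of a model trajectory maps to c*x; the
    returned parameters produce exactly those scaled trajectories:
    k_2 -> k_2/c^2, k_plus -> k_plus/c, K_m -> K_m*c^2, K_M -> K_M*c^2,
    m_0 -> m_0*c, and k_n -> k_n*c (in vitro constant-source convention)
    or k_n/c (homogeneous k_n m^2 convention).
    """
    if not (isinstance(c, (int, float)) and math.isfinite(c) and c > 0):
        raise InvalidParameterError(f"concentration scale must be positive, got {c!r}")
    kn_power = 1.0 if params.kn_convention == KN_INVITRO else -1.0
    return params.replace(
        k_n=params.k_n * c**kn_power,
        k_plus=params.k_plus / c,
        k_2=params.k_2 / c**2,
        K_m=params.K_m * c**2,
        K_M=params.K_M * c**2,
        m_0=params.m_0 * c,
        conc_scale=params.conc_scale * c,
    )


def validate_parameters(params: KineticParameters) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    out: list[str] = []
    for name in ("k_n", "k_plus", "k_2", "K_m", "K_M", "m_0", "conc_scale"):
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            out.append(f"{name}: must be a finite number, got {v!r}")
        elif v <= 0:
            out.append(f"{name}: must be strictly positive, got {v!r}")
    if (
        params.K_M is not None
        and params.K_m > 0
        and params.K_M > 0
        and not math.isclose(params.K_M, params.K_m, rel_tol=1e-12)
    ):
        out.append(
            "K_M: differs from K_m (allowed, but the default model assumption "
            "is K_M = K_m; make sure the override is intentional)"
        )
    return out


_CONFIG_KEYS = ("k_n", "k_plus", "k_2", "K_m", "K_M", "m_0", "conc_scale")


def load_parameters(path: str | Path) -> KineticParameters:
    """Load a flat key/value parameter file (YAML or JSON dialect).

    Accepted keys are exactly k_n, k_plus, k_2, K_m, K_M, m_0, conc_scale
    (K_M and conc_scale optional); unknown keys are rejected.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: expected a flat key/value mapping")
    unknown = sorted(set(data) - set(_CONFIG_KEYS))
    if unknown:
        raise InvalidParameterError(f"{path}: unknown parameter keys {unknown}")
    missing = sorted({"k_n", "k_plus", "k_2", "K_m", "m_0"} - set(data))
    if missing:
        raise InvalidParameterError(f"{path}: missing required keys {missing}")
    try:
        values = {k: float(v) for k, v in data.items()}
    except (TypeError, ValueError) as exc:
        raise InvalidParameterError(f"{path}: non-numeric value ({exc})") from exc
    return KineticParameters(**values)


def save_parameters(params: KineticParameters, path: str | Path) -> None:
    """Write a parameter file readable by :func:`load_parameters`."""
    path = Path(path)
    payload = {k: getattr(params, k) for k in _CONFIG_KEYS}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
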