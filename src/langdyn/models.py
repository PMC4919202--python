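"""Model definitions for two-language competition dynamics.

Four related planar models of the frequencies ``u1, u2`` of the populations
speaking language 1 and language 2 are supported.  All share logistic
intrinsic growth; they differ in how speakers convert between languages and
in how carrying capacity is shared:

``hybrid_lv``
    Lotka-Volterra growth plus a one-way conversion term ``+c*u1*u2`` /
    ``-c*u1*u2`` (language 1 attracts speakers of language 2).  No diffusion.

``basic_rd``
    The same reaction terms as ``hybrid_lv`` with Fickian diffusion
    ``d_i * Laplacian(u_i)`` added to each species.

``common_capacity_rd``
    One-way conversion, but each species' logistic term saturates against the
    capacity left over by the other: ``a1*u1*(1 - u1/(K - u2))``.

``ecology_society``
    Classic two-species Lotka-Volterra competition (coefficients ``alpha``,
    ``beta``) plus *bidirectional* attractiveness terms ``+c1*u1*u2`` and
    ``+c2*u1*u2``, so each language gains speakers in proportion to contact.
    The ``c1, c2`` rates stand in for social status (media, policy,
    prestige), while the Lotka-Volterra part carries the ecological
    competition for speakers.

The reaction right-hand sides for the two spatial models are

    du1/dt = d1*Lap(u1) + a1*u1*(1 - u1/K1 - alpha*u2/K1) + c1*u1*u2
    du2/dt = d2*Lap(u2) + a2*u2*(1 - u2/K2 - beta*u1/K2)  + c2*u1*u2

(``ecology_society``; set alpha = beta = 0, c1 = c, c2 = -c for the basic
model).  This module evaluates the reaction parts and their analytic
Jacobians; diffusion lives in :mod:`langdyn.pde`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .exceptions import RangeError, SingularStateError, ValidationError

__all__ = [
    "Variant",
    "ModelSpec",
    "RatePair",
    "make_model",
    "reaction_rates",
    "reaction_jacobian",
    "VARIANT_PARAMS",
]

# Relative threshold below which a shared-capacity denominator K - u is
# treated as singular (only when the term it divides is nonzero).
_SINGULAR_RTOL = 1e-9


class Variant(str, Enum):
    """Tag for the four model variants."""

    HYBRID_LV = "hybrid_lv"
    BASIC_RD = "basic_rd"
    COMMON_CAPACITY_RD = "common_capacity_rd"
    ECOLOGY_SOCIETY = "ecology_society"


#: Required parameter names per variant.  Exactly these must be supplied.
VARIANT_PARAMS: Mapping[Variant, tuple[str, ...]] = {
    Variant.HYBRID_LV: ("a1", "a2", "K1", "K2", "c"),
    Variant.BASIC_RD: ("a1", "a2", "K1", "K2", "c", "d1", "d2"),
    Variant.COMMON_CAPACITY_RD: ("a1", "a2", "K", "c", "d1", "d2"),
    Variant.ECOLOGY_SOCIETY: (
        "a1", "a2", "K1", "K2", "c1", "c2", "alpha", "beta", "d1", "d2",
    ),
}

# Parameters that may be zero (diffusion switches off cleanly).
_MAY_BE_ZERO = frozenset({"d1", "d2"})


@dataclass(frozen=True)
class ModelSpec:
    """A validated model variant with its parameter set.

    Only the fields belonging to ``variant`` are set; the rest are ``None``.
    Use :func:`make_model` rather than constructing directly.
    """

    variant: Variant
    a1: float
    a2: float
    K1: float | None = None
    K2: float | None = None
    K: float | None = None
    c: float | None = None
    c1: float | None = None
    c2: float | None = None
    alpha: float | None = None
    beta: float | None = None
    d1: float | None = None
    d2: float | None = None

    @property
    def diffusivities(self) -> tuple[float, float]:
        """(d1, d2), zero for the non-spatial hybrid model."""
        return (self.d1 or 0.0, self.d2 or 0.0)

    def params(self) -> dict[str, float]:
        """The variant's parameters as a plain dict (config-file names)."""
        return {name: getattr(self, name) for name in VARIANT_PARAMS[self.variant]}


@dataclass(frozen=True)
class RatePair:
    """Reaction rates (df/dt, no diffusion) for the two species at a point."""

    f1: float | np.ndarray
    f2: float | np.ndarray


def make_model(variant: Variant | str, **params: float) -> ModelSpec:
    """Build and validate a :class:`ModelSpec`.

    Parameters
    ----------
    variant
        One of the four variant tags (enum or its string value).
    **params
        Exactly the parameters required by the variant (see
        :data:`VARIANT_PARAMS`); extraneous or missing names raise
        :class:`~langdyn.exceptions.ValidationError`, non-positive required
        rates raise :class:`~langdyn.exceptions.RangeError`.
    """
    variant = Variant(variant)
    required = VARIANT_PARAMS[variant]

    extra = [name for name in params if name not in required]
    if extra:
        raise ValidationError(
            f"{variant.value}: {', '.join(extra)} not a {variant.value} parameter"
        )
    missing = [name for name in required if name not in params]
    if missing:
        raise ValidationError(
            f"{variant.value}: missing parameter(s) {', '.join(missing)}"
        )

    values: dict[str, float] = {}
    for name in required:
        value = float(params[name])
        if not np.isfinite(value):
            raise RangeError(f"{name} must be finite, got {value}")
        if name in _MAY_BE_ZERO:
            if value < 0:
                raise RangeError(f"{name} must be >= 0, got {value}")
        elif value <= 0:
            raise RangeError(f"{name} must be > 0, got {value}")
        values[name] = value

    return ModelSpec(variant=variant, **values)


def _check_common_capacity_denominators(u1, u2, K: float) -> None:
    """Raise if a term actually divided by a vanishing K - u is present."""
    bad1 = (np.abs(K - u2) < _SINGULAR_RTOL * K) & (u1 != 0)
    bad2 = (np.abs(K - u1) < _SINGULAR_RTOL * K) & (u2 != 0)
    if np.any(bad1) or np.any(bad2):
        raise SingularStateError(
            "common-capacity denominator K - u vanishes at a state with a "
            "nonzero opposing frequency"
        )


def _safe_ratio(u, den):
    """u/den with the convention 0/0 = 0 (terms carrying a factor u vanish)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(u == 0, 0.0, u / np.where(den == 0, np.nan, den))
    return np.nan_to_num(r, nan=0.0, posinf=np.inf, neginf=-np.inf)


def reaction_rates(model: ModelSpec, point) -> RatePair:
    """Evaluate the non-diffusive right-hand side at a state point.

    ``point`` is ``(u1, u2)``; each component may be a scalar or an ndarray
    (broadcast together).  Evaluation is plain algebra on the printed
    equations, so candidate equilibria with negative coordinates may be probed
    as well.  For the common-capacity model a vanishing denominator
    ``K - u_j`` raises :class:`~langdyn.exceptions.SingularStateError` unless
    the term it divides carries a zero factor.
    """
    u1 = np.asarray(point[0], dtype=float)
    u2 = np.asarray(point[1], dtype=float)
    v = model.variant

    if v in (Variant.HYBRID_LV, Variant.BASIC_RD):
        f1 = model.c * u1 * u2 + model.a1 * u1 * (1.0 - u1 / model.K1)
        f2 = -model.c * u1 * u2 + model.a2 * u2 * (1.0 - u2 / model.K2)
    elif v is Variant.COMMON_CAPACITY_RD:
        K = model.K
        _check_common_capacity_denominators(u1, u2, K)
        f1 = model.a1 * u1 * (1.0 - _safe_ratio(u1, K - u2)) + model.c * u1 * u2
        f2 = model.a2 * u2 * (1.0 - _safe_ratio(u2, K - u1)) - model.c * u1 * u2
    else:  # ecology_society
        f1 = (
            model.a1 * u1 * (1.0 - u1 / model.K1 - model.alpha * u2 / model.K1)
            + model.c1 * u1 * u2
        )
        f2 = (
            model.a2 * u2 * (1.0 - u2 / model.K2 - model.beta * u1 / model.K2)
            + model.c2 * u1 * u2
        )

    if f1.ndim == 0:
        return RatePair(float(f1), float(f2))
    return RatePair(f1, f2)


def reaction_jacobian(model: ModelSpec, point) -> np.ndarray:
    """Analytic 2x2 Jacobian of the reaction terms at a scalar state point.

    Matches the closed-form linearization matrices used in the stability
    analysis entry-for-entry; the same 0/0 = 0 convention as
    :func:`reaction_rates` applies at states where a species is absent.
    """
    u1 = float(point[0])
    u2 = float(point[1])
    v = model.variant

    if v in (Variant.HYBRID_LV, Variant.BASIC_RD):
        return np.array(
            [
                [model.a1 - 2.0 * model.a1 * u1 / model.K1 + model.c * u2,
                 model.c * u1],
                [-model.c * u2,
                 model.a2 - model.c * u1 - 2.0 * model.a2 * u2 / model.K2],
            ]
        )
    if v is Variant.COMMON_CAPACITY_RD:
        K = model.K
        _check_common_capacity_denominators(u1, u2, K)
        r1 = float(_safe_ratio(u1, K - u2))      # u1 / (K - u2)
        r2 = float(_safe_ratio(u2, K - u1))      # u2 / (K - u1)
        return np.array(
            [
                [model.a1 - 2.0 * model.a1 * r1 + model.c * u2,
                 model.c * u1 - model.a1 * r1 * r1],
                [-model.c * u2 - model.a2 * r2 * r2,
                 model.a2 - model.c * u1 - 2.0 * model.a2 * r2],
            ]
        )
    # ecology_society
    a1, a2 = model.a1, model.a2
    K1, K2 = model.K1, model.K2
    al, be = model.alpha, model.beta
    c1, c2 = model.c1, model.c2
    return np.array(
        [
            [a1 - 2.0 * a1 * u1 / K1 - al * a1 * u2 / K1 + c1 * u2,
             c1 * u1 - al * a1 * u1 / K1],
            [c2 * u2 - be * a2 * u2 / K2,
             a2 - 2.0 * a2 * u2 / K2 - be * a2 * u1 / K2 + c2 * u1],
        ]
    )
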