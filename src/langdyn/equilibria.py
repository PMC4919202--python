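"""Closed-form equilibria, p/q stability, and feasibility windows.

Stability of a planar equilibrium is decided from the linearization matrix
``A`` (the reaction Jacobian) through the classic trace/determinant test:
with ``p = -trace(A)`` and ``q = det(A)``,

* ``p > 0`` and ``q > 0``  -> asymptotically stable,
* ``p < 0`` or ``q < 0``   -> unstable,
* ``p = 0`` or ``q = 0``   -> non-hyperbolic: the linear test is
  inconclusive for asymptotic stability.

This is exactly the planar Routh-Hurwitz condition (both eigenvalues have
negative real part iff p, q > 0), which :func:`eigen_stability` uses as an
independent numerical oracle.

Each model variant admits a short list of closed-form equilibria: the origin,
the two single-language states, and one or two interior (coexistence) roots.
Interior candidates may be infeasible (a negative coordinate, or violating a
shared carrying capacity); they are returned flagged but still classified,
since the qualitative analysis needs their character either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import (
    BoundaryCaseError,
    DegenerateDenominatorError,
    ValidationError,
)
from .models import ModelSpec, Variant, reaction_jacobian, reaction_rates

__all__ = [
    "Classification",
    "StabilityReport",
    "EquilibriumLabel",
    "Equilibrium",
    "FeasibilityReport",
    "closed_form_equilibria",
    "pq_stability",
    "eigen_stability",
    "classify_equilibria",
    "interior_feasibility",
    "numeric_equilibrium_residual",
]

#: Relative tolerance (against the Jacobian max-norm) for p/q sign decisions.
DEFAULT_SIGN_RTOL = 1e-12

#: Relative tolerance below which the interior denominator counts as zero.
_DEGENERATE_RTOL = 1e-14


class Classification(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NON_HYPERBOLIC = "non_hyperbolic"


class EquilibriumLabel(str, Enum):
    ORIGIN = "origin"
    ONLY_LANG1 = "only_lang1"
    ONLY_LANG2 = "only_lang2"
    INTERIOR = "interior"
    INTERIOR_PLUS = "interior_plus"
    INTERIOR_MINUS = "interior_minus"


@dataclass(frozen=True)
class StabilityReport:
    """p = -trace, q = det of the Jacobian, and the resulting class."""

    p: float
    q: float
    classification: Classification
    tol: float


@dataclass(frozen=True)
class Equilibrium:
    """A candidate steady state with feasibility and (optionally) stability.

    ``feasible`` means strictly positive coordinates and, for the
    common-capacity model, ``u1* + u2* <= K``.  ``paper_verdict`` is set to
    ``"not stable"`` for the center-like non-hyperbolic case (p = 0, q > 0):
    no asymptotic stability, but 'unstable' would overclaim.
    """

    label: EquilibriumLabel
    coords: tuple[float, float]
    feasible: bool
    report: StabilityReport | None = None
    discriminant_complex: bool = False
    capacity_ok: bool | None = None
    paper_verdict: str | None = None


@dataclass(frozen=True)
class FeasibilityReport:
    """Variant-specific admissibility of the interior (coexistence) root.

    ``window`` is the open admissible interval for the swept capacity
    parameter (K1 for the bidirectional model, K for the common-capacity
    model, K1 for the one-way models) or ``None`` when empty.  ``details``
    carries every printed inequality evaluated on the way.
    """

    variant: Variant
    feasible: bool
    window: tuple[float, float] | None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stability criteria


def _require_finite(jac: np.ndarray) -> np.ndarray:
    jac = np.asarray(jac, dtype=float)
    if jac.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 matrix, got shape {jac.shape}")
    if not np.all(np.isfinite(jac)):
        raise ValidationError("Jacobian entries must be finite")
    return jac


def _default_tol(jac: np.ndarray) -> float:
    return DEFAULT_SIGN_RTOL * float(np.max(np.abs(jac)))


def pq_stability(jac: np.ndarray, tol: float | None = None) -> StabilityReport:
    """Classify a planar equilibrium from its Jacobian via the p/q test.

    ``tol`` (default ``1e-12 * max|A|``) absorbs floating-point noise around
    the p = 0 / q = 0 boundaries, which are reported as non-hyperbolic.
    """
    jac = _require_finite(jac)
    if tol is None:
        tol = _default_tol(jac)
    elif tol < 0:
        raise ValidationError("tol must be >= 0")
    p = -(jac[0, 0] + jac[1, 1])
    q = jac[0, 0] * jac[1, 1] - jac[1, 0] * jac[0, 1]
    if p > tol and q > tol:
        cls = Classification.STABLE
    elif p < -tol or q < -tol:
        cls = Classification.UNSTABLE
    else:
        cls = Classification.NON_HYPERBOLIC
    return StabilityReport(p=float(p), q=float(q), classification=cls, tol=tol)


def eigen_stability(jac: np.ndarray, tol: float | None = None) -> StabilityReport:
    """Oracle classification from eigenvalue real parts (p, q reported too)."""
    jac = _require_finite(jac)
    if tol is None:
        tol = _default_tol(jac)
    real = np.linalg.eigvals(jac).real
    if np.all(real < -tol):
        cls = Classification.STABLE
    elif np.any(real > tol):
        cls = Classification.UNSTABLE
    else:
        cls = Classification.NON_HYPERBOLIC
    p = -float(jac[0, 0] + jac[1, 1])
    q = float(jac[0, 0] * jac[1, 1] - jac[1, 0] * jac[0, 1])
    return StabilityReport(p=p, q=q, classification=cls, tol=tol)


# ---------------------------------------------------------------------------
# closed-form equilibria


def _interior_denominator(m: ModelSpec) -> float:
    """D = -a1a2 + ab*a1a2 - b*a2*c1*K1 - c2*K2*a*a1 + c2*K2*c1*K1."""
    return (
        -m.a1 * m.a2
        + m.alpha * m.beta * m.a1 * m.a2
        - m.beta * m.a2 * m.c1 * m.K1
        - m.c2 * m.K2 * m.alpha * m.a1
        + m.c2 * m.K2 * m.c1 * m.K1
    )


def _denominator_scale(m: ModelSpec) -> float:
    return max(
        m.a1 * m.a2,
        m.alpha * m.beta * m.a1 * m.a2,
        m.beta * m.a2 * m.c1 * m.K1,
        m.c2 * m.K2 * m.alpha * m.a1,
        m.c2 * m.K2 * m.c1 * m.K1,
    )


def closed_form_equilibria(model: ModelSpec) -> list[Equilibrium]:
    """Enumerate the printed closed-form equilibria of a model (unclassified).

    Returns 4 candidates for ``hybrid_lv``/``basic_rd``/``ecology_society``
    and 5 for ``common_capacity_rd`` (two interior quadratic roots, labeled by
    their discriminant branch).  The origin is always first.  Infeasible
    candidates (negative coordinates, capacity violation, or a complex
    discriminant) are included with ``feasible=False``.
    """
    v = model.variant
    out: list[Equilibrium] = []

    if v in (Variant.HYBRID_LV, Variant.BASIC_RD):
        den = model.a1 * model.a2 + model.c**2 * model.K1 * model.K2
        u1 = model.a2 * model.K1 * (model.a1 + model.c * model.K2) / den
        u2 = model.a1 * model.K2 * (model.a2 - model.c * model.K1) / den
        out = [
            Equilibrium(EquilibriumLabel.ORIGIN, (0.0, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG1, (model.K1, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG2, (0.0, model.K2), False),
            Equilibrium(EquilibriumLabel.INTERIOR, (u1, u2), u1 > 0 and u2 > 0),
        ]
    elif v is Variant.COMMON_CAPACITY_RD:
        K, c = model.K, model.c
        disc = c**2 * K**2 - 4.0 * model.a1 * model.a2
        out = [
            Equilibrium(EquilibriumLabel.ORIGIN, (0.0, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG1, (K, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG2, (0.0, K), False),
        ]
        if disc < 0:
            for lab in (EquilibriumLabel.INTERIOR_PLUS, EquilibriumLabel.INTERIOR_MINUS):
                out.append(
                    Equilibrium(
                        lab, (math.nan, math.nan), False,
                        discriminant_complex=True,
                    )
                )
        else:
            root = math.sqrt(disc)
            for lab, s in (
                (EquilibriumLabel.INTERIOR_PLUS, +1.0),
                (EquilibriumLabel.INTERIOR_MINUS, -1.0),
            ):
                u1 = (c * K + 2.0 * model.a2 + s * root) / (2.0 * c)
                u2 = (c * K - 2.0 * model.a1 + s * root) / (2.0 * c)
                cap_ok = u1 + u2 <= K
                out.append(
                    Equilibrium(
                        lab, (u1, u2), u1 > 0 and u2 > 0 and cap_ok,
                        capacity_ok=cap_ok,
                    )
                )
    else:  # ecology_society
        D = _interior_denominator(model)
        if abs(D) <= _DEGENERATE_RTOL * _denominator_scale(model):
            raise DegenerateDenominatorError(
                "interior-equilibrium denominator is zero for these parameters"
            )
        u1 = model.a2 * (
            model.K2 * model.alpha * model.a1
            - model.K2 * model.c1 * model.K1
            - model.a1 * model.K1
        ) / D
        u2 = model.a1 * (
            model.K1 * model.beta * model.a2
            - model.K2 * model.c2 * model.K1
            - model.a2 * model.K2
        ) / D
        out = [
            Equilibrium(EquilibriumLabel.ORIGIN, (0.0, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG1, (model.K1, 0.0), False),
            Equilibrium(EquilibriumLabel.ONLY_LANG2, (0.0, model.K2), False),
            Equilibrium(EquilibriumLabel.INTERIOR, (u1, u2), u1 > 0 and u2 > 0),
        ]
    return out


def classify_equilibria(
    model: ModelSpec, tol: float | None = None
) -> list[Equilibrium]:
    """Attach a :class:`StabilityReport` to every closed-form candidate.

    Candidates with complex (NaN) coordinates keep ``report=None``.  A
    non-hyperbolic verdict caused by p = 0 with q > 0 additionally carries
    ``paper_verdict="not stable"``: such a linear center is not
    asymptotically stable (the common-capacity interior roots always land
    here).
    """
    out = []
    for eq in closed_form_equilibria(model):
        if not all(math.isfinite(x) for x in eq.coords):
            out.append(eq)
            continue
        jac = reaction_jacobian(model, eq.coords)
        report = pq_stability(jac, tol)
        verdict = None
        if (
            report.classification is Classification.NON_HYPERBOLIC
            and abs(report.p) <= report.tol
            and report.q > report.tol
        ):
            verdict = "not stable"
        out.append(
            Equilibrium(
                label=eq.label,
                coords=eq.coords,
                feasible=eq.feasible,
                report=report,
                discriminant_complex=eq.discriminant_complex,
                capacity_ok=eq.capacity_ok,
                paper_verdict=verdict,
            )
        )
    return out


# ---------------------------------------------------------------------------
# feasibility windows


def interior_feasibility(model: ModelSpec) -> FeasibilityReport:
    """Evaluate the printed positivity/capacity conditions for the interior root.

    * ``hybrid_lv``/``basic_rd``: the interior root is positive iff
      ``K1 < a2/c``; the window is ``(0, a2/c)`` for K1.
    * ``common_capacity_rd``: real interior roots need ``K > 2*sqrt(a1*a2)/c``;
      the minus root is positive only for ``2*sqrt(a1*a2)/c < K < (a1+a2)/c``
      with ``a2 > a1``, and on that window the capacity check fails
      (``u1*+u2* >= K``, with equality only at ``K = (a1+a2)/c``) by
      monotonicity of ``phi(x) = x + (a2 - a1 - sqrt(c^2 x^2 - 4 a1 a2))/c``.
    * ``ecology_society``: the admissible K1 window splits on the sign of
      ``s = c2*K2 - beta*a2``:

      - ``s > 0``:  ``K2*alpha*a1/(K2*c1 + a1) < K1 <
        a1*(c2*K2*alpha + a2 - alpha*beta*a2)/(c1*s)``,
      - ``s < 0``:  ``max(K2*alpha*a1/(K2*c1 + a1), <same upper expr>) < K1 <
        a2*K2/(beta*a2 - K2*c2)``,
      - ``s = 0`` (to 1e-14 relative): :class:`BoundaryCaseError` — the
        analysis splits strictly on this sign.

      ``details`` also carries the simplified K1 = K2 = 1 diagnostic
      ``alpha > c1/a1`` (a looser printed reduction that the full inequality
      supersedes; it is informational only and does not enter the verdict).
    """
    v = model.variant

    if v in (Variant.HYBRID_LV, Variant.BASIC_RD):
        bound = model.a2 / model.c
        feasible = model.K1 < bound
        return FeasibilityReport(
            variant=v,
            feasible=feasible,
            window=(0.0, bound),
            details={"K1": model.K1, "a2_over_c": bound,
                     "K1_lt_a2_over_c": feasible},
        )

    if v is Variant.COMMON_CAPACITY_RD:
        a1, a2, c, K = model.a1, model.a2, model.c, model.K
        lower = 2.0 * math.sqrt(a1 * a2) / c
        upper = (a1 + a2) / c
        details: dict = {
            "K": K,
            "K_gt_2sqrt_a1a2_over_c": K > lower,
            "K_lt_a1_plus_a2_over_c": K < upper,
            "a2_gt_a1": a2 > a1,
            "discriminant": c**2 * K**2 - 4.0 * a1 * a2,
        }
        feasible = False
        for eq in closed_form_equilibria(model):
            if eq.label in (EquilibriumLabel.INTERIOR_PLUS,
                            EquilibriumLabel.INTERIOR_MINUS):
                key = eq.label.value
                if eq.discriminant_complex:
                    details[f"{key}_sum"] = math.nan
                else:
                    details[f"{key}_sum"] = eq.coords[0] + eq.coords[1]
                details[f"{key}_capacity_ok"] = eq.capacity_ok
                details[f"{key}_feasible"] = eq.feasible
                feasible = feasible or eq.feasible
        window = (lower, upper) if lower < upper else None
        return FeasibilityReport(v, feasible, window, details)

    # ecology_society
    a1, a2 = model.a1, model.a2
    K1, K2 = model.K1, model.K2
    al, be = model.alpha, model.beta
    c1, c2 = model.c1, model.c2

    s = c2 * K2 - be * a2
    scale = max(c2 * K2, be * a2)
    if abs(s) <= _DEGENERATE_RTOL * scale:
        raise BoundaryCaseError(
            "c2*K2 - beta*a2 = 0: the positivity analysis splits strictly "
            "on its sign"
        )
    D = _interior_denominator(model)
    lower_common = K2 * al * a1 / (K2 * c1 + a1)
    ratio = a1 * (c2 * K2 * al + a2 - al * be * a2) / (c1 * s)
    if s > 0:
        lower, upper = lower_common, ratio
    else:
        lower = max(lower_common, ratio)
        upper = a2 * K2 / (be * a2 - K2 * c2)
    window = (lower, upper) if lower < upper else None
    feasible = window is not None and lower < K1 < upper
    details = {
        "D": D,
        "c2K2_minus_beta_a2": s,
        "lower_candidate_threshold": lower_common,
        "denominator_sign_threshold": ratio,
        "K1": K1,
        "simplified_alpha_gt_c1_over_a1": al > c1 / a1,
    }
    return FeasibilityReport(v, feasible, window, details)


def numeric_equilibrium_residual(model: ModelSpec, point) -> float:
    """Max-norm of the reaction rates at a point (0 at a true equilibrium)."""
    rates = reaction_rates(model, point)
    return max(abs(rates.f1), abs(rates.f2))
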