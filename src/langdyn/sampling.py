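"""Seeded random parameter draws for property tests and cross-checks.

Ranges are chosen to match the regime the models are used in: per-capita
rates of a few percent per time unit, order-one carrying capacities,
conversion/attractiveness rates an order of magnitude below the growth
rates, and competition coefficients strictly inside (0, 1) (so
``alpha*beta < 1``, the regime in which the printed K1 feasibility windows
coincide with exact interior positivity).
"""

from __future__ import annotations

import numpy as np

from .models import ModelSpec, Variant, make_model

__all__ = ["draw_model", "draw_jacobian"]


def draw_model(variant: Variant | str, rng: np.random.Generator) -> ModelSpec:
    """One random, valid parameter set for the given variant."""
    variant = Variant(variant)
    a1 = rng.uniform(0.005, 0.2)
    a2 = rng.uniform(0.005, 0.2)
    if variant in (Variant.HYBRID_LV, Variant.BASIC_RD):
        params = dict(
            a1=a1, a2=a2,
            K1=rng.uniform(0.5, 2.0), K2=rng.uniform(0.5, 2.0),
            c=rng.uniform(0.004, 0.05),
        )
        if variant is Variant.BASIC_RD:
            params.update(d1=rng.uniform(0.0, 0.01), d2=rng.uniform(0.0, 0.01))
        return make_model(variant, **params)
    if variant is Variant.COMMON_CAPACITY_RD:
        return make_model(
            variant,
            a1=a1, a2=a2,
            K=rng.uniform(0.5, 2.0),
            c=rng.uniform(0.01, 0.2),
            d1=rng.uniform(0.0, 0.01), d2=rng.uniform(0.0, 0.01),
        )
    return make_model(
        variant,
        a1=a1, a2=a2,
        K1=rng.uniform(0.5, 2.0), K2=rng.uniform(0.5, 2.0),
        c1=rng.uniform(0.004, 0.05), c2=rng.uniform(0.004, 0.05),
        alpha=rng.uniform(0.2, 0.9), beta=rng.uniform(0.2, 0.9),
        d1=rng.uniform(0.0, 0.01), d2=rng.uniform(0.0, 0.01),
    )


def draw_jacobian(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A random 2x2 matrix with entries uniform in [-scale, scale]."""
    return rng.uniform(-scale, scale, size=(2, 2))
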