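"""Mixture designs and forward prediction of mixture concentration-response curves.

Supported designs:

fixed_ratio
    Components dosed at fixed molar fractions of the total concentration.
equipotent_at_ECx
    Fractions chosen so each component contributes equally at effect level X
    (fractions proportional to the individual ECx values).
coexposure_with_reference
    A fixed dose of the reference agonist (e.g. E2 at its EC50) co-dosed
    with the mixture dilution series.

CA curves are built by inverting the effective-concentration relation: at
each requested total concentration the effect level solving the toxic-unit
equation ``sum_i f_i T / ECX_i(X) (+ x_ref/ECX_ref(X)) = 1`` is found by
bracketed root-finding, which is exact to solver tolerance. Levels above
the smallest component efficacy are unreachable under CA, so the curve is
truncated (NaN) there with a warning recorded in the curve metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .curves import UnreachableEffectError, ecx_from_hill, gra_response
from .types import LigandParams, MixtureSpec, ReferenceScale, ResponseCurve

__all__ = [
    "DESIGN_KINDS",
    "MixtureDesign",
    "log_grid",
    "predict_curve_gra",
    "predict_curve_ca",
    "equipotent_fractions",
]

DESIGN_KINDS = ("fixed_ratio", "equipotent_at_ECx", "coexposure_with_reference")


def log_grid(center: float, decades: float = 2.0, points: int = 8) -> np.ndarray:
    """Log-spaced total-concentration grid spanning ``center`` ± ``decades``."""
    lc = np.log10(center)
    return np.logspace(lc - decades, lc + decades, points)


@dataclass
class MixtureDesign:
    spec: MixtureSpec
    kind: str
    grid: np.ndarray
    effect_level: Optional[float] = None
    reference: Optional[tuple[LigandParams, float]] = None  # (params, fixed dose)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"design kind must be one of {DESIGN_KINDS}, got {self.kind!r}")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid must be a one-dimensional concentration array")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly positive and strictly increasing")
        self.grid = grid
        if self.kind == "coexposure_with_reference":
            if self.reference is None:
                raise ValueError("co-exposure design requires a reference (params, dose)")
            if self.reference[1] < 0:
                raise ValueError("reference dose must be >= 0")
        if self.kind == "equipotent_at_ECx":
            if self.effect_level is None:
                raise ValueError("equipotent design requires an effect level X")
            for cid, p in self.spec.components:
                if self.effect_level / 100.0 >= p.a:
                    raise UnreachableEffectError(
                        f"component {cid} cannot reach X={self.effect_level}%"
                    )


def _component_doses(design: MixtureDesign) -> list[tuple[LigandParams, np.ndarray]]:
    pairs = [
        (p, f * design.grid)
        for (_, p), f in zip(design.spec.components, design.spec.fractions)
    ]
    if design.kind == "coexposure_with_reference" and design.reference is not None:
        ref_p, ref_dose = design.reference
        if ref_dose > 0:
            pairs.append((ref_p, np.full_like(design.grid, ref_dose)))
    return pairs


def predict_curve_gra(design: MixtureDesign, scale: ReferenceScale) -> ResponseCurve:
    """GRA-predicted mixture curve over the design's total-concentration grid."""
    y = gra_response(_component_doses(design), scale)
    meta = {"sample_id": design.meta.get("sample_id", "mixture"), "model": "GRA",
            "design": design.kind}
    return ResponseCurve(design.grid.copy(), np.asarray(y)[:, None], meta)


def _toxic_unit_gap(design: MixtureDesign, T: float, X: float,
                    scale: ReferenceScale) -> float:
    """1 - total toxic units at effect level X for total concentration T.

    Positive when X overshoots what T can produce; the CA response at T is
    the root in X. Decreasing terms: each ECX_i grows with X.
    """
    tu = 0.0
    for (cid, p), f in zip(design.spec.components, design.spec.fractions):
        if f > 0:
            tu += f * T / ecx_from_hill(p, scale, X)
    if design.kind == "coexposure_with_reference" and design.reference is not None:
        ref_p, ref_dose = design.reference
        if ref_dose > 0:
            tu += ref_dose / ecx_from_hill(ref_p, scale, X)
    return tu - 1.0


def predict_curve_ca(design: MixtureDesign, scale: ReferenceScale) -> ResponseCurve:
    """CA-predicted mixture curve; truncated where partial agonists cap the level.

    The response at effect level X is ``y0 + (m - y0) X / 100`` by the
    definition of an effect level on the reference span.
    """
    # the smallest efficacy among dosed components caps reachable CA levels
    a_cap = min(
        [p.a for (_, p), f in zip(design.spec.components, design.spec.fractions) if f > 0]
        + ([design.reference[0].a]
           if design.kind == "coexposure_with_reference"
           and design.reference is not None and design.reference[1] > 0 else [])
    )
    x_hi = 100.0 * a_cap * (1.0 - 1e-9)
    x_lo = 1e-9
    y = np.empty_like(design.grid)
    warnings: list[str] = []
    for i, T in enumerate(design.grid):
        g_hi = _toxic_unit_gap(design, T, x_hi, scale)
        if g_hi > 0.0:
            # even the highest reachable level is exceeded: CA undefined here
            y[i] = np.nan
            warnings.append(
                f"T={T:.6g} M exceeds the CA-reachable effect ceiling "
                f"({100 * a_cap:.4g}%): curve truncated"
            )
            continue
        X = brentq(lambda X_: _toxic_unit_gap(design, T, X_, scale),
                   x_lo, x_hi, xtol=1e-12, rtol=8.9e-16)
        y[i] = scale.y0 + scale.span * X / 100.0
    meta = {"sample_id": design.meta.get("sample_id", "mixture"), "model": "CA",
            "design": design.kind, "warnings": warnings}
    return ResponseCurve(design.grid.copy(), y[:, None], meta)


def equipotent_fractions(
    components: Sequence[tuple[str, LigandParams]],
    X: float,
    scale: ReferenceScale,
) -> MixtureSpec:
    """Fractions proportional to each component's ECx, so all contribute equally.

    ``f_i = ECX_i / sum_j ECX_j``: dosing the mixture at total concentration
    ``sum_j ECX_j`` then puts every component exactly at its own ECx.
    """
    ecx = []
    for cid, p in components:
        try:
            ecx.append(ecx_from_hill(p, scale, X))
        except UnreachableEffectError as err:
            raise UnreachableEffectError(
                f"component {cid} cannot reach X={X}%: {err}"
            ) from err
    total = sum(ecx)
    fracs = [e / total for e in ecx]
    # renormalise exactly against accumulated rounding
    s = sum(fracs)
    fracs = [f / s for f in fracs]
    return MixtureSpec(components=tuple(components), fractions=tuple(fracs))
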