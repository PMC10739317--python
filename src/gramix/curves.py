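"""Forward dose-response mathematics.

Single-ligand Hill response, the multi-ligand generic response addition
(GRA) model derived from mass-action receptor occupancy, concentration
addition (CA) effective-concentration arithmetic, and the ECx / apparent
EC50 / IC50 inversions.

The GRA response for ligands with efficacy ``a_i``, potency ``c_i`` and
slope ``n_i`` at free concentrations ``x_i`` is

    y = y0 + (m - y0) * sum_i a_i (x_i/c_i)^n_i / (1 + sum_i (x_i/c_i)^n_i)

A pure antagonist (a = 0) binds the receptor without activating it and
contributes only to the denominator.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .types import LigandParams, MixtureSpec, ReferenceScale

__all__ = [
    "UnreachableEffectError",
    "hill_response",
    "gra_response",
    "ecx_from_hill",
    "ca_mixture_ecx",
    "apparent_ec50_shift",
    "ic50_of_antagonist",
]

# occupancy terms are clipped so that saturated ratios stay finite; the
# clipped ratio converges to the efficacy-weighted limit
_TERM_CAP = 1e300


class UnreachableEffectError(ValueError):
    """Requested effect level exceeds what a ligand's efficacy allows."""


def _validate_conc(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{name} must be finite and >= 0")
    return arr


def _occupancy_term(p: LigandParams, x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        t = (x / p.c) ** p.n
    return np.clip(t, 0.0, _TERM_CAP)


def hill_response(p: LigandParams, scale: ReferenceScale, x) -> np.ndarray | float:
    """Response of a single ligand at concentration(s) ``x`` (% activity)."""
    arr = _validate_conc(x)
    t = _occupancy_term(p, arr)
    # grouped as (a*t)/(1+t) so the single-ligand GRA reduction is bit-exact
    y = scale.y0 + scale.span * (p.a * t) / (1.0 + t)
    return float(y) if np.isscalar(x) else y


def gra_response(
    mix: Sequence[tuple[LigandParams, object]],
    scale: ReferenceScale,
) -> np.ndarray | float:
    """Multi-ligand response; ``mix`` pairs each ligand with its concentration.

    Concentrations may be scalars or broadcastable arrays. Reduces exactly
    to :func:`hill_response` for a single ligand.
    """
    mix = list(mix)
    if not mix:
        raise ValueError("gra_response requires at least one ligand")
    num = 0.0
    den = 0.0
    scalar = all(np.isscalar(x) for _, x in mix)
    for p, x in mix:
        t = _occupancy_term(p, _validate_conc(x, "ligand concentration"))
        num = num + p.a * t
        den = den + t
    y = scale.y0 + scale.span * num / (1.0 + den)
    return float(y) if scalar else y


def ecx_from_hill(p: LigandParams, scale: ReferenceScale, X: float) -> float:
    """Concentration at which ligand ``p`` alone produces effect ``X``.

    ``X`` is percent of the reference span (m - y0); a ligand can only
    reach levels strictly below ``100 * a``.
    """
    r = float(X) / 100.0
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"effect level X must be positive and finite, got {X}")
    if r >= p.a:
        raise UnreachableEffectError(
            f"effect level {X}% is unreachable for ligand with efficacy "
            f"a={p.a} (maximum approach {100 * p.a}%)"
        )
    return p.c * (r / (p.a - r)) ** (1.0 / p.n)


def ca_mixture_ecx(mix: MixtureSpec, scale: ReferenceScale, X: float) -> float:
    """Concentration-addition effective concentration of the whole mixture.

    ``ECX_mix = (sum_i f_i / ECX_i)^-1``. Every component must be able to
    reach ``X``; partial agonists block levels above their efficacy, which
    is CA's documented limitation.
    """
    offenders = [cid for (cid, p) in mix.components if X / 100.0 >= p.a]
    if offenders:
        raise UnreachableEffectError(
            f"effect level {X}% unreachable for component(s): {', '.join(offenders)}"
        )
    total = 0.0
    for (cid, p), f in zip(mix.components, mix.fractions):
        total += f / ecx_from_hill(p, scale, X)
    return 1.0 / total


def _bracketed_root(f, lo: float, hi: float, expand: int = 6) -> float:
    """Brent root of ``f`` on log10-concentration with bracket expansion."""
    flo, fhi = f(lo), f(hi)
    k = 0
    while flo * fhi > 0 and k < expand:
        lo -= 2.0
        hi += 2.0
        flo, fhi = f(lo), f(hi)
        k += 1
    if flo * fhi > 0:
        raise RuntimeError(
            f"root not bracketed on log10 concentration in [{lo}, {hi}]: "
            f"f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    return brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)


def apparent_ec50_shift(
    agonist: LigandParams,
    antagonist: LigandParams,
    x_ant: float,
    scale: ReferenceScale,
) -> float:
    """Apparent EC50 of an agonist in the presence of a fixed antagonist dose.

    Solves for the agonist concentration at which the joint response reaches
    half of the agonist's own maximal span. A reversible competitive
    antagonist right-shifts the curve: for ``n_ag = n_ant = 1`` the result
    equals the Schild-type closed form ``c_ag * (1 + x_ant/c_ant)``.
    """
    if not antagonist.is_antagonist():
        raise ValueError("antagonist must have efficacy a = 0")
    if agonist.a <= 0:
        raise ValueError("agonist must have efficacy a > 0")
    x_ant = float(_validate_conc(x_ant, "x_ant"))
    target = scale.y0 + scale.span * agonist.a / 2.0

    def f(logx: float) -> float:
        x = 10.0 ** logx
        return gra_response([(agonist, x), (antagonist, x_ant)], scale) - target

    lc = np.log10(agonist.c)
    logroot = _bracketed_root(f, lc - 6.0, lc + 6.0)
    return 10.0 ** logroot


def ic50_of_antagonist(
    agonist: LigandParams,
    agonist_conc: float,
    antagonist: LigandParams,
    scale: ReferenceScale,
) -> float:
    """Antagonist concentration halving the agonist response above baseline.

    The antagonist-free response at ``agonist_conc`` defines 100%; the IC50
    is where the joint response falls to half of that span over ``y0``. The
    result is invariant to (y0, m) rescaling.
    """
    if not antagonist.is_antagonist():
        raise ValueError("antagonist must have efficacy a = 0")
    agonist_conc = float(_validate_conc(agonist_conc, "agonist_conc"))
    r0 = hill_response(agonist, scale, agonist_conc)
    if r0 <= scale.y0:
        raise ValueError("agonist response at agonist_conc must exceed baseline")
    target = scale.y0 + (r0 - scale.y0) / 2.0

    def f(logx: float) -> float:
        x = 10.0 ** logx
        return gra_response([(agonist, agonist_conc), (antagonist, x)], scale) - target

    lc = np.log10(antagonist.c)
    logroot = _bracketed_root(f, lc - 6.0, lc + 6.0)
    return 10.0 ** logroot
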