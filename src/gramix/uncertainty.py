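"""Monte-Carlo prediction envelopes and the additivity / interaction verdict.

Parameter uncertainty (normal or uniform per parameter, truncated to the
valid domain a >= 0, c > 0, n > 0) is propagated through the CA or GRA
forward model to pointwise 2.5% / 50% / 97.5% quantile bands. An observed
mixture curve is then flagged point-by-point against the band; the additive
(equivalence) hypothesis is rejected when at least two consecutive mean
points in the curve's dynamic range fall outside the envelope on the same
side — above the band suggests synergy, below suggests antagonism.
Isolated single-point excursions are reported but do not flip the verdict.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fitting import FitResult, goodness_of_fit
from .mixtures import MixtureDesign, predict_curve_gra
from .types import LigandParams, ReferenceScale, ResponseCurve

__all__ = [
    "Normal",
    "Uniform",
    "ParamUncertainty",
    "Envelope",
    "AdditivityVerdict",
    "ModelComparison",
    "from_fit_results",
    "uniform_pct",
    "mc_envelope",
    "additivity_test",
    "compare_models",
]


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size)


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("uniform requires hi >= lo")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size)


DistSpec = Union[Normal, Uniform]
#: one {"a": spec, "c": spec, "n": spec} mapping per mixture component
ParamUncertainty = Sequence[dict[str, DistSpec]]


def from_fit_results(fits: Sequence[FitResult]) -> list[dict[str, DistSpec]]:
    """Normal(estimate, SE) uncertainty for each fitted component."""
    specs = []
    for f in fits:
        if f.params is None or not f.converged:
            raise ValueError("all component fits must have converged")
        specs.append({
            "a": Normal(f.params.a, f.se["a"]),
            "c": Normal(f.params.c, f.se["c"]),
            "n": Normal(f.params.n, f.se["n"]),
        })
    return specs


def uniform_pct(params: Sequence[LigandParams], pct: float = 0.10) -> list[dict[str, DistSpec]]:
    """Uniform ±pct uncertainty around nominal parameters (fixture compounds)."""
    return [{
        "a": Uniform(p.a * (1 - pct), p.a * (1 + pct)),
        "c": Uniform(p.c * (1 - pct), p.c * (1 + pct)),
        "n": Uniform(p.n * (1 - pct), p.n * (1 + pct)),
    } for p in params]


@dataclass
class Envelope:
    grid: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    n_sims: int
    seed: Optional[int]
    model: str

    def __post_init__(self) -> None:
        for name in ("grid", "lower", "median", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.lower.shape == self.median.shape == self.upper.shape
                == self.grid.shape):
            raise ValueError("envelope bands must match the grid shape")
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValueError("envelope quantiles must be ordered lower <= median <= upper")


_VALID = {"a": lambda v: v >= 0, "c": lambda v: v > 0, "n": lambda v: v > 0}


def _draw_params(
    uncertainty: ParamUncertainty, n_sims: int, rng: np.random.Generator
) -> list[dict[str, np.ndarray]]:
    """Truncated draws: invalid rows are redrawn; an uncertainty spec whose
    first pass is >50% invalid is rejected as inconsistent."""
    draws = [{k: spec[k].sample(rng, n_sims) for k in ("a", "c", "n")}
             for spec in uncertainty]
    invalid = np.zeros(n_sims, dtype=bool)
    for d in draws:
        for k, ok in _VALID.items():
            invalid |= ~ok(d[k]) | ~np.isfinite(d[k])
    if invalid.mean() > 0.5:
        raise ValueError(
            f"uncertainty spec inconsistent: {100 * invalid.mean():.1f}% of "
            "draws invalid after truncation to a>=0, c>0, n>0"
        )
    for _ in range(1000):
        if not invalid.any():
            break
        idx = np.flatnonzero(invalid)
        for spec, d in zip(uncertainty, draws):
            for k in ("a", "c", "n"):
                d[k][idx] = spec[k].sample(rng, idx.size)
        invalid = np.zeros(n_sims, dtype=bool)
        for d in draws:
            for k, ok in _VALID.items():
                invalid |= ~ok(d[k]) | ~np.isfinite(d[k])
    if invalid.any():
        raise ValueError("could not obtain valid parameter draws by truncation")
    return draws


def _gra_sim_matrix(
    design: MixtureDesign,
    scale: ReferenceScale,
    draws: list[dict[str, np.ndarray]],
) -> np.ndarray:
    """(n_sims, grid) GRA responses, vectorised over parameter draws."""
    T = design.grid[None, :]
    num = 0.0
    den = 0.0
    for (_, _p), f, d in zip(design.spec.components, design.spec.fractions, draws):
        with np.errstate(over="ignore", invalid="ignore"):
            t = (f * T / d["c"][:, None]) ** d["n"][:, None]
        t = np.clip(np.nan_to_num(t, nan=0.0, posinf=1e300), 0.0, 1e300)
        num = num + d["a"][:, None] * t
        den = den + t
    if design.kind == "coexposure_with_reference" and design.reference is not None:
        ref_p, ref_dose = design.reference
        if ref_dose > 0:
            t = np.clip((ref_dose / ref_p.c) ** ref_p.n, 0.0, 1e300)
            num = num + ref_p.a * t
            den = den + t
    return scale.y0 + scale.span * num / (1.0 + den)


def _ca_sim_matrix(
    design: MixtureDesign,
    scale: ReferenceScale,
    draws: list[dict[str, np.ndarray]],
    levels: int = 512,
) -> np.ndarray:
    """(n_sims, grid) CA responses via vectorised effect-grid inversion.

    Per draw, the effective concentration is tabulated on a relative effect
    grid up to that draw's efficacy ceiling and interpolated in
    (log T -> effect). Concentrations beyond the ceiling saturate at it.
    """
    n_sims = draws[0]["a"].size
    rel = np.linspace(1e-6, 1.0 - 1e-6, levels)[None, :]        # (1, R)
    a_min = np.min(np.stack([
        np.where(f > 0, d["a"], np.inf)
        for f, d in zip(design.spec.fractions, draws)
    ]), axis=0)                                                  # (n_sims,)
    if design.kind == "coexposure_with_reference" and design.reference is not None:
        ref_p, ref_dose = design.reference
        if ref_dose > 0:
            a_min = np.minimum(a_min, ref_p.a)
    r = rel * a_min[:, None]                                     # effect fraction grid
    inv_ecmix = 0.0
    for f, d in zip(design.spec.fractions, draws):
        if np.all(f == 0):
            continue
        a, c, n = d["a"][:, None], d["c"][:, None], d["n"][:, None]
        with np.errstate(over="ignore", divide="ignore"):
            ecx = c * (r / (a - r)) ** (1.0 / n)
            inv_ecmix = inv_ecmix + f / ecx
    budget = np.ones_like(r)
    if design.kind == "coexposure_with_reference" and design.reference is not None:
        ref_p, ref_dose = design.reference
        if ref_dose > 0:
            with np.errstate(over="ignore", divide="ignore"):
                ecx_ref = ref_p.c * (r / (ref_p.a - r)) ** (1.0 / ref_p.n)
                budget = budget - ref_dose / ecx_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        T_of_r = budget / inv_ecmix
    out = np.empty((n_sims, design.grid.size))
    logT = np.log(design.grid)
    for s in range(n_sims):
        valid = np.isfinite(T_of_r[s]) & (T_of_r[s] > 0)
        Ts, rs = T_of_r[s, valid], r[s, valid]
        order = np.argsort(Ts)
        # np.interp clamps outside the tabulated range: below it the response
        # sits at the smallest tabulated effect (~baseline), above it at the
        # draw's CA ceiling
        out[s] = scale.y0 + scale.span * np.interp(logT, np.log(Ts[order]), rs[order])
    return out


def mc_envelope(
    design: MixtureDesign,
    scale: ReferenceScale,
    uncertainty: ParamUncertainty,
    model: str = "GRA",
    n_sims: int = 10_000,
    seed: Optional[int] = None,
) -> Envelope:
    """Monte-Carlo 95% prediction envelope for a mixture design.

    Draws parameter sets from the per-parameter distributions (truncated to
    validity), predicts the full curve for each draw and returns pointwise
    2.5/50/97.5 percent quantiles. Reproducible for a fixed seed. The
    co-exposure reference dose and parameters are treated as known.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for stable 95% quantiles")
    if model not in ("CA", "GRA"):
        raise ValueError(f"model must be 'CA' or 'GRA', got {model!r}")
    if len(uncertainty) != len(design.spec):
        raise ValueError("one uncertainty spec per mixture component required")
    rng = np.random.default_rng(seed)
    draws = _draw_params(uncertainty, n_sims, rng)
    sims = (_gra_sim_matrix(design, scale, draws) if model == "GRA"
            else _ca_sim_matrix(design, scale, draws))
    lo, med, hi = np.quantile(sims, [0.025, 0.5, 0.975], axis=0)
    return Envelope(grid=design.grid.copy(), lower=lo, median=med, upper=hi,
                    n_sims=n_sims, seed=seed, model=model)


@dataclass
class AdditivityVerdict:
    flags: list[str]                      # per evaluated grid point: inside/above/below
    overall: str                          # additive | synergy_candidate | antagonism_candidate
    counts: dict[str, int]
    grid: np.ndarray                      # envelope grid points actually evaluated
    observed: np.ndarray                  # observed means on that grid
    isolated_excursions: int = 0


def _longest_same_side_run(flags: Sequence[str], side: str, mask: Sequence[bool]) -> int:
    best = run = 0
    for fl, in_range in zip(flags, mask):
        if in_range and fl == side:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def additivity_test(observed: ResponseCurve, envelope: Envelope) -> AdditivityVerdict:
    """Flag an observed mixture curve against a Monte-Carlo envelope.

    Observed replicate means are interpolated onto the envelope grid by
    monotone cubic (PCHIP) interpolation in log concentration; only grid
    points inside the observed concentration range are evaluated. The
    equivalence hypothesis is rejected when >= 2 consecutive points within
    the dynamic range (10%-90% of the envelope-median span) sit outside the
    band on the same side.
    """
    oc = observed.concentrations
    lo_T, hi_T = oc.min(), oc.max()
    sel = (envelope.grid >= lo_T * (1 - 1e-12)) & (envelope.grid <= hi_T * (1 + 1e-12))
    if not sel.any():
        raise ValueError("observed and envelope concentration ranges do not overlap")
    if oc.size < 2:
        raise ValueError("observed curve needs >= 2 concentrations for interpolation")
    interp = PchipInterpolator(np.log10(oc), observed.mean_responses)
    grid = envelope.grid[sel]
    obs = interp(np.log10(grid))
    lower, upper, med = envelope.lower[sel], envelope.upper[sel], envelope.median[sel]

    flags = ["above" if o > u else "below" if o < l else "inside"
             for o, l, u in zip(obs, lower, upper)]
    span = med.max() - med.min()
    if span > 0:
        rel = (med - med.min()) / span
        dynamic = (rel >= 0.10) & (rel <= 0.90)
    else:
        dynamic = np.ones_like(med, dtype=bool)

    run_above = _longest_same_side_run(flags, "above", dynamic)
    run_below = _longest_same_side_run(flags, "below", dynamic)
    n_above = sum(1 for fl, d in zip(flags, dynamic) if d and fl == "above")
    n_below = sum(1 for fl, d in zip(flags, dynamic) if d and fl == "below")

    overall = "additive"
    if run_above >= 2 or run_below >= 2:
        if run_above != run_below:
            side = "above" if run_above > run_below else "below"
        else:
            side = "above" if n_above >= n_below else "below"
        overall = "synergy_candidate" if side == "above" else "antagonism_candidate"
    isolated = sum(
        1 for fl, d in zip(flags, dynamic) if d and fl != "inside"
    ) if overall == "additive" else 0

    counts = {
        "inside": flags.count("inside"),
        "above": flags.count("above"),
        "below": flags.count("below"),
        "dynamic_above": n_above,
        "dynamic_below": n_below,
    }
    return AdditivityVerdict(flags=flags, overall=overall, counts=counts,
                             grid=grid, observed=obs, isolated_excursions=isolated)


@dataclass
class ModelComparison:
    rmse_ca: float
    rsq_ca: float
    rmse_gra: float
    rsq_gra: float
    winner: str                           # "CA" | "GRA" | "tie"
    n_points: int


def compare_models(
    observed: ResponseCurve,
    ca_pred: ResponseCurve,
    gra_pred: ResponseCurve,
    rel_tol: float = 1e-9,
) -> ModelComparison:
    """RMSE/R² of CA and GRA predictions against the observed means.

    All three curves must share the concentration grid. Points where the CA
    curve is truncated (NaN) are excluded from both comparisons so the two
    models are judged on the same observations.
    """
    for pred in (ca_pred, gra_pred):
        if pred.concentrations.shape != observed.concentrations.shape or not np.allclose(
            pred.concentrations, observed.concentrations, rtol=1e-9
        ):
            raise ValueError("predictions must share the observed concentration grid")
    obs = observed.mean_responses
    ca = ca_pred.mean_responses
    gra = gra_pred.mean_responses
    mask = np.isfinite(obs) & np.isfinite(ca) & np.isfinite(gra)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 mutually finite points to compare")
    rmse_ca, rsq_ca = goodness_of_fit(obs[mask], ca[mask])
    rmse_gra, rsq_gra = goodness_of_fit(obs[mask], gra[mask])
    if abs(rmse_ca - rmse_gra) <= rel_tol * max(rmse_ca, rmse_gra, 1e-300):
        winner = "tie"
    else:
        winner = "CA" if rmse_ca < rmse_gra else "GRA"
    return ModelComparison(rmse_ca=rmse_ca, rsq_ca=rsq_ca, rmse_gra=rmse_gra,
                           rsq_gra=rsq_gra, winner=winner, n_points=int(mask.sum()))
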