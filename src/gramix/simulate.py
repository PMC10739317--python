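"""Synthetic CALUX-like reporter plates with the statistical structure the
analysis assumes: 8-point 1:10 serial dilutions in triplicate, an E2
reference curve defining the 0-100% scale, QC wells dosed at the E2 EC50,
and 7% multiplicative noise on the luminescence-derived % activity.

The compound fixture library ships SYNTHETIC Hill parameters for the 14
study compounds plus E2. The values respect the qualitative constraints
reported for these substances (daidzein/genistein as supra-inductive
agonists near 180-200% efficacy, kaempferol a partial agonist at 60%,
phthalates and related food-contact chemicals weakly active, E2 potent in
the low picomolar range) but are placeholders, not measurements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .curves import gra_response, hill_response
from .mixtures import MixtureDesign, equipotent_fractions, log_grid
from .types import LigandParams, MixtureSpec, ReferenceScale, ResponseCurve

__all__ = [
    "CompoundFixture",
    "PlateDesign",
    "simulate_curve",
    "fixture_library",
    "fixture_map",
    "FOOD_MIXTURE_RECIPES",
    "StudyData",
    "simulate_study",
]

COMPOUND_CLASSES = ("phytoestrogen", "plant_protection", "FCM_related",
                    "reference", "fictitious")


@dataclass(frozen=True)
class CompoundFixture:
    id: str
    compound_class: str
    params: LigandParams
    note: str = "synthetic placeholder parameters"

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        p = self.params
        if not (0.0 <= p.a <= 2.2):
            raise ValueError(f"{self.id}: efficacy {p.a} outside fixture range [0, 2.2]")
        if not (0.4 <= p.n <= 5.5):
            raise ValueError(f"{self.id}: slope {p.n} outside fixture range [0.4, 5.5]")
        if not (1e-12 <= p.c <= 1e-4):
            raise ValueError(f"{self.id}: EC50 {p.c} outside fixture range [1e-12, 1e-4] M")


@dataclass(frozen=True)
class PlateDesign:
    """Dilution-series layout of one simulated plate."""

    n_points: int = 8
    top: float = 1e-5           # molar, highest dose of the series
    dilution_factor: float = 10.0
    replicates: int = 3
    n_blanks: int = 3
    qc_replicates: int = 3
    noise_fraction: float = 0.07

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.top <= 0 or self.dilution_factor <= 1:
            raise ValueError("invalid dilution series")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")
        if self.qc_replicates < 3:
            raise ValueError("QC wells are run at least in triplicate")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")

    def concentrations(self) -> np.ndarray:
        k = np.arange(self.n_points)
        return np.sort(self.top / self.dilution_factor ** k)

    def with_top(self, top: float) -> "PlateDesign":
        from dataclasses import replace
        return replace(self, top=top)


Truth = Union[LigandParams, MixtureSpec, MixtureDesign]


def _true_response(truth: Truth, conc: np.ndarray, scale: ReferenceScale) -> np.ndarray:
    if isinstance(truth, LigandParams):
        return np.asarray(hill_response(truth, scale, conc))
    if isinstance(truth, MixtureSpec):
        pairs = [(p, f * conc) for (_, p), f in zip(truth.components, truth.fractions)]
        return np.asarray(gra_response(pairs, scale))
    if isinstance(truth, MixtureDesign):
        from .mixtures import predict_curve_gra
        design = MixtureDesign(spec=truth.spec, kind=truth.kind, grid=conc,
                               effect_level=truth.effect_level,
                               reference=truth.reference, meta=truth.meta)
        return predict_curve_gra(design, scale).mean_responses
    raise TypeError(f"unsupported truth type {type(truth)!r}")


def simulate_curve(
    truth: Truth,
    design: PlateDesign,
    scale: ReferenceScale,
    noise_fraction: Optional[float] = None,
    seed: Optional[int] = None,
    noise_model: str = "multiplicative",
    sample_id: str = "sample",
    concentrations: Optional[np.ndarray] = None,
) -> ResponseCurve:
    """Simulate one dilution series with replicate noise.

    Multiplicative noise perturbs each well by a Gaussian with sd equal to
    ``noise_fraction`` times the true signal (CV-style, typical of
    luminescence readouts); the additive switch uses a constant sd of
    ``noise_fraction`` times the reference span. Responses are truncated
    at zero. Reproducible for a fixed seed.
    """
    nf = design.noise_fraction if noise_fraction is None else float(noise_fraction)
    if nf < 0:
        raise ValueError("noise fraction must be >= 0")
    conc = design.concentrations() if concentrations is None else np.sort(
        np.asarray(concentrations, dtype=float))
    y_true = _true_response(truth, conc, scale)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((conc.size, design.replicates))
    if noise_model == "multiplicative":
        resp = y_true[:, None] * (1.0 + nf * z)
    elif noise_model == "additive":
        resp = y_true[:, None] + nf * scale.span * z
    else:
        raise ValueError(f"noise_model must be 'multiplicative' or 'additive', got {noise_model!r}")
    resp = np.clip(resp, 0.0, None)
    meta = {"sample_id": sample_id, "seed": seed, "noise_fraction": nf,
            "noise_model": noise_model, "true_response": y_true}
    return ResponseCurve(conc, resp, meta)


def fixture_library() -> list[CompoundFixture]:
    """Synthetic Hill parameters for the 14 study compounds plus E2.

    Every value is a frozen placeholder chosen to respect the reported
    qualitative behaviour of each substance class; none is a measurement.
    """
    L = LigandParams
    return [
        CompoundFixture("E2", "reference", L(a=1.0, c=5e-12, n=1.0),
                        "synthetic; reference agonist, low-pM potency"),
        # phytoestrogens
        CompoundFixture("8-PN", "phytoestrogen", L(a=1.0, c=8e-10, n=1.2),
                        "synthetic; potent full agonist"),
        CompoundFixture("6-PN", "phytoestrogen", L(a=0.8, c=5e-8, n=1.0),
                        "synthetic; near-full agonist"),
        CompoundFixture("daidzein", "phytoestrogen", L(a=1.9, c=3e-7, n=1.1),
                        "synthetic; supra-inductive agonist (efficacy 180-200%)"),
        CompoundFixture("genistein", "phytoestrogen", L(a=1.8, c=1e-7, n=1.3),
                        "synthetic; supra-inductive agonist (efficacy 180-200%)"),
        CompoundFixture("kaempferol", "phytoestrogen", L(a=0.6, c=2e-6, n=1.0),
                        "synthetic; partial agonist (60% efficacy)"),
        CompoundFixture("equol", "phytoestrogen", L(a=1.0, c=6e-8, n=0.9),
                        "synthetic; full agonist"),
        CompoundFixture("enterolactone", "phytoestrogen", L(a=0.5, c=5e-6, n=0.8),
                        "synthetic; weak partial agonist"),
        # food additives / FCM-related
        CompoundFixture("BHT", "FCM_related", L(a=0.12, c=9e-6, n=1.0),
                        "synthetic; weakly active antioxidant"),
        CompoundFixture("benzophenone", "FCM_related", L(a=0.3, c=8e-6, n=1.5),
                        "synthetic; weak agonist"),
        CompoundFixture("DEHP", "FCM_related", L(a=0.05, c=2e-5, n=1.0),
                        "synthetic; marginally active phthalate"),
        CompoundFixture("DBP", "FCM_related", L(a=0.2, c=1e-5, n=0.7),
                        "synthetic; weakly active phthalate"),
        CompoundFixture("DIBP", "FCM_related", L(a=0.15, c=2e-5, n=0.9),
                        "synthetic; weakly active phthalate"),
        CompoundFixture("BBP", "FCM_related", L(a=0.4, c=6e-6, n=1.1),
                        "synthetic; weak agonist phthalate"),
        # plant protection products
        CompoundFixture("triadimenol", "plant_protection", L(a=0.25, c=1e-5, n=2.0),
                        "synthetic; weakly active triazole fungicide"),
    ]


def fixture_map() -> dict[str, CompoundFixture]:
    return {f.id: f for f in fixture_library()}


# Fixed-ratio recipes standing in for the (undeposited) food-sample ratios:
# 12 mixtures of 2-5 compounds, phytoestrogen-dominated with minor additive/
# phthalate/fungicide shares. Entirely synthetic.
FOOD_MIXTURE_RECIPES: dict[str, list[tuple[str, float]]] = {
    "mix01": [("daidzein", 0.6), ("genistein", 0.4)],
    "mix02": [("daidzein", 0.7), ("equol", 0.3)],
    "mix03": [("genistein", 0.8), ("8-PN", 0.2)],
    "mix04": [("daidzein", 0.5), ("genistein", 0.3), ("kaempferol", 0.2)],
    "mix05": [("daidzein", 0.4), ("genistein", 0.3), ("6-PN", 0.1), ("kaempferol", 0.2)],
    "mix06": [("daidzein", 0.4), ("genistein", 0.3), ("6-PN", 0.1), ("enterolactone", 0.2)],
    "mix07": [("8-PN", 0.2), ("equol", 0.5), ("enterolactone", 0.3)],
    "mix08": [("daidzein", 0.5), ("DBP", 0.3), ("benzophenone", 0.2)],
    "mix09": [("genistein", 0.4), ("DEHP", 0.3), ("DIBP", 0.2), ("BBP", 0.1)],
    "mix10": [("daidzein", 0.35), ("genistein", 0.25), ("6-PN", 0.1),
              ("enterolactone", 0.2), ("BHT", 0.1)],
    "mix11": [("daidzein", 0.35), ("genistein", 0.25), ("DIBP", 0.2),
              ("benzophenone", 0.1), ("triadimenol", 0.1)],
    "mix12": [("daidzein", 0.4), ("kaempferol", 0.3), ("BBP", 0.2), ("BHT", 0.1)],
}

# the four-phytoestrogen blend used for the benchmark-dose designs
BMD_BLEND = ("8-PN", "daidzein", "kaempferol", "equol")


def _mixture_spec(recipe: Sequence[tuple[str, float]],
                  lib: dict[str, CompoundFixture]) -> MixtureSpec:
    return MixtureSpec(
        components=tuple((cid, lib[cid].params) for cid, _ in recipe),
        fractions=tuple(f for _, f in recipe),
    )


def _mixture_center(spec: MixtureSpec) -> float:
    """Rough mixture EC50 used only to centre the dilution grid."""
    return 1.0 / sum(f / p.c for (_, p), f in zip(spec.components, spec.fractions))


@dataclass
class StudyData:
    """One fully simulated study: plates plus the generating ground truth."""

    scale: ReferenceScale
    e2_params: LigandParams
    e2_curve: ResponseCurve
    qc_responses: np.ndarray
    blanks: np.ndarray
    singles: dict[str, ResponseCurve]
    mixtures: dict[str, tuple[MixtureSpec, ResponseCurve]]
    equipotent: dict[str, tuple[MixtureSpec, ResponseCurve]]
    coexposure: Optional[tuple[MixtureSpec, float, ResponseCurve]]
    truths: dict
    seed: int
    scenario: dict = field(default_factory=dict)

    def all_curves(self) -> dict[str, ResponseCurve]:
        out = {"E2": self.e2_curve}
        out.update(self.singles)
        out.update({k: c for k, (_, c) in self.mixtures.items()})
        out.update({k: c for k, (_, c) in self.equipotent.items()})
        if self.coexposure is not None:
            out["coexposure_E2_EC50"] = self.coexposure[2]
        return out


DEFAULT_SCENARIO: dict = {
    "noise_fraction": 0.07,
    "replicates": 3,
    "n_points": 8,
    "dilution_factor": 10.0,
    "grid_decades": 3.5,
    "include_equipotent": True,
    "include_coexposure": True,
    "effect_levels": (10.0, 50.0),
    "noise_model": "multiplicative",
}


def simulate_study(scenario: Optional[dict] = None, seed: int = 0) -> StudyData:
    """Simulate the full study layout from the fixture library.

    Emits the E2 reference series with QC wells and blanks, single-compound
    plates for every compound used in a mixture, the 12 fixed-ratio food
    mixtures (2-5 components), EC10/EC50 equipotent phytoestrogen blends and
    the E2-plus-mixture co-exposure series, together with the generating
    ground truth for recovery testing.
    """
    cfg = dict(DEFAULT_SCENARIO)
    if scenario:
        unknown = set(scenario) - set(DEFAULT_SCENARIO)
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        cfg.update(scenario)
    lib = fixture_map()
    scale = ReferenceScale(y0=0.0, m=100.0)
    e2 = lib["E2"].params
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(200) % (2 ** 31))

    base = PlateDesign(
        n_points=int(cfg["n_points"]),
        dilution_factor=float(cfg["dilution_factor"]),
        replicates=int(cfg["replicates"]),
        noise_fraction=float(cfg["noise_fraction"]),
    )
    nm = cfg["noise_model"]
    half_dec = cfg["grid_decades"] / 2.0

    def grid_for(center: float) -> np.ndarray:
        return log_grid(center, decades=half_dec, points=base.n_points)

    # E2 reference plate, QC wells at the E2 EC50, solvent blanks
    e2_curve = simulate_curve(e2, base, scale, seed=int(next(seeds)),
                              noise_model=nm, sample_id="E2",
                              concentrations=grid_for(e2.c))
    rng_qc = np.random.default_rng(int(next(seeds)))
    qc_true = hill_response(e2, scale, e2.c)
    qc = np.clip(qc_true * (1.0 + base.noise_fraction
                            * rng_qc.standard_normal(base.qc_replicates)), 0.0, None)
    blanks = np.clip(scale.y0 + base.noise_fraction * scale.span * 0.05
                     * rng_qc.standard_normal(base.n_blanks), 0.0, None)

    used = sorted({cid for r in FOOD_MIXTURE_RECIPES.values() for cid, _ in r}
                  | set(BMD_BLEND))
    singles = {}
    for cid in used:
        p = lib[cid].params
        singles[cid] = simulate_curve(p, base, scale, seed=int(next(seeds)),
                                      noise_model=nm, sample_id=cid,
                                      concentrations=grid_for(p.c))

    mixtures = {}
    for name, recipe in FOOD_MIXTURE_RECIPES.items():
        spec = _mixture_spec(recipe, lib)
        conc = grid_for(_mixture_center(spec))
        curve = simulate_curve(spec, base, scale, seed=int(next(seeds)),
                               noise_model=nm, sample_id=name,
                               concentrations=conc)
        curve.meta["component_ids"] = ";".join(spec.ids)
        mixtures[name] = (spec, curve)

    equipotent = {}
    if cfg["include_equipotent"]:
        comps = [(cid, lib[cid].params) for cid in BMD_BLEND]
        for X in cfg["effect_levels"]:
            spec = equipotent_fractions(comps, X, scale)
            conc = grid_for(_mixture_center(spec))
            curve = simulate_curve(spec, base, scale, seed=int(next(seeds)),
                                   noise_model=nm,
                                   sample_id=f"equipotent_EC{X:g}",
                                   concentrations=conc)
            curve.meta["component_ids"] = ";".join(spec.ids)
            equipotent[f"EC{X:g}"] = (spec, curve)

    coexposure = None
    if cfg["include_coexposure"]:
        # E2 held at its EC50 while the phytoestrogen blend is diluted
        comps = [(cid, lib[cid].params) for cid in BMD_BLEND if cid != "8-PN"]
        fracs = (0.4, 0.3, 0.3)
        spec = MixtureSpec(components=tuple(comps), fractions=fracs)
        conc = grid_for(_mixture_center(spec))
        design = MixtureDesign(spec=spec, kind="coexposure_with_reference",
                               grid=conc, reference=(e2, e2.c))
        curve = simulate_curve(design, base, scale, seed=int(next(seeds)),
                               noise_model=nm, sample_id="coexposure_E2_EC50",
                               concentrations=conc)
        curve.meta["component_ids"] = ";".join(spec.ids) + ";E2"
        coexposure = (spec, e2.c, curve)

    truths = {
        "scale": {"y0": scale.y0, "m": scale.m},
        "E2": {"a": e2.a, "c": e2.c, "n": e2.n},
        "compounds": {cid: {"a": lib[cid].params.a, "c": lib[cid].params.c,
                            "n": lib[cid].params.n, "class": lib[cid].compound_class,
                            "note": lib[cid].note}
                      for cid in used},
        "mixtures": {name: {"components": list(spec.ids),
                            "fractions": list(spec.fractions)}
                     for name, (spec, _) in mixtures.items()},
        "scenario": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "seed": seed,
    }
    return StudyData(scale=scale, e2_params=e2, e2_curve=e2_curve,
                     qc_responses=qc, blanks=blanks, singles=singles,
                     mixtures=mixtures, equipotent=equipotent,
                     coexposure=coexposure, truths=truths, seed=seed,
                     scenario=cfg)
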