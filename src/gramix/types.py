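"""Core domain containers for reporter-gene dose-response analysis.

All responses are expressed in percent of the reference-agonist (E2) span,
so a ligand's efficacy ``a`` is a dimensionless fraction of ``m - y0``.
Concentrations are molar throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = ["ReferenceScale", "LigandParams", "MixtureSpec", "ResponseCurve"]


@dataclass(frozen=True)
class ReferenceScale:
    """Lower/upper asymptotes of the reference agonist (E2) curve.

    ``y0`` is the baseline (% activity) and ``m`` the E2 maximum,
    conventionally 100 after plate normalisation.
    """

    y0: float = 0.0
    m: float = 100.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.y0) and np.isfinite(self.m)):
            raise ValueError("reference asymptotes must be finite")
        if self.y0 < 0:
            raise ValueError(f"baseline y0 must be >= 0, got {self.y0}")
        if self.m <= self.y0:
            raise ValueError(f"upper asymptote m={self.m} must exceed y0={self.y0}")

    @property
    def span(self) -> float:
        return self.m - self.y0


@dataclass(frozen=True)
class LigandParams:
    """Hill parameters of one ligand.

    a : efficacy, fraction of the reference span (0 = pure antagonist,
        1 = full agonist, >1 = supra-agonist)
    c : potency (EC50), molar
    n : Hill slope / sensitivity coefficient

    The apparent dissociation constant of the mass-action derivation is
    ``K = c**n`` and is never stored separately.
    """

    a: float
    c: float
    n: float

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("c", self.c), ("n", self.n)):
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        if self.a < 0:
            raise ValueError(f"efficacy a must be >= 0, got {self.a}")
        if self.c <= 0:
            raise ValueError(f"potency c must be > 0, got {self.c}")
        if self.n <= 0:
            raise ValueError(f"Hill slope n must be > 0, got {self.n}")

    @property
    def K(self) -> float:
        """Apparent dissociation constant ``c**n``."""
        return self.c ** self.n

    def is_antagonist(self, tol: float = 0.0) -> bool:
        return self.a <= tol


_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MixtureSpec:
    """Named components with molar fractions of the total mixture concentration."""

    components: tuple[tuple[str, LigandParams], ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        comps = tuple((str(cid), p) for cid, p in self.components)
        fracs = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "fractions", fracs)
        if len(comps) == 0:
            raise ValueError("mixture needs at least one component")
        if len(fracs) != len(comps):
            raise ValueError("one fraction per component required")
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)!r}")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, LigandParams, float]]) -> "MixtureSpec":
        return cls(
            components=tuple((cid, p) for cid, p, _ in pairs),
            fractions=tuple(f for _, _, f in pairs),
        )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.components)

    @property
    def params(self) -> tuple[LigandParams, ...]:
        return tuple(p for _, p in self.components)

    def __len__(self) -> int:
        return len(self.components)


@dataclass
class ResponseCurve:
    """A concentration series with replicate responses in % activity.

    ``responses`` has shape (n_concentrations, n_replicates); ragged designs
    are represented with NaN wells and flagged in ``meta['ragged']``.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if resp.ndim == 1:
            resp = resp[:, None]
        if conc.ndim != 1:
            raise ValueError("concentrations must be one-dimensional")
        if resp.shape[0] != conc.shape[0]:
            raise ValueError(
                f"responses rows ({resp.shape[0]}) must match "
                f"concentrations ({conc.shape[0]})"
            )
        if not np.all(np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("concentrations must be finite and strictly positive")
        order = np.argsort(conc)
        conc = conc[order]
        resp = resp[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing (no duplicates)")
        self.concentrations = conc
        self.responses = resp

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[1]

    @property
    def mean_responses(self) -> np.ndarray:
        # all-NaN rows (e.g. truncated CA predictions) stay NaN silently
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.responses, axis=1)

    def mean_curve(self) -> "ResponseCurve":
        """Collapse replicates to their per-concentration mean."""
        meta = dict(self.meta)
        meta["aggregated"] = "mean"
        return ResponseCurve(self.concentrations.copy(), self.mean_responses[:, None], meta)

    @property
    def sample_id(self) -> str:
        return str(self.meta.get("sample_id", ""))
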