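"""Meiosis-II sex-chromosome transmission model.

Male meiosis II starts from equal numbers of X-bearing and Y-bearing
secondary spermatocytes.  A normal division yields two single-chromosome
sperm; a nondisjoined division yields one disomic sperm (XX or YY) and one
nullo-XY sperm.  Sperm classes are weighted by viability and renormalized;
fertilization by a euploid X-bearing egg maps sperm content to zygote
karyotype (X -> XX, Y -> XY, XX -> XXX, YY -> XYY, nullo -> XO), which is
weighted by zygote viability and renormalized.  Sex follows X dose: XX and
XXX zygotes are female; XY, XYY and XO are male (XO males are viable but
sterile, and are counted as progeny).

With both nondisjunction rates at zero the model collapses to the Mendelian
1:1 sex ratio regardless of disomic/nullo viabilities.  Removing YY products
(e.g. YY sperm failing to mature) while Y nondisjunction is elevated yields
female-biased broods — the logic of the D. simulans Paris sex-ratio drive.

All default viabilities are conventions, not measured values: the XXX class
defaults to low-but-nonzero viability; every number is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "SPERM_CLASSES",
    "ZYGOTE_CLASSES",
    "MeiosisParams",
    "BroodExpectation",
    "TransmissionModel",
    "TransmissionFit",
    "sperm_pool",
    "progeny_distribution",
]

SPERM_CLASSES = ("X", "Y", "XX", "YY", "nullo")
ZYGOTE_CLASSES = ("XX", "XY", "XXX", "XYY", "XO")
_SPERM_TO_ZYGOTE = {"X": "XX", "Y": "XY", "XX": "XXX", "YY": "XYY",
                    "nullo": "XO"}
_FEMALE_KARYOTYPES = {"XX", "XXX"}

# default zygote viabilities: XXX dramatically reduced but nonzero; XO male
# viable (sterile).  Conventions only; the source data constrain none of them.
_DEFAULT_ZYGOTE_VIABILITY = {
    "XX": 1.0, "XY": 1.0, "XXX": 0.05, "XYY": 1.0, "XO": 1.0,
}
_DEFAULT_SPERM_VIABILITY = {c: 1.0 for c in SPERM_CLASSES}


def _check_prob(name: str, value: float) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0) or not np.isfinite(v):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return v


@dataclass
class MeiosisParams:
    """Nondisjunction rates and viability maps driving brood expectations.

    ndj_X, ndj_Y : probability that an X- (Y-) bearing secondary
        spermatocyte nondisjoins at meiosis II.
    sperm_viability : map over {X, Y, XX, YY, nullo}.
    zygote_viability : map over {XX, XY, XXX, XYY, XO}.
    """

    ndj_X: float = 0.0
    ndj_Y: float = 0.0
    sperm_viability: dict = field(default_factory=lambda: dict(_DEFAULT_SPERM_VIABILITY))
    zygote_viability: dict = field(default_factory=lambda: dict(_DEFAULT_ZYGOTE_VIABILITY))

    def __post_init__(self) -> None:
        self.ndj_X = _check_prob("ndj_X", self.ndj_X)
        self.ndj_Y = _check_prob("ndj_Y", self.ndj_Y)
        sv = dict(_DEFAULT_SPERM_VIABILITY)
        sv.update(self.sperm_viability)
        zv = dict(_DEFAULT_ZYGOTE_VIABILITY)
        zv.update(self.zygote_viability)
        if set(sv) != set(SPERM_CLASSES):
            raise ValueError(f"sperm_viability keys must be {SPERM_CLASSES}")
        if set(zv) != set(ZYGOTE_CLASSES):
            raise ValueError(f"zygote_viability keys must be {ZYGOTE_CLASSES}")
        self.sperm_viability = {k: _check_prob(f"sperm_viability[{k}]", v)
                                for k, v in sv.items()}
        self.zygote_viability = {k: _check_prob(f"zygote_viability[{k}]", v)
                                 for k, v in zv.items()}

    @classmethod
    def from_json(cls, path) -> "MeiosisParams":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def sperm_pool(params: MeiosisParams) -> dict:
    """Viability-weighted sperm-class distribution from meiosis II.

    Equal X- and Y-bearing spermatocytes; each division yields two sperm.
    Normal: two X (or two Y).  Nondisjoined: one XX (or YY) plus one nullo.
    """
    raw = {
        "X": 0.5 * (1.0 - params.ndj_X),
        "Y": 0.5 * (1.0 - params.ndj_Y),
        "XX": 0.25 * params.ndj_X,
        "YY": 0.25 * params.ndj_Y,
        "nullo": 0.25 * params.ndj_X + 0.25 * params.ndj_Y,
    }
    weighted = {k: raw[k] * params.sperm_viability[k] for k in SPERM_CLASSES}
    total = sum(weighted.values())
    if total == 0.0:
        raise ValueError("all sperm classes have zero weight (empty pool)")
    return {k: v / total for k, v in weighted.items()}


@dataclass
class BroodExpectation:
    """Expected sperm and surviving-zygote distributions for one male."""

    sperm_freq: dict
    zygote_freq: dict
    female_fraction: float
    xo_male_fraction: float

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"class": f"sperm:{k}", "frequency": v}
            for k, v in self.sperm_freq.items()
        ] + [
            {"class": f"zygote:{k}", "frequency": v}
            for k, v in self.zygote_freq.items()
        ] + [
            {"class": "female_fraction", "frequency": self.female_fraction},
            {"class": "xo_male_fraction", "frequency": self.xo_male_fraction},
        ]
        return pd.DataFrame(rows)


def progeny_distribution(pool: dict, params: MeiosisParams) -> BroodExpectation:
    """Zygote-class distribution from a sperm pool and euploid X-bearing eggs."""
    total_in = sum(pool.values())
    if not np.isclose(total_in, 1.0, atol=1e-9):
        raise ValueError("sperm pool is not a normalized distribution")
    zygote = {z: 0.0 for z in ZYGOTE_CLASSES}
    for sperm, freq in pool.items():
        zygote[_SPERM_TO_ZYGOTE[sperm]] += freq
    weighted = {z: zygote[z] * params.zygote_viability[z]
                for z in ZYGOTE_CLASSES}
    total = sum(weighted.values())
    if total == 0.0:
        raise ValueError("no surviving zygote class")
    zygote_freq = {z: v / total for z, v in weighted.items()}
    female = sum(v for z, v in zygote_freq.items() if z in _FEMALE_KARYOTYPES)
    return BroodExpectation(
        sperm_freq=dict(pool),
        zygote_freq=zygote_freq,
        female_fraction=female,
        xo_male_fraction=zygote_freq["XO"],
    )


class TransmissionModel:
    """Forward and inverse use of the meiosis-II transmission accounting.

    ``expectation()`` maps parameters to expected brood composition;
    ``fit()`` inverts observed summary fractions to nondisjunction rates
    under fixed viability maps (grid search plus local refinement).
    """

    def __init__(self, params: MeiosisParams | None = None):
        self.params = params if params is not None else MeiosisParams()

    def expectation(self, ndj_X=None, ndj_Y=None) -> BroodExpectation:
        p = self.params
        if ndj_X is not None or ndj_Y is not None:
            p = MeiosisParams(
                ndj_X=p.ndj_X if ndj_X is None else ndj_X,
                ndj_Y=p.ndj_Y if ndj_Y is None else ndj_Y,
                sperm_viability=dict(p.sperm_viability),
                zygote_viability=dict(p.zygote_viability),
            )
        return progeny_distribution(sperm_pool(p), p)

    def fit(self, female_fraction: float, xo_male_fraction: float,
            grid: int = 41, residual_tol: float = 1e-4) -> "TransmissionFit":
        """Estimate (ndj_X, ndj_Y) from observed brood summary fractions.

        Least squares over a ``grid`` x ``grid`` lattice on [0, 1]^2 followed
        by bounded Nelder-Mead refinement.  A residual above ``residual_tol``
        marks the observations inconsistent with the model; a flat objective
        (several grid optima) marks the configuration non-identifiable.
        """
        obs = np.array([
            _check_prob("female_fraction", female_fraction),
            _check_prob("xo_male_fraction", xo_male_fraction),
        ])

        def objective(theta) -> float:
            x, y = np.clip(theta, 0.0, 1.0)
            try:
                exp = self.expectation(ndj_X=x, ndj_Y=y)
            except ValueError:
                return np.inf
            pred = np.array([exp.female_fraction, exp.xo_male_fraction])
            return float(np.sum((pred - obs) ** 2))

        axis = np.linspace(0.0, 1.0, grid)
        vals = np.array([[objective((x, y)) for y in axis] for x in axis])
        best = np.unravel_index(np.argmin(vals), vals.shape)
        start = (axis[best[0]], axis[best[1]])
        # flat objective over distant grid points -> non-identifiable
        near_best = vals <= vals[best] + 1e-12
        idx = np.argwhere(near_best)
        spread = idx.max(axis=0) - idx.min(axis=0) if len(idx) > 1 else (0, 0)
        identifiable = max(spread) <= max(2, grid // 10)

        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        est = np.clip(res.x, 0.0, 1.0)
        residual = objective(est)
        return TransmissionFit(
            model=self,
            ndj_X=float(est[0]),
            ndj_Y=float(est[1]),
            residual=float(residual),
            consistent=residual <= residual_tol,
            identifiable=bool(identifiable),
            observed={"female_fraction": float(obs[0]),
                      "xo_male_fraction": float(obs[1])},
        )


@dataclass
class TransmissionFit:
    model: TransmissionModel
    ndj_X: float
    ndj_Y: float
    residual: float
    consistent: bool
    identifiable: bool
    observed: dict

    def expectation(self) -> BroodExpectation:
        return self.model.expectation(ndj_X=self.ndj_X, ndj_Y=self.ndj_Y)

    def summary(self) -> str:
        lines = [
            "Meiosis-II transmission fit",
            f"  observed: female_fraction = {self.observed['female_fraction']:.4f}, "
            f"xo_male_fraction = {self.observed['xo_male_fraction']:.4f}",
            f"  estimated ndj_X = {self.ndj_X:.4f}, ndj_Y = {self.ndj_Y:.4f}",
            f"  squared residual = {self.residual:.3g}",
        ]
        if not self.consistent:
            lines.append(
                "  WARNING: observations inconsistent with any parameter "
                "pair under the supplied viabilities (minimal-residual "
                "estimate reported)"
            )
        if not self.identifiable:
            lines.append(
                "  WARNING: objective is flat; (ndj_X, ndj_Y) not uniquely "
                "identifiable under the supplied viabilities"
            )
        return "\n".join(lines)
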