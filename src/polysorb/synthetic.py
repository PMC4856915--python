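"""Synthetic polymer libraries with a planted structure-property signal.

The generator emulates the statistical situation the modelling pipeline is
designed for: a wide descriptor matrix (hundreds to thousands of columns)
in which only a few descriptors carry the property signal, some columns
are noisy copies of informative ones, and the rest are irrelevant noise.
The property is a saturating water-uptake time course sampled on the
standard incubation grid with multiplicative measurement noise.

The planted map from informative descriptors to equilibrium water uptake
is a sum of per-coordinate logistic terms: monotone in every informative
descriptor (so correlation-based selection can detect it) but nonlinear
(so a linear model cannot reproduce it exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    INCUBATION_GRID_DAYS,
    DescriptorTable,
    EquilibriumProperty,
    InvalidInputError,
    PlateauConfig,
    PropertySeries,
    estimate_equilibrium,
)

__all__ = ["GeneratorConfig", "GroundTruth", "uptake_curve", "generate_library"]

#: Logistic steepness per informative descriptor (cycled when more than 3).
_STEEPNESS = (1.5, 2.0, 2.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic library.

    Defaults mirror the small-training-set regime the pipeline targets:
    18 polymers, 300 descriptors of which 3 are informative and 6 are
    redundant copies, equilibrium uptake spanning roughly 2-140 % of dry
    mass, first-order uptake kinetics equilibrating within the 42-day
    incubation window, and ~8 % multiplicative measurement noise.
    """

    n_polymers: int = 18
    n_descriptors: int = 300
    n_informative: int = 3
    n_redundant: int = 6
    noise_sd_descriptor: float = 0.5
    target_range: tuple[float, float] = (2.0, 140.0)
    kinetics_rate_range: tuple[float, float] = (0.2, 3.0)
    meas_noise_cv: float = 0.08
    seed: int = 0
    times: tuple[float, ...] = INCUBATION_GRID_DAYS

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_descriptors:
            raise InvalidInputError("informative + redundant exceeds descriptor count")
        if not (self.target_range[0] < self.target_range[1]):
            raise InvalidInputError("target_range must be ordered (lo < hi)")
        if not (0 < self.kinetics_rate_range[0] <= self.kinetics_rate_range[1]):
            raise InvalidInputError("kinetics_rate_range must be positive and ordered")
        if self.meas_noise_cv < 0:
            raise InvalidInputError("meas_noise_cv must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    informative_names: tuple[str, ...]
    redundant_map: dict[str, str]  # redundant name -> parent informative name
    true_wu_eq: dict[str, float]
    true_rate_k: dict[str, float]

    @property
    def signal_names(self) -> frozenset[str]:
        """Informative descriptors plus their redundant copies."""
        return frozenset(self.informative_names) | frozenset(self.redundant_map)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_names": list(self.informative_names),
            "redundant_map": self.redundant_map,
            "true_wu_eq": self.true_wu_eq,
            "true_rate_k": self.true_rate_k,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return GroundTruth(
            tuple(d["informative_names"]),
            dict(d["redundant_map"]),
            {k: float(v) for k, v in d["true_wu_eq"].items()},
            {k: float(v) for k, v in d["true_rate_k"].items()},
        )


def uptake_curve(wu_eq: float, k: float, times: np.ndarray) -> np.ndarray:
    """First-order saturating uptake: ``WU(t) = wu_eq * (1 - exp(-k t))``.

    ``k`` is the uptake rate in 1/day; the curve starts at 0, is monotone
    non-decreasing and approaches ``wu_eq``.
    """
    if wu_eq < 0:
        raise InvalidInputError("wu_eq must be non-negative")
    if k <= 0:
        raise InvalidInputError("rate k must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    return wu_eq * (1.0 - np.exp(-k * t))


def _planted_target(z_inf: np.ndarray, target_range: tuple[float, float]) -> np.ndarray:
    """Monotone saturating map: sum of logistic terms, affinely scaled.

    Each informative coordinate contributes ``1/(1+exp(-a z))`` with fixed
    steepness ``a``; the sum (in ``(0, n_inf)``) is mapped linearly onto
    ``target_range`` so the library spans the intended low-to-high range.
    """
    n_inf = z_inf.shape[1]
    a = np.array([_STEEPNESS[j % len(_STEEPNESS)] for j in range(n_inf)])
    s = (1.0 / (1.0 + np.exp(-a * z_inf))).sum(axis=1)
    lo, hi = target_range
    return lo + (hi - lo) * s / n_inf


def generate_library(
    cfg: GeneratorConfig,
) -> tuple[DescriptorTable, list[PropertySeries], list[EquilibriumProperty], GroundTruth]:
    """Generate one synthetic library, fully reproducible from ``cfg.seed``.

    Returns the descriptor table, the noisy time series, the per-polymer
    equilibrium estimates obtained by the plateau rule on those noisy
    series (what an experimentalist would tabulate), and the ground truth.
    """
    if cfg.n_polymers < 4:
        raise InvalidInputError("need at least 4 polymers to form train/test splits")
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_polymers, cfg.n_descriptors
    n_inf, n_red = cfg.n_informative, cfg.n_redundant

    z_inf = rng.standard_normal((n, n_inf))
    parents = rng.integers(0, n_inf, size=n_red) if n_inf else np.empty(0, int)
    z_red = (
        z_inf[:, parents] + cfg.noise_sd_descriptor * rng.standard_normal((n, n_red))
        if n_red
        else np.empty((n, 0))
    )
    z_noise = rng.standard_normal((n, p - n_inf - n_red))

    inf_names = tuple(f"inf_{j:02d}" for j in range(n_inf))
    red_names = tuple(f"red_{j:02d}_of_{parents[j]:02d}" for j in range(n_red))
    noise_names = tuple(f"noise_{j:03d}" for j in range(p - n_inf - n_red))
    names = inf_names + red_names + noise_names
    values = np.column_stack([z_inf, z_red, z_noise]) if p else np.empty((n, 0))
    ids = tuple(f"polymer_{i:03d}" for i in range(n))
    provenance = ("synthetic",) * p
    table = DescriptorTable(ids, names, values, provenance)

    wu_true = _planted_target(z_inf, cfg.target_range) if n_inf else np.full(
        n, np.mean(cfg.target_range)
    )
    k_lo, k_hi = cfg.kinetics_rate_range
    log_k = rng.uniform(np.log(k_lo), np.log(k_hi), size=n)
    k_true = np.exp(log_k)

    times = np.asarray(cfg.times, dtype=float)
    series: list[PropertySeries] = []
    eqs: list[EquilibriumProperty] = []
    plateau = PlateauConfig()
    for i, pid in enumerate(ids):
        clean = uptake_curve(wu_true[i], k_true[i], times)
        if cfg.meas_noise_cv > 0:
            # lognormal factor with unit mean and CV = meas_noise_cv
            sigma = np.sqrt(np.log1p(cfg.meas_noise_cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(times))
        else:
            noise = np.ones(len(times))
        observed = clean * noise
        # replicate SD scales with the measured value (multiplicative noise)
        s = PropertySeries(pid, times, observed, cfg.meas_noise_cv * observed)
        series.append(s)
        eqs.append(estimate_equilibrium(s, plateau))

    truth = GroundTruth(
        inf_names,
        {red_names[j]: inf_names[parents[j]] for j in range(n_red)},
        {ids[i]: float(wu_true[i]) for i in range(n)},
        {ids[i]: float(k_true[i]) for i in range(n)},
    )
    return table, series, eqs, truth
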