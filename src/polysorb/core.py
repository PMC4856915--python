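"""Domain containers and core measurement arithmetic.

The quantities modelled throughout the package are water-uptake (WU)
measurements on polymer films: WU is the mass of absorbed water expressed
as a percentage of the film's dry mass.  A film incubated in water
approaches an equilibrium water uptake ``WU_eq``; the time course is
sampled on a fixed incubation grid (hours to weeks).  The containers here
hold the descriptor matrix (polymers x named molecular descriptors), the
per-polymer time series, and the consolidated per-polymer equilibrium
value with its experimental standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidInputError",
    "ParseError",
    "DescriptorTable",
    "PropertySeries",
    "EquilibriumProperty",
    "ModelingDataset",
    "PlateauConfig",
    "INCUBATION_GRID_DAYS",
    "TIME_FEATURE",
    "compute_water_uptake",
    "estimate_equilibrium",
]

#: Standard incubation sampling grid, in days (6 h, 12 h, then 1..42 d).
INCUBATION_GRID_DAYS: tuple[float, ...] = (
    0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0,
)

#: Name of the incubation-time column when time is carried as a feature.
TIME_FEATURE = "time"


class InvalidInputError(ValueError):
    """A physically or structurally invalid input value."""


class ParseError(ValueError):
    """A malformed input file (the message names the offending row/column)."""


def compute_water_uptake(m_water: float, m_sample: float) -> float:
    """Water uptake in percent of dry mass: ``100 * m_water / m_sample``.

    Parameters
    ----------
    m_water : float
        Mass of absorbed water (any mass unit).
    m_sample : float
        Dry mass of the sample, same unit; must be positive.
    """
    if m_sample <= 0:
        raise InvalidInputError(f"dry sample mass must be positive, got {m_sample!r}")
    if m_water < 0:
        raise InvalidInputError(f"water mass must be non-negative, got {m_water!r}")
    return 100.0 * m_water / m_sample


@dataclass(frozen=True)
class DescriptorTable:
    """Polymers x named molecular descriptors.

    ``values`` has shape ``(n_polymers, n_descriptors)``; ``provenance``
    carries one free-text tag per descriptor (``"2D"``, ``"3D-vacuum"``,
    ``"3D-water"``, ``"synthetic"``, ...).
    """

    polymer_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = tuple(self.polymer_ids)
        names = tuple(self.descriptor_names)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "polymer_ids", ids)
        object.__setattr__(self, "descriptor_names", names)
        object.__setattr__(self, "values", vals)
        prov = tuple(self.provenance) if self.provenance else ("unknown",) * len(names)
        object.__setattr__(self, "provenance", prov)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate polymer ids in descriptor table")
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate descriptor names in descriptor table")
        if vals.shape != (len(ids), len(names)):
            raise InvalidInputError(
                f"descriptor matrix shape {vals.shape} does not match "
                f"{len(ids)} polymers x {len(names)} descriptors"
            )
        if len(prov) != len(names):
            raise InvalidInputError("provenance length does not match descriptor count")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("descriptor matrix contains non-finite values")

    @property
    def n_polymers(self) -> int:
        return len(self.polymer_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor {name!r}") from None
        return self.values[:, j]

    def constant_columns(self) -> tuple[str, ...]:
        """Names of descriptors with zero variance across polymers."""
        sd = self.values.std(axis=0)
        return tuple(n for n, s in zip(self.descriptor_names, sd) if s == 0.0)

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(
            self.polymer_ids,
            tuple(names),
            self.values[:, idx],
            tuple(self.provenance[j] for j in idx),
        )

    def rows(self, polymer_ids: Sequence[str]) -> "DescriptorTable":
        idx = [self.polymer_ids.index(p) for p in polymer_ids]
        return DescriptorTable(
            tuple(polymer_ids), self.descriptor_names, self.values[idx], self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.descriptor_names))
        df.insert(0, "polymer_id", list(self.polymer_ids))
        return df


@dataclass(frozen=True)
class PropertySeries:
    """One polymer's water-uptake time course (times in days, WU in %)."""

    polymer_id: str
    times: np.ndarray
    wu_percent: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wu_percent, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wu_percent", w)
        if self.replicate_sd is not None:
            object.__setattr__(self, "replicate_sd", np.asarray(self.replicate_sd, float))
        if t.ndim != 1 or w.shape != t.shape:
            raise InvalidInputError("times and wu_percent must be 1-d and equal length")
        if len(t) and t[0] < 0:
            raise InvalidInputError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(w < 0):
            raise InvalidInputError("water uptake percentages must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class EquilibriumProperty:
    """Consolidated equilibrium water uptake for one polymer.

    ``wu_eq`` and ``sd_exp`` are in percent of dry mass.  ``plateau_times``
    records which time points entered the plateau window when the value was
    estimated from a series; ``flagged`` marks a fallback estimate for which
    no plateau satisfying the tolerance was found.
    """

    polymer_id: str
    wu_eq: float
    sd_exp: float
    plateau_times: tuple[float, ...] = ()
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.wu_eq < 0:
            raise InvalidInputError("wu_eq must be non-negative")
        if self.sd_exp < 0:
            raise InvalidInputError("sd_exp must be non-negative")


@dataclass(frozen=True)
class PlateauConfig:
    """Plateau-window rule for consolidating a series into ``WU_eq``.

    Points with ``t >= t_min_days`` are admitted while the absolute relative
    change from the previously admitted point stays within ``tol``; at least
    ``min_points`` admitted points are required, otherwise the estimate
    falls back to the mean of the last ``min_points`` observations and the
    result is flagged.
    """

    t_min_days: float = 7.0
    tol: float = 0.10
    min_points: int = 3


def estimate_equilibrium(
    series: PropertySeries, cfg: PlateauConfig | None = None
) -> EquilibriumProperty:
    """Consolidate a WU(t) series into an equilibrium value with its SD.

    The plateau window (see :class:`PlateauConfig`) is averaged; its sample
    standard deviation becomes the experimental SD.  Series that never
    settle under the tolerance yield a flagged last-``min_points`` fallback.
    """
    cfg = cfg or PlateauConfig()
    if len(series) < 3:
        raise InvalidInputError("need at least 3 time points to estimate equilibrium")
    t, w = series.times, series.wu_percent
    admitted: list[int] = []
    for i in range(len(t)):
        if t[i] < cfg.t_min_days:
            continue
        if not admitted:
            admitted.append(i)
            continue
        prev = w[admitted[-1]]
        if prev == 0.0:
            rel = 0.0 if w[i] == 0.0 else np.inf
        else:
            rel = abs(w[i] - prev) / abs(prev)
        if rel <= cfg.tol:
            admitted.append(i)
    if len(admitted) >= cfg.min_points:
        window = w[admitted]
        return EquilibriumProperty(
            series.polymer_id,
            float(np.mean(window)),
            float(np.std(window, ddof=1)) if len(window) > 1 else 0.0,
            plateau_times=tuple(float(x) for x in t[admitted]),
            flagged=False,
        )
    tail = w[-cfg.min_points:]
    return EquilibriumProperty(
        series.polymer_id,
        float(np.mean(tail)),
        float(np.std(tail, ddof=1)),
        plateau_times=tuple(float(x) for x in t[-cfg.min_points:]),
        flagged=True,
    )


TargetKind = Literal["equilibrium", "all_points"]


@dataclass(frozen=True)
class ModelingDataset:
    """Descriptors joined with a regression target.

    ``target_kind == "equilibrium"`` holds one consolidated WU_eq per
    polymer; ``"all_points"`` holds every (polymer, time, WU) observation
    as a row, with incubation time carried as an extra feature column.
    """

    descriptors: DescriptorTable
    target_kind: TargetKind
    equilibrium: tuple[EquilibriumProperty, ...] = ()
    point_polymer_ids: tuple[str, ...] = ()
    point_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    point_wu: np.ndarray = field(default_factory=lambda: np.empty(0))
    point_sd: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        known = set(self.descriptors.polymer_ids)
        if self.target_kind == "equilibrium":
            ids = [e.polymer_id for e in self.equilibrium]
        else:
            ids = list(self.point_polymer_ids)
            object.__setattr__(self, "point_times", np.asarray(self.point_times, float))
            object.__setattr__(self, "point_wu", np.asarray(self.point_wu, float))
            object.__setattr__(self, "point_sd", np.asarray(self.point_sd, float))
        missing = sorted(set(ids) - known)
        if missing:
            raise InvalidInputError(f"target polymers missing from descriptors: {missing}")
        if TIME_FEATURE in self.descriptors.descriptor_names:
            raise InvalidInputError(
                f"descriptor table must not contain a column named {TIME_FEATURE!r}"
            )

    # -- constructors -----------------------------------------------------

    @staticmethod
    def from_equilibrium(
        descriptors: DescriptorTable, eqs: Iterable[EquilibriumProperty]
    ) -> "ModelingDataset":
        return ModelingDataset(descriptors, "equilibrium", equilibrium=tuple(eqs))

    @staticmethod
    def from_series(
        descriptors: DescriptorTable,
        series: Iterable[PropertySeries],
        plateau: PlateauConfig | None = None,
    ) -> "ModelingDataset":
        """All-points dataset.

        Each row's experimental SD is its replicate SD when the series
        carries one, otherwise the polymer's plateau SD.
        """
        ids: list[str] = []
        times: list[float] = []
        wu: list[float] = []
        sd: list[float] = []
        for s in series:
            ids.extend([s.polymer_id] * len(s))
            times.extend(s.times.tolist())
            wu.extend(s.wu_percent.tolist())
            if s.replicate_sd is not None:
                sd.extend(s.replicate_sd.tolist())
            else:
                eq = estimate_equilibrium(s, plateau)
                sd.extend([eq.sd_exp] * len(s))
        return ModelingDataset(
            descriptors,
            "all_points",
            point_polymer_ids=tuple(ids),
            point_times=np.array(times),
            point_wu=np.array(wu),
            point_sd=np.array(sd),
        )

    # -- views ------------------------------------------------------------

    @property
    def unit_ids(self) -> tuple[str, ...]:
        """Independent-unit ids: polymers (equilibrium) or row labels."""
        if self.target_kind == "equilibrium":
            return tuple(e.polymer_id for e in self.equilibrium)
        return tuple(
            f"{p}@{t:g}" for p, t in zip(self.point_polymer_ids, self.point_times)
        )

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
        """Feature matrix, target vector and feature names.

        For the all-points target the incubation time (days) is appended as
        the last feature column, named :data:`TIME_FEATURE`.
        """
        desc = self.descriptors
        if self.target_kind == "equilibrium":
            ids = [e.polymer_id for e in self.equilibrium]
            X = desc.rows(ids).values
            y = np.array([e.wu_eq for e in self.equilibrium])
            return X, y, desc.descriptor_names
        rows = [desc.polymer_ids.index(p) for p in self.point_polymer_ids]
        X = np.column_stack([desc.values[rows], self.point_times])
        return X, self.point_wu.copy(), desc.descriptor_names + (TIME_FEATURE,)

    def target_sd(self) -> dict[str, float]:
        """Per-polymer experimental SD used by the within-variability metric."""
        if self.target_kind == "equilibrium":
            return {e.polymer_id: e.sd_exp for e in self.equilibrium}
        out: dict[str, float] = {}
        for p, s in zip(self.point_polymer_ids, self.point_sd):
            out[p] = float(s)
        return out

    def with_descriptors(self, descriptors: DescriptorTable) -> "ModelingDataset":
        return replace(self, descriptors=descriptors)
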