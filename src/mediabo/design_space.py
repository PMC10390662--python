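"""Media design space: component bounds, normalization, and the linear cost model.

The design space is an ordered list of media components. Each component has a
physical concentration range [conc_min, conc_max] (mg/mL, or "x"-multiples of a
stock for grouped basal variables) and a unitless marginal cost coefficient.
Every vector ``x`` handled by the optimizer lives on the min-max normalized
[0, 1]^p scale defined by this ordering.

Two coordinate scales coexist:

* **min-max scale** ``x_k = (conc_k - min_k) / (max_k - min_k)`` — used by the
  surrogate model and the acquisition function (the search box is [0,1]^p);
* **fraction-of-max scale** ``x~_k = conc_k / max_k`` — used by the cost model
  ``c(x) = c_min + sum_j c_j * x~_j``.

The fraction-of-max convention is the default cost scale because it reproduces
the published unitless costs of the reference media; min-max cost scaling is
available behind the ``scale`` option of :func:`compute_cost`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "DesignSpace",
    "MediumFormulation",
    "BoundsViolationError",
    "DesignSpaceParseError",
    "load_design_space",
    "save_design_space",
    "load_formulations",
    "save_formulations",
    "load_observation_log",
    "save_observation_log",
    "media26_design_space",
    "reported_media",
]


class BoundsViolationError(ValueError):
    """A concentration lies outside its component's [min, max] range."""


class DesignSpaceParseError(ValueError):
    """A design-space table failed validation (duplicate name, bad bounds...)."""


@dataclass(frozen=True)
class ComponentSpec:
    """One media component (or grouped basal variable) of the design space.

    Parameters
    ----------
    name:
        Short unique identifier (e.g. ``"FGF2"``, ``"NEAA"``).
    conc_min, conc_max:
        Concentration bounds. mg/mL for individual components; for grouped
        basal variables (``is_group=True``) the unit is an "x"-multiple of the
        stock concentration. Units need only be consistent within a component.
    cost_coeff:
        Unitless marginal cost on the fraction-of-max [0, 1] scale.
    is_group:
        Whether this is a grouped basal variable (amino acids, vitamins, ...).
    """

    name: str
    conc_min: float
    conc_max: float
    cost_coeff: float = 0.0
    is_group: bool = False

    def __post_init__(self) -> None:
        if not self.conc_min < self.conc_max:
            raise DesignSpaceParseError(
                f"component {self.name!r}: conc_min ({self.conc_min}) must be "
                f"< conc_max ({self.conc_max})"
            )
        if self.cost_coeff < 0:
            raise DesignSpaceParseError(
                f"component {self.name!r}: cost_coeff must be >= 0, "
                f"got {self.cost_coeff}"
            )


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of :class:`ComponentSpec` defining the search box.

    The iteration order is fixed and defines the meaning of every coordinate
    vector handled by the package.
    """

    components: tuple[ComponentSpec, ...]
    cmin: float = 0.0

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise DesignSpaceParseError("design space needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DesignSpaceParseError(f"duplicate component names: {dupes}")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def p(self) -> int:
        return len(self.components)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def conc_min(self) -> np.ndarray:
        return np.array([c.conc_min for c in self.components], dtype=float)

    @property
    def conc_max(self) -> np.ndarray:
        return np.array([c.conc_max for c in self.components], dtype=float)

    @property
    def cost_coeffs(self) -> np.ndarray:
        return np.array([c.cost_coeff for c in self.components], dtype=float)

    def content_hash(self) -> str:
        """Stable hash of the table, for checkpoint compatibility checks."""
        import hashlib

        payload = json.dumps(
            [
                [c.name, c.conc_min, c.conc_max, c.cost_coeff, c.is_group]
                for c in self.components
            ]
            + [self.cmin]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class MediumFormulation:
    """A single medium: normalized coordinates plus optional physical ones.

    ``x`` is on the min-max [0,1] scale in design-space order. ``conc`` (when
    present) holds the parallel physical concentrations.
    """

    x: np.ndarray
    conc: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValueError("x must be a 1-D vector")
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise BoundsViolationError(
                f"normalized coordinates outside [0,1]: {x[(x < 0) | (x > 1)]}"
            )
        object.__setattr__(self, "x", np.clip(x, 0.0, 1.0))
        if self.conc is not None:
            object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(conc: Sequence[float], space: DesignSpace, *, label: str | None = None,
              atol: float = 1e-9) -> MediumFormulation:
    """Map physical concentrations to the min-max [0, 1] scale.

    Raises :class:`BoundsViolationError` naming the first offending component
    if any concentration lies outside its [conc_min, conc_max] range (within
    ``atol`` absolute slack for boundary round-off).
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (space.p,):
        raise ValueError(f"expected {space.p} concentrations, got {conc.shape}")
    lo, hi = space.conc_min, space.conc_max
    bad = (conc < lo - atol) | (conc > hi + atol)
    if np.any(bad):
        k = int(np.argmax(bad))
        c = space.components[k]
        raise BoundsViolationError(
            f"concentration {conc[k]!r} of component {c.name!r} outside "
            f"[{c.conc_min}, {c.conc_max}]"
        )
    conc = np.clip(conc, lo, hi)
    x = (conc - lo) / (hi - lo)
    return MediumFormulation(x=x, conc=conc, label=label)


def denormalize(x: Sequence[float] | MediumFormulation, space: DesignSpace) -> np.ndarray:
    """Map min-max normalized coordinates back to physical concentrations."""
    if isinstance(x, MediumFormulation):
        x = x.x
    x = np.asarray(x, dtype=float)
    return space.conc_min + x * (space.conc_max - space.conc_min)


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

def compute_cost(x: MediumFormulation | Sequence[float], space: DesignSpace, *,
                 scale: str = "fraction_of_max") -> float:
    """Unitless linear cost ``c(x) = c_min + sum_j c_j * x~_j``.

    ``x`` is accepted either as a :class:`MediumFormulation` or as a raw
    vector on the min-max [0, 1] scale. With the default
    ``scale="fraction_of_max"`` the cost coordinate is
    ``x~_j = conc_j / conc_max_j``; with ``scale="minmax"`` it is the min-max
    normalized coordinate itself. The cost is deterministic and monotone
    non-decreasing in every coordinate (all ``c_j >= 0``).
    """
    if isinstance(x, MediumFormulation):
        xv = x.x
    else:
        xv = np.asarray(x, dtype=float)
        if np.any(xv < -1e-12) or np.any(xv > 1 + 1e-12):
            raise BoundsViolationError("normalized coordinates outside [0,1]")
    if scale == "fraction_of_max":
        conc = space.conc_min + np.clip(xv, 0, 1) * (space.conc_max - space.conc_min)
        coord = conc / space.conc_max
    elif scale == "minmax":
        coord = np.clip(xv, 0, 1)
    else:
        raise ValueError(f"unknown cost scale {scale!r}")
    return float(space.cmin + np.dot(space.cost_coeffs, coord))


def cost_from_unit_batch(X: np.ndarray, space: DesignSpace, *,
                         scale: str = "fraction_of_max") -> np.ndarray:
    """Vectorized :func:`compute_cost` over rows of a (n, p) array on [0,1]^p."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if scale == "fraction_of_max":
        conc = space.conc_min + np.clip(X, 0, 1) * (space.conc_max - space.conc_min)
        coord = conc / space.conc_max
    elif scale == "minmax":
        coord = np.clip(X, 0, 1)
    else:
        raise ValueError(f"unknown cost scale {scale!r}")
    return space.cmin + coord @ space.cost_coeffs


# ---------------------------------------------------------------------------
# I/O: design-space tables, formulation sheets, observation logs
# ---------------------------------------------------------------------------

_DS_COLUMNS = ["name", "min", "max", "cost", "group"]


def load_design_space(path: str | Path) -> DesignSpace:
    """Read a design-space CSV (columns name,min,max,cost,group), order preserved."""
    df = pd.read_csv(path)
    missing = [c for c in _DS_COLUMNS if c not in df.columns]
    if missing:
        raise DesignSpaceParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise DesignSpaceParseError(f"{path}: empty design-space table")
    comps = []
    for i, row in df.iterrows():
        try:
            comps.append(
                ComponentSpec(
                    name=str(row["name"]),
                    conc_min=float(row["min"]),
                    conc_max=float(row["max"]),
                    cost_coeff=float(row["cost"]),
                    is_group=bool(int(row["group"])),
                )
            )
        except DesignSpaceParseError as e:
            raise DesignSpaceParseError(f"{path} row {i}: {e}") from e
    try:
        return DesignSpace(components=tuple(comps))
    except DesignSpaceParseError as e:
        raise DesignSpaceParseError(f"{path}: {e}") from e


def save_design_space(space: DesignSpace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": space.names,
            "min": space.conc_min,
            "max": space.conc_max,
            "cost": space.cost_coeffs,
            "group": [int(c.is_group) for c in space.components],
        }
    )
    df.to_csv(path, index=False)


def save_formulations(forms: Iterable[MediumFormulation], space: DesignSpace,
                      path: str | Path) -> None:
    """Write a lab sheet: one row per medium, physical concentrations."""
    rows = []
    for i, f in enumerate(forms):
        conc = f.conc if f.conc is not None else denormalize(f.x, space)
        rows.append({"label": f.label or f"medium_{i}", **dict(zip(space.names, conc))})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_formulations(path: str | Path, space: DesignSpace) -> list[MediumFormulation]:
    """Read a lab sheet written by :func:`save_formulations`."""
    df = pd.read_csv(path)
    missing = [n for n in space.names if n not in df.columns]
    if missing:
        raise DesignSpaceParseError(f"{path}: missing component columns {missing}")
    out = []
    for _, row in df.iterrows():
        conc = np.array([float(row[n]) for n in space.names])
        out.append(normalize(conc, space, label=row.get("label")))
    return out


def save_observation_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_observation_log(path: str | Path, space: DesignSpace) -> pd.DataFrame:
    """Read an observation log: component columns + fidelity + y (+ batch)."""
    df = pd.read_csv(path)
    required = space.names + ["fidelity", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DesignSpaceParseError(f"{path}: missing columns {missing}")
    if "batch" not in df.columns:
        df["batch"] = 0
    return df


# ---------------------------------------------------------------------------
# Packaged fixtures: the 26-component media design space and reference media
# ---------------------------------------------------------------------------

def media26_design_space() -> DesignSpace:
    """The packaged 26-component serum-free media design space."""
    with resources.as_file(
        resources.files("mediabo.data") / "design_space_media26.csv"
    ) as p:
        return load_design_space(p)


def reported_media() -> pd.DataFrame:
    """Reference media formulations (physical concentrations, one row each).

    These are the published control and optimized media used to validate the
    linear cost model; the ``label`` column identifies each medium.
    """
    with resources.as_file(
        resources.files("mediabo.data") / "reported_media.csv"
    ) as p:
        return pd.read_csv(p)
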