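"""Synthetic plate data with the statistical structure the analysis assumes.

Each plate receives one Gaussian random effect ``b`` on the log-odds scale,
shared by both species on that plate; fate counts are then multinomial.
Concretely, for a cell with base probabilities ``(p_germ, p_dead)`` (dormant
is the remainder), the plate-level fate probabilities are the multinomial
logit with the dormant class as reference and ``b`` added to both
non-reference logits::

    q_germ = p_germ * exp(b),  q_dead = p_dead * exp(b),  q_dorm = p_dorm
    p'_f   = q_f / (q_germ + q_dead + q_dorm)

This keeps the fate simplex valid for any ``b`` and induces a positive
correlation between the two species' responses on the same plate — the
dependency the paired-plate bootstrap is designed to respect.  With
``sigma_plate = 0`` the construction reduces to independent multinomial
sampling at the base rates.

The generator is a pure function of its configuration: the same
:class:`SyntheticConfig` (seed included) always yields the identical
:class:`~seedfate.plates.Dataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .plates import (
    CONTROL,
    Dataset,
    DesignError,
    PlateRecord,
    Species,
    Temperature,
)

__all__ = [
    "CellParams",
    "SyntheticConfig",
    "CellKey",
    "generate",
    "calibrate_marginal_germination",
    "standard_design_config",
    "load_config",
    "save_config",
]

CellKey = tuple[str, Species, Temperature]


@dataclass(frozen=True)
class CellParams:
    """Base fate rates of one group x species x temperature cell."""

    p_germ: float
    p_dead: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_germ <= 1.0 and 0.0 <= self.p_dead <= 1.0):
            raise DesignError(f"probabilities out of [0,1]: {self}")
        if self.p_germ + self.p_dead > 1.0 + 1e-12:
            raise DesignError(f"p_germ + p_dead > 1: {self}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a simulated experiment.

    ``sigma_plate`` is the standard deviation of the per-plate random
    effect on the log-odds scale (0 = independent plates). The default
    of 0.5 is a convention; no empirical plate-variance estimate exists
    for the assay this emulates.
    """

    cells: Mapping[CellKey, CellParams]
    n_replicates: int = 5
    n_seeds: int = 10
    sigma_plate: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        cells = {
            (str(g), Species(sp), Temperature(t)): p
            for (g, sp, t), p in dict(self.cells).items()
        }
        object.__setattr__(self, "cells", cells)
        if self.n_replicates < 1 or self.n_seeds < 1:
            raise DesignError("n_replicates and n_seeds must be >= 1")
        if self.sigma_plate < 0:
            raise DesignError("sigma_plate must be >= 0")
        temps = {t for (_, _, t) in cells}
        for t in temps:
            if (CONTROL, Species.BRTO, t) not in cells or (
                CONTROL,
                Species.PLOV,
                t,
            ) not in cells:
                raise DesignError(
                    f"CONTROL cells for both species required under {t.value}"
                )
        for (g, sp, t) in cells:
            other = Species.PLOV if sp is Species.BRTO else Species.BRTO
            if (g, other, t) not in cells:
                raise DesignError(
                    f"group {g} under {t.value} lacks a cell for {other.value}"
                )

    def groups(self) -> list[str]:
        return sorted({g for (g, _, _) in self.cells})

    def temperatures_of(self, group: str) -> list[Temperature]:
        return sorted(
            {t for (g, _, t) in self.cells if g == group}, key=lambda t: t.value
        )


def generate(config: SyntheticConfig) -> Dataset:
    """Draw one full dataset from a configuration.

    Deterministic traversal order (groups, then temperatures, then
    replicates, then species, all sorted) makes generation reproducible:
    identical configs give bit-identical datasets.
    """
    rng = np.random.default_rng(config.rng_seed)
    records = []
    for group in config.groups():
        for temp in config.temperatures_of(group):
            for rep in range(1, config.n_replicates + 1):
                b = rng.normal(0.0, config.sigma_plate)
                for sp in sorted(Species, key=lambda s: s.value):
                    pars = config.cells[(group, sp, temp)]
                    probs = _perturbed_probs(pars, b)
                    n_g, n_d, n_dorm = rng.multinomial(config.n_seeds, probs)
                    records.append(
                        PlateRecord(
                            group=group,
                            temperature=temp,
                            replicate=rep,
                            species=sp,
                            n_germinated=int(n_g),
                            n_dead=int(n_d),
                            n_dormant=int(n_dorm),
                            n_total=config.n_seeds,
                        )
                    )
    return Dataset(records=tuple(records))


def _perturbed_probs(pars: CellParams, b: float) -> np.ndarray:
    p_dorm = max(0.0, 1.0 - pars.p_germ - pars.p_dead)
    w = math.exp(b)
    q = np.array([pars.p_germ * w, pars.p_dead * w, p_dorm], dtype=float)
    total = q.sum()
    if total == 0.0:  # p_germ = p_dead = p_dorm = 0 is impossible; guard anyway
        return np.array([0.0, 0.0, 1.0])
    return q / total


def calibrate_marginal_germination(
    target: float, sigma_plate: float, n_quad: int = 81
) -> float:
    """Base germination rate whose *marginal* mean fraction equals ``target``.

    With ``p_dead = 0`` the plate-level germination probability is
    ``expit(logit(p) + b)`` with ``b ~ N(0, sigma_plate^2)``, so the
    marginal expected fraction ``E[expit(logit(p) + b)]`` differs from the
    base rate ``p`` whenever ``sigma_plate > 0``.  This inverts that map by
    Gauss-Hermite quadrature, so that simulated effects are stated on the
    marginal fraction scale — the estimand of a difference of cell means.
    """
    if not 0.0 < target < 1.0:
        raise DesignError("target marginal fraction must be in (0, 1)")
    if sigma_plate == 0.0:
        return float(target)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()

    def marginal(p: float) -> float:
        return float(weights @ expit(logit(p) + sigma_plate * nodes))

    return float(brentq(lambda p: marginal(p) - target, 1e-12, 1 - 1e-12, xtol=1e-12))


# -- a ready-made experiment-shaped configuration -------------------------

# Baseline (uninoculated) fate rates per species x temperature.  Winter
# germination baselines mirror the low control germination typical of
# freshly dormant winter-annual seed lots (2 % and 16 %); summer baselines
# are small by convention.
_CONTROL_RATES: dict[tuple[Species, Temperature], CellParams] = {
    (Species.BRTO, Temperature.WINTER): CellParams(0.02, 0.01),
    (Species.PLOV, Temperature.WINTER): CellParams(0.16, 0.01),
    (Species.BRTO, Temperature.SUMMER): CellParams(0.05, 0.04),
    (Species.PLOV, Temperature.SUMMER): CellParams(0.08, 0.04),
}

# Heterogeneous strain effects: overrides of the baseline rates for
# selected strains, chosen so the simulated community spans the qualitative
# range of behaviours the analysis must resolve — strong host-specific
# summer loss in both directions, host-specific winter germination, broad
# non-specific mortality, and many near-null strains.
_STRAIN_OVERRIDES: dict[tuple[str, Species, Temperature], CellParams] = {
    # strong summer germination of BRTO only (host-specific loss to BRTO)
    ("01C", Species.BRTO, Temperature.SUMMER): CellParams(0.85, 0.05),
    ("01C", Species.PLOV, Temperature.SUMMER): CellParams(0.08, 0.04),
    ("01C", Species.BRTO, Temperature.WINTER): CellParams(0.05, 0.01),
    ("01C", Species.PLOV, Temperature.WINTER): CellParams(0.40, 0.01),
    # strong winter germination of PLOV; summer pathogen of BRTO
    ("01D", Species.BRTO, Temperature.WINTER): CellParams(0.03, 0.01),
    ("01D", Species.PLOV, Temperature.WINTER): CellParams(0.55, 0.01),
    ("01D", Species.BRTO, Temperature.SUMMER): CellParams(0.10, 0.50),
    ("01D", Species.PLOV, Temperature.SUMMER): CellParams(0.50, 0.20),
    # non-specific and BRTO-skewed summer mortality
    ("04A", Species.BRTO, Temperature.SUMMER): CellParams(0.05, 0.70),
    ("04A", Species.PLOV, Temperature.SUMMER): CellParams(0.08, 0.10),
    ("04B", Species.BRTO, Temperature.SUMMER): CellParams(0.05, 0.40),
    ("04B", Species.PLOV, Temperature.SUMMER): CellParams(0.08, 0.18),
    ("08", Species.BRTO, Temperature.SUMMER): CellParams(0.05, 0.50),
    ("08", Species.PLOV, Temperature.SUMMER): CellParams(0.08, 0.45),
    ("08", Species.BRTO, Temperature.WINTER): CellParams(0.10, 0.01),
    ("08", Species.PLOV, Temperature.WINTER): CellParams(0.03, 0.01),
    # host-specific summer loss toward PLOV via germination
    ("09", Species.BRTO, Temperature.SUMMER): CellParams(0.10, 0.04),
    ("09", Species.PLOV, Temperature.SUMMER): CellParams(0.55, 0.05),
    # winter germination suppression of PLOV by several strains
    ("02B", Species.PLOV, Temperature.WINTER): CellParams(0.02, 0.01),
    ("03A", Species.PLOV, Temperature.WINTER): CellParams(0.02, 0.01),
    ("03A", Species.BRTO, Temperature.WINTER): CellParams(0.06, 0.08),
    ("03B", Species.PLOV, Temperature.WINTER): CellParams(0.02, 0.01),
    ("03B", Species.BRTO, Temperature.WINTER): CellParams(0.06, 0.08),
    ("03C", Species.PLOV, Temperature.WINTER): CellParams(0.03, 0.01),
    ("06", Species.PLOV, Temperature.WINTER): CellParams(0.03, 0.01),
    ("07", Species.PLOV, Temperature.WINTER): CellParams(0.04, 0.01),
}

_STANDARD_STRAINS = (
    "01A", "01B", "01C", "01D",
    "02A", "02B", "02C", "02D",
    "03A", "03B", "03C",
    "04A", "04B",
    "05", "06", "07", "08", "09",
)


def standard_design_config(rng_seed: int = 0) -> SyntheticConfig:
    """The full experiment-shaped configuration.

    18 strains plus CONTROL x 2 temperature regimes x 5 replicate plates
    x 2 species x 10 seeds: 190 plates, 380 records.  Cell rates are fixed,
    documented values (see module constants); only ``rng_seed`` varies.
    """
    cells: dict[CellKey, CellParams] = {}
    for (sp, t), pars in _CONTROL_RATES.items():
        cells[(CONTROL, sp, t)] = pars
    for strain in _STANDARD_STRAINS:
        for (sp, t), base in _CONTROL_RATES.items():
            cells[(strain, sp, t)] = _STRAIN_OVERRIDES.get((strain, sp, t), base)
    return SyntheticConfig(cells=cells, rng_seed=rng_seed)


# -- plain-text configuration files ---------------------------------------


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML."""
    doc = {
        "n_replicates": config.n_replicates,
        "n_seeds": config.n_seeds,
        "sigma_plate": float(config.sigma_plate),
        "rng_seed": int(config.rng_seed),
        "cells": [
            {
                "group": g,
                "species": sp.value,
                "temperature": t.value,
                "p_germ": float(p.p_germ),
                "p_dead": float(p.p_dead),
            }
            for (g, sp, t), p in sorted(
                config.cells.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
            )
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> SyntheticConfig:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        cells = {
            (str(c["group"]), Species(c["species"]), Temperature(c["temperature"])):
            CellParams(float(c["p_germ"]), float(c.get("p_dead", 0.0)))
            for c in doc["cells"]
        }
        return SyntheticConfig(
            cells=cells,
            n_replicates=int(doc.get("n_replicates", 5)),
            n_seeds=int(doc.get("n_seeds", 10)),
            sigma_plate=float(doc.get("sigma_plate", 0.5)),
            rng_seed=int(doc.get("rng_seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise DesignError(f"malformed simulation config {path}: {exc}") from exc
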