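"""Control-corrected effect sizes on the per-plate fraction scale.

All point estimates follow the same convention: a response fraction is
computed per plate, averaged over the replicates of a cell, and effects are
differences of those cell means.

* ``effect_vs_control`` — inoculated-cell mean minus control-cell mean
  (positive = the strain increases the response).
* ``host_specificity`` — vs-control effect of the *first* species argument
  minus that of the second (antisymmetric in argument order).
* ``control_mean`` — the uninoculated baseline fraction itself.

Fractions are averaged per plate rather than pooled across plates; with
equal seeds per plate the two coincide, but the per-plate definition is the
canonical one here and is what the paired-plate bootstrap resamples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .plates import (
    CONTROL,
    Dataset,
    PlateRecord,
    ResponseKind,
    SeedFateError,
    Species,
    Temperature,
)

__all__ = [
    "EffectKind",
    "FractionSummary",
    "EffectEstimate",
    "CellLookupError",
    "fraction",
    "cell_fractions",
    "fraction_summary",
    "effect_vs_control",
    "host_specificity",
    "control_mean",
]


class CellLookupError(SeedFateError, LookupError):
    """A requested group x species x temperature cell has no plates."""


class EffectKind(str, enum.Enum):
    VS_CONTROL = "vs_control"
    HOST_SPECIFICITY = "host_specificity"
    CONTROL_MEAN = "control_mean"


@dataclass(frozen=True)
class FractionSummary:
    """Per-plate response fractions of one cell and their mean."""

    group: str
    species: Species
    temperature: Temperature
    response: ResponseKind
    per_plate_fractions: tuple[float, ...]
    mean_fraction: float


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate on the fraction scale, in [-1, 1].

    ``species`` is a single species code for vs-control and control-mean
    estimates, and an ordered ``(species_a, species_b)`` pair for host
    specificity (effect = A's vs-control effect minus B's).
    """

    group: str
    species: Species | tuple[Species, Species]
    temperature: Temperature
    response: ResponseKind
    effect: float
    kind: EffectKind


def fraction(record: PlateRecord, response: ResponseKind) -> float:
    """Per-plate response fraction.

    ``LOSS`` (germination + mortality) is only defined for summer plates:
    winter germination is not a loss from the seed bank.
    """
    response = ResponseKind(response)
    if response is ResponseKind.GERMINATION:
        return record.n_germinated / record.n_total
    if response is ResponseKind.MORTALITY:
        return record.n_dead / record.n_total
    if record.temperature is not Temperature.SUMMER:
        raise SeedFateError(
            "seed loss is defined only under the summer temperature regime "
            f"(got {record.temperature.value})"
        )
    return (record.n_germinated + record.n_dead) / record.n_total


def cell_fractions(
    dataset: Dataset,
    group: str,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
) -> np.ndarray:
    """Per-plate fractions of one cell, ordered by replicate index."""
    recs = dataset.cell(group, species, temperature)
    if not recs:
        raise CellLookupError(
            f"no plates for cell (group={group}, species={Species(species).value}, "
            f"temperature={Temperature(temperature).value})"
        )
    return np.array([fraction(r, response) for r in recs], dtype=float)


def fraction_summary(
    dataset: Dataset,
    group: str,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
) -> FractionSummary:
    fr = cell_fractions(dataset, group, species, temperature, response)
    return FractionSummary(
        group=group,
        species=Species(species),
        temperature=Temperature(temperature),
        response=ResponseKind(response),
        per_plate_fractions=tuple(float(x) for x in fr),
        mean_fraction=float(fr.mean()),
    )


def effect_vs_control(
    dataset: Dataset,
    group: str,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
) -> EffectEstimate:
    """Inoculated-minus-control difference in mean per-plate fraction."""
    if group == CONTROL:
        raise SeedFateError("effect_vs_control requires a non-control group")
    treated = cell_fractions(dataset, group, species, temperature, response)
    control = cell_fractions(dataset, CONTROL, species, temperature, response)
    return EffectEstimate(
        group=group,
        species=Species(species),
        temperature=Temperature(temperature),
        response=ResponseKind(response),
        effect=float(treated.mean() - control.mean()),
        kind=EffectKind.VS_CONTROL,
    )


def host_specificity(
    dataset: Dataset,
    group: str,
    species_a: Species,
    species_b: Species,
    temperature: Temperature,
    response: ResponseKind,
) -> EffectEstimate:
    """Between-species difference in vs-control effect (A minus B)."""
    species_a, species_b = Species(species_a), Species(species_b)
    if species_a == species_b:
        raise SeedFateError("host specificity needs two distinct species")
    ea = effect_vs_control(dataset, group, species_a, temperature, response)
    eb = effect_vs_control(dataset, group, species_b, temperature, response)
    return EffectEstimate(
        group=group,
        species=(species_a, species_b),
        temperature=Temperature(temperature),
        response=ResponseKind(response),
        effect=ea.effect - eb.effect,
        kind=EffectKind.HOST_SPECIFICITY,
    )


def control_mean(
    dataset: Dataset,
    species: Species,
    temperature: Temperature,
    response: ResponseKind,
) -> EffectEstimate:
    """Mean uninoculated response fraction (the baseline itself)."""
    fr = cell_fractions(dataset, CONTROL, species, temperature, response)
    return EffectEstimate(
        group=CONTROL,
        species=Species(species),
        temperature=Temperature(temperature),
        response=ResponseKind(response),
        effect=float(fr.mean()),
        kind=EffectKind.CONTROL_MEAN,
    )
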