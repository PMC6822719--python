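"""Plate-level seed-fate data model, validation and CSV I/O.

The experimental unit is a Petri plate holding seeds of two plant species
(codes ``BRTO`` and ``PLOV``) exposed to one fungal strain (or an
uninoculated control) under one temperature regime.  After incubation each
seed is scored into exactly one of three fates: germinated, dead, or
dormant.  One :class:`PlateRecord` holds the fate counts for one species on
one plate; a :class:`Dataset` is the collection of records for a whole
experiment, with the invariant that every plate carries exactly one record
per species (plates are *paired* across species, which the resampling
module relies on).

Strain identifiers are a numeric OTU prefix (95 % ITS rDNA sequence
similarity cluster) plus an optional single-letter genotype suffix (100 %
similarity), e.g. ``01A`` or ``09``.  The reserved group token ``CONTROL``
never collides with a strain id because strain ids must start with a digit.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "CONTROL",
    "Species",
    "Temperature",
    "ResponseKind",
    "SeedFateError",
    "SchemaError",
    "RecordValidationError",
    "PairingError",
    "DesignError",
    "StrainInfo",
    "PlateRecord",
    "Dataset",
    "TaxaSummary",
    "parse_strain_id",
    "summarize_taxa",
    "read_plates",
    "write_plates",
    "load_strain_metadata",
]

#: Reserved group token for uninoculated plates.
CONTROL = "CONTROL"

#: Columns of the plate CSV, in canonical order.
PLATE_COLUMNS = (
    "group",
    "temperature",
    "replicate",
    "species",
    "n_germinated",
    "n_dead",
    "n_dormant",
    "n_total",
)

STRAIN_ID_RE = re.compile(r"^(\d+)([A-Z]?)$")
SEED_SOURCES = ("V", "D", "V&D")


class Species(str, enum.Enum):
    """Two-letter-coded plant species. The library treats them symmetrically."""

    BRTO = "BRTO"  # Brassica tournefortii
    PLOV = "PLOV"  # Plantago ovata


class Temperature(str, enum.Enum):
    """Simulated seasonal temperature regime of the growth chamber."""

    SUMMER = "summer"
    WINTER = "winter"


class ResponseKind(str, enum.Enum):
    """Seed demographic response.

    ``LOSS`` (germination + mortality, i.e. exit from the seed bank) is
    defined only under the summer regime, where germination is lethal for
    winter annuals.
    """

    GERMINATION = "germination"
    MORTALITY = "mortality"
    LOSS = "loss"


class SeedFateError(ValueError):
    """Base class for data-model errors."""


class SchemaError(SeedFateError):
    """A required column is missing or malformed in an input file."""


class RecordValidationError(SeedFateError):
    """A single record violates a count or identifier invariant."""


class PairingError(SeedFateError):
    """A plate is missing one species' record, breaking species pairing."""


class DesignError(SeedFateError):
    """Dataset-level design invariant violated (duplicates, metadata gaps)."""


def parse_strain_id(strain_id: str) -> tuple[str, str]:
    """Split a strain id into its OTU prefix and genotype suffix.

    >>> parse_strain_id("01A")
    ('01', 'A')
    >>> parse_strain_id("09")
    ('09', '')
    """
    m = STRAIN_ID_RE.match(strain_id)
    if m is None:
        raise RecordValidationError(
            f"malformed strain id {strain_id!r}: expected digits plus an "
            "optional single capital letter (e.g. '01A', '09')"
        )
    return m.group(1), m.group(2)


@dataclass(frozen=True)
class StrainInfo:
    """Identity and provenance of one fungal strain.

    ``seed_source`` records whether the strain was isolated from viable
    (``V``), degraded (``D``) or both (``V&D``) seeds.
    """

    strain_id: str
    seed_source: str
    genus_label: str
    order_label: str
    otu_id: str = field(init=False)
    genotype: str = field(init=False)

    def __post_init__(self) -> None:
        otu, geno = parse_strain_id(self.strain_id)
        object.__setattr__(self, "otu_id", otu)
        object.__setattr__(self, "genotype", geno)
        if self.seed_source not in SEED_SOURCES:
            raise RecordValidationError(
                f"seed_source {self.seed_source!r} for strain "
                f"{self.strain_id!r} not one of {SEED_SOURCES}"
            )


class TaxaSummary(NamedTuple):
    n_strains: int
    n_otus: int
    n_orders: int


def summarize_taxa(metadata: Sequence[StrainInfo]) -> TaxaSummary:
    """Count distinct strains, OTUs and orders in a strain-metadata table."""
    if not metadata:
        raise DesignError("empty strain metadata")
    ids = [s.strain_id for s in metadata]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate strain ids in metadata: {dupes}")
    return TaxaSummary(
        n_strains=len(set(ids)),
        n_otus=len({s.otu_id for s in metadata}),
        n_orders=len({s.order_label for s in metadata}),
    )


@dataclass(frozen=True)
class PlateRecord:
    """Seed-fate counts for one plant species on one Petri plate."""

    group: str
    temperature: Temperature
    replicate: int
    species: Species
    n_germinated: int
    n_dead: int
    n_dormant: int
    n_total: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperature", Temperature(self.temperature))
        object.__setattr__(self, "species", Species(self.species))
        if self.group != CONTROL:
            parse_strain_id(self.group)
        if self.replicate < 1:
            raise RecordValidationError(
                f"replicate must be >= 1, got {self.replicate} ({self._tag()})"
            )
        counts = (self.n_germinated, self.n_dead, self.n_dormant)
        if any(c < 0 for c in counts):
            raise RecordValidationError(f"negative fate count in {self._tag()}")
        if self.n_total < 1:
            raise RecordValidationError(f"n_total must be >= 1 in {self._tag()}")
        if sum(counts) != self.n_total:
            raise RecordValidationError(
                f"fate counts {counts} sum to {sum(counts)}, not n_total="
                f"{self.n_total} ({self._tag()})"
            )

    def _tag(self) -> str:
        sp = self.species.value if isinstance(self.species, Species) else self.species
        return f"group={self.group}, temperature={getattr(self.temperature, 'value', self.temperature)}, replicate={self.replicate}, species={sp}"

    @property
    def plate_key(self) -> tuple[str, Temperature, int]:
        return (self.group, self.temperature, self.replicate)


def _record_sort_key(r: PlateRecord):
    return (r.group, r.temperature.value, r.replicate, r.species.value)


@dataclass(frozen=True)
class Dataset:
    """A validated, order-normalized collection of plate records.

    Records are stored sorted by (group, temperature, replicate, species),
    so two datasets with the same plates compare equal regardless of input
    order.  Construction enforces that every plate present carries exactly
    one record per species.
    """

    records: tuple[PlateRecord, ...]
    strain_metadata: Optional[tuple[StrainInfo, ...]] = None

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=_record_sort_key))
        object.__setattr__(self, "records", recs)
        if self.strain_metadata is not None:
            object.__setattr__(self, "strain_metadata", tuple(self.strain_metadata))
        seen: dict[tuple, PlateRecord] = {}
        for r in recs:
            key = (r.group, r.temperature, r.replicate, r.species)
            if key in seen:
                raise DesignError(f"duplicate record for {r._tag()}")
            seen[key] = r
        species = tuple(Species)
        plates = {r.plate_key for r in recs}
        for group, temp, rep in sorted(plates, key=lambda k: (k[0], k[1].value, k[2])):
            present = [sp for sp in species if (group, temp, rep, sp) in seen]
            if len(present) != len(species):
                missing = [sp.value for sp in species if sp not in present]
                raise PairingError(
                    f"plate (group={group}, temperature={temp.value}, "
                    f"replicate={rep}) is missing species {missing}"
                )
        if self.strain_metadata is not None:
            summarize_taxa(self.strain_metadata)  # uniqueness check
            known = {s.strain_id for s in self.strain_metadata}
            unknown = sorted(
                {r.group for r in recs if r.group != CONTROL} - known
            )
            if unknown:
                raise DesignError(
                    f"groups {unknown} have no entry in strain metadata"
                )

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> list[str]:
        """All group tokens present, CONTROL included, sorted."""
        return sorted({r.group for r in self.records})

    def strains(self) -> list[str]:
        """Non-control groups, sorted."""
        return [g for g in self.groups() if g != CONTROL]

    def temperatures(self) -> list[Temperature]:
        return sorted({r.temperature for r in self.records}, key=lambda t: t.value)

    def cell(
        self, group: str, species: Species, temperature: Temperature
    ) -> list[PlateRecord]:
        """Records of one group x species x temperature cell, by replicate."""
        out = [
            r
            for r in self.records
            if r.group == group
            and r.species == Species(species)
            and r.temperature == Temperature(temperature)
        ]
        return sorted(out, key=lambda r: r.replicate)

    def n_replicates(self, group: str, temperature: Temperature) -> int:
        return len({r.replicate for r in self.records
                    if r.group == group and r.temperature == Temperature(temperature)})


# -- CSV I/O --------------------------------------------------------------


def read_plates(
    path: str | Path,
    dialect: Optional[Mapping] = None,
    strain_metadata: Optional[Sequence[StrainInfo]] = None,
) -> Dataset:
    """Read a plate-count CSV into a validated :class:`Dataset`.

    The file must carry a header with the columns
    ``group,temperature,replicate,species,n_germinated,n_dead,n_dormant,n_total``
    (any order).  ``dialect`` passes extra keyword arguments to
    :func:`pandas.read_csv` (e.g. ``{"sep": ";"}``).
    """
    # leading-zero strain ids ("09") must survive parsing as strings
    kwargs: dict = {"dtype": {"group": str, "temperature": str, "species": str}}
    kwargs.update(dict(dialect or {}))
    df = pd.read_csv(path, **kwargs)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PlateRecord(
                    group=str(row["group"]),
                    temperature=Temperature(str(row["temperature"])),
                    replicate=int(row["replicate"]),
                    species=Species(str(row["species"])),
                    n_germinated=int(row["n_germinated"]),
                    n_dead=int(row["n_dead"]),
                    n_dormant=int(row["n_dormant"]),
                    n_total=int(row["n_total"]),
                )
            )
        except (ValueError, SeedFateError) as exc:
            raise RecordValidationError(
                f"row {idx + 2} of {path}: {exc}"
            ) from exc
    meta = tuple(strain_metadata) if strain_metadata is not None else None
    return Dataset(records=tuple(records), strain_metadata=meta)


def write_plates(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as CSV with stable column order and row sort.

    ``read_plates(write_plates(d))`` round-trips to an equal dataset, and
    the bytes written do not depend on the input record order (records are
    sorted by group/temperature/replicate/species).
    """
    rows = [
        {
            "group": r.group,
            "temperature": r.temperature.value,
            "replicate": r.replicate,
            "species": r.species.value,
            "n_germinated": r.n_germinated,
            "n_dead": r.n_dead,
            "n_dormant": r.n_dormant,
            "n_total": r.n_total,
        }
        for r in dataset.records
    ]
    df = pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
    df.to_csv(path, index=False)


def load_strain_metadata() -> tuple[StrainInfo, ...]:
    """The packaged 18-strain metadata table (9 OTUs, 5 fungal orders)."""
    with resources.files("seedfate.data").joinpath("strain_metadata.csv").open() as fh:
        df = pd.read_csv(fh)
    return tuple(
        StrainInfo(
            strain_id=str(r.strain_id),
            seed_source=str(r.seed_source),
            genus_label=str(r.genus_label),
            order_label=str(r.order_label),
        )
        for r in df.itertuples()
    )
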