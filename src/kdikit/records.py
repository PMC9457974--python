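"""Core domain types: descriptor vectors, compound records and collections.

The six physicochemical descriptors used throughout the package are the
classic blood-brain-barrier-relevant set: molecular weight (MW, g/mol),
water-octanol partition coefficient (logP, dimensionless), hydrogen-bond
donor and acceptor counts (HD, HA), topological polar surface area
(PSA, Å²) and rotatable-bond count (RB).  HD and HA are stored as reals
because descriptor engines in the field emit fractional counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Canonical descriptor ordering used in every report and parameter set.
DESCRIPTOR_NAMES: tuple[str, ...] = ("MW", "logP", "HD", "HA", "PSA", "RB")


class KdikitError(Exception):
    """Base class for all package errors."""


class InputError(KdikitError):
    """Invalid user input (file, table, policy...)."""


class ParameterError(KdikitError):
    """Invalid model parameters (e.g. non-positive sigma)."""


class ConfigurationError(KdikitError):
    """Invalid configuration (e.g. malformed region set)."""


class StructureError(KdikitError):
    """A molecular structure could not be parsed or sanitized."""


@dataclass(frozen=True)
class DescriptorVector:
    """The six per-compound physicochemical descriptors.

    Invariants: MW > 0; HD, HA, PSA, RB >= 0; logP unrestricted in sign.
    All values must be finite.
    """

    MW: float
    logP: float
    HD: float
    HA: float
    PSA: float
    RB: float

    def __post_init__(self) -> None:
        for name in DESCRIPTOR_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise InputError(f"descriptor {name} must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))
        if self.MW <= 0:
            raise InputError(f"MW must be positive, got {self.MW}")
        for name in ("HD", "HA", "PSA", "RB"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative, got {getattr(self, name)}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "DescriptorVector":
        missing = [n for n in DESCRIPTOR_NAMES if n not in values]
        if missing:
            raise InputError(f"missing descriptor values: {', '.join(missing)}")
        return cls(**{n: float(values[n]) for n in DESCRIPTOR_NAMES})


@dataclass
class CompoundRecord:
    """One compound: identifier plus structure and/or descriptor values.

    At least one of ``smiles`` / ``descriptors`` must be present; ``logbb``
    is the optional experimental log10 brain/blood concentration ratio.
    """

    id: str
    smiles: str | None = None
    descriptors: DescriptorVector | None = None
    logbb: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("compound id must be non-empty")
        if self.smiles is None and self.descriptors is None:
            raise InputError(f"record {self.id!r} has neither structure nor descriptors")


@dataclass(frozen=True)
class ReadFailure:
    """A non-fatal per-record input failure, enumerated so it is never silent."""

    source: str
    reason: str


@dataclass
class CompoundCollection:
    """An ordered, id-unique collection of compound records.

    Duplicate ids are disambiguated on construction by suffixing ``_2``,
    ``_3``... (with a warning) so that collections merged from several
    files never abort.  Per-record read failures are carried alongside the
    surviving records.
    """

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""
    failures: list[ReadFailure] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        deduped: list[CompoundRecord] = []
        for rec in self.records:
            if rec.id in seen:
                seen[rec.id] += 1
                new_id = f"{rec.id}_{seen[rec.id]}"
                while new_id in seen:
                    seen[rec.id] += 1
                    new_id = f"{rec.id}_{seen[rec.id]}"
                logger.warning("duplicate id %r renamed to %r", rec.id, new_id)
                rec = replace(rec, id=new_id)
            seen[rec.id] = seen.get(rec.id, 1)
            deduped.append(rec)
        self.records = deduped

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def extend(self, records: Iterable[CompoundRecord]) -> None:
        merged = CompoundCollection(
            records=self.records + list(records),
            provenance=self.provenance,
            failures=self.failures,
        )
        self.records = merged.records
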