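"""Chemical-space classification against named descriptor-bounded regions.

Regions (lead-like, drug-like, Known Drug Space...) are axis-aligned boxes
in the six-descriptor space, ordered innermost to outermost.  Classification
reports, per descriptor and overall, the innermost region containing the
value, with membership inclusive of bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .records import DESCRIPTOR_NAMES, ConfigurationError, DescriptorVector

#: Label used when a value (or compound) falls outside every region.
OUTSIDE = "outside"


@dataclass(frozen=True)
class ChemSpaceRegion:
    """A named region: per-descriptor closed interval [lo, hi] (bounds may be infinite)."""

    name: str
    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [n for n in DESCRIPTOR_NAMES if n not in self.bounds]
        if missing:
            raise ConfigurationError(
                f"region {self.name!r} missing bounds for: {', '.join(missing)}"
            )
        clean: dict[str, tuple[float, float]] = {}
        for name in DESCRIPTOR_NAMES:
            lo, hi = (float(v) for v in self.bounds[name])
            if math.isnan(lo) or math.isnan(hi):
                raise ConfigurationError(f"region {self.name!r}: NaN bound for {name}")
            if lo > hi:
                raise ConfigurationError(
                    f"region {self.name!r}: lower bound {lo} exceeds upper bound {hi} for {name}"
                )
            clean[name] = (lo, hi)
        object.__setattr__(self, "bounds", clean)

    def contains_value(self, descriptor: str, value: float) -> bool:
        lo, hi = self.bounds[descriptor]
        return lo <= value <= hi

    def contains(self, desc: DescriptorVector) -> bool:
        return all(self.contains_value(n, getattr(desc, n)) for n in DESCRIPTOR_NAMES)


@dataclass(frozen=True)
class RegionSet:
    """An ordered (innermost to outermost) set of regions, optionally declared nested."""

    regions: Sequence[ChemSpaceRegion]
    nested: bool = True
    source: str = "inline"
    _validated: bool = field(default=False, compare=False)


@dataclass(frozen=True)
class Violation:
    """One descriptor falling outside a region's interval."""

    descriptor: str
    region: str
    value: float
    bound: tuple[float, float]


@dataclass(frozen=True)
class ClassificationResult:
    """Innermost region per descriptor and overall, with innermost-region violations."""

    per_descriptor: Mapping[str, str]
    overall: str
    violations: Sequence[Violation]
    region_source: str = "inline"


def validate_region_set(regions: RegionSet) -> RegionSet:
    """Check interval sanity and (if declared) nesting; return a validated copy.

    Nesting requires each region's interval to lie inside the next region's,
    for every descriptor.  Raises :class:`ConfigurationError` naming the
    first offending descriptor and region pair.
    """
    if not regions.regions:
        raise ConfigurationError("region set is empty")
    names = [r.name for r in regions.regions]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate region names: {names}")
    if regions.nested:
        for inner, outer in zip(regions.regions, regions.regions[1:]):
            for name in DESCRIPTOR_NAMES:
                ilo, ihi = inner.bounds[name]
                olo, ohi = outer.bounds[name]
                if ilo < olo or ihi > ohi:
                    raise ConfigurationError(
                        f"declared-nested regions do not nest on {name}: "
                        f"{inner.name!r} [{ilo}, {ihi}] is not inside "
                        f"{outer.name!r} [{olo}, {ohi}]"
                    )
    return RegionSet(
        regions=tuple(regions.regions),
        nested=regions.nested,
        source=regions.source,
        _validated=True,
    )


def load_regions(path: str | Path | None = None) -> RegionSet:
    """Load and validate a region set from YAML (shipped defaults when *path* is None)."""
    if path is None:
        text = resources.files("kdikit.data").joinpath("regions.yaml").read_text()
        source = "kdikit default regions (lead-like/drug-like/KDS, literature bounds)"
    else:
        text = Path(path).read_text()
        source = str(path)
    raw = yaml.safe_load(text)
    try:
        regions = [
            ChemSpaceRegion(
                name=entry["name"],
                bounds={k: tuple(v) for k, v in entry["bounds"].items()},
            )
            for entry in raw["regions"]
        ]
        nested = bool(raw.get("nested", True))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed region file {source}: {exc}") from exc
    return validate_region_set(RegionSet(regions=regions, nested=nested, source=source))


def classify(desc: DescriptorVector, regions: RegionSet) -> ClassificationResult:
    """Classify a descriptor vector against an ordered, validated region set.

    Per descriptor: the name of the innermost region whose interval contains
    the value, or ``"outside"``.  Overall: the innermost region containing
    all six descriptors, or ``"outside"``.  Violations list every descriptor
    that falls outside the innermost region, with the offending interval.
    """
    if not regions._validated:
        raise ConfigurationError("region set must pass validate_region_set before use")
    per_desc: dict[str, str] = {}
    for name in DESCRIPTOR_NAMES:
        value = getattr(desc, name)
        per_desc[name] = next(
            (r.name for r in regions.regions if r.contains_value(name, value)), OUTSIDE
        )
    overall = next((r.name for r in regions.regions if r.contains(desc)), OUTSIDE)
    innermost = regions.regions[0]
    violations = tuple(
        Violation(
            descriptor=name,
            region=innermost.name,
            value=getattr(desc, name),
            bound=innermost.bounds[name],
        )
        for name in DESCRIPTOR_NAMES
        if not innermost.contains_value(name, getattr(desc, name))
    )
    return ClassificationResult(
        per_descriptor=per_desc,
        overall=overall,
        violations=violations,
        region_source=regions.source,
    )
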