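"""Known Drug Index (KDI) scoring.

The KDI expresses drug-likeness as a product or sum of per-descriptor
Gaussian desirability functions fitted to the descriptor distributions of
drugs in clinical use (Eurtivong & Reynisson, Mol. Inform. 2019).  For a
descriptor value :math:`x` with known-drug mean :math:`\\mu` and standard
deviation :math:`\\sigma`, the index is

.. math:: I(x) = \\exp\\left(-\\frac{(x - \\mu)^2}{2\\sigma^2}\\right)

so :math:`I \\in (0, 1]` with the maximum at the known-drug mean.  The six
indexes are aggregated two ways: ``KDI_2a`` is their sum (theoretical
maximum 6) and ``KDI_2b`` their product (theoretical maximum 1).  KDI_2b
is the unforgiving variant: one poor descriptor drags the whole score down.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .records import (
    DESCRIPTOR_NAMES,
    CompoundCollection,
    DescriptorVector,
    InputError,
    ParameterError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaussianParamSet:
    """Per-descriptor (mean, sigma) pairs of the known-drug Gaussians.

    ``means`` and ``sigmas`` map each of the six descriptor names to the
    fitted known-drug mean and standard deviation, in descriptor units.
    All sigmas must be strictly positive.
    """

    means: Mapping[str, float]
    sigmas: Mapping[str, float]

    def __post_init__(self) -> None:
        for mapping, label in ((self.means, "mean"), (self.sigmas, "sigma")):
            missing = [n for n in DESCRIPTOR_NAMES if n not in mapping]
            if missing:
                raise ParameterError(f"missing {label} for: {', '.join(missing)}")
        for name in DESCRIPTOR_NAMES:
            if self.sigmas[name] <= 0:
                raise ParameterError(
                    f"sigma for {name} must be > 0, got {self.sigmas[name]}"
                )
        object.__setattr__(self, "means", dict(self.means))
        object.__setattr__(self, "sigmas", dict(self.sigmas))

    @classmethod
    def default(cls) -> "GaussianParamSet":
        """The shipped known-drug parameters (see ``data/kdi_params.yaml``)."""
        return load_params(None)

    def replace(self, **pairs: tuple[float, float]) -> "GaussianParamSet":
        """Return a copy with (mean, sigma) overridden for the named descriptors."""
        means = dict(self.means)
        sigmas = dict(self.sigmas)
        for name, (mu, sd) in pairs.items():
            if name not in DESCRIPTOR_NAMES:
                raise ParameterError(f"unknown descriptor {name!r}")
            means[name], sigmas[name] = float(mu), float(sd)
        return GaussianParamSet(means=means, sigmas=sigmas)


def load_params(path: str | Path | None = None) -> GaussianParamSet:
    """Load a Gaussian parameter set from YAML (shipped defaults when *path* is None)."""
    if path is None:
        text = resources.files("kdikit.data").joinpath("kdi_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        entries = raw["descriptors"]
        means = {name: float(entry["mean"]) for name, entry in entries.items()}
        sigmas = {name: float(entry["sigma"]) for name, entry in entries.items()}
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"malformed KDI parameter file: {exc}") from exc
    return GaussianParamSet(means=means, sigmas=sigmas)


@dataclass(frozen=True)
class KDIResult:
    """Six per-descriptor indexes plus their sum (KDI_2a) and product (KDI_2b)."""

    indexes: Mapping[str, float]
    kdi_2a: float
    kdi_2b: float


@dataclass(frozen=True)
class CollectionSummary:
    """Mean and sample standard deviation of KDI_2a / KDI_2b over a collection."""

    n: int
    mean_kdi_2a: float
    sd_kdi_2a: float
    mean_kdi_2b: float
    sd_kdi_2b: float


def gaussian_index(value: float, mean: float, sigma: float) -> float:
    """Gaussian desirability index exp(-(value-mean)^2 / (2 sigma^2)).

    Returns a value in (0, 1]; equals 1 iff ``value == mean``.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if not math.isfinite(value):
        raise InputError(f"descriptor value must be finite, got {value!r}")
    return math.exp(-((value - mean) ** 2) / (2.0 * sigma**2))


def score_kdi(desc: DescriptorVector, params: GaussianParamSet | None = None) -> KDIResult:
    """Score one descriptor vector: six Gaussian indexes, KDI_2a (sum), KDI_2b (product)."""
    if params is None:
        params = GaussianParamSet.default()
    indexes = {
        name: gaussian_index(getattr(desc, name), params.means[name], params.sigmas[name])
        for name in DESCRIPTOR_NAMES
    }
    return KDIResult(
        indexes=indexes,
        kdi_2a=float(sum(indexes.values())),
        kdi_2b=float(math.prod(indexes.values())),
    )


def score_collection(
    collection: CompoundCollection, params: GaussianParamSet | None = None
) -> dict[str, KDIResult]:
    """Score every record carrying descriptors; keyed by record id."""
    if params is None:
        params = GaussianParamSet.default()
    scores: dict[str, KDIResult] = {}
    for rec in collection:
        if rec.descriptors is None:
            raise InputError(f"record {rec.id!r} has no descriptors to score")
        scores[rec.id] = score_kdi(rec.descriptors, params)
    return scores


def summarize_collection(scores: Mapping[str, KDIResult]) -> CollectionSummary:
    """Arithmetic mean and sample sd (n-1 denominator) of KDI_2a and KDI_2b.

    For a single compound the sd is reported as 0 with a warning, since the
    n-1 estimator is undefined at n = 1.
    """
    if not scores:
        raise InputError("cannot summarize an empty collection")
    a = np.array([s.kdi_2a for s in scores.values()], dtype=float)
    b = np.array([s.kdi_2b for s in scores.values()], dtype=float)
    n = a.size
    if n == 1:
        logger.warning("collection of size 1: sample sd reported as 0")
        sd_a = sd_b = 0.0
    else:
        sd_a = float(a.std(ddof=1))
        sd_b = float(b.std(ddof=1))
    return CollectionSummary(
        n=int(n),
        mean_kdi_2a=float(a.mean()),
        sd_kdi_2a=sd_a,
        mean_kdi_2b=float(b.mean()),
        sd_kdi_2b=sd_b,
    )
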