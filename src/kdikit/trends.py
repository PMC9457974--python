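"""Descriptor-versus-logBB trend analysis over a compound collection.

For each descriptor, complete cases (records with both the descriptor and
an experimental logBB) are correlated with logBB: Pearson's r, Spearman's
rho, and the least-squares line logBB = slope * descriptor + intercept.
Direction calls use Pearson as the primary coefficient — linear trend
lines with scatter are what such analyses plot — with Spearman reported
alongside as the outlier-robust check.  A descriptor "facilitates"
permeability when r > +t and "impedes" it when r < -t (default t = 0.1);
no p-value gate is applied because the underlying analyses report
qualitative directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .records import DESCRIPTOR_NAMES, CompoundCollection, InputError

#: Direction labels.
FACILITATES = "facilitates"
IMPEDES = "impedes"
NONE = "none"
INSUFFICIENT = "insufficient data"
UNDEFINED = "undefined correlation"


@dataclass(frozen=True)
class DescriptorTrend:
    """Correlation/trend of one descriptor against logBB."""

    descriptor: str
    n_used: int
    pearson_r: float | None
    spearman_rho: float | None
    slope: float | None
    intercept: float | None
    direction: str


@dataclass(frozen=True)
class TrendReport:
    """Per-descriptor trends plus the threshold used for direction calls."""

    trends: Mapping[str, DescriptorTrend]
    threshold: float
    n_records: int


def correlate_logbb(collection: CompoundCollection, threshold: float = 0.1) -> TrendReport:
    """Correlate every descriptor with experimental logBB over complete cases.

    Requires at least 3 records carrying both descriptors and logBB.
    Descriptors with fewer than 3 complete cases are reported as
    "insufficient data"; zero-variance descriptors as "undefined
    correlation" — never as a direction.
    """
    if threshold < 0:
        raise InputError(f"direction threshold must be >= 0, got {threshold}")
    complete = [r for r in collection if r.descriptors is not None and r.logbb is not None]
    if len(complete) < 3:
        raise InputError(
            f"trend analysis needs at least 3 records with descriptors and logBB, got {len(complete)}"
        )
    logbb = np.array([r.logbb for r in complete], dtype=float)
    trends: dict[str, DescriptorTrend] = {}
    for name in DESCRIPTOR_NAMES:
        x = np.array([getattr(r.descriptors, name) for r in complete], dtype=float)
        n = x.size
        if n < 3:
            trends[name] = DescriptorTrend(name, n, None, None, None, None, INSUFFICIENT)
            continue
        if np.ptp(x) == 0.0:
            trends[name] = DescriptorTrend(name, n, None, None, None, None, UNDEFINED)
            continue
        r = float(stats.pearsonr(x, logbb).statistic)
        rho = float(stats.spearmanr(x, logbb).statistic)
        fit = stats.linregress(x, logbb)
        if r > threshold:
            direction = FACILITATES
        elif r < -threshold:
            direction = IMPEDES
        else:
            direction = NONE
        trends[name] = DescriptorTrend(
            descriptor=name,
            n_used=int(n),
            pearson_r=r,
            spearman_rho=rho,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            direction=direction,
        )
    return TrendReport(trends=trends, threshold=float(threshold), n_records=len(collection))


def trend_summary_text(report: TrendReport) -> str:
    """One deterministic sentence per descriptor naming direction and coefficient."""
    lines = []
    for name in DESCRIPTOR_NAMES:
        t = report.trends[name]
        if t.direction == INSUFFICIENT:
            lines.append(
                f"{name}: insufficient data for a trend (n = {t.n_used} complete cases)."
            )
        elif t.direction == UNDEFINED:
            lines.append(f"{name}: undefined correlation (zero variance over {t.n_used} cases).")
        elif t.direction == NONE:
            lines.append(
                f"{name}: no trend detected (Pearson r = {t.pearson_r:+.3f}, n = {t.n_used})."
            )
        else:
            verb = "facilitates" if t.direction == FACILITATES else "impedes"
            lines.append(
                f"Higher {name} {verb} barrier permeability "
                f"(Pearson r = {t.pearson_r:+.3f}, Spearman rho = {t.spearman_rho:+.3f}, "
                f"n = {t.n_used})."
            )
    return "\n".join(lines)


def report_to_dict(report: TrendReport) -> dict:
    """JSON-serializable form of a trend report."""
    return {
        "threshold": report.threshold,
        "n_records": report.n_records,
        "trends": {
            name: {
                "n_used": t.n_used,
                "pearson_r": t.pearson_r,
                "spearman_rho": t.spearman_rho,
                "slope": t.slope,
                "intercept": t.intercept,
                "direction": t.direction,
            }
            for name, t in report.trends.items()
        },
    }


def plot_trends(
    collection: CompoundCollection, report: TrendReport, outdir: str | Path, fmt: str = "png"
) -> list[Path]:
    """Scatter-plus-line plot per descriptor; one file per descriptor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    complete = [r for r in collection if r.descriptors is not None and r.logbb is not None]
    logbb = np.array([r.logbb for r in complete], dtype=float)
    written: list[Path] = []
    for name in DESCRIPTOR_NAMES:
        t = report.trends[name]
        if t.pearson_r is None:
            continue
        x = np.array([getattr(r.descriptors, name) for r in complete], dtype=float)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(x, logbb, s=8, alpha=0.6)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, t.slope * xs + t.intercept, color="crimson")
        ax.set_xlabel(name)
        ax.set_ylabel("logBB")
        ax.set_title(f"{name} vs logBB (r = {t.pearson_r:+.2f}, {t.direction})")
        fig.tight_layout()
        out = outdir / f"trend_{name}.{fmt}"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
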