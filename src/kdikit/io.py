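"""Readers and writers for compound collections and scored reports.

Supported inputs: SMILES list files (one structure per line, optional id,
``#`` comments), SDF (V2000/V3000), and CSV descriptor tables with
case-insensitive column aliases covering the spellings found in practice
("log p", "logP", "log_p"...).  Outputs: CSV reports mirroring the usual
descriptor-table column order (RB, MW, HD, HA, log p, PSA, then KDI and
classification columns) and JSON reports at full precision.

Per-record failures (bad SMILES, corrupt SDF blocks, non-numeric cells)
are collected on the returned collection and logged — never silently
dropped; only file-level problems raise.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from rdkit import Chem, RDLogger

from .chemspace import ClassificationResult
from .kdi import KDIResult
from .records import (
    DESCRIPTOR_NAMES,
    CompoundCollection,
    CompoundRecord,
    DescriptorVector,
    InputError,
    ReadFailure,
)

logger = logging.getLogger(__name__)

# Column aliases, all compared lowercase with spaces/underscores stripped.
_ALIASES: dict[str, str] = {
    "mw": "MW", "molecularweight": "MW",
    "logp": "logP", "clogp": "logP",
    "hd": "HD", "donors": "HD", "hbd": "HD",
    "ha": "HA", "acceptors": "HA", "hba": "HA",
    "psa": "PSA", "tpsa": "PSA",
    "rb": "RB", "rotatablebonds": "RB",
    "logbb": "logBB",
    "id": "id", "name": "id", "compound": "id", "compoundid": "id",
}

_REPORT_DESCRIPTOR_ORDER = ("RB", "MW", "HD", "HA", "logP", "PSA")


def _norm(column: str) -> str:
    return column.strip().lower().replace(" ", "").replace("_", "").replace("-", "")


def read_smiles_file(path: str | Path) -> CompoundCollection:
    """Read a SMILES list file: ``SMILES`` or ``SMILES<ws>ID`` per line.

    Blank lines and ``#`` comments are skipped; records with unparsable
    SMILES are collected as failures.  Missing ids are auto-generated as
    ``cmpd_0001``...
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[CompoundRecord] = []
    failures: list[ReadFailure] = []
    rdlog = RDLogger.logger()
    rdlog.setLevel(RDLogger.CRITICAL)
    try:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"cmpd_{lineno:04d}"
            if Chem.MolFromSmiles(smiles) is None:
                failures.append(
                    ReadFailure(source=f"{path.name}:{lineno}", reason=f"unparsable SMILES {smiles!r}")
                )
                continue
            records.append(CompoundRecord(id=cid, smiles=smiles))
    finally:
        rdlog.setLevel(RDLogger.ERROR)
    if not records and not failures:
        logger.warning("SMILES file %s contained no records", path)
    for f in failures:
        logger.warning("skipped %s: %s", f.source, f.reason)
    return CompoundCollection(records=records, provenance=str(path), failures=failures)


def read_descriptor_csv(path: str | Path) -> CompoundCollection:
    """Read a CSV descriptor table into a collection.

    Requires an id column and the six descriptor columns (case-insensitive
    aliases); an optional logBB column is attached when present.  HD and HA
    may be fractional.  Rows with non-numeric cells become failures.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse CSV {path}: {exc}") from exc
    colmap: dict[str, str] = {}
    for col in df.columns:
        canon = _ALIASES.get(_norm(col))
        if canon is not None and canon not in colmap.values():
            colmap[col] = canon
    present = set(colmap.values())
    missing = [n for n in ("id", *DESCRIPTOR_NAMES) if n not in present]
    if missing:
        raise InputError(f"descriptor CSV {path} is missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=colmap)
    has_logbb = "logBB" in df.columns

    records: list[CompoundRecord] = []
    failures: list[ReadFailure] = []
    for i, row in df.iterrows():
        source = f"{path.name}:row {i + 2}"  # +2: header + 1-based
        try:
            desc = DescriptorVector.from_mapping(
                {n: float(row[n]) for n in DESCRIPTOR_NAMES}
            )
            logbb = None
            if has_logbb and pd.notna(row["logBB"]):
                logbb = float(row["logBB"])
            records.append(CompoundRecord(id=str(row["id"]), descriptors=desc, logbb=logbb))
        except (ValueError, TypeError, InputError) as exc:
            failures.append(ReadFailure(source=source, reason=str(exc)))
    for f in failures:
        logger.warning("skipped %s: %s", f.source, f.reason)
    return CompoundCollection(records=records, provenance=str(path), failures=failures)


def read_sdf(path: str | Path, id_tag: str | None = None) -> CompoundCollection:
    """Read an SDF (V2000/V3000): one record per molecule block.

    Ids come from the title line, or from SD tag *id_tag* if given; blank
    titles get auto-generated ids.  Malformed blocks are skipped and
    recorded as failures.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    rdlog = RDLogger.logger()
    rdlog.setLevel(RDLogger.CRITICAL)
    records: list[CompoundRecord] = []
    failures: list[ReadFailure] = []
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                failures.append(
                    ReadFailure(source=f"{path.name}:block {i + 1}", reason="malformed molecule block")
                )
                continue
            cid = ""
            if id_tag and mol.HasProp(id_tag):
                cid = mol.GetProp(id_tag).strip()
            elif mol.HasProp("_Name"):
                cid = mol.GetProp("_Name").strip()
            if not cid:
                cid = f"cmpd_{i + 1:04d}"
            records.append(CompoundRecord(id=cid, smiles=Chem.MolToSmiles(mol)))
    finally:
        rdlog.setLevel(RDLogger.ERROR)
    for f in failures:
        logger.warning("skipped %s: %s", f.source, f.reason)
    return CompoundCollection(records=records, provenance=str(path), failures=failures)


def _report_rows(
    collection: CompoundCollection,
    scores: Mapping[str, KDIResult],
    classifications: Mapping[str, ClassificationResult] | None,
) -> list[dict]:
    rows = []
    for rec in collection:
        if rec.id not in scores:
            raise InputError(f"no KDI result supplied for record {rec.id!r}")
        if rec.descriptors is None:
            raise InputError(f"record {rec.id!r} has no descriptors to report")
        score = scores[rec.id]
        row: dict = {"id": rec.id}
        for name in _REPORT_DESCRIPTOR_ORDER:
            row[name] = getattr(rec.descriptors, name)
        row["KDI_2a"] = score.kdi_2a
        row["KDI_2b"] = score.kdi_2b
        if rec.logbb is not None:
            row["logBB"] = rec.logbb
        if classifications is not None:
            cls = classifications.get(rec.id)
            if cls is None:
                raise InputError(f"no classification supplied for record {rec.id!r}")
            row["overall_region"] = cls.overall
            for name in _REPORT_DESCRIPTOR_ORDER:
                row[f"region_{name}"] = cls.per_descriptor[name]
            row["violations"] = "; ".join(
                f"{v.descriptor}={v.value:g} outside {v.region} [{v.bound[0]:g}, {v.bound[1]:g}]"
                for v in cls.violations
            )
        rows.append(row)
    return rows


def write_report(
    collection: CompoundCollection,
    scores: Mapping[str, KDIResult],
    path: str | Path,
    classifications: Mapping[str, ClassificationResult] | None = None,
    format: str | None = None,
) -> None:
    """Write a per-compound report as CSV or JSON (inferred from suffix).

    CSV rounds KDI_2a/KDI_2b to 2 decimals — the precision such tables are
    printed at — while descriptors are written at full precision so the file
    round-trips through :func:`read_descriptor_csv`.  JSON keeps full
    precision everywhere, including the six per-descriptor indexes.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise InputError(f"unknown report format {fmt!r} (use csv or json)")
    rows = _report_rows(collection, scores, classifications)
    try:
        if fmt == "csv":
            columns = ["id", *_REPORT_DESCRIPTOR_ORDER, "KDI_2a", "KDI_2b"]
            if any("logBB" in r for r in rows):
                columns.append("logBB")
            if classifications is not None:
                columns += ["overall_region"] + [f"region_{n}" for n in _REPORT_DESCRIPTOR_ORDER] + ["violations"]
            df = pd.DataFrame(rows, columns=columns)
            if len(df):
                df["KDI_2a"] = df["KDI_2a"].round(2)
                df["KDI_2b"] = df["KDI_2b"].round(2)
            df.to_csv(path, index=False)
        else:
            for row, rec in zip(rows, collection):
                row["indexes"] = dict(scores[rec.id].indexes)
            path.write_text(json.dumps(rows, indent=2))
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc


def write_collection_csv(collection: CompoundCollection, path: str | Path) -> None:
    """Write a plain descriptor table (plus logBB when present) readable by
    :func:`read_descriptor_csv`."""
    rows = []
    for rec in collection:
        if rec.descriptors is None:
            raise InputError(f"record {rec.id!r} has no descriptors to write")
        row = {"id": rec.id, **{n: getattr(rec.descriptors, n) for n in _REPORT_DESCRIPTOR_ORDER}}
        if rec.logbb is not None:
            row["logBB"] = rec.logbb
        rows.append(row)
    columns = ["id", *_REPORT_DESCRIPTOR_ORDER]
    if any("logBB" in r for r in rows):
        columns.append("logBB")
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
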