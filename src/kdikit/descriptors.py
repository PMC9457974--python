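"""Compute the six descriptors from structure with open, standard algorithms.

MW is the average molecular weight; logP is the Crippen atom-contribution
estimate; HD/HA are Lipinski-style donor/acceptor counts; PSA is the
topological polar surface area (the only open, structure-only standard for
"polar surface area"); RB is the strict rotatable-bond count, which
excludes amide C-N bonds — the dominant convention, stated here so users
can compare against other engines.  Commercial engines use different logP
models and fractional donor/acceptor conventions, so table values and
computed values for the same compound legitimately differ; the resolution
policy below makes the choice explicit and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .records import CompoundRecord, DescriptorVector, InputError, StructureError

Policy = Literal["prefer_table", "prefer_computed", "computed_only"]


def mol_from_smiles(smiles: str, compound_id: str = "?") -> Chem.Mol:
    """Parse and sanitize a SMILES string, raising StructureError with the id."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"compound {compound_id!r}: unparsable SMILES {smiles!r}")
    return mol


def compute_descriptors(mol: Chem.Mol | str, compound_id: str = "?") -> DescriptorVector:
    """Compute all six descriptors for a sanitized molecule (or SMILES).

    Deterministic and independent of input atom ordering: the molecule is
    canonicalized before computation, so contribution sums are accumulated
    in a fixed order and equivalent SMILES writings give bit-identical
    vectors.
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol, compound_id)
    # re-parse the canonical SMILES to fix the atom order
    mol = mol_from_smiles(Chem.MolToSmiles(mol), compound_id)
    return DescriptorVector(
        MW=Descriptors.MolWt(mol),
        logP=Crippen.MolLogP(mol),
        HD=float(Lipinski.NumHDonors(mol)),
        HA=float(Lipinski.NumHAcceptors(mol)),
        PSA=Descriptors.TPSA(mol),
        RB=float(
            rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
            )
        ),
    )


@dataclass(frozen=True)
class ResolvedDescriptors:
    """A descriptor vector plus where it came from ('table' or 'computed')."""

    descriptors: DescriptorVector
    source: Literal["table", "computed"]


def resolve_descriptors(record: CompoundRecord, policy: Policy = "prefer_table") -> ResolvedDescriptors:
    """Select table vs computed descriptors for one record, per policy.

    ``prefer_table`` uses supplied table values, falling back to computing
    from structure; ``prefer_computed`` is the reverse; ``computed_only``
    requires a structure.  The source is recorded for the report.
    """
    if policy not in ("prefer_table", "prefer_computed", "computed_only"):
        raise InputError(f"unknown descriptor policy {policy!r}")

    def computed() -> ResolvedDescriptors:
        if record.smiles is None:
            raise InputError(
                f"record {record.id!r}: policy {policy!r} needs a structure, none supplied"
            )
        return ResolvedDescriptors(compute_descriptors(record.smiles, record.id), "computed")

    if policy == "computed_only":
        return computed()
    if policy == "prefer_table":
        if record.descriptors is not None:
            return ResolvedDescriptors(record.descriptors, "table")
        return computed()
    # prefer_computed
    if record.smiles is not None:
        return computed()
    if record.descriptors is None:
        raise InputError(f"record {record.id!r}: no structure and no table descriptors")
    return ResolvedDescriptors(record.descriptors, "table")
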