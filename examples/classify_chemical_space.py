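"""Classify compounds against lead-like / drug-like / Known Drug Space.

Computes descriptors from SMILES with the built-in engine, classifies each
compound against the shipped nested region bounds, and prints the overall
region plus any violations of the innermost (lead-like) box.
"""

from kdikit import CompoundRecord, classify, compute_descriptors, load_regions

COMPOUNDS = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "adamantane": "C1C2CC3CC1CC(C2)C3",
}


def main() -> None:
    regions = load_regions()
    for name, smiles in COMPOUNDS.items():
        desc = compute_descriptors(smiles, name)
        res = classify(desc, regions)
        viol = ", ".join(f"{v.descriptor}={v.value:g}" for v in res.violations) or "none"
        print(f"{name:<11} overall={res.overall:<16} lead-like violations: {viol}")
    print("\nThe overall label is the innermost region containing all six")
    print("descriptors; violations explain why a compound misses lead-like space.")


if __name__ == "__main__":
    main()
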