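"""Score a small descriptor table with the Known Drug Index.

Builds the three-compound table of two adamantane-myrtenal conjugates
(MAC-197, MAC-198) and their parent monoterpene myrtenal, scores each
compound with the default known-drug Gaussian parameters, and prints the
per-compound KDI_2a (sum of the six desirability indexes, max 6) and
KDI_2b (their product, max 1).  Higher values mean a descriptor profile
closer to that of drugs in clinical use.
"""

import io

from kdikit import read_descriptor_csv, score_collection

TABLE = """\
id,RB,MW,HD,HA,Log p,PSA
MAC-197,3,285.5,1,1.5,4.5,9.6
MAC-198,3,285.5,1,1,4.9,10.7
Myrtenal,1,150.2,0,2,1.8,36.6
"""


def main() -> None:
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "table.csv"
        path.write_text(TABLE)
        collection = read_descriptor_csv(path)
    scores = score_collection(collection)
    print(f"{'compound':<10} {'KDI_2a':>7} {'KDI_2b':>7}")
    for cid, score in scores.items():
        print(f"{cid:<10} {score.kdi_2a:>7.2f} {score.kdi_2b:>7.2f}")
    print("\nKDI_2a near 4 is typical of known drugs; KDI_2b is the stricter")
    print("product form, where any single poor descriptor collapses the score.")


if __name__ == "__main__":
    main()
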