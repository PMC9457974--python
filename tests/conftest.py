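"""Shared fixtures: the three printed descriptor rows and helpers.

The printed table fixture (two adamantane-carbonic-acid myrtenal
conjugates plus the parent monoterpene myrtenal) is the desk-scale ground
truth used across the I/O, scoring and classification tests.
"""

from __future__ import annotations

import textwrap

import pytest

from kdikit import DescriptorVector, GaussianParamSet

# id -> (RB, MW, HD, HA, logP, PSA, printed KDI_2a, printed KDI_2b)
TABLE1 = {
    "MAC-197": (3, 285.5, 1, 1.5, 4.5, 9.6, 4.05, 0.07),
    "MAC-198": (3, 285.5, 1, 1.0, 4.9, 10.7, 3.89, 0.04),
    "Myrtenal": (1, 150.2, 0, 2.0, 1.8, 36.6, 3.38, 0.01),
}

TABLE1_CSV = textwrap.dedent(
    """\
    id,RB,MW,HD,HA,Log p,PSA
    MAC-197,3,285.5,1,1.5,4.5,9.6
    MAC-198,3,285.5,1,1,4.9,10.7
    Myrtenal,1,150.2,0,2,1.8,36.6
    """
)


@pytest.fixture()
def table1_csv(tmp_path):
    path = tmp_path / "table1.csv"
    path.write_text(TABLE1_CSV)
    return path


@pytest.fixture()
def table1_vectors() -> dict[str, DescriptorVector]:
    return {
        cid: DescriptorVector(RB=rb, MW=mw, HD=hd, HA=ha, logP=logp, PSA=psa)
        for cid, (rb, mw, hd, ha, logp, psa, _, _) in TABLE1.items()
    }


@pytest.fixture(scope="session")
def default_params() -> GaussianParamSet:
    return GaussianParamSet.default()
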