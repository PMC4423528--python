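"""Shared fixtures: hand-built KGML documents and small sequences.

Everything is generated in memory; no test touches the network or any
binary data.
"""

from __future__ import annotations

import pytest

from essalign.ec import ECCode
from essalign.ess import ESS


def kgml_doc(body: str, number: str = "t001", title: str = "toy") -> str:
    return (
        f'<?xml version="1.0"?>\n'
        f'<pathway name="path:{number}" number="{number}" title="{title}">\n'
        f"{body}\n</pathway>\n"
    )


def enzyme_entry(eid: str, ec: str, reaction: str) -> str:
    return f'<entry id="{eid}" name="ec:{ec}" type="enzyme" reaction="rn:{reaction}"/>'


def reaction(name: str, substrates, products, reversible: bool = False) -> str:
    rtype = "reversible" if reversible else "irreversible"
    subs = "".join(f'<substrate name="cpd:{c}"/>' for c in substrates)
    prods = "".join(f'<product name="cpd:{c}"/>' for c in products)
    return f'<reaction name="rn:{name}" type="{rtype}">{subs}{prods}</reaction>'


@pytest.fixture
def chain_kgml() -> str:
    """E1(1.1.1) -> E2(2.7.1) -> E3(5.3.1), all irreversible."""
    body = "\n".join(
        [
            enzyme_entry("1", "1.1.1.1", "R1"),
            enzyme_entry("2", "2.7.1.1", "R2"),
            enzyme_entry("3", "5.3.1.9", "R3"),
            reaction("R1", ["C0"], ["C1"]),
            reaction("R2", ["C1"], ["C2"]),
            reaction("R3", ["C2"], ["C3"]),
        ]
    )
    return kgml_doc(body)


def make_ess(ess_id: str, codes: str, map_id: str = "m", root: str = "r") -> ESS:
    """``make_ess("a", "2.7.1 5.3.1")``"""
    steps = tuple(ECCode.parse(tok) for tok in codes.split())
    return ESS(ess_id=ess_id, map_id=map_id, root_id=root, steps=steps)


@pytest.fixture
def ess_factory():
    return make_ess
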