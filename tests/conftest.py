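"""Shared fixtures: small gene-set collections and temporary input files.

All fixtures are generated programmatically; the only stored data are the
package's own reference-table CSVs.
"""

from __future__ import annotations

import pytest

from cocultrx.genesets import GeneSet, GeneUniverse
from cocultrx.synthetic_data import reference_tables


@pytest.fixture(scope="session")
def fixtures():
    return reference_tables()


@pytest.fixture()
def small_universe() -> GeneUniverse:
    return GeneUniverse(frozenset(f"G{i:03d}" for i in range(100)))


@pytest.fixture()
def gmt_file(tmp_path):
    """A tiny valid GMT file with two sets."""
    path = tmp_path / "sets.gmt"
    path.write_text(
        "COLONOCYTE\tCOPE\tMUC2\tmuc2\tTFF3\n"
        "ENTEROCYTE\tCOPE\tCD36\tFABP1\tFABP2\n"
    )
    return path


def make_set(name: str, indices) -> GeneSet:
    return GeneSet(name=name, genes=frozenset(f"G{i:03d}" for i in indices))
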