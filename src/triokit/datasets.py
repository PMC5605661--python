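"""Loaders for the packaged reference fixtures.

The bundle covers the whole pipeline: the Trio-9 gene/domain model, the
case/control/inherited mutation list with its expected per-domain tally,
the ddG prediction table, and a synthetic two-chain toy structure for
interface-distance computations.

Published residue-level information in these fixtures is limited to the
DH1-region case events, the CNV deletion range, the PH1 control missense
position and the ddG table; other mutation positions are synthetic
placeholders consistent with the per-domain tallies (see the fixture
headers).  Domain boundaries are plausible reconstructions (DH1 fixed at
175 aa) and can be overridden by supplying a different annotation file.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .catalog import DomainTally, GeneModel, MutationRecord, read_gene_model, read_mutations, read_tally
from .ddg import DdgRecord, read_ddg_table

__all__ = [
    "fixture_path",
    "load_trio_gene_model",
    "load_trio_mutations",
    "load_expected_tally",
    "load_ddg_table",
    "toy_structure_path",
    "fixture_checksums",
]

_FIXTURES = {
    "gene_model": "trio_gene_model.tsv",
    "mutations": "trio_mutations.tsv",
    "tally": "trio_domain_tally.tsv",
    "ddg": "trio_ddg_table.tsv",
    "structure": "toy_complex.pdb",
}


def fixture_path(key: str) -> Path:
    """Filesystem path of a packaged fixture (keys: gene_model, mutations,
    tally, ddg, structure)."""
    if key not in _FIXTURES:
        raise KeyError(f"unknown fixture {key!r}; options: {sorted(_FIXTURES)}")
    return Path(resources.files("triokit.data") / _FIXTURES[key])


def load_trio_gene_model() -> GeneModel:
    return read_gene_model(fixture_path("gene_model"))


def load_trio_mutations() -> list[MutationRecord]:
    return read_mutations(fixture_path("mutations"))


def load_expected_tally() -> DomainTally:
    return read_tally(fixture_path("tally"))


def load_ddg_table() -> list[DdgRecord]:
    return read_ddg_table(fixture_path("ddg"))


def toy_structure_path() -> Path:
    return fixture_path("structure")


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of every packaged fixture, for run manifests."""
    return {
        key: hashlib.sha256(fixture_path(key).read_bytes()).hexdigest()
        for key in _FIXTURES
    }
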