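"""Shared fixtures: a scrubbed reference with a planted gene model, regions
with and without an HDR template, and a full on-disk experiment layout.

All alignment fixtures are generated at test time by the bundled simulator;
nothing binary is stored in the repository.
"""

import dataclasses
import json
from pathlib import Path

import pytest

from editprofile.config import GeneRegion, RunConfig
from editprofile.simulate import make_reference, write_reference_fasta
from editprofile.variants import Variant


@pytest.fixture(scope="session")
def std_ref() -> str:
    return make_reference(600, seed=1, cds=(201, 380))


def _std_region() -> GeneRegion:
    return GeneRegion(
        name="g1",
        chrom="frag",
        region_start=101,
        region_end=500,
        strand="+",
        cut_sites=(300,),
        window_start=130,
        window_end=470,
        cds_start=201,
        cds_end=380,
    )


@pytest.fixture()
def std_region(std_ref) -> GeneRegion:
    region = _std_region()
    region.validate(std_ref)
    return region


@pytest.fixture()
def hdr_region(std_ref) -> GeneRegion:
    """Same locus with a single-SNP knock-in template at position 350."""
    region = _std_region()
    ref_b = std_ref[349]
    alt = next(b for b in "ACGT" if b != ref_b)
    region.hdr_template = (Variant("SNP", 350, 350, ref_b, alt),)
    region.validate(std_ref)
    return region


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def experiment_root(tmp_path_factory, std_ref) -> Path:
    """files/index + files/config + files/input/<sample>/ skeleton with the
    reference FASTA and gene table written; BAMs are added per test."""
    root = tmp_path_factory.mktemp("experiment")
    (root / "files" / "index").mkdir(parents=True)
    (root / "files" / "config").mkdir(parents=True)
    (root / "files" / "input").mkdir(parents=True)
    write_reference_fasta(std_ref, "frag", root / "files" / "index" / "frag.fa")
    return root
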