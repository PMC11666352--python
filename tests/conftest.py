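from pathlib import Path

import pytest

from taqdesign.dataset import load_property_table, load_study_tables
from taqdesign.variants import ProteinSequence, taq_reference

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "taqdesign" / "data"


@pytest.fixture(scope="session")
def taq() -> ProteinSequence:
    return taq_reference()


@pytest.fixture(scope="session")
def toy_ref() -> ProteinSequence:
    # 40 residues, every canonical amino acid present
    return ProteinSequence("toy", "ACDEFGHIKLMNPQRSTVWY" * 2)


@pytest.fixture(scope="session")
def table1():
    return load_property_table(DATA_DIR / "table1.tsv")


@pytest.fixture(scope="session")
def table2():
    return load_property_table(DATA_DIR / "table2.tsv")


@pytest.fixture(scope="session")
def study_tables():
    return load_study_tables()


@pytest.fixture
def toy_round_config(tmp_path):
    """A complete toy design-round setup: reference FASTA, measured table
    TSV from a small synthetic landscape, and a config dict."""
    from taqdesign.dataset import write_property_table
    from taqdesign.synthetic import LandscapeConfig, generate_landscape
    from taqdesign.variants import write_fasta

    land = generate_landscape(
        LandscapeConfig(seed=3, reference_length=30, n_combinatorial_sites=3,
                        residues_per_site=4), n_variants=20)
    write_fasta([land.reference], tmp_path / "ref.fasta")
    write_property_table(land.measured, tmp_path / "table.tsv")
    sites = sorted({m.position for v in land.variants for m in v.mutations})[:3]
    config = {
        "reference_fasta": str(tmp_path / "ref.fasta"),
        "property_tables": [str(tmp_path / "table.tsv")],
        "output_dir": str(tmp_path / "run"),
        "seed": 7,
        "scan": {"sites": sites, "max_substitutions": 2, "limit": 150},
        "objective": "rt90",
        "top_n": 8,
    }
    return land, config
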