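"""Shared fixtures: tiny on-disk tables and trees built per test."""

import textwrap

import pytest


@pytest.fixture
def venom_csv(tmp_path):
    """Three-record venom table; totals 100, 104.2 and 115 percent."""
    path = tmp_path / "venom.csv"
    path.write_text(textwrap.dedent("""\
        species,record_id,source,method,toxin_family,percent_abundance
        Naja naja,r1,smith2020,proteome,3FTx,60
        Naja naja,r1,smith2020,proteome,PLA2,30
        Naja naja,r1,smith2020,proteome,SVMP,10
        Naja naja,r2,lee2021,transcriptome,3FTx,52.1
        Naja naja,r2,lee2021,transcriptome,PLA2,52.1
        Bitis arietans,r3,kim2019,proteome,SVMP,70
        Bitis arietans,r3,kim2019,proteome,PLA2,45
        """))
    return path


@pytest.fixture
def diet_csv(tmp_path):
    path = tmp_path / "diet.csv"
    path.write_text(textwrap.dedent("""\
        species,prey_family,prey_order,n_records
        Naja naja,Muridae,Rodentia,3
        Naja naja,Muridae,Rodentia,2
        Naja naja,Bufonidae,Anura,4
        Bitis arietans,Muridae,Rodentia,2
        Bitis arietans,Soricidae,Eulipotyphla,2
        """))
    return path


@pytest.fixture
def newick_file(tmp_path):
    path = tmp_path / "tree.nwk"
    path.write_text("((A:1,B:1):1,C:2);\n")
    return path
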