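import pytest

from sliprio.fixtures import (
    load_candidate_shortlist,
    load_multivariant_table,
    load_protein_annotations,
    load_stopgain_table,
)
from sliprio.models import Affection, Genotype, Individual, Pedigree, Sex


@pytest.fixture(scope="session")
def candidate_table():
    return load_candidate_shortlist()


@pytest.fixture(scope="session")
def stopgain_table():
    return load_stopgain_table()


@pytest.fixture(scope="session")
def multivariant_table():
    return load_multivariant_table()


@pytest.fixture(scope="session")
def protein_annotations():
    return load_protein_annotations()


def make_family(fid="F1", children_status=("affected", "affected"), genotypes=None):
    """Nuclear family with a proband and siblings; genotypes given as
    {(iid_suffix, key): Genotype}."""
    father = Individual(iid=f"{fid}_D", fid=fid, sex=Sex.male, role="parent")
    mother = Individual(iid=f"{fid}_M", fid=fid, sex=Sex.female, role="parent")
    members = [father, mother]
    for i, status in enumerate(children_status):
        iid = f"{fid}_P" if i == 0 else f"{fid}_S{i}"
        child = Individual(
            iid=iid,
            fid=fid,
            father=father.iid,
            mother=mother.iid,
            role="proband" if i == 0 else "sibling",
            affected=Affection(status),
        )
        members.append(child)
    fam = Pedigree(fid=fid, members=members)
    for (suffix, key), gt in (genotypes or {}).items():
        fam.genotypes[(f"{fid}_{suffix}", key)] = gt
    return fam


@pytest.fixture
def family_factory():
    return make_family
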