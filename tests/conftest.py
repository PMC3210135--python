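import pytest

from solviface import pipeline as pl
from solviface.fixtures import make_complex_corpus
from solviface.inference import read_correspondences
from solviface.structure_io import ChemistryDictionary, SaccharideCodeList

CORPUS_SEED = 7


@pytest.fixture(scope="session")
def chem():
    dictionary = ChemistryDictionary.default()
    dictionary.register_generic_polar(SaccharideCodeList.default().codes)
    return dictionary


@pytest.fixture(scope="session")
def sac_codes():
    return SaccharideCodeList.default()


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    make_complex_corpus(CORPUS_SEED, out)
    return out


@pytest.fixture(scope="session")
def corpus_scan(corpus_dir):
    defs, chem_, sac = pl.load_tables(corpus_dir / "domains.tsv")
    return pl.scan_files(
        sorted((corpus_dir / "pdb").glob("*.pdb")), defs, chem_, sac, pl.RunConfig()
    )


@pytest.fixture(scope="session")
def corpus_interfaces(corpus_scan):
    return [iface for result in corpus_scan for iface in result.interfaces]


@pytest.fixture(scope="session")
def corpus_alignments(corpus_dir, corpus_scan):
    orders = {}
    for result in corpus_scan:
        orders.update(result.domain_residue_order)
    return pl.load_alignments(corpus_dir / "alignments", orders, {})


@pytest.fixture(scope="session")
def corpus_hierarchy(corpus_interfaces, corpus_alignments):
    _, hierarchy, _ = pl.classify(corpus_interfaces, corpus_alignments, cutoff=0.0)
    return hierarchy


@pytest.fixture(scope="session")
def corpus_correspondences(corpus_dir):
    return read_correspondences((corpus_dir / "correspondences.tsv").read_text())
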