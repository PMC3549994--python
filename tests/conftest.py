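import numpy as np
import pytest

from profclust import (
    PlantedSpec,
    generate_profiles,
    generate_taxonomy,
    load_taxonomy_tsv,
    similarity_graph,
)

TOY_TAXONOMY_TSV = """tax_id\tparent_id\trank\tname
1\t1\tno rank\troot
2\t1\tsuperkingdom\tEukaryota
3\t2\tphylum\tChordata
4\t2\tphylum\tArthropoda
10\t3\tspecies\tHomo sapiens
11\t3\tspecies\tMus musculus
12\t4\tspecies\tDrosophila melanogaster
20\t10\tstrain\tH. sapiens strain 1
21\t10\tstrain\tH. sapiens strain 2
"""


@pytest.fixture(scope="session")
def toy_db():
    return load_taxonomy_tsv(TOY_TAXONOMY_TSV)


@pytest.fixture(scope="session")
def planted():
    """Default planted instance: (spec, db, universe, query_taxid, profiles, labels)."""
    spec = PlantedSpec(seed=0)
    db, universe, query_sp = generate_taxonomy(spec)
    ps, labels = generate_profiles(spec, universe)
    return spec, db, universe, query_sp, ps, labels


@pytest.fixture(scope="session")
def planted_graph(planted):
    _, _, _, _, ps, _ = planted
    return similarity_graph(ps)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
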