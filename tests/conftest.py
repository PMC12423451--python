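import pytest

import tfcoop as t

CLUSTER_SPEC = (
    ("chr1", 0, ("F1", "F1")),          # primary in window 0
    ("chr1", 1, ("F1", "F3")),          # shares F1 -> merges with window 0
    ("chr2", 2, ("F2", "F2", "F4")),    # isolated primary
)


@pytest.fixture(scope="session")
def genome_bundle():
    cfg = t.GenomeSimConfig(cluster_spec=CLUSTER_SPEC, seed=11)
    return t.gen_genome(cfg)


@pytest.fixture(scope="session")
def catalog_dir(tmp_path_factory, genome_bundle):
    d = tmp_path_factory.mktemp("genome")
    genome_bundle.write(d)
    return d


@pytest.fixture(scope="session")
def catalog(catalog_dir):
    return t.load_catalog(catalog_dir / "annotation.gff3",
                          catalog_dir / "genome.fa",
                          catalog_dir / "families.tsv")


@pytest.fixture(scope="session")
def motif_library():
    cfg = t.MotifSimConfig(
        n_motifs=6, planted_pairs=((0, 1, 3), (2, 3, 4), (4, 4, 3)),
        n_decoys=10, seed=5)
    return t.gen_motif_library(cfg)
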