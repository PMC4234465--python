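import pathlib

import pytest
import yaml

from ctkb.fixtures import FixtureConfig, generate_fixture
from ctkb.genes import load_gene_index
from ctkb.homology import load_homology_table
from ctkb.ingest import SourceConfig, load_xref_table, read_source
from ctkb.kb import build_kb


def read_corpus(directory: pathlib.Path):
    """Read every configured source of a generated fixture directory."""
    doc = yaml.safe_load((directory / "build_config.yaml").read_text())
    records, diagnostics = [], []
    for sc in doc["sources"]:
        cfg = SourceConfig(
            source_db=sc["source_db"],
            format=sc["format"],
            delimiter=sc.get("delimiter", "\t"),
            fields=sc.get("fields", {}),
        )
        recs, diags = read_source(directory / sc["path"], cfg)
        records.extend(recs)
        diagnostics.extend(diags)
    return records, diagnostics


def build_from_dir(directory: pathlib.Path, **kwargs):
    records, _ = read_corpus(directory)
    return build_kb(
        records,
        load_gene_index(directory / "gene_index.tsv"),
        load_xref_table(directory / "xrefs.tsv"),
        load_homology_table(directory / "homology.tsv"),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small generated corpus: directory, config and ground truth."""
    d = tmp_path_factory.mktemp("fixture_small")
    cfg = FixtureConfig(seed=1, n_true_compounds=20, n_genes=20)
    truth = generate_fixture(cfg, d)
    return d, cfg, truth


@pytest.fixture(scope="session")
def small_kb(small_fixture):
    d, _, _ = small_fixture
    return build_from_dir(d)


@pytest.fixture(scope="session")
def query_fixture(tmp_path_factory):
    """A corpus sized to give a couple hundred relations for query tests."""
    d = tmp_path_factory.mktemp("fixture_query")
    cfg = FixtureConfig(seed=7, n_true_compounds=80, n_genes=50, n_homology_groups=8)
    truth = generate_fixture(cfg, d)
    kb = build_from_dir(d)
    return kb, truth
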