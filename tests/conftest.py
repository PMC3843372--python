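import pytest

from tagcplot import fixtures
from tagcplot.formats_io import TagcRow, TagcTable


@pytest.fixture(scope="session")
def standard_bundle():
    """The standard three-genome fixture, built once per session."""
    return fixtures.make_standard_fixture(seed=42)


@pytest.fixture(scope="session")
def bundle_dir(standard_bundle, tmp_path_factory):
    """The standard bundle written to disk; returns the path map."""
    outdir = tmp_path_factory.mktemp("bundle")
    return standard_bundle.write(outdir)


@pytest.fixture(scope="session")
def mini_tree():
    return fixtures.mini_taxdump()


def make_table(rows, libraries=("lib1", "total"), ranks=("order",)):
    """Small TagcTable from (seqid, length, gc, covs, taxa) tuples."""
    table = TagcTable(library_labels=list(libraries), rank_labels=list(ranks))
    for seqid, length, gc, covs, taxa in rows:
        table.rows.append(
            TagcRow(
                seqid=seqid,
                length=length,
                gc=gc,
                coverages=dict(zip(libraries, covs)),
                taxa=dict(zip(ranks, taxa)),
            )
        )
    table.validate()
    return table


@pytest.fixture
def toy_table():
    return make_table(
        [
            ("c1", 1000, 0.40, (100.0, 100.0), ("Rhabditida",)),
            ("c2", 800, 0.42, (90.0, 90.0), ("Rhabditida",)),
            ("c3", 500, 0.62, (10.0, 10.0), ("Pseudomonadales",)),
            ("c4", 600, 0.66, (200.0, 200.0), ("Actinomycetales",)),
            ("c5", 400, 0.41, (0.0, 0.0), ("not_annotated",)),
        ]
    )
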