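import numpy as np
import pytest

import digitalmicrobe as dm
from digitalmicrobe import synthetic


@pytest.fixture()
def spec():
    return synthetic.FixtureSpec(seed=1)


@pytest.fixture()
def sim_genome(spec):
    return synthetic.simulate_genome(spec)


@pytest.fixture()
def toy_pkg(tmp_path, spec, sim_genome):
    """A genome package populated from the simulated fixture set."""
    paths = sim_genome.write(tmp_path / "fixture")
    pkg = dm.create_package("toy", "genome")
    dm.add_genome(pkg, paths["fasta"])
    dm.import_gene_calls(pkg, paths["gene_calls"], format="external_tsv")
    dm.import_functional_annotations(pkg, paths["annotations_custom"], "custom")
    dm.import_functional_annotations(pkg, paths["annotations_CAZyme"], "CAZyme")
    return pkg


@pytest.fixture()
def toy_pkg_with_coverage(toy_pkg, spec, sim_genome):
    lengths = (sim_genome.gene_calls["stop"] - sim_genome.gene_calls["start"]).to_numpy(float)
    samples = synthetic.simulate_coverage_samples(spec, np.ones(len(lengths)), lengths)
    for sid, table in samples.items():
        dm.add_coverage_layer(toy_pkg, sid, table, total_mapped_reads=spec.library_size)
    return toy_pkg
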