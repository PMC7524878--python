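import numpy as np
import pytest
from hypothesis import settings

import mintscreen as ms

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    return ms.paper_scenario(rng_seed=0)


@pytest.fixture(scope="session")
def panel(scenario):
    return ms.generate_accession_panel(scenario)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, scenario):
    d = tmp_path_factory.mktemp("study")
    ms.generate_study(scenario, d)
    return d


@pytest.fixture(scope="session")
def alignment(scenario, panel):
    tree = ms.species_tree(scenario)
    seqs = ms.generate_marker_sequences(panel, tree, 600, 1.0, rng_seed=0)
    return ms.Alignment(seqs)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary unrooted tree with positive branch lengths, plus its
    additive path-length distance matrix."""
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = [ms.barcoding.TreeNode(l, float(rng.uniform(0.5, 3.0))) for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 3:
        a = nodes.pop()
        b = nodes.pop()
        joined = ms.barcoding.TreeNode("", float(rng.uniform(0.5, 3.0)), None, [a, b])
        nodes.append(joined)
        rng.shuffle(nodes)
    tree = ms.PhyloTree(ms.barcoding.TreeNode("", 0.0, None, nodes), rooted=False)
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = tree.path_length(labels[i], labels[j])
    return tree, ms.DistanceMatrix(labels, d)
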