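"""Shared fixtures: small trees and simulated alignments (all generated)."""

import numpy as np
import pytest

from batvision.codonseq import CodonAlignment
from batvision.evomodels import CodonModel
from batvision.simulate import make_study_like_fixture, simulate_alignment
from batvision.trees import read_newick


def balanced_tree(n_leaves, seed=0, lo=0.02, hi=0.25):
    """Balanced binary tree with seeded branch lengths."""
    names = [f"t{i}" for i in range(n_leaves)]

    def nest(ns):
        if len(ns) == 1:
            return ns[0]
        h = len(ns) // 2
        return f"({nest(ns[:h])},{nest(ns[h:])})"

    tree = read_newick(nest(names) + ";")
    rng = np.random.default_rng(seed)
    tree.length = rng.uniform(lo, hi, tree.n_nodes)
    tree.length[tree.root] = np.nan
    return tree


@pytest.fixture(scope="session")
def quartet_tree():
    return read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.08);")


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_like_fixture(11)


@pytest.fixture(scope="session")
def small_codon_sim():
    """8 taxa x 150 codons under strong purifying selection."""
    tree = balanced_tree(8, seed=3)
    rec = simulate_alignment(tree, CodonModel(2.0, 0.1), 150, seed=21)
    return tree, rec


@pytest.fixture(scope="session")
def tiny_alignment():
    return CodonAlignment(["a", "b"], ["ATGGCT", "ATGGCC"])
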