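"""Shared fixtures: a passerine-flavoured species tree and synthetic SINEs.

All data are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import pytest

from retromark import simulate as sim
from retromark import trees

# 8 leaves mirroring the deep passerine sampling: songbirds (Taeniopygia,
# Corvus, Menura, Climacteris), suboscines (Pitta, Sayornis), the New Zealand
# wren Acanthisitta, and the chicken outgroup.
PASSERINE_NEWICK = (
    "(((((Taeniopygia,Corvus),(Menura,Climacteris)),(Pitta,Sayornis)),"
    "Acanthisitta),Gallus);"
)

#: branch ids (sorted comma-joined clades) used across tests
OSCINE_PAIR = "Corvus,Taeniopygia"
OSCINES = "Climacteris,Corvus,Menura,Taeniopygia"
EUPASSERES = "Climacteris,Corvus,Menura,Pitta,Sayornis,Taeniopygia"
PASSERINES = "Acanthisitta,Climacteris,Corvus,Menura,Pitta,Sayornis,Taeniopygia"
SUBOSCINES = "Pitta,Sayornis"


def make_tree(edge_length: float = 0.015):
    tree = trees.tree_from_newick(PASSERINE_NEWICK)
    for edge in tree.preorder_edge_iter():
        edge.length = edge_length
    return tree


@pytest.fixture
def passerine_tree():
    return make_tree()


@pytest.fixture(scope="session")
def template():
    return sim.make_sine_template(sim.SYNTH_TRNA_ILE, sim.SYNTH_CR1_TAIL,
                                  name="TguSINE1_synth")


@pytest.fixture(scope="session")
def library(template):
    lib = sim.synthetic_library()
    lib[template.name] = template.sequence
    return lib


def quick_config(n_loci_per_branch, seed, **kwargs):
    defaults = dict(ils_probability=0.0, flank_length=150)
    defaults.update(kwargs)
    return sim.SimConfig(n_loci_per_branch=n_loci_per_branch, seed=seed,
                         **defaults)
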