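"""Shared fixtures: small hand-built trees and session-cached simulations."""
from __future__ import annotations

import numpy as np
import pytest

from discotree import synthetic_data as syn
from discotree import treeio

# 3-taxon species tree with internal branch T = 1 coalescent unit
TRIPLE_T1 = "((A:1,B:1):1,C:2);"
# 4-taxon rooted caterpillar with a distant outgroup (internal branch T = 1)
QUARTET_T1 = "(((A:1,B:1):1,C:2):8,O:10);"

# 12-ingroup-sample network with two planted hybrids receiving from
# *ancestral* branches of foreign clades (gamma = 0.3 each):
# a4 <- clade-b ancestor, c3 <- clade-a ancestor.
TWO_HYBRIDS_NET = (
    "(O:6,(("
    "((((a1:0.3,a2:0.3):0.2,a3:0.5):0.3,(a4:0.2)#H1:0.6::0.7):0.4,#H2:1.0::0.3):1.3,"
    "(((b1:0.3,b2:0.3):0.2,(b3:0.3,b4:0.3):0.2):0.7,#H1:1.0::0.3):1.3"
    "):0.5,"
    "((c1:0.3,c2:0.3):0.5,(c3:0.2)#H2:0.6::0.7):2.2"
    "):3.0);"
)
TWO_HYBRIDS_SPECIES_TREE = (
    "(((((a1,a2),a3),a4),((b1,b2),(b3,b4))),((c1,c2),c3));"
)

# cascade: two sister hybrids h1 (gamma 0.4) and h2 (gamma 0.2) receiving
# from the same ancestral donor branch of clade y. As long as both are
# present, each is the other's only sister, so the min-over-sisters f4-ratio
# of the weaker hybrid is negative (masked); removing h1 exposes h2. The
# long shared stem keeps (h1,h2) a cherry in the re-estimated species tree.
CASCADE_NET = (
    "(O:5,(("
    "(x1:0.7,x2:0.7):0.7,"
    "((h1:0.1)#H1:0.1::0.6,(h2:0.1)#H2:0.1::0.8):1.2):0.6,"
    "((y1:0.5,y2:0.5):0.2,#H1:0.6::0.4,#H2:0.6::0.2):1.3"
    "):3.0);"
)

# no-gene-flow version of the 12-sample setup (same topology, no hybrids)
NO_FLOW_NET = (
    "(O:6,(("
    "((a1:0.3,a2:0.3):0.2,(a3:0.3,a4:0.3):0.2):2.0,"
    "((b1:0.3,b2:0.3):0.2,(b3:0.3,b4:0.3):0.2):2.0"
    "):0.5,"
    "((c1:0.3,c2:0.3):0.2,c3:0.5):2.5"
    "):3.0);"
)


def two_hybrid_taxon_map() -> treeio.TaxonMap:
    clade = {}
    for s in ("a1", "a2", "a3", "a4"):
        clade[s] = "cladeA"
    for s in ("b1", "b2", "b3", "b4"):
        clade[s] = "cladeB"
    for s in ("c1", "c2", "c3"):
        clade[s] = "cladeC"
    clade["O"] = "outgroup"
    return treeio.TaxonMap(
        species={s: s for s in clade},
        clade=clade,
        outgroup={"O"},
    )


def cascade_taxon_map() -> treeio.TaxonMap:
    clade = {s: "cladeX" for s in ("x1", "x2", "h1", "h2")}
    clade.update({s: "cladeY" for s in ("y1", "y2")})
    clade["O"] = "outgroup"
    return treeio.TaxonMap(
        species={s: s for s in clade}, clade=clade, outgroup={"O"}
    )


@pytest.fixture(scope="session")
def triple_trees_t1():
    return syn.simulate_gene_trees(TRIPLE_T1, n=4000, seed=11)


@pytest.fixture(scope="session")
def quartet_trees_t1():
    return syn.simulate_gene_trees(QUARTET_T1, n=4000, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
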