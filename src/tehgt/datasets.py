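"""Built-in study inputs: the vertebrate host phylogeny and the
genomic-PCR presence/absence survey of the recent (Group 1) Tc1
family.

The tree covers the jawless fishes (hagfishes; northern- and
southern-hemisphere lampreys), cartilaginous fishes, non-teleost ray-
finned fishes (sturgeon, gar), a teleost sample mixing carrier species
(salmonids, pike, catfishes, perch) with genome-sequenced non-carriers
(zebrafish, medaka, stickleback), and sarcopterygians.  The family was
amplified only from northern-hemisphere lampreys and a scattered
subset of teleosts; under a single vertical origin at the vertebrate
root this pattern forces independent losses in every absent lineage.
"""

from __future__ import annotations

from .hgt import PresenceAbsence
from .tree import PhyloTree

VERTEBRATE_TREE_NEWICK = (
    "((hagfish_Atlantic:1,hagfish_inshore:1)hagfishes:1,"
    "((lamprey_sea:1,lamprey_Japanese:1)lampreys_north:1,"
    "(lamprey_pouched:1,lamprey_shortheaded:1)lampreys_south:1)lampreys:1,"
    "((shark:1,ray:1)chondrichthyes:1,"
    "((sturgeon:1,(gar:1,"
    "((salmon_Atlantic:1,(pike_northern:1,(catfish_channel:1,"
    "(perch_European:1,zebrafish:1):1):1):1):1,"
    "(medaka:1,stickleback:1):1)Teleostei:1):1):1,"
    "(frog:1,(chicken:1,mouse:1):1)sarcopterygians:1):1)gnathostomes:1);"
)

PCR_SURVEY = {
    "hagfish_Atlantic": "absent",
    "hagfish_inshore": "absent",
    "lamprey_sea": "present",
    "lamprey_Japanese": "present",
    "lamprey_pouched": "absent",
    "lamprey_shortheaded": "absent",
    "shark": "absent",
    "ray": "absent",
    "sturgeon": "absent",
    "gar": "absent",
    "salmon_Atlantic": "present",
    "pike_northern": "present",
    "catfish_channel": "present",
    "perch_European": "present",
    "zebrafish": "absent",
    "medaka": "absent",
    "stickleback": "absent",
    "frog": "absent",
    "chicken": "absent",
    "mouse": "absent",
}


def vertebrate_host_tree() -> PhyloTree:
    return PhyloTree.from_newick(VERTEBRATE_TREE_NEWICK)


def pcr_presence_pattern() -> PresenceAbsence:
    return PresenceAbsence(dict(PCR_SURVEY))


def teleost_leaves() -> frozenset[str]:
    tree = vertebrate_host_tree()
    for node in tree.root.preorder():
        if node.label == "Teleostei":
            return node.leaf_names()
    raise RuntimeError("Teleostei clade missing")
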