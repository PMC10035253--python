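"""Independent brute-force oracles shared by the test modules.

The embedding counter here is deliberately search-based (it tries every
child of a node for every motif child) rather than position-indexed like
the library implementation, so the two can disagree if either is wrong.
"""

from glycosmiles.glycan_ast import Anomer


def _link_ok(mlink, link):
    if (mlink.child_position, mlink.parent_position) != \
            (link.child_position, link.parent_position):
        return False
    return mlink.child_anomer is Anomer.UNSPECIFIED or \
        mlink.child_anomer == link.child_anomer


def _mods_ok(motif, node):
    return sorted((m.token, m.position) for m in motif.modifications) == \
        sorted((m.token, m.position) for m in node.modifications)


def embeds(motif, node):
    if motif.base_name != node.base_name or not _mods_ok(motif, node):
        return False
    for mlink, mchild in motif.children:
        if not any(_link_ok(mlink, link) and embeds(mchild, child)
                   for link, child in node.children):
            return False
    return True


def brute_force_count(tree, motif):
    return sum(embeds(motif, node) for node in tree.walk())
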