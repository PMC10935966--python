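"""Bundled word list for randomly named parameters.

Parameters flagged ``R`` in an ``inputconfig.txt`` draw a value from this
list with a seeded generator, so runs are reproducible.  The list is part
of the public interface: changing it changes captured parameter vectors.
All words are lowercase ASCII (valid image-name material).
"""

WORDS: tuple[str, ...] = (
    "acacia", "alder", "almond", "amber", "anchovy", "aspen", "badger", "bamboo",
    "barley", "basil", "beech", "birch", "bison", "bramble", "briar", "cedar",
    "cherry", "chervil", "chicory", "clover", "cobalt", "condor", "coral", "crane",
    "cress", "cricket", "cumin", "cypress", "dahlia", "damson", "dingo", "dune",
    "ebony", "egret", "elder", "falcon", "fennel", "fern", "finch", "flax",
    "gannet", "garnet", "gecko", "ginger", "grouse", "hazel", "heron", "hickory",
    "ibis", "indigo", "jasmine", "juniper", "kestrel", "kelp", "larch", "laurel",
    "lichen", "linden", "lotus", "lupin", "magpie", "mallow", "maple", "marten",
    "medlar", "mimosa", "minnow", "mulberry", "myrtle", "nettle", "nutmeg", "ocelot",
    "olive", "orchid", "osprey", "otter", "pelican", "pepper", "petrel", "pimpernel",
    "plover", "poplar", "quince", "raven", "reed", "rowan", "saffron", "sage",
    "sorrel", "sparrow", "spruce", "sycamore", "tamarind", "teal", "thistle", "thyme",
    "vetch", "walnut", "willow", "yarrow",
)

assert len(WORDS) == 100
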