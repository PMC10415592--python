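import itertools

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


FOUR_TAXON_NEWICK = "((A:1,B:1):2,(C:2,D:2):1);"


@pytest.fixture
def four_taxon_chronogram():
    from hgtclock.trees import Chronogram

    return Chronogram.from_newick(FOUR_TAXON_NEWICK)


def iter_labeled_trees(labels):
    """All rooted binary labelled tree topologies (Newick, no lengths).

    The first label is anchored to the left subtree to avoid the
    left/right double count of the same rooted topology.
    """
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in iter_labeled_trees(left):
                for rt in iter_labeled_trees(right):
                    yield f"({lt},{rt})"


def labeled_trees(n):
    return [t + ";" for t in iter_labeled_trees("ABCDEF"[:n])]
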