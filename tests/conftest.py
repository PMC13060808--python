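import pytest

from rescue_rank.fixtures import FixtureSpec, make_bundle
from rescue_rank.taxonomy import load_taxonomy


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One shared synthetic input bundle with its ground-truth manifest."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = make_bundle(FixtureSpec(seed=11), out)
    return out, manifest


@pytest.fixture()
def small_tree():
    """Two domains, one genus each, two species leaves per genus.

    ids: 1 root; 2,3 domains; 4,5 genera; 6,7 species under 4; 8,9 under 5.
    """
    rows = "\n".join(
        [
            "1\t1\tno_rank\troot",
            "2\t1\tdomain\tBacteria",
            "3\t1\tdomain\tArchaea",
            "4\t2\tgenus\tGenusA",
            "5\t3\tgenus\tGenusB",
            "6\t4\tspecies\tA1",
            "7\t4\tspecies\tA2",
            "8\t5\tspecies\tB1",
            "9\t5\tspecies\tB2",
        ]
    )
    return load_taxonomy(rows + "\n")


def normalized(text: str) -> str:
    return " ".join(text.split())


def is_grounded(value: str, source: str) -> bool:
    """Whitespace-normalized verbatim containment."""
    return normalized(value) in normalized(source)
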