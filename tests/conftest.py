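import pytest

from fawhap.iupac import union_code
from fawhap.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def het_merge():
    """Site-wise IUPAC consensus of two same-length allele sequences."""

    def merge(a: str, b: str) -> str:
        return "".join(
            x if x == y else union_code(x, y) for x, y in zip(a, b)
        )

    return merge
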