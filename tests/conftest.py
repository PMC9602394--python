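import numpy as np
import pytest

from nestner.corpus import NestedEntity

# the annotated fragment "IL - 2R alpha mRNA that is": a protein mention
# over the first four tokens nested inside an RNA mention over the first five
FRAGMENT_TOKENS = ["IL", "-", "2R", "alpha", "mRNA", "that", "is"]
FRAGMENT_TAGS = [
    ["B-protein", "B-RNA", "O", "O"],
    ["I-protein", "I-RNA", "O", "O"],
    ["I-protein", "I-RNA", "O", "O"],
    ["I-protein", "I-RNA", "O", "O"],
    ["O", "I-RNA", "O", "O"],
    ["O", "O", "O", "O"],
    ["O", "O", "O", "O"],
]
FRAGMENT_ENTITIES = {
    NestedEntity(0, 4, "protein", depth=1),
    NestedEntity(0, 5, "RNA", depth=2),
}


@pytest.fixture
def fragment_file(tmp_path):
    path = tmp_path / "fragment.bio"
    lines = ["\t".join([tok, *tags]) for tok, tags in zip(FRAGMENT_TOKENS, FRAGMENT_TAGS)]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
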