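import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _factories import make_hit  # noqa: E402,F401  (re-exported for tests)

from deduf.search_io import FamilyRecord  # noqa: E402


@pytest.fixture
def family_index() -> dict[str, FamilyRecord]:
    return {
        "DUF0001": FamilyRecord("DUF0001", 150, [511145]),
        "DUF0002": FamilyRecord("DUF0002", 222, [9606]),
    }


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One shared synthetic bundle with every structural feature present."""
    from deduf.fixtures import FixtureSpec, generate

    outdir = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(
        seed=11,
        tier_histogram={5: 2, 4: 2, 3: 2, 2: 3, 1: 4},
        n_outvoted=2,
        per_method_assigned={"nrichd": 4, "supfam_plus": 3},
        per_method_conflicting={"nrichd": 2, "supfam_plus": 1},
        link_spec=(12, 3),
        kingdom_mix={"Bacteria": 10, "Bacteria+Eukaryota": 5, "Archaea+Viruses": 5},
    )
    return generate(spec, outdir)
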