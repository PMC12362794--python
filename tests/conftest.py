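import numpy as np
import pytest

from puftyper import ReferenceLocus

# 60 bp toy amplicon: 10 bp fixed flanks around a 40 bp central region with
# the blunt cut between positions 29|30 (central index 19|20, context AC|GT).
TOY_LEFT = "ACGTACGTAC"
TOY_CENTRAL = "GATTACAGATTACAGATT" + "ACGT" + "CCATGGCCATGGCCATGG"
TOY_RIGHT = "TCAGTCAGTC"
TOY_CUT_INDEX = 20  # cut position within the central region

assert len(TOY_CENTRAL) == 40


@pytest.fixture
def toy_locus() -> ReferenceLocus:
    return ReferenceLocus(
        name="toy", sequence=TOY_LEFT + TOY_CENTRAL + TOY_RIGHT, cut_pos=30
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def enumerate_single_indel_placements(ref: str, obs: str):
    """Brute-force oracle: every placement of one contiguous indel turning
    ``ref`` into ``obs``, as (kind, position, bases) tuples in left-to-right
    order."""
    d = len(obs) - len(ref)
    placements = []
    if d > 0:
        for p in range(len(ref) + 1):
            if obs[:p] == ref[:p] and obs[p + d :] == ref[p:]:
                placements.append(("I", p, obs[p : p + d]))
    elif d < 0:
        for p in range(len(obs) + 1):
            if obs[:p] == ref[:p] and obs[p:] == ref[p - d :]:
                placements.append(("D", p, ref[p : p - d]))
    return placements
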