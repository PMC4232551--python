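import numpy as np
import pytest

from cuparray import build_single_locus, load_strain_table, packaged_table1


@pytest.fixture(scope="session")
def single_locus():
    """One deterministic single-copy locus shared across tests."""
    locus, truth = build_single_locus(seed=11)
    return locus, truth


@pytest.fixture(scope="session")
def table1_records():
    return load_strain_table(packaged_table1())


# --- independent brute-force junction oracle -------------------------------
# Exhaustive scan over every (reference start, extension length) pair with a
# declarative window-validity rule, used to cross-check the package's greedy
# seed-and-extend junction mapper.

SEED_LEN = 12
FLANK = 5


def _max_valid_extension(mask: np.ndarray) -> int:
    """Longest window prefix of a match mask that satisfies the mismatch rules.

    Valid windows start with SEED_LEN exact matches, end on a match, and
    every mismatch inside is isolated with FLANK exact matches on each side.
    """
    m = len(mask)
    if m < SEED_LEN or not mask[:SEED_LEN].all():
        return 0
    bad = m
    for i in np.nonzero(~mask)[0]:
        ok = (
            i >= FLANK
            and mask[i - FLANK : i].all()
            and i + FLANK < m
            and mask[i + 1 : i + 1 + FLANK].all()
        )
        if not ok:
            bad = int(i)
            break
    # every tolerated mismatch is followed by FLANK matches, so position
    # bad-1 is always a match and the maximal valid window ends there
    return bad


def oracle_best_prefix(query: str, ref: str) -> int:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = 0
    for s in range(len(r) - SEED_LEN + 1):
        n = min(len(q), len(r) - s)
        mask = q[:n] == r[s : s + n]
        best = max(best, _max_valid_extension(mask))
    return best


def oracle_map_junction(junction: str, distal_ref: str, proximal_ref: str):
    """(microhomology_len, inserted_seq) by exhaustive search."""
    p = oracle_best_prefix(junction, distal_ref)
    s = oracle_best_prefix(junction[::-1], proximal_ref[::-1])
    L = len(junction)
    overlap = p + s - L
    if overlap >= 0:
        return overlap, ""
    return 0, junction[p : L - s]
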