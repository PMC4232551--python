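"""Repeat-junction breakpoint mapping, microhomology accounting and unit inference.

A CUP1 repeat junction is the sequence spanning the end of one unit and the
start of the next.  Matching the junction outward against the two flanking
references — the centromere-distal flank (RSC30 side) and the
centromere-proximal flank (CIC1 side) — partitions it into a prefix derived
from the distal flank, a suffix derived from the proximal flank, an overlap
attributable to both (microhomology) and any middle bases attributable to
neither (a junction insertion).  Junctions with at most a few bases of
microhomology and no extended shared homology are the signature of
nonhomologous end-joining; long shared homology points to a
homology-mediated origin instead.

The accounting identity

    prefix_len + suffix_len - microhomology_len + len(inserted_seq) == len(junction)

holds for every mapped junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MismatchPolicy",
    "JunctionCall",
    "map_junction",
    "classify_junction",
    "UnitInference",
    "infer_unit_length",
    "classify_repeat_type",
]

from .locus_model import DEFAULT_EXACT_LEN_BP

NONHOMOLOGOUS = "nonhomologous"
HOMOLOGY_MEDIATED = "homology-mediated"
UNMAPPABLE = "unmappable"


@dataclass(frozen=True)
class MismatchPolicy:
    """How matched extensions tolerate sequence divergence.

    An extension must begin with ``seed_len`` exact matches (the anchor).
    Beyond the anchor, an isolated single-base mismatch is tolerated only
    when flanked by at least ``flank_exact`` exact matches on both sides;
    two adjacent mismatches always terminate the extension.  Setting
    ``tolerate_mismatches`` to False demands exact matches throughout.
    """

    seed_len: int = 12
    flank_exact: int = 5
    tolerate_mismatches: bool = True


@dataclass
class JunctionCall:
    """Decomposition of a junction into flank-derived, shared and inserted bases."""

    prefix_len: int
    suffix_len: int
    microhomology_len: int
    inserted_seq: str
    mismatch_positions: list[int] = field(default_factory=list)
    classification: str = NONHOMOLOGOUS
    mappable: bool = True
    # matched spans in reference coordinates (0-based half-open), for
    # translating a junction call back to breakpoints on the references
    distal_match: tuple[int, int] | None = None
    proximal_match: tuple[int, int] | None = None
    homopolymer_expansion: bool = False
    junction_len: int = 0

    def check_identity(self) -> None:
        total = self.prefix_len + self.suffix_len - self.microhomology_len + len(self.inserted_seq)
        if self.mappable and total != self.junction_len:
            raise AssertionError(
                f"junction accounting violated: {self.prefix_len}+{self.suffix_len}"
                f"-{self.microhomology_len}+{len(self.inserted_seq)} != {self.junction_len}"
            )


def _extend(query: str, ref: str, start: int, policy: MismatchPolicy) -> tuple[int, list[int]]:
    """Greedy maximal extension of ``query`` along ``ref[start:]`` under the policy.

    Returns the extension length and the tolerated mismatch offsets (query
    coordinates).  The extension always ends on a matching base.
    """
    limit = min(len(query), len(ref) - start)
    mismatches: list[int] = []
    i = 0
    while i < limit:
        if query[i] == ref[start + i]:
            i += 1
            continue
        if not policy.tolerate_mismatches:
            break
        k = policy.flank_exact
        # isolated mismatch: >= k exact matches immediately before and after
        before_ok = i >= k and all(query[i - j] == ref[start + i - j] for j in range(1, k + 1))
        after_ok = i + k < limit and all(
            query[i + j] == ref[start + i + j] for j in range(1, k + 1)
        )
        if before_ok and after_ok and (not mismatches or i - mismatches[-1] > 1):
            mismatches.append(i)
            i += 1
        else:
            break
    return i, mismatches


def _find_all(hay: str, needle: str) -> list[int]:
    out, pos = [], hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def _best_prefix(junction: str, ref: str, policy: MismatchPolicy) -> tuple[int, list[int], tuple[int, int] | None]:
    """Longest anchored prefix of ``junction`` matching a substring of ``ref``.

    Ties between equally long matches are broken toward the match whose end
    lies closest to the reference's end (the junction continues the distal
    flank rightward, so the rightmost placement is the biologically natural
    one and the rule is deterministic).
    """
    seed = junction[: policy.seed_len]
    if len(seed) < policy.seed_len:
        return 0, [], None
    best_len, best_mm, best_span = 0, [], None
    for s in _find_all(ref, seed):
        length, mm = _extend(junction, ref, s, policy)
        if length > best_len or (length == best_len and best_span and s + length > best_span[1]):
            best_len, best_mm, best_span = length, mm, (s, s + length)
    if best_len < policy.seed_len:
        return 0, [], None
    return best_len, best_mm, best_span


def _best_suffix(junction: str, ref: str, policy: MismatchPolicy) -> tuple[int, list[int], tuple[int, int] | None]:
    """Mirror image of :func:`_best_prefix` for the junction's right end.

    Ties prefer the match whose start lies closest to the reference's start.
    """
    rj, rr = junction[::-1], ref[::-1]
    length, mm, span = _best_prefix(rj, rr, policy)
    if span is None:
        return 0, [], None
    # translate reversed coordinates back
    start = len(ref) - span[1]
    end = len(ref) - span[0]
    mm_fwd = sorted(len(junction) - 1 - m for m in mm)
    return length, mm_fwd, (start, end)


def map_junction(
    junction: str,
    distal_ref: str,
    proximal_ref: str,
    policy: MismatchPolicy | None = None,
    homology_threshold_bp: int = 3,
) -> JunctionCall:
    """Locate a repeat junction against its two flanking references.

    The junction's start is extended maximally against ``distal_ref`` and its
    end against ``proximal_ref`` (both under the mismatch policy).  Overlap
    of the two matched spans on the junction is microhomology; an unmatched
    middle segment is a junction insertion.  If neither side can be anchored
    with ``policy.seed_len`` exact bases the junction is reported unmappable
    rather than raising.
    """
    if not junction or not distal_ref or not proximal_ref:
        raise ValueError("junction and both references must be nonempty")
    if len(junction) > len(distal_ref) + len(proximal_ref):
        raise ValueError("junction longer than combined references")
    policy = policy or MismatchPolicy()

    plen, pmm, pspan = _best_prefix(junction, distal_ref, policy)
    slen, smm, sspan = _best_suffix(junction, proximal_ref, policy)

    L = len(junction)
    if plen == 0 and slen == 0:
        call = JunctionCall(
            prefix_len=0,
            suffix_len=0,
            microhomology_len=0,
            inserted_seq="",
            classification=UNMAPPABLE,
            mappable=False,
            junction_len=L,
        )
        return call

    overlap = plen + slen - L
    if overlap >= 0:
        micro, inserted = overlap, ""
    else:
        micro, inserted = 0, junction[plen : L - slen]

    call = JunctionCall(
        prefix_len=plen,
        suffix_len=slen,
        microhomology_len=micro,
        inserted_seq=inserted,
        mismatch_positions=sorted(pmm + smm),
        distal_match=pspan,
        proximal_match=sspan,
        homopolymer_expansion=_is_homopolymer_expansion(junction, plen, inserted),
        junction_len=L,
    )
    call.classification = classify_junction(call, homology_threshold_bp)
    call.check_identity()
    return call


def _is_homopolymer_expansion(junction: str, prefix_len: int, inserted: str) -> bool:
    """Flag insertions that merely lengthen the adjacent homopolymer run.

    The Type 1 junction's T-tract, seven bases longer in the repeat than in
    either flank, is the motivating case.
    """
    if not inserted or len(set(inserted)) != 1:
        return False
    base = inserted[0]
    left = prefix_len > 0 and junction[prefix_len - 1] == base
    right_pos = prefix_len + len(inserted)
    right = right_pos < len(junction) and junction[right_pos] == base
    return left or right


def classify_junction(call: JunctionCall, homology_threshold_bp: int = 3) -> str:
    """Nonhomologous (microhomology at or below threshold) vs homology-mediated."""
    if not call.mappable:
        return UNMAPPABLE
    if call.microhomology_len <= homology_threshold_bp:
        return NONHOMOLOGOUS
    return HOMOLOGY_MEDIATED


# --- tandem period inference ----------------------------------------------

@dataclass(frozen=True)
class UnitInference:
    """Result of repeat-unit period detection on an array sequence."""

    unit_len: int | None
    match_fraction: float
    phase: int | None
    tandem: bool

    @property
    def reason(self) -> str:
        return "" if self.tandem else "no tandem structure"


def infer_unit_length(
    array_seq: str,
    min_p: int = 800,
    max_p: int = 2500,
    match_threshold: float = 0.95,
) -> UnitInference:
    """Detect the repeat-unit length of a tandem array by self-match periodicity.

    Scans periods ``p`` in [min_p, max_p] and scores each by the fraction of
    positions ``i`` with ``array_seq[i] == array_seq[i + p]``.  The smallest
    period reaching ``match_threshold`` with the maximal score wins (ties to
    the smaller period, so a perfect array reports the unit, not a multiple).
    ``phase`` is the first position at which the periodic self-match begins.
    """
    n = len(array_seq)
    if n < 2 * min_p:
        raise ValueError(f"sequence of {n} bp is shorter than 2 * min_p = {2 * min_p}")
    a = np.frombuffer(array_seq.encode(), dtype=np.uint8)
    max_p = min(max_p, n - 1)
    fracs: dict[int, float] = {}
    best_p, best_frac = None, -1.0
    for p in range(min_p, max_p + 1):
        eq = a[:-p] == a[p:]
        frac = float(eq.mean())
        fracs[p] = frac
        if frac > best_frac + 1e-12:
            best_frac, best_p = frac, p
    if best_p is None or best_frac < match_threshold:
        return UnitInference(None, max(best_frac, 0.0), None, False)
    # under divergence a harmonic (2p, 3p, ...) can outscore the fundamental
    # by sampling noise; prefer the smallest scanned divisor that also clears
    # the threshold
    for q in range(min_p, best_p):
        if best_p % q == 0 and fracs.get(q, 0.0) >= match_threshold:
            best_p, best_frac = q, fracs[q]
            break
    eq = a[:-best_p] == a[best_p:]
    phase = int(np.argmax(eq)) if eq.any() else 0
    return UnitInference(best_p, best_frac, phase, True)


def classify_repeat_type(
    unit_len_bp: int,
    tolerance_bp: int = 60,
    exact_lengths: dict[int, int] | None = None,
) -> int | str:
    """Assign an inferred unit length to one of the five repeat types.

    Returns the type id, ``"unknown"`` when no nominal length is within
    ``tolerance_bp``, or ``"ambiguous"`` when more than one is (possible for
    the 1998 bp Type 1 vs the 1900 bp Type 4 bins).
    """
    if unit_len_bp <= 0:
        raise ValueError("unit length must be positive")
    lengths = exact_lengths or DEFAULT_EXACT_LEN_BP
    hits = [t for t, L in sorted(lengths.items()) if abs(unit_len_bp - L) <= tolerance_bp]
    if not hits:
        return "unknown"
    if len(hits) > 1:
        return "ambiguous"
    return hits[0]
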