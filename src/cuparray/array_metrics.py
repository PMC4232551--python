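"""Copy-number estimation and in-silico assays for CUP1 tandem arrays.

Two independent copy-number estimators are provided, mirroring how array
sizes are measured in practice:

* restriction fragments — EcoRI does not cut within a CUP1 repeat, so the
  probe-hybridizing fragment grows by exactly one unit per extra copy and
  the copy number follows from the fragment size, the single-copy fragment
  size (5.2 kb by default) and the unit size;
* read depth — mean sequencing depth over the repeat relative to the median
  depth over single-copy baseline regions.

The PCR assays are presence/absence: a primer pair pointing outward within
CUP1 amplifies only across a repeat junction (so a product requires at
least two tandem copies and runs about one unit minus the primer spacing),
while primers in the flanking CIC1 and RSC30 genes give a short (~2.7 kb)
product only when the locus holds a single copy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .locus_model import revcomp

__all__ = [
    "DigestFragment",
    "PcrProduct",
    "virtual_digest",
    "copy_number_from_fragment",
    "predict_fragment",
    "copy_number_from_depth",
    "insilico_pcr",
]

ECORI_SITE = "GAATTC"
#: cut offset within the recognition site: G^AATTC
ECORI_CUT_OFFSET = 1
#: single-copy EcoRI probe-fragment size, kb
SINGLE_COPY_FRAGMENT_KB = 5.2


@dataclass(frozen=True)
class DigestFragment:
    start: int
    end: int
    contains_probe: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PcrProduct:
    fwd_site: int  # 0-based start of the forward-primer binding site
    rev_site: int  # 0-based start of the reverse-primer binding site (minus strand)
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("PCR product length must be positive")


def virtual_digest(
    seq: str,
    site: str = ECORI_SITE,
    cut_offset: int = ECORI_CUT_OFFSET,
    probe: tuple[int, int] | None = None,
) -> list[DigestFragment]:
    """Cut ``seq`` at every occurrence of ``site`` and return ordered fragments.

    Fragments partition the sequence (lengths sum to ``len(seq)``).  When a
    ``probe`` interval is given, fragments overlapping it are flagged.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    cuts = []
    pos = seq.find(site)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = seq.find(site, pos + 1)
    bounds = [0] + cuts + [len(seq)]
    frags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        has_probe = probe is not None and max(a, probe[0]) < min(b, probe[1])
        frags.append(DigestFragment(a, b, has_probe))
    return frags


def _round_half_even(x: float) -> int:
    return int(round(x))


def copy_number_from_fragment(
    L_frag_kb: float,
    L_single_kb: float = SINGLE_COPY_FRAGMENT_KB,
    unit_kb: float = 2.0,
    tolerance_kb: float = 0.5,
) -> int:
    """Repeat copies implied by an EcoRI probe-fragment size.

    The fragment holds one single-copy locus plus (n - 1) extra units, so
    n is the nearest integer to (L_frag - L_single)/unit + 1 (ties resolved
    half-to-even).  ``tolerance_kb`` absorbs gel-sizing error for fragments
    slightly below the single-copy size.
    """
    if unit_kb <= 0:
        raise ValueError("unit size must be positive")
    if L_frag_kb < L_single_kb - tolerance_kb:
        raise ValueError(
            f"fragment {L_frag_kb} kb is more than {tolerance_kb} kb below "
            f"the single-copy fragment {L_single_kb} kb"
        )
    n = _round_half_even((L_frag_kb - L_single_kb) / unit_kb + 1.0)
    return max(n, 1)


def predict_fragment(L_single_kb: float, unit_kb: float, n: int) -> float:
    """Inverse of :func:`copy_number_from_fragment`: fragment size for n copies."""
    if n < 1:
        raise ValueError("copy number must be >= 1")
    return L_single_kb + (n - 1) * unit_kb


def copy_number_from_depth(
    depth_track: np.ndarray,
    unit_interval: tuple[int, int],
    baseline_intervals: list[tuple[int, int]],
) -> tuple[float, int]:
    """Copy number as mean depth over the repeat relative to baseline median.

    Returns the real-valued estimate and its nearest integer.
    """
    depth = np.asarray(depth_track, dtype=float)
    baseline = np.concatenate([depth[a:b] for a, b in baseline_intervals])
    med = float(np.median(baseline))
    if med <= 0:
        raise ValueError("baseline median depth is zero")
    if med < 5:
        warnings.warn(
            f"baseline median depth {med:.2f} is low; integer rounding is unreliable",
            stacklevel=2,
        )
    a, b = unit_interval
    copies = float(np.mean(depth[a:b])) / med
    return copies, _round_half_even(copies)


def _find_all(hay: str, needle: str) -> list[int]:
    out, pos = [], hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def insilico_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_len: int = 3000,
    min_primer_len: int = 15,
) -> list[PcrProduct]:
    """All products a convergent primer pair would amplify from ``template``.

    Binding is exact-match on full primer length (the assays modelled are
    presence/absence, not thermodynamic).  Both primer role assignments are
    scanned; a product requires the two sites convergently oriented with the
    3' ends facing and total length at most ``max_len``.  A primer with no
    site yields an empty list, not an error.
    """
    if len(fwd) < min_primer_len or len(rev) < min_primer_len:
        raise ValueError(f"primers must be at least {min_primer_len} bases")
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()

    products: set[PcrProduct] = set()
    for plus, minus in ((fwd, rev), (rev, fwd)):
        plus_sites = _find_all(template, plus)
        minus_sites = _find_all(template, revcomp(minus))
        for i in plus_sites:
            for j in minus_sites:
                end = j + len(minus)
                length = end - i
                if i <= j and 0 < length <= max_len:
                    products.add(PcrProduct(fwd_site=i, rev_site=j, length=length))
    return sorted(products, key=lambda p: (p.fwd_site, p.rev_site))
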