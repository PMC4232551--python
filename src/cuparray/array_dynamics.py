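"""Mechanistic simulation of tandem-array genesis and copy-number change.

Two classes of event shape a CUP1 array:

* genesis — a single-copy locus is duplicated when two replication-fork
  breaks, one centromere-proximal and one centromere-distal to CUP1, are
  rejoined crosswise by nonhomologous end-joining.  The duplication product
  carries the inter-break segment twice (head to tail) with any bases the
  joining reaction adds at the new junction; the reciprocal sister-chromatid
  product deletes the segment.
* remodelling — once at least two units exist, homologous recombination
  between misaligned sister arrays (unequal crossover) grows one product
  and shrinks the other by the misalignment offset, while intrachromatid
  pop-outs (excising a circle of units) and single-strand annealing shrink
  an array nonreciprocally.

Population-scale simulation works on unit-count abstractions
(:class:`ArrayState`), with full sequence-level realization available for
any single event through :func:`nhej_duplicate`.  A marked (URA3-bearing)
unit is tracked through every event, emulating the 5-FOA marker-loss screen
used to measure array-contraction rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .locus_model import GeneFeature, LocusMap

__all__ = [
    "ArrayState",
    "ContractionResult",
    "MarkerLossTally",
    "nhej_duplicate",
    "unequal_crossover",
    "contract_array",
    "simulate_marker_loss",
]


@dataclass(frozen=True)
class ArrayState:
    """A tandem array abstracted to its units; each unit may carry a marker.

    ``units`` holds one bool per repeat (True = URA3-marked).  Unequal
    crossover can concentrate zero, one or two markers on a product, so the
    marker set is per-unit rather than a single index.
    """

    units: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.units) < 1:
            raise ValueError("an array must retain at least one unit")

    @classmethod
    def make(cls, n: int, marker_unit: int | None = None) -> "ArrayState":
        if n < 1:
            raise ValueError("n must be >= 1")
        units = [False] * n
        if marker_unit is not None:
            if not 0 <= marker_unit < n:
                raise ValueError(f"marker unit {marker_unit} outside 0..{n - 1}")
            units[marker_unit] = True
        return cls(tuple(units))

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def marker_count(self) -> int:
        return sum(self.units)

    @property
    def marker_units(self) -> tuple[int, ...]:
        return tuple(i for i, m in enumerate(self.units) if m)


def _remap_features(
    features: list[GeneFeature], window: tuple[int, int], offset: int
) -> list[GeneFeature]:
    """Features overlapping ``window`` clipped to it, then shifted by ``offset``."""
    out = []
    for f in features:
        a, b = max(f.start, window[0]), min(f.end, window[1])
        if a < b:
            out.append(GeneFeature(f.name, a + offset, b + offset, f.strand))
    return out


def nhej_duplicate(
    locus: LocusMap,
    proximal_break: int,
    distal_break: int,
    insertion: str = "",
    microhomology_used: int = 0,
) -> tuple[LocusMap, LocusMap]:
    """Crosswise rejoining of two replication-fork breaks around CUP1.

    Returns ``(duplication, deletion)``: the duplication carries
    ``[proximal_break, distal_break)`` twice with ``insertion`` at the new
    junction (length L + span + len(insertion)); the reciprocal deletion
    product lacks the segment (length L - span).  When
    ``microhomology_used`` > 0, the joining is checked to be feasible: the
    first that-many bases after each break must be identical.
    """
    L = len(locus.sequence)
    if not (0 < proximal_break < distal_break < L):
        raise ValueError(
            f"breaks ({proximal_break}, {distal_break}) must lie strictly inside the locus"
        )
    seq = locus.sequence
    m = microhomology_used
    if m > 0 and seq[proximal_break : proximal_break + m] != seq[distal_break : distal_break + m]:
        raise ValueError(f"{m} bases after the two breaks are not identical")
    insertion = insertion.upper()

    p, d = proximal_break, distal_break
    shift = d - p + len(insertion)
    dup_seq = seq[:d] + insertion + seq[p:]
    dup_features = _remap_features(locus.features, (0, d), 0) + _remap_features(
        locus.features, (p, L), shift
    )
    dup = LocusMap(
        sequence=dup_seq,
        features=sorted(dup_features, key=lambda f: (f.start, f.end)),
        left_ecoRI=locus.left_ecoRI,
        right_ecoRI=None if locus.right_ecoRI is None else locus.right_ecoRI + shift,
        name=locus.name + "_dup",
    )

    del_seq = seq[:p] + seq[d:]
    del_features = _remap_features(locus.features, (0, p), 0) + _remap_features(
        locus.features, (d, L), -(d - p)
    )
    deletion = LocusMap(
        sequence=del_seq,
        features=sorted(del_features, key=lambda f: (f.start, f.end)),
        left_ecoRI=locus.left_ecoRI,
        right_ecoRI=None if locus.right_ecoRI is None else locus.right_ecoRI - (d - p),
        name=locus.name + "_del",
    )
    return dup, deletion


def unequal_crossover(
    a: ArrayState,
    b: ArrayState,
    offset_k: int,
    crossover_j: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ArrayState, ArrayState]:
    """Reciprocal exchange between sister arrays misaligned by ``offset_k`` units.

    Products carry ``a.n + k`` and ``b.n - k`` units; the total unit count
    and the total marker count are conserved.  ``crossover_j`` selects the
    exchange boundary (units ``b[:j]`` join ``a[j-k:]``); when omitted it is
    drawn uniformly from the feasible range.
    """
    k = offset_k
    if k < 1:
        raise ValueError("offset must be >= 1")
    if k >= b.n:
        raise ValueError(f"offset {k} would leave the contracted product empty (b.n = {b.n})")
    j_lo, j_hi = k, min(b.n, a.n + k)
    if crossover_j is None:
        rng = rng or np.random.default_rng()
        j = int(rng.integers(j_lo, j_hi + 1))
    else:
        j = crossover_j
        if not j_lo <= j <= j_hi:
            raise ValueError(f"crossover point {j} outside feasible range [{j_lo}, {j_hi}]")
    gained = ArrayState(b.units[:j] + a.units[j - k :])
    lost = ArrayState(a.units[: j - k] + b.units[j:])
    assert gained.n == a.n + k and lost.n == b.n - k
    return gained, lost


@dataclass(frozen=True)
class ContractionResult:
    state: ArrayState
    marker_lost: bool
    excised_units: tuple[bool, ...] | None = None  # pop-out circle, when applicable


def contract_array(
    a: ArrayState,
    kind: str,
    k_lost: int,
    excise_start: int | None = None,
    rng: np.random.Generator | None = None,
) -> ContractionResult:
    """Nonreciprocal loss of ``k_lost`` contiguous units by pop-out or SSA.

    A pop-out additionally reports the excised circle of units.  The marker
    is lost iff a marked unit lies within the excised span.
    """
    if kind not in ("popout", "SSA"):
        raise ValueError(f"unknown contraction kind {kind!r}")
    if not 1 <= k_lost <= a.n - 1:
        raise ValueError(f"k_lost must be in 1..{a.n - 1}, got {k_lost}")
    if excise_start is None:
        rng = rng or np.random.default_rng()
        excise_start = int(rng.integers(0, a.n - k_lost + 1))
    if not 0 <= excise_start <= a.n - k_lost:
        raise ValueError(f"excision start {excise_start} outside 0..{a.n - k_lost}")
    span = a.units[excise_start : excise_start + k_lost]
    remaining = a.units[:excise_start] + a.units[excise_start + k_lost :]
    return ContractionResult(
        state=ArrayState(remaining),
        marker_lost=any(span),
        excised_units=span if kind == "popout" else None,
    )


@dataclass
class MarkerLossTally:
    """Outcome tally of a simulated marker-loss screen."""

    n_divisions: int
    n_events: int
    n_marker_loss: int
    final_n_counts: dict[int, int] = field(default_factory=dict)
    single_copy_fraction: float | None = None
    seed: int | None = None


def _uniform_k_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(1, n)
    return ks, np.full(n - 1, 1.0 / (n - 1))


def simulate_marker_loss(
    n0: int,
    marker_unit: int,
    per_division_loss_rate: float,
    n_divisions: int,
    seed: int,
    event_size_distribution: dict[int, float] | None = None,
    condition_on_marker: bool = True,
) -> MarkerLossTally:
    """Simulate array contractions in a marker-loss (5-FOA) screen.

    Each division triggers a contraction with probability
    ``per_division_loss_rate``; the event removes ``k`` contiguous units,
    ``k`` drawn from ``event_size_distribution`` (uniform on 1..n0-1 by
    default).  With ``condition_on_marker`` (the default) excision spans are
    drawn uniformly among spans containing the marked unit — the screen only
    detects marker-loss events, so undetectable events are not simulated.
    With it off, spans are uniform over all placements and events sparing
    the marker are tallied but not counted as losses.
    """
    if not 0 < per_division_loss_rate <= 1:
        if per_division_loss_rate == 0:
            return MarkerLossTally(n_divisions, 0, 0, {}, None, seed)
        raise ValueError("loss rate must lie in [0, 1]")
    if not 0 <= marker_unit < n0:
        raise ValueError("marker unit outside the array")

    if event_size_distribution is None:
        ks, probs = _uniform_k_distribution(n0)
    else:
        ks = np.array(sorted(event_size_distribution), dtype=int)
        probs = np.array([event_size_distribution[int(k)] for k in ks], dtype=float)
        if (ks < 1).any() or (ks > n0 - 1).any():
            raise ValueError("event sizes must lie in 1..n0-1")
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("event size distribution must be a probability distribution")

    rng = np.random.default_rng(seed)
    n_events = int(rng.binomial(n_divisions, per_division_loss_rate))
    if n_events == 0:
        return MarkerLossTally(n_divisions, 0, 0, {}, None, seed)

    k_draw = ks[rng.choice(len(ks), size=n_events, p=probs)]
    if condition_on_marker:
        lo = np.maximum(0, marker_unit - k_draw + 1)
        hi = np.minimum(marker_unit, n0 - k_draw)
        starts = lo + (rng.random(n_events) * (hi - lo + 1)).astype(int)
        lost = np.ones(n_events, dtype=bool)
    else:
        starts = (rng.random(n_events) * (n0 - k_draw + 1)).astype(int)
        lost = (starts <= marker_unit) & (marker_unit < starts + k_draw)

    final_n = n0 - k_draw
    loss_final = final_n[lost]
    counts = {int(n): int(c) for n, c in zip(*np.unique(loss_final, return_counts=True))}
    n_loss = int(lost.sum())
    frac = float((loss_final == 1).mean()) if n_loss else None
    return MarkerLossTally(
        n_divisions=n_divisions,
        n_events=n_events,
        n_marker_loss=n_loss,
        final_n_counts=counts,
        single_copy_fraction=frac,
        seed=seed,
    )
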