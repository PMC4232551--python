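"""Synthetic CUP1 loci, arrays, junction cases and depth tracks with truth logs.

No public accession resolves to the study strains' array sequences, so every
input the pipeline needs is generated here: a single-copy
CIC1 - RUF5/CUP1/ARS - RSC30 locus with flanking EcoRI sites, typed tandem
arrays built by replaying the genesis mechanism (one nonhomologous
end-joining duplication, then unequal-crossover expansions), labelled
junction test cases, and per-base read-depth tracks.  Every product ships a
:class:`SyntheticTruth` log holding the exact breakpoints, unit length,
junction composition and expected restriction-fragment size, and the
generator is byte-deterministic per (seed, config).

Geometry defaults are chosen so that the single-copy EcoRI probe fragment
is exactly 5.2 kb, the flanking-gene primer pair gives a 2.7 kb product on
one copy, and all five repeat-type breakpoints are realizable on one locus.
The divergence model applies substitutions only (no indels), at rates of
0.7% over the centromere-proximal 600 bp flank, 0.4% over the distal
flank and 0.5% within the repeats.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .array_dynamics import nhej_duplicate
from .array_metrics import ECORI_SITE, virtual_digest
from .locus_model import (
    DEFAULT_EXACT_LEN_BP,
    NOMINAL_UNIT_KB,
    GeneFeature,
    LocusMap,
    RepeatTypeSpec,
    revcomp,
    write_fasta,
    write_gff3,
)

__all__ = [
    "DivergenceConfig",
    "ZERO_DIVERGENCE",
    "LocusConfig",
    "DEFAULT_CONFIG",
    "SyntheticTruth",
    "ArrayStrain",
    "JunctionCase",
    "build_single_locus",
    "generate_array_strain",
    "generate_junction_cases",
    "generate_depth_track",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DivergenceConfig:
    """Substitution rates applied to a generated strain (fractions, not %)."""

    proximal_flank: float = 0.007
    distal_flank: float = 0.004
    repeat: float = 0.005
    flank_window: int = 600

    def __post_init__(self) -> None:
        for r in (self.proximal_flank, self.distal_flank, self.repeat):
            if not 0 <= r <= 0.05:
                raise ValueError("divergence rates must lie in [0, 0.05]")


ZERO_DIVERGENCE = DivergenceConfig(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LocusConfig:
    """Geometry of the synthetic single-copy locus (0-based half-open spans)."""

    total_len: int = 5600
    ecoRI_left_site: int = 119  # GAATTC site start; cut one base in
    ecoRI_right_site: int = 5319
    cic1: tuple[int, int] = (200, 1300)
    ruf5: tuple[int, int] = (1450, 2530)
    cup1: tuple[int, int] = (1830, 2016)  # 186 bp ORF, minus strand, inside RUF5
    ars: tuple[int, int] = (2470, 2590)
    rsc30: tuple[int, int] = (2600, 5200)
    # assay primer sites: flanking pair (CIC1 -> RSC30, 2.7 kb on one copy)
    flank_fwd_primer: tuple[int, int] = (1180, 1200)
    flank_rev_primer: tuple[int, int] = (3860, 3880)
    # outward pair within CUP1 (5' ends ~40 bp apart; product = unit - 40)
    cup1_outward_fwd: tuple[int, int] = (1940, 1960)
    cup1_outward_rev: tuple[int, int] = (1880, 1900)
    # per-type (proximal break, distal break, junction insert)
    breakpoints: dict[int, tuple[int, int, str]] = field(
        default_factory=lambda: {
            1: (1350, 3347, "A"),
            2: (1360, 3160, ""),
            3: (1390, 2590, ""),
            4: (1250, 3150, ""),
            5: (1370, 2970, ""),
        }
    )
    exact_len_bp: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_EXACT_LEN_BP))

    @property
    def ecoRI_cuts(self) -> tuple[int, int]:
        return self.ecoRI_left_site + 1, self.ecoRI_right_site + 1

    def type_spec(self, type_id: int) -> RepeatTypeSpec:
        if type_id not in self.breakpoints:
            raise ValueError(f"unknown repeat type {type_id}")
        p, d, ins = self.breakpoints[type_id]
        return RepeatTypeSpec(
            type_id=type_id,
            nominal_kb=NOMINAL_UNIT_KB[type_id],
            exact_len_bp=self.exact_len_bp[type_id],
            proximal_break=p,
            distal_break=d,
            junction_insert=ins,
        )

    def validate(self) -> None:
        spans = [self.cic1, self.ruf5, self.rsc30]
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            if b1 > a2:
                raise ValueError("gene features overlap")
        if not (self.ruf5[0] <= self.cup1[0] and self.cup1[1] <= self.ruf5[1]):
            raise ValueError("CUP1 must lie within RUF5")
        for t in self.breakpoints:
            self.type_spec(t)  # raises if the span does not equal the unit length

    def primer_pair(self, locus_seq: str, which: str) -> tuple[str, str]:
        """Primer sequences for the named assay, read off the locus."""
        if which == "flanking":
            f, r = self.flank_fwd_primer, self.flank_rev_primer
        elif which == "outward":
            f, r = self.cup1_outward_fwd, self.cup1_outward_rev
        else:
            raise ValueError(f"unknown assay {which!r}")
        return locus_seq[f[0] : f[1]], revcomp(locus_seq[r[0] : r[1]])


DEFAULT_CONFIG = LocusConfig()


@dataclass
class SyntheticTruth:
    """Everything the generator knows about what it produced."""

    seed: int
    locus_len: int
    ecoRI_cuts: tuple[int, int]
    features: dict[str, tuple[int, int, str]]
    type_id: int | None = None
    final_n: int = 1
    exact_unit_len: int | None = None
    breaks: tuple[int, int] | None = None
    junction_insert: str = ""
    expected_microhomology: int = 0
    junction_positions: list[int] = field(default_factory=list)
    repeat_span: tuple[int, int] | None = None
    expected_probe_fragment_bp: int = 0
    divergence: dict[str, float] = field(default_factory=dict)
    n_substitutions: dict[str, int] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# --- single-copy locus -----------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _scrub_site(arr: np.ndarray, keep: tuple[int, ...], forbidden: dict[int, set[int]]) -> bool:
    """Destroy every GAATTC occurrence except those starting at ``keep``.

    Replacement bases respect ``forbidden`` (position -> byte values that
    must not be written there).  Returns True if anything changed.
    """
    s = arr.tobytes()
    changed = False
    pos = s.find(b"GAATTC")
    while pos != -1:
        if pos not in keep:
            t = pos + 2
            for cand in b"CGTA":
                if cand != arr[t] and cand not in forbidden.get(t, set()):
                    arr[t] = cand
                    break
            changed = True
        pos = s.find(b"GAATTC", pos + 1)
    return changed


def _junction_constraints(config: LocusConfig, arr: np.ndarray) -> dict[int, set[int]]:
    """Forbidden bases at positions adjacent to every type's breakpoints.

    Four constraints per type pin the emergent junction structure to the
    truth log: the bases immediately past each break must mismatch the
    junction's continuation (so matched extensions stop exactly at the
    breaks) and the next base out must mismatch as well (so the mismatch
    cannot be absorbed as a tolerated isolated SNP).
    """
    cons: dict[int, set[int]] = {}

    def forbid(target: int, value: int) -> None:
        cons.setdefault(target, set()).add(int(value))

    for p, d, ins in config.breakpoints.values():
        ib = ins.encode()
        # prefix side: junction continues with ins then seq[p:]
        nxt0 = ib[0] if ib else arr[p]
        nxt1 = (ib[1] if len(ib) > 1 else arr[p]) if ib else arr[p + 1]
        forbid(d, nxt0)
        forbid(d + 1, nxt1)
        # suffix side: junction is preceded by ins then seq[:d]
        prv0 = ib[-1] if ib else arr[d - 1]
        prv1 = (ib[-2] if len(ib) > 1 else arr[d - 1]) if ib else arr[d - 2]
        forbid(p - 1, prv0)
        forbid(p - 2, prv1)
    return cons


def _apply_constraints(arr: np.ndarray, cons: dict[int, set[int]]) -> bool:
    changed = False
    for t, banned in cons.items():
        if int(arr[t]) in banned:
            for cand in b"ACGT":
                if cand not in banned:
                    arr[t] = cand
                    changed = True
                    break
            else:  # pragma: no cover - 4 bases, <=2 banned in practice
                raise RuntimeError("no admissible base for junction constraint")
    return changed


def build_single_locus(seed: int, config: LocusConfig = DEFAULT_CONFIG) -> tuple[LocusMap, SyntheticTruth]:
    """Random single-copy CUP1 locus honouring the configured geometry.

    The EcoRI probe fragment of the result is exactly
    ``ecoRI_cuts[1] - ecoRI_cuts[0]`` bp (5200 by default), there is no
    internal GAATTC between the flanking sites, and the bases around every
    configured breakpoint are fixed so that each repeat type's junction has
    exactly the microhomology (none) and insertion its spec declares.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    arr = _random_seq(rng, config.total_len)

    site = np.frombuffer(ECORI_SITE.encode(), dtype=np.uint8)
    for s in (config.ecoRI_left_site, config.ecoRI_right_site):
        arr[s : s + 6] = site
    # CUP1 ORF ends on the minus strand: start codon ATG at the distal end,
    # TAA stop at the proximal end
    c0, c1 = config.cup1
    arr[c1 - 3 : c1] = np.frombuffer(b"CAT", dtype=np.uint8)
    arr[c0 : c0 + 3] = np.frombuffer(b"TTA", dtype=np.uint8)

    keep = (config.ecoRI_left_site, config.ecoRI_right_site)
    for _ in range(20):
        cons = _junction_constraints(config, arr)
        changed = _apply_constraints(arr, cons)
        changed |= _scrub_site(arr, keep, cons)
        if not changed:
            break
    else:  # pragma: no cover
        raise RuntimeError("junction-constraint enforcement did not converge")

    seq = arr.tobytes().decode()
    cuts = config.ecoRI_cuts
    features = [
        GeneFeature("CIC1", *config.cic1, "+"),
        GeneFeature("RUF5", *config.ruf5, "+"),
        GeneFeature("CUP1", *config.cup1, "-"),
        GeneFeature("ARS", *config.ars, "+"),
        GeneFeature("RSC30", *config.rsc30, "-"),
    ]
    locus = LocusMap(sequence=seq, features=features, left_ecoRI=cuts[0], right_ecoRI=cuts[1], name="synthetic_single_copy")
    locus.validate()

    truth = SyntheticTruth(
        seed=seed,
        locus_len=len(seq),
        ecoRI_cuts=cuts,
        features={f.name: (f.start, f.end, f.strand) for f in features},
        expected_probe_fragment_bp=cuts[1] - cuts[0],
        repeat_span=None,
    )
    return locus, truth


# --- typed arrays ----------------------------------------------------------

@dataclass
class ArrayStrain:
    """A synthetic strain: array locus map plus its generation truth."""

    name: str
    locus: LocusMap
    truth: SyntheticTruth

    @property
    def sequence(self) -> str:
        return self.locus.sequence

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{self.name}.fasta",
            "gff3": outdir / f"{self.name}.gff3",
            "truth": outdir / f"{self.name}.truth.json",
        }
        write_fasta({self.name: self.sequence}, paths["fasta"])
        write_gff3(self.locus, paths["gff3"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _array_features(config: LocusConfig, spec: RepeatTypeSpec, n: int) -> list[GeneFeature]:
    p, d = spec.proximal_break, spec.distal_break
    u = spec.exact_len_bp
    shift_tail = (n - 1) * u

    def suffix(name: str, i: int) -> str:
        return name if n == 1 else f"{name}_copy{i + 1}"

    feats = [GeneFeature("CIC1", *config.cic1, "+")]
    for i in range(n):
        off = i * u
        feats.append(GeneFeature(suffix("RUF5", i), config.ruf5[0] + off, config.ruf5[1] + off, "+"))
        feats.append(GeneFeature(suffix("CUP1", i), config.cup1[0] + off, config.cup1[1] + off, "-"))
        feats.append(GeneFeature(suffix("ARS", i), config.ars[0] + off, config.ars[1] + off, "+"))
        # RSC30-derived terminal fragment carried inside every non-final copy
        if d > config.rsc30[0] and i < n - 1:
            feats.append(
                GeneFeature(suffix("YHR054C", i), config.rsc30[0] + off, d + off, "-")
            )
    feats.append(GeneFeature("RSC30", config.rsc30[0] + shift_tail, config.rsc30[1] + shift_tail, "-"))
    return sorted(feats, key=lambda f: (f.start, f.end))


def _apply_divergence(
    rng: np.random.Generator,
    arr: np.ndarray,
    windows: dict[str, tuple[int, int, float]],
) -> dict[str, int]:
    counts = {}
    for name, (a, b, rate) in windows.items():
        if rate <= 0 or b <= a:
            counts[name] = 0
            continue
        mask = rng.random(b - a) < rate
        idx = np.nonzero(mask)[0] + a
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        counts[name] = int(len(idx))
    return counts


def generate_array_strain(
    type_id: int,
    n: int,
    seed: int,
    divergence: DivergenceConfig | None = None,
    config: LocusConfig = DEFAULT_CONFIG,
) -> ArrayStrain:
    """A synthetic strain carrying an n-copy array of the given repeat type.

    The array is built the way the mechanism model says real arrays arise:
    one unequal NHEJ duplication of the single-copy locus at the type's
    breakpoints, then unequal-crossover expansions adding one unit each,
    all recorded in the event log.  ``divergence=None`` applies the default
    rates; pass :data:`ZERO_DIVERGENCE` for a clean sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = config.type_spec(type_id)
    divergence = DivergenceConfig() if divergence is None else divergence
    locus, locus_truth = build_single_locus(seed, config)

    p, d, ins = spec.proximal_break, spec.distal_break, spec.junction_insert
    u = spec.exact_len_bp
    events: list[dict] = []
    if n == 1:
        seq = locus.sequence
    else:
        dup, _deletion = nhej_duplicate(locus, p, d, insertion=ins)
        events.append(
            {"kind": "NHEJ_dup", "proximal_break": p, "distal_break": d, "insertion": ins}
        )
        unit = locus.sequence[p:d] + ins
        seq = locus.sequence[:p] + unit * (n - 1) + locus.sequence[p:]
        if n == 2:
            assert seq == dup.sequence
        for i in range(n - 2):
            events.append({"kind": "unequal_CO", "offset_k": 1, "note": f"expansion {i + 1}"})

    repeat_end = d + (n - 1) * u
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng = np.random.default_rng(seed + 1)  # divergence stream, separate from locus
    w = divergence.flank_window
    counts = _apply_divergence(
        rng,
        arr,
        {
            "proximal_flank": (p - w, p, divergence.proximal_flank),
            "repeat": (p, repeat_end, divergence.repeat),
            "distal_flank": (repeat_end, repeat_end + w, divergence.distal_flank),
        },
    )
    # substitutions must not mint a new EcoRI site inside the probe fragment
    right_site = config.ecoRI_right_site + (n - 1) * u
    _scrub_site(arr, (config.ecoRI_left_site, right_site), {})
    seq = arr.tobytes().decode()

    cuts = (config.ecoRI_cuts[0], config.ecoRI_cuts[1] + (n - 1) * u)
    array_locus = LocusMap(
        sequence=seq,
        features=_array_features(config, spec, n),
        left_ecoRI=cuts[0],
        right_ecoRI=cuts[1],
        name=f"type{type_id}_n{n}_seed{seed}",
    )
    truth = SyntheticTruth(
        seed=seed,
        locus_len=len(seq),
        ecoRI_cuts=cuts,
        features={f.name: (f.start, f.end, f.strand) for f in array_locus.features},
        type_id=type_id,
        final_n=n,
        exact_unit_len=u,
        breaks=(p, d),
        junction_insert=ins,
        expected_microhomology=0,
        junction_positions=[d + i * u for i in range(n - 1)],
        repeat_span=(p, repeat_end),
        expected_probe_fragment_bp=locus_truth.expected_probe_fragment_bp + (n - 1) * u,
        divergence=dataclasses.asdict(divergence),
        n_substitutions=counts,
        events=events,
    )
    return ArrayStrain(name=array_locus.name, locus=array_locus, truth=truth)


# --- junction test cases ---------------------------------------------------

@dataclass(frozen=True)
class JunctionCase:
    """A labelled junction with its two flanking references."""

    name: str
    junction: str
    distal_ref: str
    proximal_ref: str
    true_prefix: int
    true_suffix: int
    true_microhomology: int
    true_insert: str
    snp_offsets: tuple[int, ...] = ()
    homopolymer_expansion: bool = False


def _rand_str(rng: np.random.Generator, n: int) -> str:
    return _random_seq(rng, n).tobytes().decode()


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def generate_junction_cases(
    seed: int,
    n_cases: int,
    mh_range: tuple[int, int] = (0, 10),
    ins_range: tuple[int, int] = (0, 10),
    mismatch_rate: float = 0.0,
    homopolymer_prob: float = 0.2,
) -> list[JunctionCase]:
    """Labelled junctions spanning microhomology 0..10 and insertions 0..10 bp.

    Each case is distal-derived prefix + shared bases + optional insertion +
    proximal-derived suffix; two enforced mismatching bases beyond each
    matched span in the references pin the truth labels exactly.  With
    ``mismatch_rate`` > 0 a case may carry one isolated SNP inside a matched
    segment (at least 12 bases from the junction start/end and 7 from the
    segment boundary, so the mismatch policy can absorb it).  Insertions are
    homopolymer expansions of the adjacent base with ``homopolymer_prob``.
    """
    if not (0 <= mh_range[0] <= mh_range[1] and 0 <= ins_range[0] <= ins_range[1]):
        raise ValueError("invalid ranges")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        mh = int(rng.integers(mh_range[0], mh_range[1] + 1))
        if mh > 0:
            ins = ""
        else:
            ilen = int(rng.integers(ins_range[0], ins_range[1] + 1))
            ins = _rand_str(rng, ilen)
        dlen = int(rng.integers(25, 41))
        plen = int(rng.integers(25, 41))
        D = _rand_str(rng, dlen)
        P = _rand_str(rng, plen)
        M = _rand_str(rng, mh)
        homopolymer = bool(ins) and rng.random() < homopolymer_prob
        if homopolymer:
            ins = D[-1] * len(ins)

        junction = D + M + ins + P
        L = len(junction)
        # stop bases: two enforced mismatches right after/before each match
        nxt = junction[dlen + mh], junction[dlen + mh + 1]
        s1, s2 = _other_base(rng, nxt[0]), _other_base(rng, nxt[1])
        prv = junction[L - mh - plen - 1], junction[L - mh - plen - 2]
        t1, t2 = _other_base(rng, prv[0]), _other_base(rng, prv[1])
        distal_ref = _rand_str(rng, 15) + D + M + s1 + s2 + _rand_str(rng, 15)
        proximal_ref = _rand_str(rng, 15) + t2 + t1 + M + P + _rand_str(rng, 15)

        snps: tuple[int, ...] = ()
        if mismatch_rate > 0 and rng.random() < mismatch_rate:
            if rng.random() < 0.5 and dlen >= 19:
                q = int(rng.integers(12, dlen - 6))
            else:
                q = int(rng.integers(L - plen + 6, L - 12))
            junction = junction[:q] + _other_base(rng, junction[q]) + junction[q + 1 :]
            snps = (q,)

        cases.append(
            JunctionCase(
                name=f"case{i:04d}_mh{mh}_ins{len(ins)}",
                junction=junction,
                distal_ref=distal_ref,
                proximal_ref=proximal_ref,
                true_prefix=dlen + mh,
                true_suffix=mh + plen,
                true_microhomology=mh,
                true_insert=ins,
                snp_offsets=snps,
                homopolymer_expansion=homopolymer,
            )
        )
    return cases


# --- read-depth tracks -----------------------------------------------------

def generate_depth_track(
    truth: SyntheticTruth, mean_coverage: float, seed: int
) -> np.ndarray:
    """Independent Poisson per-base depth, multiplied by copy number over the repeat.

    The track emulates short-read coverage of the *single-copy reference*:
    reads from all n repeat copies pile onto the one reference unit, so the
    repeat span shows n-fold depth.
    """
    if mean_coverage <= 0:
        raise ValueError("coverage must be positive")
    if mean_coverage < 1:
        warnings.warn(
            f"mean coverage {mean_coverage} is below 1x; copy-number rounding "
            "from such a track is unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # reference-scale track: one repeat unit between the original breaks
    if truth.breaks is not None:
        p, d = truth.breaks
        length = truth.locus_len - (truth.final_n - 1) * (truth.exact_unit_len or 0)
        lam = np.full(length, mean_coverage)
        lam[p:d] *= truth.final_n
    else:
        length = truth.locus_len
        lam = np.full(length, mean_coverage)
    return rng.poisson(lam).astype(float)
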