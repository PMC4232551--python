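"""Domain types and file formats for the CUP1 locus pipeline.

The CUP1 metallothionein gene of *Saccharomyces cerevisiae* sits inside the
noncoding RNA gene RUF5, between CIC1 (centromere-proximal) and RSC30
(centromere-distal) on chromosome VIII.  Most natural isolates carry CUP1 in
a head-to-tail tandem array; this module provides the shared value types
(gene features, locus maps, repeat-type specifications, strain records) and
the FASTA / GFF3 / CSV readers and writers used by the rest of the package.

Coordinate convention: all internal coordinates are 0-based half-open;
everything user-facing (GFF3, JSON reports) is 1-based inclusive, the SGD
convention.  :func:`to_external_coords` / :func:`to_internal_coords` convert
between the two and composing them is the identity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "LocusMap",
    "RepeatTypeSpec",
    "StrainRecord",
    "load_strain_table",
    "write_strain_table",
    "to_external_coords",
    "to_internal_coords",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")

#: nominal unit sizes (kb) printed for the five repeat types
NOMINAL_UNIT_KB = {1: 2.0, 2: 1.8, 3: 1.2, 4: 1.9, 5: 1.6}

#: exact unit lengths in bp.  Type 1 is 1998 bp; the exact lengths of
#: Types 2-5 are configuration (only 0.1-kb sizes are printed) and default
#: to the nominal sizes.
DEFAULT_EXACT_LEN_BP = {1: 1998, 2: 1800, 3: 1200, 4: 1900, 5: 1600}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


def to_external_coords(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive (SGD style)."""
    if start >= end:
        raise ValueError(f"empty or inverted interval ({start}, {end})")
    if start < 0:
        raise ValueError(f"negative start {start}")
    return start + 1, end


def to_internal_coords(first: int, last: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval back to 0-based half-open."""
    if first < 1 or last < first:
        raise ValueError(f"bad 1-based interval ({first}, {last})")
    return first - 1, last


@dataclass(frozen=True)
class GeneFeature:
    """An annotated interval on a locus (gene, ARS or restriction site)."""

    name: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.name}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GeneFeature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class LocusMap:
    """A sequence with ordered gene features and the flanking EcoRI cut sites.

    ``left_ecoRI`` / ``right_ecoRI`` are the cut coordinates (0-based offsets
    at which the enzyme severs the strand, one base into the GAATTC site).
    """

    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    left_ecoRI: int | None = None
    right_ecoRI: int | None = None
    name: str = "locus"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.name}: non-ACGTN characters {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.name} exceeds sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self) -> None:
        """Check the structural invariants of a CUP1 locus annotation."""
        cup1 = self.feature("CUP1")
        ruf5 = self.feature("RUF5")
        if not (ruf5.start <= cup1.start and cup1.end <= ruf5.end):
            raise ValueError("CUP1 must lie within RUF5")
        if cup1.strand == ruf5.strand:
            raise ValueError("CUP1 must be on the strand opposite RUF5")
        if self.left_ecoRI is not None and self.right_ecoRI is not None:
            genes = [f for f in self.features if f.name != "EcoRI_site"]
            lo = min(f.start for f in genes)
            hi = max(f.end for f in genes)
            if not (self.left_ecoRI < lo and hi < self.right_ecoRI):
                raise ValueError("EcoRI cut sites must flank all gene features")


@dataclass(frozen=True)
class RepeatTypeSpec:
    """Breakpoint specification of one of the five CUP1 repeat types.

    ``proximal_break`` / ``distal_break`` are positions on the single-copy
    locus; the repeat unit is the segment between them plus any bases
    inserted at the junction by the founding end-joining event.
    """

    type_id: int
    nominal_kb: float
    exact_len_bp: int
    proximal_break: int
    distal_break: int
    junction_insert: str = ""

    def __post_init__(self) -> None:
        if self.type_id not in NOMINAL_UNIT_KB:
            raise ValueError(f"unknown repeat type {self.type_id}")
        if not self.proximal_break < self.distal_break:
            raise ValueError("proximal break must precede distal break")
        span = self.distal_break - self.proximal_break + len(self.junction_insert)
        if span != self.exact_len_bp:
            raise ValueError(
                f"type {self.type_id}: break span {span} != exact length {self.exact_len_bp}"
            )


@dataclass(frozen=True)
class StrainRecord:
    """One row of the 14-strain array survey table.

    ``cu_censored`` marks an inhibitory-copper value recorded only as an
    upper bound (the single-copy strain DTY3 is '<0.1 mM'); the numeric
    field then carries the bound itself, never a sentinel.
    """

    strain: str
    repeat_type: int | None
    unit_kb: float | None
    ecoRI_frag_kb: float
    southern_copies: int
    deepseq_copies: int | None
    cu_inhib_mM: float
    cu_censored: bool
    ploidy: str

    def __post_init__(self) -> None:
        if self.repeat_type is None and self.southern_copies != 1:
            raise ValueError(f"{self.strain}: no repeat type but {self.southern_copies} copies")
        if self.repeat_type is not None:
            expected = NOMINAL_UNIT_KB[self.repeat_type]
            if self.unit_kb is None or abs(self.unit_kb - expected) > 1e-9:
                raise ValueError(
                    f"{self.strain}: unit {self.unit_kb} kb does not match "
                    f"type {self.repeat_type} nominal {expected} kb"
                )
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"{self.strain}: ploidy must be haploid or diploid")


_TABLE_COLUMNS = [
    "strain",
    "repeat_type",
    "unit_kb",
    "ecoRI_frag_kb",
    "southern_copies",
    "deepseq_copies",
    "cu_inhib_mM",
    "ploidy",
]


def _parse_record(row: pd.Series, label: str) -> StrainRecord:
    def blank(v) -> bool:
        return pd.isna(v) or str(v).strip() == ""

    raw_type = str(row["repeat_type"]).strip()
    if blank(row["repeat_type"]) or raw_type.lower() in ("none", "no repeat"):
        rep_type: int | None = None
    elif raw_type in {"1", "2", "3", "4", "5"}:
        rep_type = int(raw_type)
    else:
        raise ValueError(f"{label}: unknown repeat type label {raw_type!r}")

    cu_raw = str(row["cu_inhib_mM"]).strip()
    censored = cu_raw.startswith("<")
    cu_val = float(cu_raw.lstrip("<"))

    try:
        return StrainRecord(
            strain=str(row["strain"]).strip(),
            repeat_type=rep_type,
            unit_kb=None if blank(row["unit_kb"]) else float(row["unit_kb"]),
            ecoRI_frag_kb=float(row["ecoRI_frag_kb"]),
            southern_copies=int(row["southern_copies"]),
            deepseq_copies=None if blank(row["deepseq_copies"]) else int(row["deepseq_copies"]),
            cu_inhib_mM=cu_val,
            cu_censored=censored,
            ploidy=str(row["ploidy"]).strip(),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{label}: {exc}") from exc


def load_strain_table(path: str | Path) -> list[StrainRecord]:
    """Read a strain survey CSV into :class:`StrainRecord` objects, in file order."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        label = f"{path} row {i + 2}"  # header is line 1
        records.append(_parse_record(row, label))
    return records


def write_strain_table(records: Iterable[StrainRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "strain": r.strain,
                "repeat_type": "none" if r.repeat_type is None else r.repeat_type,
                "unit_kb": "" if r.unit_kb is None else r.unit_kb,
                "ecoRI_frag_kb": r.ecoRI_frag_kb,
                "southern_copies": r.southern_copies,
                "deepseq_copies": "" if r.deepseq_copies is None else r.deepseq_copies,
                "cu_inhib_mM": f"<{r.cu_inhib_mM}" if r.cu_censored else r.cu_inhib_mM,
                "ploidy": r.ploidy,
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"record {rec.id}: non-ACGTN characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.upper()), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 ------------------------------------------------------------------
# Features are written 1-based inclusive per the GFF3 spec; the feature name
# travels in the ID attribute and the type in column 3.

def write_gff3(locus: LocusMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {locus.name} 1 {len(locus.sequence)}\n")
        for f in locus.features:
            first, last = to_external_coords(f.start, f.end)
            ftype = "ARS" if f.name.startswith("ARS") else "gene"
            if f.name == "EcoRI_site":
                ftype = "restriction_site"
            fh.write(
                "\t".join(
                    [
                        locus.name,
                        "cuparray",
                        ftype,
                        str(first),
                        str(last),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name}",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            start, end = to_internal_coords(int(cols[3]), int(cols[4]))
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("ID", cols[2])
            features.append(GeneFeature(name=name, start=start, end=end, strand=cols[6]))
    return features
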