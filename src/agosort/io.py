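"""Readers and writers for the external formats the pipeline touches.

All sequences are held internally as uppercase RNA (``ACGUN``); DNA input is
normalized on read (``T`` -> ``U``).  Coordinates are 0-based half-open
internally; GFF3 I/O converts to and from 1-based inclusive.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MiRNALocus:
    """A hairpin precursor with optional structure and mature-arm intervals.

    Arm intervals are half-open ``(start, end)`` in hairpin-local coordinates.
    """

    locus_id: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    hairpin_seq: str
    structure: Optional[str] = None
    arm5p: Optional[tuple[int, int]] = None
    arm3p: Optional[tuple[int, int]] = None
    energy_kcal_mol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -, got {self.strand!r}")
        self.hairpin_seq = normalize_rna(self.hairpin_seq)
        if not set(self.hairpin_seq) <= RNA_ALPHABET:
            raise ValueError(f"{self.locus_id}: hairpin has non-RNA characters")
        if self.structure is not None:
            if len(self.structure) != len(self.hairpin_seq):
                raise ValueError(
                    f"{self.locus_id}: structure length {len(self.structure)} != "
                    f"hairpin length {len(self.hairpin_seq)}"
                )
            _check_balanced(self.structure, self.locus_id)
        if self.arm5p is None and self.arm3p is None:
            raise ValueError(f"{self.locus_id}: at least one mature arm is required")
        n = len(self.hairpin_seq)
        for name, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if arm is None:
                continue
            s, e = arm
            if not (0 <= s < e <= n):
                raise ValueError(f"{self.locus_id}: {name} {arm} outside hairpin [0,{n})")
        if self.arm5p and self.arm3p and self.arm5p[1] > self.arm3p[0]:
            raise ValueError(f"{self.locus_id}: overlapping arms {self.arm5p}/{self.arm3p}")

    def arm_interval(self, arm: str) -> Optional[tuple[int, int]]:
        return self.arm5p if arm == "5p" else self.arm3p

    def arm_sequence(self, arm: str) -> Optional[str]:
        iv = self.arm_interval(arm)
        if iv is None:
            return None
        return self.hairpin_seq[iv[0]: iv[1]]

    def pair_table(self) -> list[Optional[int]]:
        """Partner index per hairpin position from the dot-bracket (None = unpaired)."""
        if self.structure is None:
            raise ValueError(f"{self.locus_id}: no structure available")
        return pair_table(self.structure)


@dataclass
class MatureStrand:
    """One mature strand of a hairpin locus."""

    strand_id: str
    locus_id: str
    arm: str  # '5p' or '3p'
    sequence: str
    star: str = "unassigned"  # 'miR', 'miR*', 'unassigned'

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.strand_id}: arm must be 5p or 3p")
        self.sequence = normalize_rna(self.sequence)
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(f"{self.strand_id}: mature length {len(self.sequence)} outside [15,30]")


@dataclass
class Library:
    """One sequencing library: pool type, time point, collapsed read multiset."""

    library_id: str
    pool: str  # 'total', 'ago1', 'ago2'
    time_h_pbm: int
    reads: dict[str, int] = field(default_factory=dict)

    VALID_POOLS = ("total", "ago1", "ago2")
    VALID_TIMES = (0, 12, 24, 36, 48, 72)

    def __post_init__(self) -> None:
        if self.pool not in self.VALID_POOLS:
            raise ValueError(f"{self.library_id}: unknown pool {self.pool!r}")
        if self.time_h_pbm not in self.VALID_TIMES:
            raise ValueError(f"{self.library_id}: unknown time point {self.time_h_pbm}")

    @property
    def total_count(self) -> int:
        return sum(self.reads.values())


BLAST6_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bit_score",
)


@dataclass
class BlastHit:
    """One record of BLAST tabular output (outfmt 6, standard 12 columns)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if not self.evalue >= 0.0 or self.evalue != self.evalue:
            raise ValueError(f"evalue must be finite and >= 0, got {self.evalue}")


# ---------------------------------------------------------------------------
# Dot-bracket helpers
# ---------------------------------------------------------------------------


def _check_balanced(structure: str, name: str = "structure") -> None:
    depth = 0
    for i, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"{name}: unbalanced ')' at position {i}")
        elif ch != ".":
            raise ValueError(f"{name}: invalid character {ch!r} at position {i}")
    if depth != 0:
        raise ValueError(f"{name}: {depth} unmatched '('")


def pair_table(structure: str) -> list[Optional[int]]:
    """Partner index per position, None where unpaired."""
    _check_balanced(structure)
    out: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            out[i], out[j] = j, i
    return out


# ---------------------------------------------------------------------------
# Collapsed FASTA
# ---------------------------------------------------------------------------

_COUNT_RE = re.compile(r"_x(\S+)$")


def read_collapsed_fasta(path) -> dict[str, int]:
    """Read collapsed small-RNA FASTA into a ``{sequence: count}`` multiset.

    Headers of the form ``id_x<count>`` carry a read count; plain headers
    default to count 1.  Sequences are normalized to RNA; duplicates merge.
    """
    reads: dict[str, int] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        m = _COUNT_RE.search(rec.id)
        if m:
            try:
                count = int(m.group(1))
            except ValueError:
                raise ParseError(f"{path}: record {rec.id!r}: malformed count {m.group(1)!r}")
            if count < 1:
                raise ParseError(f"{path}: record {rec.id!r}: count must be >= 1")
        else:
            count = 1
        seq = normalize_rna(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r}: empty sequence")
        if not set(seq) <= RNA_ALPHABET:
            raise ParseError(f"{path}: record {rec.id!r}: non-RNA characters in sequence")
        reads[seq] = reads.get(seq, 0) + count
    if n_records == 0:
        warnings.warn(f"{path}: empty collapsed FASTA", stacklevel=2)
    return reads


def read_fastq(path) -> dict[str, int]:
    """Read a FASTQ file into a ``{sequence: count}`` multiset.

    Qualities are ignored; downstream filtering drops reads containing N."""
    reads: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = normalize_rna(str(rec.seq))
        if seq:
            reads[seq] = reads.get(seq, 0) + 1
    return reads


def write_collapsed_fasta(reads: dict[str, int], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"r{i}_x{count}", description="")
        for i, (seq, count) in enumerate(sorted(reads.items()), start=1)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Coordinate mapping (genomic <-> hairpin-local)
# ---------------------------------------------------------------------------


def genomic_to_local(hp_start: int, hp_end: int, strand: str,
                     g_start: int, g_end: int) -> tuple[int, int]:
    """Map a genomic half-open interval into hairpin-local half-open coordinates.

    On the minus strand the hairpin sequence runs antiparallel to the genome,
    so intervals are reflected.
    """
    if not (hp_start <= g_start < g_end <= hp_end):
        raise ValueError(f"interval [{g_start},{g_end}) outside hairpin [{hp_start},{hp_end})")
    if strand == "+":
        return g_start - hp_start, g_end - hp_start
    return hp_end - g_end, hp_end - g_start


def local_to_genomic(hp_start: int, hp_end: int, strand: str,
                     l_start: int, l_end: int) -> tuple[int, int]:
    """Inverse of :func:`genomic_to_local`."""
    n = hp_end - hp_start
    if not (0 <= l_start < l_end <= n):
        raise ValueError(f"local interval [{l_start},{l_end}) outside [0,{n})")
    if strand == "+":
        return hp_start + l_start, hp_start + l_end
    return hp_end - l_end, hp_end - l_start


# ---------------------------------------------------------------------------
# Hairpin annotations (FASTA + GFF3 + optional Vienna)
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


_STRUCT_RE = re.compile(r"^([.()]+)(?:\s+\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_vienna(path) -> dict[str, tuple[str, Optional[float]]]:
    """Read a Vienna (RNAfold-style) file: ``>id`` / optional sequence /
    dot-bracket line with optional trailing ``(energy)``."""
    out: dict[str, tuple[str, Optional[float]]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                continue
            m = _STRUCT_RE.match(line.strip())
            if m and ("(" in m.group(1) or "." in m.group(1)):
                if current is None:
                    raise ParseError(f"{path}: structure line before any header")
                energy = float(m.group(2)) if m.group(2) is not None else None
                out[current] = (m.group(1), energy)
                continue
            # otherwise assume a sequence line; ignored (FASTA is authoritative)
    return out


def read_hairpin_annotations(fasta, gff3, vienna=None) -> list[MiRNALocus]:
    """Assemble :class:`MiRNALocus` records from a hairpin FASTA, a GFF3 of
    mature arms, and an optional Vienna structure file.

    GFF3 ``miRNA_primary_transcript`` records place hairpins on the genome;
    ``miRNA`` records with a matching ``Parent`` (or ``Derives_from``) define
    mature arms.  Genomic 1-based inclusive coordinates are converted to
    hairpin-local half-open intervals, reverse-mapped on the minus strand.
    """
    hairpins = {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")}
    structures = read_vienna(vienna) if vienna is not None else {}

    primaries: dict[str, dict] = {}
    matures: list[dict] = []
    with open(gff3) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{gff3}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr = fields
            attrs = _parse_gff3_attributes(attr)
            rec = {
                "chrom": chrom,
                "type": ftype,
                "start": int(start) - 1,  # to 0-based half-open
                "end": int(end),
                "strand": strand,
                "attrs": attrs,
                "lineno": lineno,
            }
            if ftype == "miRNA_primary_transcript":
                fid = attrs.get("ID") or attrs.get("Name")
                if fid is None:
                    raise ParseError(f"{gff3}:{lineno}: primary transcript without ID")
                primaries[fid] = rec
            elif ftype == "miRNA":
                matures.append(rec)

    loci: dict[str, dict] = {}
    for pid, rec in primaries.items():
        if pid not in hairpins:
            raise ParseError(f"{gff3}: hairpin {pid!r} not present in {fasta}")
        loci[pid] = {"rec": rec, "arm5p": None, "arm3p": None}

    for m in matures:
        parent = m["attrs"].get("Parent") or m["attrs"].get("Derives_from")
        if parent is None or parent not in loci:
            raise ParseError(f"{gff3}:{m['lineno']}: mature record without known Parent")
        p = loci[parent]["rec"]
        if m["chrom"] != p["chrom"] or m["strand"] != p["strand"]:
            raise ParseError(f"{gff3}:{m['lineno']}: mature not colocated with hairpin {parent}")
        try:
            local = genomic_to_local(p["start"], p["end"], p["strand"], m["start"], m["end"])
        except ValueError as exc:
            raise ParseError(f"{gff3}:{m['lineno']}: {exc}") from exc
        name = m["attrs"].get("Name", "")
        if name.endswith("-5p"):
            arm = "5p"
        elif name.endswith("-3p"):
            arm = "3p"
        else:
            # fall back to position: midpoint in the first half of the hairpin -> 5p
            hp_len = p["end"] - p["start"]
            arm = "5p" if (local[0] + local[1]) / 2 < hp_len / 2 else "3p"
        key = f"arm{arm}"
        if loci[parent][key] is not None:
            raise ParseError(f"{gff3}:{m['lineno']}: duplicate {arm} arm for {parent}")
        loci[parent][key] = local

    out: list[MiRNALocus] = []
    for pid, entry in loci.items():
        rec = entry["rec"]
        struct, energy = structures.get(pid, (None, None))
        seq = hairpins[pid]
        if struct is not None and len(struct) != len(seq):
            raise ParseError(f"{pid}: structure length {len(struct)} != hairpin length {len(seq)}")
        out.append(
            MiRNALocus(
                locus_id=pid,
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                strand=rec["strand"],
                hairpin_seq=seq,
                structure=struct,
                arm5p=entry["arm5p"],
                arm3p=entry["arm3p"],
                energy_kcal_mol=energy,
            )
        )
    return out


def write_hairpin_annotations(loci: Iterable[MiRNALocus], fasta, gff3, vienna=None) -> None:
    """Write hairpin FASTA, mature-arm GFF3, and optionally a Vienna file."""
    loci = list(loci)
    records = [SeqRecord(Seq(l.hairpin_seq), id=l.locus_id, description="") for l in loci]
    SeqIO.write(records, str(fasta), "fasta")

    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                "\t".join([
                    l.chrom, "agosort", "miRNA_primary_transcript",
                    str(l.start + 1), str(l.end), ".", l.strand, ".",
                    f"ID={l.locus_id};Name={l.locus_id}",
                ]) + "\n"
            )
            for arm in ("5p", "3p"):
                iv = l.arm_interval(arm)
                if iv is None:
                    continue
                gs, ge = local_to_genomic(l.start, l.end, l.strand, iv[0], iv[1])
                fh.write(
                    "\t".join([
                        l.chrom, "agosort", "miRNA",
                        str(gs + 1), str(ge), ".", l.strand, ".",
                        f"ID={l.locus_id}-{arm};Name={l.locus_id}-{arm};Parent={l.locus_id}",
                    ]) + "\n"
                )

    if vienna is not None:
        with open(vienna, "w") as fh:
            for l in loci:
                if l.structure is None:
                    continue
                fh.write(f">{l.locus_id}\n{l.hairpin_seq}\n{l.structure}")
                if l.energy_kcal_mol is not None:
                    fh.write(f" ({l.energy_kcal_mol:.2f})")
                fh.write("\n")


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------


def read_blast_tab6(path) -> list[BlastHit]:
    """Read standard 12-column BLAST tabular output."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Count-matrix TSV
# ---------------------------------------------------------------------------


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "strand_id") -> None:
    """Write a strand x library matrix as TSV; duplicate row ids are rejected."""
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids: {dups}")
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids: {dups}")
    return df
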