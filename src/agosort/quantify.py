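"""Read processing, hairpin-first alignment, category annotation and TPM.

The aligner is exact-match only: a read is assigned to a mature strand when
its maximal exact match to the hairpin starts within a small window around
the annotated mature 5' end and any unmatched 3' suffix is short enough to be
a non-template tail.  Template extension always takes precedence over calling
a tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import Library, MatureStrand, MiRNALocus, normalize_rna

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("miRNA", "repeats", "ncRNA", "mRNA", "unannotated")


@dataclass
class AlignPolicy:
    max_tail: int = 3
    max_offset5: int = 3
    arm_window: int = 3
    min_templated: int = 12
    seed_len: int = 10


@dataclass
class Assignment:
    """One read assigned to one mature strand."""

    sequence: str
    strand_id: Optional[str]
    offset5: int           # read 5' start minus annotated mature 5' (hairpin frame)
    templated_len: int     # exact-match length on the hairpin
    tail: str              # non-template 3' suffix
    weight: float = 1.0
    count: int = 1


# ---------------------------------------------------------------------------
# Read processing
# ---------------------------------------------------------------------------


def trim_adapter(reads: dict[str, int], adapter: str, min_overlap: int = 6) -> dict[str, int]:
    """Remove the leftmost exact match of the adapter prefix (>= ``min_overlap``
    nt, 0 mismatches) and everything 3' of it.  Reads without a match pass
    through unchanged; fully-adapter reads become empty and are dropped later
    by size selection."""
    adapter = normalize_rna(adapter)
    if len(adapter) < min_overlap:
        raise ValueError(f"adapter shorter than min overlap {min_overlap}")
    out: dict[str, int] = {}
    for seq, count in reads.items():
        cut = len(seq)
        for i in range(len(seq)):
            m = min(len(adapter), len(seq) - i)
            if m >= min_overlap and seq[i:i + m] == adapter[:m]:
                cut = i
                break
        trimmed = seq[:cut]
        out[trimmed] = out.get(trimmed, 0) + count
    return out


def size_select(reads: dict[str, int], min_len: int = 15, max_len: int = 30) -> dict[str, int]:
    """Keep reads with min_len <= length <= max_len (inclusive)."""
    if not (0 < min_len <= max_len):
        raise ValueError(f"invalid size range [{min_len},{max_len}]")
    return {s: c for s, c in reads.items() if min_len <= len(s) <= max_len}


def drop_n_reads(reads: dict[str, int]) -> dict[str, int]:
    """Minimal quality filter: discard reads containing N."""
    return {s: c for s, c in reads.items() if "N" not in s}


# ---------------------------------------------------------------------------
# Hairpin alignment
# ---------------------------------------------------------------------------


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


class HairpinIndex:
    """Seed index over the allowed alignment start positions of every arm."""

    def __init__(self, loci: Iterable[MiRNALocus], strands: Iterable[MatureStrand],
                 policy: Optional[AlignPolicy] = None):
        self.policy = policy or AlignPolicy()
        self.loci = {l.locus_id: l for l in loci}
        self.strands = list(strands)
        self._locus_of = {s.strand_id: s.locus_id for s in self.strands}
        self._seed: dict[str, list[tuple[str, int, int]]] = {}
        k = self.policy.seed_len
        for s in self.strands:
            locus = self.loci[s.locus_id]
            iv = locus.arm_interval(s.arm)
            if iv is None:
                continue
            for d in range(-self.policy.arm_window, self.policy.arm_window + 1):
                p = iv[0] + d
                if p < 0 or p + k > len(locus.hairpin_seq):
                    continue
                key = locus.hairpin_seq[p:p + k]
                self._seed.setdefault(key, []).append((s.strand_id, p, d))

    def match_read(self, seq: str) -> list[tuple[str, int, int, str]]:
        """All (strand_id, offset5, templated_len, tail) matches of one read.

        A match requires the whole read to decompose into an exact hairpin
        match from the candidate start plus a tail of length <= max_tail;
        the templated part is maximal (template extension precedence).  The
        best candidate per strand is kept (longest template, then smallest
        |offset|)."""
        pol = self.policy
        if len(seq) < pol.seed_len:
            return []
        best: dict[str, tuple[int, int, int, str]] = {}
        for strand_id, p, d in self._seed.get(seq[:pol.seed_len], ()):
            locus = self.loci[self._strand_locus(strand_id)]
            tl = _common_prefix_len(seq, locus.hairpin_seq[p:])
            tail = seq[tl:]
            if tl < pol.min_templated or len(tail) > pol.max_tail:
                continue
            if abs(d) > pol.max_offset5:
                continue
            prev = best.get(strand_id)
            cand = (-tl, abs(d), d, tail)
            if prev is None or cand < prev:
                best[strand_id] = cand
        return [(sid, d, -ntl, tail) for sid, (ntl, _ad, d, tail) in sorted(best.items())]

    def _strand_locus(self, strand_id: str) -> str:
        return self._locus_of[strand_id]


def align_to_hairpins(reads: dict[str, int], loci: list[MiRNALocus],
                      strands: list[MatureStrand],
                      policy: Optional[AlignPolicy] = None,
                      index: Optional[HairpinIndex] = None,
                      ) -> tuple[list[Assignment], dict[str, int]]:
    """Assign reads to mature strands; returns assignments and the unassigned
    read multiset.  Reads matching k > 1 strands get weight 1/k each."""
    idx = index or HairpinIndex(loci, strands, policy)
    assignments: list[Assignment] = []
    unassigned: dict[str, int] = {}
    for seq, count in reads.items():
        matches = idx.match_read(seq)
        if not matches:
            unassigned[seq] = unassigned.get(seq, 0) + count
            continue
        w = 1.0 / len(matches)
        for strand_id, d, tl, tail in matches:
            assignments.append(Assignment(seq, strand_id, d, tl, tail, w, count))
    return assignments, unassigned


def brute_force_align(reads: dict[str, int], loci: list[MiRNALocus],
                      strands: list[MatureStrand],
                      policy: Optional[AlignPolicy] = None,
                      ) -> tuple[list[Assignment], dict[str, int]]:
    """Exhaustive reference matcher: tries every (strand, offset, split) and
    applies the same policy.  Oracle for the indexed aligner; O(reads x
    strands x offsets x positions)."""
    pol = policy or AlignPolicy()
    loci_by_id = {l.locus_id: l for l in loci}
    assignments: list[Assignment] = []
    unassigned: dict[str, int] = {}
    for seq, count in reads.items():
        per_strand: dict[str, tuple] = {}
        for s in strands:
            locus = loci_by_id[s.locus_id]
            iv = locus.arm_interval(s.arm)
            if iv is None:
                continue
            for d in range(-pol.arm_window, pol.arm_window + 1):
                if abs(d) > pol.max_offset5:
                    continue
                p = iv[0] + d
                if p < 0 or p >= len(locus.hairpin_seq):
                    continue
                # every split into templated prefix + tail, maximal template first
                for tl in range(len(seq), -1, -1):
                    if seq[:tl] != locus.hairpin_seq[p:p + tl]:
                        continue
                    tail = seq[tl:]
                    if tl >= pol.min_templated and len(tail) <= pol.max_tail:
                        cand = (-tl, abs(d), d, tail)
                        prev = per_strand.get(s.strand_id)
                        if prev is None or cand < prev:
                            per_strand[s.strand_id] = cand
                    break  # tl is maximal for this start; shorter splits are tails
        if not per_strand:
            unassigned[seq] = unassigned.get(seq, 0) + count
            continue
        w = 1.0 / len(per_strand)
        for sid, (ntl, _ad, d, tail) in sorted(per_strand.items()):
            assignments.append(Assignment(seq, sid, d, -ntl, tail, w, count))
    return assignments, unassigned


# ---------------------------------------------------------------------------
# Category annotation
# ---------------------------------------------------------------------------


def annotate_categories(unassigned: dict[str, int],
                        feature_tracks: Optional[dict[str, set[str]]] = None,
                        ) -> dict[str, int]:
    """Assign each unassigned read to the first matching category of the fixed
    cascade repeats > ncRNA > mRNA > unannotated (miRNA was consumed by the
    aligner)."""
    tracks = feature_tracks or {}
    totals = {c: 0 for c in CATEGORY_ORDER if c != "miRNA"}
    for seq, count in unassigned.items():
        for cat in ("repeats", "ncRNA", "mRNA"):
            if seq in tracks.get(cat, ()):
                totals[cat] += count
                break
        else:
            totals["unannotated"] += count
    return totals


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Mature-strand x library counts with per-library category tallies.

    ``category_totals`` rows are libraries, columns are non-miRNA categories;
    the miRNA total is the (weighted) column sum of ``raw``.
    """

    raw: pd.DataFrame
    category_totals: pd.DataFrame
    tpm: Optional[pd.DataFrame] = None
    libraries: dict[str, Library] = field(default_factory=dict)

    def mapped_totals(self) -> pd.Series:
        """Mapped reads per library: miRNA-assigned plus all annotated and
        unannotated genome-mapped categories."""
        mirna = self.raw.sum(axis=0)
        other = self.category_totals.reindex(self.raw.columns).fillna(0).sum(axis=1)
        return mirna + other


def count_assignments(assignments_by_lib: dict[str, list[Assignment]],
                      categories_by_lib: dict[str, dict[str, int]],
                      strand_ids: list[str],
                      libraries: Optional[dict[str, Library]] = None,
                      ) -> CountMatrix:
    """Aggregate weighted assignments into a strand x library matrix."""
    lib_ids = list(assignments_by_lib)
    raw = pd.DataFrame(0.0, index=strand_ids, columns=lib_ids)
    for lib_id, assignments in assignments_by_lib.items():
        for a in assignments:
            raw.loc[a.strand_id, lib_id] += a.weight * a.count
    cats = pd.DataFrame(categories_by_lib).T.reindex(lib_ids).fillna(0).astype(int)
    return CountMatrix(raw=raw, category_totals=cats, libraries=libraries or {})


def compute_tpm(matrix: CountMatrix) -> CountMatrix:
    """TPM per strand: raw / mapped_total * 1e6.

    The denominator is all genome-mapped reads in the library (miRNA plus
    other categories, excluding unmapped)."""
    totals = matrix.mapped_totals()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"mapped total is zero for libraries: {bad}")
    matrix.tpm = matrix.raw.div(totals, axis=1) * 1e6
    return matrix


def filter_low_abundance(matrix: CountMatrix, threshold: float = 20.0) -> CountMatrix:
    """Retain a strand iff TPM >= threshold in at least one library."""
    if matrix.tpm is None:
        raise ValueError("TPM not computed; call compute_tpm first")
    keep = (matrix.tpm >= threshold).any(axis=1)
    logger.info("abundance filter (TPM >= %s): retained %d of %d strands",
                threshold, int(keep.sum()), len(keep))
    return CountMatrix(
        raw=matrix.raw.loc[keep],
        category_totals=matrix.category_totals,
        tpm=matrix.tpm.loc[keep],
        libraries=matrix.libraries,
    )


def mirna_percent(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-library percentage of miRNA reads per strand (columns sum to 100).

    The sorting analysis compares strands across pools with very different
    miRNA content, so it normalizes within the miRNA fraction of each library
    rather than against all mapped reads."""
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library with zero miRNA reads")
    return raw.div(totals, axis=1) * 100.0


def length_histogram(reads: dict[str, int]) -> dict[int, float]:
    """Read-length distribution as fractions summing to 1."""
    if not reads:
        return {}
    counts: dict[int, int] = {}
    for seq, c in reads.items():
        counts[len(seq)] = counts.get(len(seq), 0) + c
    total = sum(counts.values())
    return {l: counts[l] / total for l in sorted(counts)}


def quantify_libraries(libraries: list[Library], loci: list[MiRNALocus],
                       strands: list[MatureStrand],
                       adapter: Optional[str] = None,
                       min_len: int = 15, max_len: int = 30,
                       tracks: Optional[dict[str, set[str]]] = None,
                       policy: Optional[AlignPolicy] = None,
                       ) -> tuple[CountMatrix, dict[str, list[Assignment]]]:
    """End-to-end per-library pass: trim, size-select, align, categorize,
    count, TPM-normalize."""
    index = HairpinIndex(loci, strands, policy)
    assignments_by_lib: dict[str, list[Assignment]] = {}
    categories_by_lib: dict[str, dict[str, int]] = {}
    for lib in libraries:
        reads = lib.reads
        if adapter:
            reads = trim_adapter(reads, adapter)
        reads = drop_n_reads(size_select(reads, min_len, max_len))
        assignments, unassigned = align_to_hairpins(reads, loci, strands,
                                                    policy, index=index)
        assignments_by_lib[lib.library_id] = assignments
        categories_by_lib[lib.library_id] = annotate_categories(unassigned, tracks)
    matrix = count_assignments(assignments_by_lib, categories_by_lib,
                               [s.strand_id for s in strands],
                               {lib.library_id: lib for lib in libraries})
    return compute_tpm(matrix), assignments_by_lib
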