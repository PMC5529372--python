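"""Sequence-variant (iso-miR) taxonomy.

Each assigned read is classified independently at its 5' and 3' ends relative
to a per-strand reference isoform (the most abundant read sequence over all
libraries).  5' classes: canonical or template shifts of 1-3 nt.  3' classes:
canonical, template shifts (+k), template trims (-k), or non-template
additions of 1, 2, or >=3 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .io import MatureStrand, MiRNALocus
from .quantify import Assignment

logger = logging.getLogger(__name__)

CLASS5 = ("canonical", "template_shift_-3", "template_shift_-2", "template_shift_-1",
          "template_shift_+1", "template_shift_+2", "template_shift_+3",
          "unclassified")
CLASS3 = ("canonical", "template_shift_+1", "template_shift_+2", "template_shift_+3",
          "trim_1", "trim_2", "trim_3",
          "nontemplate_add_1", "nontemplate_add_2", "nontemplate_add_3plus",
          "unclassified")


@dataclass
class IsomirRecord:
    strand_id: str
    library_id: str
    class5: str
    class3: str
    tail_seq: str
    count: float  # weighted


@dataclass
class Reference:
    """Classification reference for one strand: the most abundant isoform."""

    strand_id: str
    sequence: str
    offset5: int        # relative to the annotated mature 5' end
    templated_len: int
    tail: str


def choose_reference(assignments: Iterable[Assignment]) -> Reference:
    """Pick the single most abundant read sequence (summed weighted counts,
    all libraries pooled) as the reference; ties go to the longer sequence,
    then lexicographic order."""
    totals: dict[str, float] = {}
    rep: dict[str, Assignment] = {}
    for a in assignments:
        totals[a.sequence] = totals.get(a.sequence, 0.0) + a.weight * a.count
        rep.setdefault(a.sequence, a)
    if not totals:
        raise ValueError("no assignments to choose a reference from")
    best = max(totals, key=lambda s: (totals[s], len(s), [-ord(c) for c in s]))
    a = rep[best]
    return Reference(a.strand_id, a.sequence, a.offset5, a.templated_len, a.tail)


def classify_assignment(a: Assignment, reference: Reference,
                        library_id: str = "") -> IsomirRecord:
    """Classify both ends of one assigned read against the strand reference."""
    d5 = a.offset5 - reference.offset5
    if d5 == 0:
        class5 = "canonical"
    elif abs(d5) <= 3:
        class5 = f"template_shift_{d5:+d}"
    else:
        class5 = "unclassified"

    # templated 3' end positions in the hairpin frame
    end_read = a.offset5 + a.templated_len
    end_ref = reference.offset5 + reference.templated_len
    d3 = end_read - end_ref
    if a.tail:
        n = len(a.tail)
        class3 = ("nontemplate_add_1" if n == 1 else
                  "nontemplate_add_2" if n == 2 else "nontemplate_add_3plus")
    elif d3 == 0:
        class3 = "canonical"
    elif 0 < d3 <= 3:
        class3 = f"template_shift_+{d3}"
    elif -3 <= d3 < 0:
        class3 = f"trim_{-d3}"
    else:
        class3 = "unclassified"
    return IsomirRecord(a.strand_id, library_id, class5, class3, a.tail,
                        a.weight * a.count)


def classify_libraries(assignments_by_lib: dict[str, list[Assignment]],
                       references: Optional[dict[str, Reference]] = None,
                       ) -> tuple[list[IsomirRecord], dict[str, Reference]]:
    """Classify every assignment in every library against global references."""
    if references is None:
        pooled: dict[str, list[Assignment]] = {}
        for assignments in assignments_by_lib.values():
            for a in assignments:
                pooled.setdefault(a.strand_id, []).append(a)
        references = {sid: choose_reference(assigns) for sid, assigns in pooled.items()}
    records: list[IsomirRecord] = []
    for lib_id, assignments in assignments_by_lib.items():
        for a in assignments:
            ref = references.get(a.strand_id)
            if ref is None:
                continue
            records.append(classify_assignment(a, ref, lib_id))
    return records, references


def brute_force_classify(read: str, locus: MiRNALocus, strand: MatureStrand,
                         reference: Reference, max_tail: int = 3,
                         arm_window: int = 3) -> tuple[str, str]:
    """Oracle classifier: enumerate every split of the read into a templated
    prefix (exact hairpin match starting in the arm window) plus a 3' tail,
    apply template precedence, then derive both end classes directly."""
    iv = locus.arm_interval(strand.arm)
    hp = locus.hairpin_seq
    best = None  # (templated_len desc, |offset| asc)
    for d in range(-arm_window, arm_window + 1):
        p = iv[0] + d
        if p < 0 or p >= len(hp):
            continue
        tl = 0
        while tl < len(read) and p + tl < len(hp) and read[tl] == hp[p + tl]:
            tl += 1
        if len(read) - tl > max_tail:
            continue
        cand = (-tl, abs(d), d)
        if best is None or cand < best:
            best = cand
    if best is None:
        return "unclassified", "unclassified"
    _, _, d = best
    tl = -best[0]
    a = Assignment(read, strand.strand_id, d, tl, read[tl:], 1.0, 1)
    rec = classify_assignment(a, reference)
    return rec.class5, rec.class3


def isomir_summary(records: Iterable[IsomirRecord]) -> pd.DataFrame:
    """Per-library fraction of each (class5, class3) among miRNA-assigned
    reads; fractions sum to 1 per library."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    grouped = df.groupby(["library_id", "class5", "class3"])["count"].sum().reset_index()
    totals = grouped.groupby("library_id")["count"].transform("sum")
    grouped["fraction"] = grouped["count"] / totals
    return grouped


def class3_fraction(records: Iterable[IsomirRecord], library_id: str,
                    class3: str) -> float:
    """Weighted fraction of one 3' class in one library."""
    tot = 0.0
    hit = 0.0
    for r in records:
        if r.library_id != library_id:
            continue
        tot += r.count
        if r.class3 == class3:
            hit += r.count
    return hit / tot if tot else float("nan")


def per_strand_pool_breakdown(records: Iterable[IsomirRecord],
                              pool_of: dict[str, str]) -> pd.DataFrame:
    """Per-strand, per-pool 3'-class fractions (length-divergence analog)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return df
    df["pool"] = df["library_id"].map(pool_of)
    grouped = df.groupby(["strand_id", "pool", "class3"])["count"].sum().reset_index()
    totals = grouped.groupby(["strand_id", "pool"])["count"].transform("sum")
    grouped["fraction"] = grouped["count"] / totals
    return grouped
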