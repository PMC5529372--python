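"""Novel-miRNA candidate retention filters and reciprocal-best-hit ortholog
calling.

Hairpin prediction and BLAST themselves are upstream: this module consumes
candidate tables (with precomputed hairpin free energies) and BLAST tabular
hit files and applies the retention logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import BlastHit, pair_table

logger = logging.getLogger(__name__)

ALL_RULES = ("predictors", "read_support", "energy", "arm_fraction")


@dataclass
class CandidateHairpin:
    """One predicted hairpin with its evidence for the retention filters."""

    candidate_id: str
    hairpin_seq: str = ""
    structure: Optional[str] = None
    energy_kcal_mol: float = 0.0
    ago_ip_counts: dict[str, int] = field(default_factory=dict)  # library -> perfect-match reads
    arm_read_fraction: float = 1.0
    predicted_by: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.energy_kcal_mol > 0:
            raise ValueError(f"{self.candidate_id}: hairpin energy must be <= 0")
        if not 0.0 <= self.arm_read_fraction <= 1.0:
            raise ValueError(f"{self.candidate_id}: arm_read_fraction outside [0,1]")
        self.predicted_by = frozenset(self.predicted_by)


def stable_hairpin(candidate: CandidateHairpin, energy_max: float = -20.0,
                   min_paired: int = 15) -> bool:
    """Stability check: energy below threshold, and when a structure is given,
    a balanced dot-bracket with at least ``min_paired`` paired positions."""
    if not candidate.energy_kcal_mol < energy_max:
        return False
    if candidate.structure is not None:
        pt = pair_table(candidate.structure)
        if sum(1 for x in pt if x is not None) // 2 < min_paired:
            return False
    return True


def filter_novel_candidates(candidates: Iterable[CandidateHairpin],
                            min_reads: int = 20, min_libs: int = 2,
                            energy_max: float = -20.0,
                            arm_fraction_min: float = 0.9,
                            rules: Sequence[str] = ALL_RULES) -> pd.DataFrame:
    """Apply the retention rules; every failing candidate lists all violated
    rules.

    Rules: >=2 independent predictors; >= ``min_reads`` perfectly aligned
    reads in >= ``min_libs`` Ago-IP libraries ("more than one" is strict, so
    the default is 2); hairpin energy strictly below ``energy_max`` kcal/mol;
    arm read fraction >= ``arm_fraction_min``.  ``rules`` selects which are
    enforced.
    """
    unknown = set(rules) - set(ALL_RULES)
    if unknown:
        raise ValueError(f"unknown rules: {sorted(unknown)}")
    rows = []
    for c in candidates:
        reasons = []
        if "predictors" in rules and len(c.predicted_by) < 2:
            reasons.append("predictors")
        if "read_support" in rules:
            n_support = sum(1 for v in c.ago_ip_counts.values() if v >= min_reads)
            if n_support < min_libs:
                reasons.append("read_support")
        if "energy" in rules and not stable_hairpin(c, energy_max):
            reasons.append("energy")
        if "arm_fraction" in rules and c.arm_read_fraction < arm_fraction_min:
            reasons.append("arm_fraction")
        rows.append({
            "candidate_id": c.candidate_id,
            "energy_kcal_mol": c.energy_kcal_mol,
            "passed": not reasons,
            "failed_rules": ",".join(reasons),
        })
    df = pd.DataFrame(rows).set_index("candidate_id")
    logger.info("novel-candidate filter: %d of %d retained (rules: %s)",
                int(df["passed"].sum()), len(df), ",".join(rules))
    return df


def load_published_candidates() -> pd.DataFrame:
    """Published An. gambiae novel-miRNA candidate table (coordinates, mature
    sequences and hairpin free energies), shipped with the package."""
    with resources.files("agosort.data").joinpath("novel_mirna_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_candidates_as_hairpins() -> list[CandidateHairpin]:
    df = load_published_candidates()
    return [
        CandidateHairpin(candidate_id=row.candidate_id,
                         energy_kcal_mol=float(row.energy_kcal_mol))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------


@dataclass
class OrthologCall:
    query_id: str
    target_genome: str
    status: str  # 'found' or 'not_found'
    best_identity: Optional[float] = None
    best_evalue: Optional[float] = None
    reciprocal: bool = False


def _top_hit(hits: list[BlastHit]) -> Optional[BlastHit]:
    """Lowest e-value, ties by higher identity, then subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.pct_identity, h.subject_id))


def reciprocal_best_hit(forward: Iterable[BlastHit], reverse: Iterable[BlastHit],
                        target_genome: str, id_min: float = 80.0,
                        e_max: float = 0.1) -> list[OrthologCall]:
    """RBH ortholog calls for one target genome.

    ``forward`` holds query-vs-target hits; ``reverse`` holds target-locus-vs-
    query-genome hits.  A query is ``found`` iff its forward top hit passes
    identity >= ``id_min`` and e-value <= ``e_max``, and the reverse top hit of
    that subject locus maps back to the query and passes both thresholds.
    """
    fwd_by_query: dict[str, list[BlastHit]] = {}
    for h in forward:
        fwd_by_query.setdefault(h.query_id, []).append(h)
    rev_by_query: dict[str, list[BlastHit]] = {}
    for h in reverse:
        rev_by_query.setdefault(h.query_id, []).append(h)

    calls = []
    for query, hits in sorted(fwd_by_query.items()):
        top = _top_hit(hits)
        call = OrthologCall(query, target_genome, "not_found",
                            top.pct_identity if top else None,
                            top.evalue if top else None)
        if top and top.pct_identity >= id_min and top.evalue <= e_max:
            back = _top_hit(rev_by_query.get(top.subject_id, []))
            if (back is not None and back.subject_id == query
                    and back.pct_identity >= id_min and back.evalue <= e_max):
                call.status = "found"
                call.reciprocal = True
        calls.append(call)
    return calls


def conservation_matrix(calls: Iterable[OrthologCall],
                        queries: Optional[Sequence[str]] = None,
                        genomes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Presence/absence table (miRNAs x genomes) with 'x' / '-' analog values;
    (miRNA, genome) pairs without a call are 'untested'."""
    calls = list(calls)
    qs = list(queries) if queries is not None else sorted({c.query_id for c in calls})
    gs = list(genomes) if genomes is not None else sorted({c.target_genome for c in calls})
    mat = pd.DataFrame("untested", index=qs, columns=gs)
    for c in calls:
        if c.query_id in mat.index and c.target_genome in mat.columns:
            mat.loc[c.query_id, c.target_genome] = "x" if c.status == "found" else "-"
    mat["n_genomes_found"] = (mat[gs] == "x").sum(axis=1)
    return mat
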