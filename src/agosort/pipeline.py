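"""End-to-end pipeline: simulate -> quantify -> sort -> isomir -> de, plus a
ground-truth recovery report used by the demo command."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import diffexp, isomir, quantify, sorting
from .io import Library, MatureStrand, MiRNALocus
from .simulate import GroundTruth, SimulationParams, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    loci: list[MiRNALocus]
    strands: list[MatureStrand]
    libraries: list[Library]
    truth: GroundTruth
    matrix: quantify.CountMatrix
    star_labels: dict[str, str]
    sorting_table: pd.DataFrame
    star_enrichment: pd.DataFrame
    isomir_records: list = field(default_factory=list)
    de: Optional[pd.DataFrame] = None
    clusters: Optional[pd.DataFrame] = None


def pool_columns(matrix: quantify.CountMatrix, pool: str) -> list[str]:
    return [lib_id for lib_id, lib in matrix.libraries.items() if lib.pool == pool]


def run_synthetic_pipeline(params: SimulationParams, de_alpha: float = 0.01,
                           fold_cut: float = 4.0, n_clusters: int = 3,
                           ) -> PipelineResult:
    """Generate data and run every analysis stage on it."""
    loci, strands, libraries, truth = simulate(params)
    logger.info("simulated %d loci, %d libraries", len(loci), len(libraries))

    matrix, assignments_by_lib = quantify.quantify_libraries(libraries, loci, strands)
    strand_locus = {s.strand_id: s.locus_id for s in strands}
    strand_arm = {s.strand_id: s.arm for s in strands}

    total_cols = pool_columns(matrix, "total")
    ago1_cols = pool_columns(matrix, "ago1")
    ago2_cols = pool_columns(matrix, "ago2")

    # restrict curation to strands actually detected in the total pool
    detected = matrix.tpm[total_cols].sum(axis=1) > 0
    star_labels = sorting.curate_strands(
        matrix.tpm.loc[detected, total_cols],
        {sid: strand_locus[sid] for sid in matrix.tpm.index[detected]},
        {sid: strand_arm[sid] for sid in matrix.tpm.index[detected]},
    )

    # Ago partition on within-library miRNA percentages: the pools differ
    # hugely in miRNA content, which all-mapped TPM would fold into every
    # strand's apparent Ago fraction
    pct = quantify.mirna_percent(matrix.raw)
    sorting_table = sorting.partition_fractions(
        pct[ago1_cols], pct[ago2_cols], star_labels)
    star_enrichment = sorting.per_strand_star_enrichment(
        matrix.raw[ago2_cols], matrix.raw[total_cols], star_labels)

    records, _refs = isomir.classify_libraries(assignments_by_lib)

    design = pd.DataFrame(
        {"pool": [lib.pool for lib in libraries],
         "time_h": [lib.time_h_pbm for lib in libraries]},
        index=[lib.library_id for lib in libraries])
    de = diffexp.de_table(matrix.raw, design, alpha=de_alpha, fold_cut=fold_cut)
    fc_total = diffexp.log2fc_matrix(de, "total")
    clusters = diffexp.cluster_profiles(fc_total, k=n_clusters) if len(fc_total) >= 2 else None

    return PipelineResult(loci, strands, libraries, truth, matrix, star_labels,
                          sorting_table, star_enrichment, records, de, clusters)


# ---------------------------------------------------------------------------
# Recovery metrics against ground truth
# ---------------------------------------------------------------------------


def star_label_accuracy(result: PipelineResult, min_ratio: float = 4.0) -> float:
    """Fraction of correctly recovered miR/miR* labels among strands whose true
    arm abundance ratio is at least ``min_ratio``."""
    truth = result.truth.strands
    eligible = truth.index[(truth["arm_ratio"] >= min_ratio) |
                           (truth["arm_ratio"] <= 1.0 / min_ratio)]
    scored = [sid for sid in eligible if sid in result.star_labels]
    if not scored:
        return float("nan")
    correct = sum(result.star_labels[sid] == truth.loc[sid, "star"] for sid in scored)
    return correct / len(scored)


def mono_addition_fraction(result: PipelineResult, pool: str) -> float:
    """Mean per-library fraction of 1-nt non-template 3' additions among
    miRNA-assigned reads in one pool."""
    libs = pool_columns(result.matrix, pool)
    fracs = [isomir.class3_fraction(result.isomir_records, lib, "nontemplate_add_1")
             for lib in libs]
    return float(np.nanmean(fracs))


def star_fraction_by_pool(result: PipelineResult, pool: str) -> float:
    cols = pool_columns(result.matrix, pool)
    return sorting.star_fraction(result.matrix.raw[cols], result.star_labels)


def ago_bias_sign_recovery(result: PipelineResult) -> dict[str, bool]:
    """Direction checks for every configured Ago bias."""
    truth = result.truth.strands
    tab = result.sorting_table.join(truth[["five_prime_U", "five_prime_C",
                                           "mismatch_pos9", "mismatch_3prime_end"]])
    tab = tab.dropna(subset=["ago1_fraction"])
    checks: dict[str, bool] = {}
    seqs = {s.strand_id: s.sequence for s in result.strands}
    detected = [sid for sid in tab.index]
    background = [seqs[sid] for sid in detected]
    ago1_set = [seqs[sid] for sid in tab.index[tab["bias"] == "ago1"]]
    ago2_set = [seqs[sid] for sid in tab.index[tab["bias"] == "ago2"]]
    if ago1_set and background:
        f_u, bg_u, _ = sorting.position1_bias_test(ago1_set, background, "U")
        checks["ago1_5prime_U"] = f_u > bg_u
    if ago2_set and background:
        f_c, bg_c, _ = sorting.position1_bias_test(ago2_set, background, "C")
        checks["ago2_5prime_C"] = f_c > bg_c
    star_rows = tab[tab["star"] == "miR*"]
    nonstar_rows = tab[tab["star"] == "miR"]
    if len(star_rows) and len(nonstar_rows):
        checks["star_to_ago2"] = (star_rows["ago1_fraction"].mean()
                                  < nonstar_rows["ago1_fraction"].mean())
    for feat, key in (("mismatch_pos9", "mismatch_pos9_to_ago1"),
                      ("mismatch_3prime_end", "mismatch_3prime_to_ago2")):
        w = tab[tab[feat]]
        wo = tab[~tab[feat].astype(bool)]
        if len(w) and len(wo):
            direction = w["ago1_fraction"].mean() > wo["ago1_fraction"].mean()
            checks[key] = direction if key.endswith("ago1") else not direction
    return checks


def cluster_recovery(result: PipelineResult, onset_h: int) -> dict:
    """Did the planted cluster get flagged up at all post-onset time points in
    the total pool, and does it co-cluster?"""
    truth = result.truth
    cluster_strands = [
        sid for sid in result.matrix.raw.index
        if truth.strands.loc[sid, "locus_id"] in truth.cluster_loci
        and truth.strands.loc[sid, "star"] == "miR"
    ]
    de_total = result.de[result.de["pool"] == "total"].set_index(["strand_id", "time_h"])
    post_onset = [t for t in (12, 24, 36, 48, 72) if t >= onset_h]
    flagged = all(
        de_total.loc[(sid, t), "flag4x"] == "up"
        for sid in cluster_strands for t in post_onset
        if (sid, t) in de_total.index
    ) and bool(cluster_strands)
    co_cluster = False
    if result.clusters is not None and cluster_strands:
        present = [s for s in cluster_strands if s in result.clusters.index]
        if present:
            labels = result.clusters.loc[present, "cluster"]
            co_cluster = labels.nunique() == 1
    return {"cluster_strands": cluster_strands, "flagged_up_all_post_onset": flagged,
            "co_clustered": co_cluster}


def recovery_report(result: PipelineResult, params: SimulationParams) -> pd.DataFrame:
    """Flat metric table written by the demo command."""
    rows = [
        ("star_label_accuracy_ratio_ge4", star_label_accuracy(result, 4.0)),
        ("mono_add_fraction_ago2", mono_addition_fraction(result, "ago2")),
        ("mono_add_fraction_total", mono_addition_fraction(result, "total")),
        ("star_fraction_total", star_fraction_by_pool(result, "total")),
        ("star_fraction_ago1", star_fraction_by_pool(result, "ago1")),
        ("star_fraction_ago2", star_fraction_by_pool(result, "ago2")),
    ]
    for name, ok in ago_bias_sign_recovery(result).items():
        rows.append((f"bias_direction_{name}", float(ok)))
    onset = int(params.upregulated_cluster.get("onset_h", 12))
    cl = cluster_recovery(result, onset)
    rows.append(("cluster_flagged_up_all_post_onset", float(cl["flagged_up_all_post_onset"])))
    rows.append(("cluster_co_clustered", float(cl["co_clustered"])))
    return pd.DataFrame(rows, columns=["metric", "value"]).set_index("metric")
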