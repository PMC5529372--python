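"""miR/miR* curation, Ago1/Ago2 partition fractions, star-strand enrichment
testing, and structural determinant profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MatureStrand, MiRNALocus, pair_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# miR / miR* curation
# ---------------------------------------------------------------------------


def curate_strands(total_tpm: pd.DataFrame, strand_locus: dict[str, str],
                   strand_arm: Optional[dict[str, str]] = None) -> dict[str, str]:
    """Annotate miR/miR* from mean abundance in the total pool.

    For loci with two detected strands the higher time-point-mean TPM strand
    is miR and the other miR*; single-strand loci are miR.  Exact ties go to
    the 5p arm.  Invariant to library order and to uniform scaling.
    """
    means = total_tpm.mean(axis=1)
    by_locus: dict[str, list[str]] = {}
    for sid in total_tpm.index:
        by_locus.setdefault(strand_locus[sid], []).append(sid)
    arm_of = strand_arm or {sid: ("5p" if sid.endswith("5p") else "3p")
                            for sid in total_tpm.index}
    labels: dict[str, str] = {}
    for locus, sids in by_locus.items():
        if len(sids) == 1:
            labels[sids[0]] = "miR"
            continue
        if len(sids) != 2:
            raise ValueError(f"locus {locus} has {len(sids)} strands; expected 1 or 2")
        a, b = sids
        ma, mb = means[a], means[b]
        if ma == mb:  # tie-break: 5p wins
            winner = a if arm_of[a] == "5p" else b
        else:
            winner = a if ma > mb else b
        loser = b if winner == a else a
        labels[winner] = "miR"
        labels[loser] = "miR*"
    return labels


# ---------------------------------------------------------------------------
# Ago partition
# ---------------------------------------------------------------------------


@dataclass
class SortingResult:
    strand_id: str
    star: str
    ago1_tpm_mean: float
    ago2_tpm_mean: float
    ago1_fraction: Optional[float]
    bias: str  # 'ago1', 'ago2', 'none'
    star_enrichment_p: Optional[float] = None
    star_enrichment_q: Optional[float] = None


def partition_fractions(ago1_tpm: pd.DataFrame, ago2_tpm: pd.DataFrame,
                        star_labels: dict[str, str],
                        bias_threshold: float = 0.70) -> pd.DataFrame:
    """Per-strand Ago1 fraction from time-point-mean TPM and the resulting
    bias call: ago1 if fraction > threshold, ago2 if < 1-threshold."""
    if not ago1_tpm.index.equals(ago2_tpm.index):
        raise ValueError("Ago1 and Ago2 matrices must share the same strand universe")
    m1 = ago1_tpm.mean(axis=1)
    m2 = ago2_tpm.mean(axis=1)
    rows = []
    for sid in ago1_tpm.index:
        a1, a2 = float(m1[sid]), float(m2[sid])
        if a1 + a2 > 0:
            frac = a1 / (a1 + a2)
            if frac > bias_threshold:
                bias = "ago1"
            elif 1.0 - frac > bias_threshold:
                bias = "ago2"
            else:
                bias = "none"
        else:
            frac, bias = np.nan, "none"
        rows.append({
            "strand_id": sid,
            "star": star_labels.get(sid, "unassigned"),
            "ago1_tpm_mean": a1,
            "ago2_tpm_mean": a2,
            "ago1_fraction": frac,
            "bias": bias,
        })
    return pd.DataFrame(rows).set_index("strand_id")


# ---------------------------------------------------------------------------
# miR* enrichment (Fisher's exact, one-sided)
# ---------------------------------------------------------------------------


def star_enrichment_test(star_count: int, nonstar_count: int,
                         star_count_ref: int, nonstar_count_ref: int) -> float:
    """One-sided Fisher's exact p for star over-representation in the Ago pool
    relative to the total-pool reference."""
    for v in (star_count, nonstar_count, star_count_ref, nonstar_count_ref):
        if v < 0:
            raise ValueError("counts must be non-negative")
    table = [[star_count, nonstar_count], [star_count_ref, nonstar_count_ref]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def per_strand_star_enrichment(ago_raw: pd.DataFrame, total_raw: pd.DataFrame,
                               star_labels: dict[str, str],
                               alpha: float = 0.01) -> pd.DataFrame:
    """Per-miR*-strand enrichment in an Ago pool: that strand's reads versus
    all other miRNA reads, Ago pool against total pool, one-sided Fisher with
    BH q-values; the significance flag uses the raw p threshold."""
    ago_sum = ago_raw.sum(axis=1)
    tot_sum = total_raw.sum(axis=1)
    ago_all = float(ago_sum.sum())
    tot_all = float(tot_sum.sum())
    stars = [sid for sid in ago_raw.index if star_labels.get(sid) == "miR*"]
    rows = []
    for sid in stars:
        k_ago = int(round(ago_sum[sid]))
        k_tot = int(round(tot_sum[sid]))
        p = star_enrichment_test(k_ago, int(round(ago_all)) - k_ago,
                                 k_tot, int(round(tot_all)) - k_tot)
        rows.append({"strand_id": sid, "ago_count": k_ago, "total_count": k_tot, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["p"] <= alpha
        df = df.set_index("strand_id")
    return df


def star_fraction(raw: pd.DataFrame, star_labels: dict[str, str]) -> float:
    """Fraction of miRNA reads belonging to miR* strands."""
    total = float(raw.to_numpy().sum())
    if total == 0:
        return float("nan")
    star_rows = [sid for sid in raw.index if star_labels.get(sid) == "miR*"]
    return float(raw.loc[star_rows].to_numpy().sum()) / total


# ---------------------------------------------------------------------------
# Nucleotide composition (Fig-3a-style)
# ---------------------------------------------------------------------------


def nt_composition(sequences: Iterable[str], max_pos: int = 22) -> pd.DataFrame:
    """Per-position nucleotide frequencies over 5'-aligned sequences.

    Positions are 1-based; positions beyond a sequence's length are skipped,
    so each row sums to 1 over the sequences that reach it."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    rows = []
    for pos in range(1, max_pos + 1):
        counts = {b: 0 for b in "ACGU"}
        n = 0
        for s in seqs:
            if len(s) >= pos and s[pos - 1] in counts:
                counts[s[pos - 1]] += 1
                n += 1
        if n == 0:
            continue
        rows.append({"position": pos, **{b: counts[b] / n for b in "ACGU"}, "n": n})
    return pd.DataFrame(rows).set_index("position")


def position1_bias_test(sequences: Iterable[str], background: Iterable[str],
                        base: str) -> tuple[float, float, float]:
    """Exact two-sided binomial test of the first-nucleotide frequency of a
    biased set against the background frequency of all detected miRNAs.

    Returns (observed frequency, background frequency, p)."""
    seqs = [s for s in sequences if s]
    bg = [s for s in background if s]
    if not seqs or not bg:
        raise ValueError("empty sequence set")
    k = sum(1 for s in seqs if s[0] == base)
    p_bg = sum(1 for s in bg if s[0] == base) / len(bg)
    if p_bg in (0.0, 1.0):
        p = 1.0 if (k / len(seqs)) == p_bg else 0.0
    else:
        p = float(stats.binomtest(k, len(seqs), p_bg, alternative="two-sided").pvalue)
    return k / len(seqs), p_bg, p


# ---------------------------------------------------------------------------
# Duplex pairing profile (Fig-3b-style)
# ---------------------------------------------------------------------------


def duplex_pairing_vector(locus: MiRNALocus, strand: MatureStrand,
                          max_pos: int = 22) -> np.ndarray:
    """Per-position paired indicator for a mature strand on its hairpin.

    Position i is 1 when the hairpin base is paired with a base of the
    partner arm; mismatches and bulges on either strand are 0."""
    if locus.structure is None:
        raise ValueError(f"{locus.locus_id}: no structure available")
    pt = pair_table(locus.structure)
    iv = locus.arm_interval(strand.arm)
    if iv is None:
        raise ValueError(f"{locus.locus_id}: arm {strand.arm} not annotated")
    partner_arm = "3p" if strand.arm == "5p" else "5p"
    piv = locus.arm_interval(partner_arm)
    n = min(max_pos, iv[1] - iv[0])
    out = np.zeros(n)
    for i in range(n):
        j = pt[iv[0] + i]
        if j is None:
            continue
        if piv is None or piv[0] <= j < piv[1]:
            out[i] = 1.0
    return out


def median_pairing_profile(pairs: Iterable[tuple[MiRNALocus, MatureStrand]],
                           max_pos: int = 22) -> pd.DataFrame:
    """Median per-position pairing over a strand set (positions 1..max_pos)."""
    vecs = []
    for locus, strand in pairs:
        v = duplex_pairing_vector(locus, strand, max_pos)
        if len(v) < max_pos:
            v = np.concatenate([v, np.full(max_pos - len(v), np.nan)])
        vecs.append(v)
    if not vecs:
        raise ValueError("empty strand set")
    arr = np.vstack(vecs)
    with np.errstate(all="ignore"):
        med = np.nanmedian(arr, axis=0)
    return pd.DataFrame({"position": np.arange(1, max_pos + 1),
                         "median_paired": med}).set_index("position")


# ---------------------------------------------------------------------------
# Nussinov fold fallback
# ---------------------------------------------------------------------------

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def nussinov_fold(seq: str, min_loop: int = 3) -> str:
    """Maximum base-pairing dot-bracket by Nussinov recursion, ties broken
    toward 5'-most pairing.  A structural stand-in for synthetic or toy input
    when no folded structure is supplied; not a thermodynamic model."""
    n = len(seq)
    if n == 0:
        return ""
    dp = np.zeros((n, n), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            # pair i with the 5'-most admissible k (tie preference)
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in _CAN_PAIR:
                    inner = dp[i + 1][k - 1] if k - 1 > i else 0
                    rest = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + rest)
            dp[i][j] = best
    struct = ["."] * n

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == dp[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) not in _CAN_PAIR:
                    continue
                inner = dp[i + 1][k - 1] if k - 1 > i else 0
                rest = dp[k + 1][j] if k + 1 <= j else 0
                if dp[i][j] == 1 + inner + rest:
                    struct[i], struct[k] = "(", ")"
                    trace(i + 1, k - 1)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - dp guarantees a branch matches
                i += 1

    trace(0, n - 1)
    return "".join(struct)


def ensure_structures(loci: Iterable[MiRNALocus], allow_fold: bool = True) -> None:
    """Fill in missing structures with the Nussinov fallback (flagged in log)."""
    for locus in loci:
        if locus.structure is None:
            if not allow_fold:
                raise ValueError(f"{locus.locus_id}: structure absent and fold disabled")
            locus.structure = nussinov_fold(locus.hairpin_seq)
            logger.warning("%s: structure absent; Nussinov max-pairing fallback used "
                           "(not RNAfold-equivalent)", locus.locus_id)
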