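"""Scaffold-to-reference-chromosome assignment and chromosome-level tests.

Reference genes (a *B. mori*-like gene set with known chromosomal locations)
are aligned to each assembly; from the tabular hits we keep one best location
per gene, drop lower-scoring genes that overlap a better one on the same
scaffold, and assign each scaffold to the chromosome contributing the
majority of its genes.  Chromosome-level Log2(F/M) contrasts then test Z
homology: scaffolds homologous to the reference Z should sit a full dose
below every autosome, and an autosome that instead tracks the Z signature is
flagged as a candidate neo-Z (a Z-autosome fusion in that lineage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import Log2Profile

MIN_SCORE = 50


def best_hit_per_gene(hits: pd.DataFrame, min_score: float = MIN_SCORE) -> pd.DataFrame:
    """Keep, for each gene, only the alignment location with the best score.

    Hits under ``min_score`` are discarded first.  Ties are broken
    deterministically: lexicographically smallest scaffold id, then leftmost
    interval, so the result is independent of input order.
    """
    kept = hits[hits["score"] >= min_score]
    if kept.empty:
        return kept.copy()
    ordered = kept.sort_values(
        ["gene", "score", "scaffold", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("gene", keep="first").reset_index(drop=True)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def resolve_overlaps(hits: pd.DataFrame, max_overlap: int = 20) -> pd.DataFrame:
    """Within each scaffold, drop genes overlapping a higher-scoring gene by
    strictly more than ``max_overlap`` bp.

    Resolution is a greedy score-descending sweep: hits are accepted in
    decreasing score order (ties by gene id) and a hit is rejected if it
    overlaps any already-accepted hit by > ``max_overlap`` bp.  An overlap of
    exactly ``max_overlap`` bp keeps both genes.
    """
    out = []
    for _, group in hits.groupby("scaffold", sort=False):
        ordered = group.sort_values(["score", "gene"], ascending=[False, True],
                                    kind="mergesort")
        accepted: list[tuple[int, int]] = []
        for row in ordered.itertuples():
            if all(_overlap(row.start, row.end, s, e) <= max_overlap
                   for s, e in accepted):
                accepted.append((row.start, row.end))
                out.append(row.Index)
    return hits.loc[sorted(out)].reset_index(drop=True)


def assign_chromosome(hits: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Assign each scaffold to a reference chromosome by majority vote.

    Each overlap-resolved hit votes for the chromosome its gene lives on in
    the reference.  The chromosome with the most genes wins; a count tie goes
    to the chromosome with the larger summed alignment score; a tie on both
    leaves the scaffold unassigned (NaN).
    """
    chrom_of = dict(zip(gene_map["gene"], gene_map["chromosome"]))
    annotated = hits.assign(chromosome=hits["gene"].map(chrom_of)).dropna(
        subset=["chromosome"]
    )
    result: dict[str, str | float] = {}
    for scaf, group in annotated.groupby("scaffold", sort=False):
        votes = group.groupby("chromosome").agg(
            n=("gene", "size"), score=("score", "sum")
        )
        top = votes[votes["n"] == votes["n"].max()]
        if len(top) > 1:
            top = top[top["score"] == top["score"].max()]
        result[scaf] = top.index[0] if len(top) == 1 else np.nan
    return pd.Series(result, name="chromosome", dtype=object)


@dataclass
class ChromosomeCoverageReport:
    """Per-chromosome rank-sum contrasts against the reference Z.

    ``table`` has one row per tested chromosome with the one-tailed P that
    reference-Z scaffold ratios are lower, a Bonferroni-adjusted column, and
    the two-sided P of similarity to the reference Z.  ``neo_z`` lists the
    chromosomes flagged as neo-Z.
    """

    table: pd.DataFrame
    ref_z_id: str
    neo_z: list[str]


def test_chromosome_coverage(
    profile: Log2Profile,
    assignment: pd.Series,
    ref_z_id: str,
    alpha: float = 0.05,
    min_group: int = 10,
) -> ChromosomeCoverageReport:
    """Test every reference chromosome's Log2(F/M) signature against the Z.

    For each chromosome *c* other than the reference Z, a one-tailed
    Wilcoxon rank-sum (Mann-Whitney) test of ratios(ref Z) < ratios(c) checks
    that Z-homologous scaffolds carry the half-dose signature.  A chromosome
    is flagged neo-Z when its ratios are (i) not significantly different from
    the reference Z's (two-sided, Bonferroni-screened over the tested
    chromosomes so a true neo-Z is not rejected by the multiplicity of the
    screen) and (ii) significantly lower than those of every non-flagged
    autosome at ``alpha``.  Raw P values are reported alongside the
    Bonferroni column.  Chromosomes with fewer than ``min_group`` assigned
    scaffolds are skipped with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    assigned = assignment.dropna()
    for chrom in sorted(assigned.unique()):
        scafs = assigned.index[assigned == chrom]
        vals = profile.finite_ratios.reindex(scafs).dropna().to_numpy()
        if len(vals) < min_group:
            warnings.warn(
                f"chromosome {chrom}: only {len(vals)} scaffolds, skipped",
                stacklevel=2,
            )
            continue
        groups[chrom] = vals
    if ref_z_id not in groups:
        raise ValueError(f"reference Z {ref_z_id!r} has too few assigned scaffolds")
    z_vals = groups[ref_z_id]
    others = [c for c in groups if c != ref_z_id]

    rows = []
    for c in others:
        p_less = stats.mannwhitneyu(z_vals, groups[c], alternative="less").pvalue
        p_two = stats.mannwhitneyu(z_vals, groups[c], alternative="two-sided").pvalue
        rows.append({
            "chromosome": c,
            "n_scaffolds": len(groups[c]),
            "median_log2_fm": float(np.median(groups[c])),
            "p_z_lower": float(p_less),
            "p_vs_z_two_sided": float(p_two),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_z_lower_bonferroni"] = np.minimum(table["p_z_lower"] * len(table), 1.0)

    # neo-Z: indistinguishable from the Z, and below every non-candidate autosome
    m = max(len(table), 1)
    candidates = set(
        table.loc[table["p_vs_z_two_sided"] * m >= alpha, "chromosome"])
    neo_z = []
    for c in sorted(candidates):
        autosomes = [o for o in others if o != c and o not in candidates]
        if autosomes and all(
            stats.mannwhitneyu(groups[c], groups[a], alternative="less").pvalue < alpha
            for a in autosomes
        ):
            neo_z.append(c)
    if not table.empty:
        table["neo_z_flag"] = table["chromosome"].isin(neo_z)
    return ChromosomeCoverageReport(table=table, ref_z_id=ref_z_id, neo_z=neo_z)


def sliding_profile(
    profile: Log2Profile,
    assignment: pd.Series,
    hits: pd.DataFrame,
    gene_map: pd.DataFrame,
    chromosome: str,
    window: int = 10,
) -> pd.DataFrame:
    """Moving average of Log2(F/M) along one reference chromosome.

    Scaffolds assigned to ``chromosome`` are ordered by the reference
    position of their best-scoring gene (from the gene map's ``start``), and
    the ratio is averaged over sliding windows of ``window`` consecutive
    scaffolds.  With fewer than ``window`` scaffolds a single whole-set
    average is emitted with a warning.
    """
    if "start" not in gene_map.columns:
        raise ValueError("gene map lacks a 'start' column for ordering")
    pos_of = dict(zip(gene_map["gene"], gene_map["start"]))
    chrom_scafs = assignment.dropna()
    chrom_scafs = set(chrom_scafs.index[chrom_scafs == chromosome])
    best = (
        hits[hits["scaffold"].isin(chrom_scafs)]
        .sort_values(["scaffold", "score"], ascending=[True, False], kind="mergesort")
        .drop_duplicates("scaffold")
        .assign(ref_pos=lambda d: d["gene"].map(pos_of))
        .dropna(subset=["ref_pos"])
    )
    ordered = best.sort_values(["ref_pos", "scaffold"], kind="mergesort")
    ratios = profile.ratio.reindex(ordered["scaffold"])
    out = pd.DataFrame({
        "scaffold": ordered["scaffold"].to_numpy(),
        "ref_pos": ordered["ref_pos"].to_numpy(),
        "log2_fm": ratios.to_numpy(),
    })
    if len(out) < window:
        warnings.warn(
            f"fewer than {window} scaffolds on {chromosome}; whole-set average",
            stacklevel=2,
        )
        out["moving_average"] = out["log2_fm"].mean()
    else:
        out["moving_average"] = (
            out["log2_fm"].rolling(window, min_periods=window).mean()
        )
    return out.reset_index(drop=True)
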