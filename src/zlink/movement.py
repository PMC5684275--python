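"""Gene movement onto and off the Z chromosome across a four-species tree.

Per-species Z/autosome gene classifications are combined into a linkage
matrix (gene × species → Z, A or U for unknown).  On the fixed rooted
topology

    (((bmori, cohridella), ndegeerella), tsylvina)

— two ditrysian species, an adelid, and the deepest swift-moth-like lineage
as outgroup — a parsimony-style rule set polarises each gene's Z/A pattern
into ancestral Z content and per-branch gains ("onto Z") and losses ("off
Z"):

* a gene is on the **ancestral Z** if it is Z-linked in the outgroup
  (tsylvina) *and* in at least one other lineage;
* the Z content of the node ancestral to the Ditrysia + ndegeerella clade is
  the ancestral set plus genes Z-linked in ndegeerella and both Ditrysia
  (but not the outgroup);
* genes Z-linked in the two Ditrysia only moved onto the Z on the branch at
  the root of the Ditrysia;
* genes Z-linked in exactly one species other than the outgroup moved onto
  the Z on that terminal branch;
* losses mirror gains with A substituted for Z, evaluated against the
  ancestral-Z gene set;
* genes Z-linked only in the outgroup cannot be polarised (no further
  outgroup) and are reported separately, assigned to no branch.

Patterns the verbal rules leave open (a gene Z-linked in two non-sister
lineages) are resolved on the minimal set of terminal branches consistent
with the rules; the complete 16-pattern table is :data:`PATTERN_RULES`.

Because only a minority of reference Z genes survive the per-species
classification, branch counts are rescaled by the sampling fraction of
annotated reference Z-linked genes to estimate chromosome-wide totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Fixed species order of the linkage matrix (tree: (((bm, co), nd), ts)).
SPECIES = ("bmori", "cohridella", "ndegeerella", "tsylvina")

#: Branches onto/off which movement can be polarised.
DITRYSIA_ROOT = "ditrysia_root"
DITRYSIA_PLUS_ADELIDAE = "ditrysia_plus_adelidae"  # internal branch to the (D+nd) node
TERMINAL_BRANCHES = ("bmori", "cohridella", "ndegeerella")
BRANCHES = (DITRYSIA_ROOT, DITRYSIA_PLUS_ADELIDAE) + TERMINAL_BRANCHES

Z, A, U = "Z", "A", "U"


@dataclass(frozen=True)
class PatternRule:
    """Polarisation of one Z/A pattern (bmori, cohridella, ndegeerella, tsylvina)."""

    ancestral_z: bool            # in the ancestral-Lepidoptera-Z set
    at_ditrysia_adelidae_node: bool  # Z at the Ditrysia + ndegeerella ancestor
    onto_z: tuple[str, ...] = ()  # branches gaining the gene
    off_z: tuple[str, ...] = ()   # branches losing the gene
    unpolarized: bool = False     # Z only in the outgroup


def _build_pattern_rules() -> dict[tuple[bool, bool, bool, bool], PatternRule]:
    """Enumerate all 16 Z/A patterns and their branch attribution.

    Key order is (bmori, cohridella, ndegeerella, tsylvina); True = Z-linked.
    Double losses and non-sister double gains — which the verbal rules do not
    cover — are placed on the two implicated terminal branches (the minimal
    consistent attribution that keeps the ancestral-node counts at their
    rule-defined values).
    """
    rules: dict[tuple[bool, bool, bool, bool], PatternRule] = {}
    for bm in (True, False):
        for co in (True, False):
            for nd in (True, False):
                for ts in (True, False):
                    ancestral = ts and (bm or co or nd)
                    at_node = ancestral or (bm and co and nd and not ts)
                    onto: list[str] = []
                    off: list[str] = []
                    unpol = False
                    if ancestral:
                        losses = [name for name, state in
                                  (("bmori", bm), ("cohridella", co), ("ndegeerella", nd))
                                  if not state]
                        if not bm and not co:
                            # lost in both Ditrysia: single loss at their root
                            off.append(DITRYSIA_ROOT)
                            if not nd:  # unreachable: would mean Z in ts only
                                off.append("ndegeerella")
                        else:
                            off.extend(losses)
                    elif ts:
                        unpol = True  # Z in outgroup only
                    else:
                        gains = [name for name, state in
                                 (("bmori", bm), ("cohridella", co), ("ndegeerella", nd))
                                 if state]
                        if bm and co and nd:
                            onto.append(DITRYSIA_PLUS_ADELIDAE)
                        elif bm and co:
                            onto.append(DITRYSIA_ROOT)
                        else:
                            onto.extend(gains)
                    rules[(bm, co, nd, ts)] = PatternRule(
                        ancestral_z=ancestral,
                        at_ditrysia_adelidae_node=at_node,
                        onto_z=tuple(onto),
                        off_z=tuple(off),
                        unpolarized=unpol,
                    )
    return rules


#: The shipped rule table: Z/A pattern -> polarisation.
PATTERN_RULES = _build_pattern_rules()


@dataclass
class MovementSummary:
    """Branch-resolved counts of gene movement onto and off the Z."""

    n_classified: int
    ancestral_z_count: int
    ancestral_ditrysia_adelidae_count: int
    onto_z: dict[str, int]
    off_z: dict[str, int]
    unpolarized_outgroup_only: int
    z_per_species: dict[str, int] = field(default_factory=dict)
    pattern_counts: dict[tuple[bool, bool, bool, bool], int] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"branch": b, "onto_z": self.onto_z.get(b, 0),
                 "off_z": self.off_z.get(b, 0)} for b in BRANCHES]
        return pd.DataFrame(rows)


def build_linkage_matrix(
    scaffold_labels: dict[str, pd.Series],
    gene_scaffolds: dict[str, pd.Series],
) -> pd.DataFrame:
    """Combine per-species scaffold classifications into a gene × species matrix.

    Parameters
    ----------
    scaffold_labels
        Per species, a Series scaffold id → label in {Z, A, unclassified}.
    gene_scaffolds
        Per species, a Series gene id → scaffold id (from overlap-resolved
        best hits; a gene placed on two scaffolds in one species is an error).

    A gene's state in a species is its scaffold's label; genes missing from a
    species, or sitting on an unclassified scaffold, get state U there.  The
    returned matrix has one row per gene seen in any species and one column
    per species in :data:`SPECIES` order.
    """
    missing = [s for s in SPECIES if s not in scaffold_labels or s not in gene_scaffolds]
    if missing:
        raise ValueError(f"species without classification or placements: {missing}")
    all_genes: set[str] = set()
    for sp in SPECIES:
        placements = gene_scaffolds[sp]
        if placements.index.duplicated().any():
            dup = placements.index[placements.index.duplicated()][0]
            raise ValueError(f"gene {dup!r} maps to two scaffolds in {sp}")
        all_genes.update(placements.index)
    genes = sorted(all_genes)
    matrix = pd.DataFrame(U, index=pd.Index(genes, name="gene"), columns=list(SPECIES))
    for sp in SPECIES:
        labels = gene_scaffolds[sp].map(scaffold_labels[sp])
        labels = labels.where(labels.isin([Z, A]), U)
        matrix.loc[labels.index, sp] = labels
    return matrix


def classified_subset(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rows with a Z or A state in all four species."""
    ok = matrix[list(SPECIES)].isin([Z, A]).all(axis=1)
    return matrix.loc[ok]


def infer_movement(matrix: pd.DataFrame) -> MovementSummary:
    """Polarise every classified gene's Z/A pattern into branch movements.

    Only genes classified (Z or A) in all four species contribute.  Each
    pattern is looked up in :data:`PATTERN_RULES`; counts are accumulated per
    branch and for the two ancestral nodes.
    """
    classified = classified_subset(matrix)
    onto = {b: 0 for b in BRANCHES}
    off = {b: 0 for b in BRANCHES}
    ancestral = 0
    at_node = 0
    unpol = 0
    pattern_counts: dict[tuple[bool, bool, bool, bool], int] = {}
    patterns = (classified[list(SPECIES)] == Z).itertuples(index=False, name=None)
    for pat in patterns:
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1
    for pat, n in pattern_counts.items():
        rule = PATTERN_RULES[pat]
        ancestral += n * rule.ancestral_z
        at_node += n * rule.at_ditrysia_adelidae_node
        unpol += n * rule.unpolarized
        for b in rule.onto_z:
            onto[b] += n
        for b in rule.off_z:
            off[b] += n
    z_per_species = {
        sp: int((classified[sp] == Z).sum()) for sp in SPECIES
    }
    return MovementSummary(
        n_classified=len(classified),
        ancestral_z_count=ancestral,
        ancestral_ditrysia_adelidae_count=at_node,
        onto_z=onto,
        off_z=off,
        unpolarized_outgroup_only=unpol,
        z_per_species=z_per_species,
        pattern_counts=pattern_counts,
    )


def rescale_total(
    moves: int, sampled_ref_z_genes: int, annotated_ref_z_genes: int
) -> tuple[float, int]:
    """Rescale a sampled branch movement count to a chromosome-wide estimate.

    Only a fraction of the reference species' annotated Z-linked genes
    survive into the classified ortholog sample; dividing the observed count
    by that sampling fraction estimates the chromosome-wide total.  Returns
    ``(raw_estimate, rounded)``.
    """
    if moves < 0:
        raise ValueError("moves must be >= 0")
    if sampled_ref_z_genes <= 0 or annotated_ref_z_genes <= 0:
        raise ValueError("gene counts must be positive (zero sampling fraction)")
    fraction = sampled_ref_z_genes / annotated_ref_z_genes
    estimate = moves / fraction
    return estimate, int(round(estimate))


def sampling_fraction_percent(sampled: int, annotated: int) -> int:
    """The sampling fraction as a whole-number percentage (as reported)."""
    return int(round(100 * sampled / annotated))


def compare_branch_rates(
    moved: dict[str, int], opportunity: dict[str, int]
) -> pd.Series:
    """Chi-square homogeneity test of movement rates across branch groups.

    ``moved[b]`` genes moved out of ``opportunity[b]`` at risk on branch (or
    branch group) *b*.  Returns a Series with the statistic, degrees of
    freedom and two-tailed P; warns when any expected cell is below 1 (an
    exact test would be preferable there).
    """
    branches = sorted(moved)
    if len(branches) < 2:
        raise ValueError("need at least two branches to compare")
    table = np.array(
        [[moved[b], opportunity[b] - moved[b]] for b in branches], dtype=float
    )
    if (table < 0).any():
        raise ValueError("moved exceeds opportunity on some branch")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 1).any():
        warnings.warn(
            "expected cell count < 1; consider an exact test", stacklevel=2
        )
    return pd.Series(
        {"statistic": float(res.statistic), "df": int(res.dof), "p": float(res.pvalue)}
    )


def render_tree(summary: MovementSummary) -> str:
    """Plain-text rendering of the tree with per-branch movement arrows."""
    o, f = summary.onto_z, summary.off_z

    def arrows(b: str) -> str:
        return f"+{o.get(b, 0)}Z -{f.get(b, 0)}Z"

    lines = [
        f"ancestral Z genes: {summary.ancestral_z_count}"
        f" (at Ditrysia+Adelidae node: {summary.ancestral_ditrysia_adelidae_count})",
        f"        /-- bmori        [{arrows('bmori')}]",
        f"   /---+  (Ditrysia root) [{arrows(DITRYSIA_ROOT)}]",
        f"  +     \\-- cohridella   [{arrows('cohridella')}]",
        f"  |\\------- ndegeerella  [{arrows('ndegeerella')}]",
        f"  |  (internal branch)    [{arrows(DITRYSIA_PLUS_ADELIDAE)}]",
        f"   \\------- tsylvina     [unpolarized Z-only genes: "
        f"{summary.unpolarized_outgroup_only}]",
    ]
    return "\n".join(lines)
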