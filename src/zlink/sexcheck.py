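"""Sexing an unlabelled sample from its depth on Z vs autosomal scaffolds.

In a female-heterogametic system a male carries two Z copies and a female
one, so a male's sequencing depth is the same on Z-linked and autosomal
scaffolds while a female's Z depth is about half her autosomal depth.  Given
a scaffold classification built *without* the sample in question, a
one-tailed Wilcoxon rank-sum test of (Z depths < autosomal depths) calls the
sample female when significant and male otherwise.

The call is purely dosage-based: a Z0 female and a ZW female both show the
half-dose signature and cannot be told apart here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import A, Z

MALE, FEMALE, INDETERMINATE = "male", "female", "indeterminate"


@dataclass
class SexCallReport:
    """Outcome of a dosage-based sex call."""

    call: str
    median_z: float
    median_a: float
    p_value: float
    alpha: float
    n_z: int
    n_a: int

    def summary_line(self) -> str:
        return (
            f"call={self.call} median_Z={self.median_z:.1f} "
            f"median_A={self.median_a:.1f} P={self.p_value:.3g} "
            f"(one-tailed rank-sum, n_Z={self.n_z}, n_A={self.n_a})"
        )


def infer_sex(
    sample_depths: pd.Series,
    classification: pd.Series,
    alpha: float = 0.05,
    min_scaffolds: int = 30,
    normalize: bool = False,
) -> SexCallReport:
    """Call the sex of one library from its per-scaffold depths.

    Parameters
    ----------
    sample_depths
        Scaffold id → mean depth of the library being sexed.
    classification
        Scaffold id → label in {Z, A, unclassified}, derived from other
        individuals of known sex.
    normalize
        Divide depths by their overall median first (useful when comparing
        calls across libraries of very different size; the test itself is
        rank-based and unaffected).

    A significant one-tailed rank-sum test of Z < A depths means a single Z
    copy → female; otherwise male.  If either class has fewer than
    ``min_scaffolds`` scaffolds with depth data, the call is indeterminate.
    """
    common = classification.index.intersection(sample_depths.index)
    if common.empty:
        raise ValueError("classification and sample share no scaffold ids")
    labels = classification.loc[common]
    depths = sample_depths.loc[common].astype(float)
    if normalize:
        med = depths.median()
        if med > 0:
            depths = depths / med
    z_depths = depths[labels == Z].dropna().to_numpy()
    a_depths = depths[labels == A].dropna().to_numpy()
    median_z = float(np.median(z_depths)) if len(z_depths) else np.nan
    median_a = float(np.median(a_depths)) if len(a_depths) else np.nan
    if len(z_depths) < min_scaffolds or len(a_depths) < min_scaffolds:
        return SexCallReport(INDETERMINATE, median_z, median_a, np.nan,
                             alpha, len(z_depths), len(a_depths))
    p = float(stats.mannwhitneyu(z_depths, a_depths, alternative="less").pvalue)
    call = FEMALE if p < alpha else MALE
    return SexCallReport(call, median_z, median_a, p, alpha,
                         len(z_depths), len(a_depths))
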