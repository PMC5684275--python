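"""Z-linked vs autosomal scaffold classification from Log2(F/M) coverage.

Two methods are implemented.  The *lenient* method is purely distributional:
the Log2(F/M) histogram of a ZW/Z0 species is bimodal, with the highest peak
(the autosomal mode, ``A_mode``) near 0 and a Z-linked mode about one log2
unit lower.  Scaffolds more than 0.6 units below A_mode are called Z, those
less than 0.4 units below are called autosomal, and the in-between band is
left unclassified.

The *stringent* method borrows homology information: as the Z cutoff is made
stricter, the fraction of Z-called scaffolds that map to the reference Z
chromosome rises and then plateaus once essentially only true Z scaffolds
remain.  The cutoff is placed at the plateau onset, and two extra conditions
are imposed (female coverage below the female median, since females carry a
single Z; autosomal calls above the 10th percentile of ratios of
reference-autosome scaffolds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CoverageTable, Log2Profile, FEMALE

Z = "Z"
A = "A"
UNCLASSIFIED = "unclassified"


class EstimationError(ValueError):
    """Raised when a mode or cutoff cannot be estimated from the data."""


@dataclass
class LenientConfig:
    """Parameters of the histogram-mode classification.

    ``n_bins`` controls mode-finding resolution (200 suits dense assemblies,
    120 sparser ones); ``z_offset``/``a_offset`` are the distances below
    A_mode delimiting the Z call and the autosomal call.
    """

    n_bins: int = 200
    z_offset: float = 0.6
    a_offset: float = 0.4

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be at least 10")
        if not (self.z_offset > self.a_offset > 0):
            raise ValueError("need z_offset > a_offset > 0")


@dataclass
class StringentConfig:
    """Parameters of the homology-calibrated classification.

    ``z_cutoff`` is a Log2(F/M) value, typically from
    :func:`calibrate_stringent_cutoff` or supplied directly from a published
    analysis; ``autosome_percentile`` sets the autosomal lower bound from
    reference-autosome scaffolds.
    """

    z_cutoff: float
    autosome_percentile: float = 10.0
    require_female_below_median: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.autosome_percentile < 50):
            raise ValueError("autosome_percentile must be in (0, 50)")


def find_autosomal_mode(profile: Log2Profile, n_bins: int = 200) -> float:
    """Locate A_mode: the centre of the most populated histogram bin.

    The histogram spans [min, max] of the finite ratios with ``n_bins``
    equal-width bins.  A tie between bins is broken toward the bin whose
    centre is nearer 0, since the autosomal peak is by assumption the
    dominant one and sits at equal male/female dose.
    """
    vals = profile.finite_ratios.to_numpy()
    if len(vals) < n_bins:
        raise EstimationError(
            f"only {len(vals)} finite ratios for a {n_bins}-bin histogram"
        )
    lo, hi = vals.min(), vals.max()
    if lo == hi:  # point mass: every ratio identical
        return float(lo)
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    best = tied[np.argmin(np.abs(centers[tied]))]
    return float(centers[best])


def classify_lenient(profile: Log2Profile, config: LenientConfig | None = None,
                     a_mode: float | None = None) -> pd.Series:
    """Histogram-mode classification of every scaffold in the profile.

    Returns a Series of labels in {Z, A, unclassified} indexed like the
    profile.  Ratios strictly below ``A_mode − z_offset`` are Z, strictly
    above ``A_mode − a_offset`` autosomal; boundary values and the gap in
    between, as well as non-finite ratios, are unclassified.
    """
    config = config or LenientConfig()
    if a_mode is None:
        a_mode = find_autosomal_mode(profile, config.n_bins)
    labels = pd.Series(UNCLASSIFIED, index=profile.ratio.index, name="label")
    r = profile.ratio
    labels[profile.finite & (r < a_mode - config.z_offset)] = Z
    labels[profile.finite & (r > a_mode - config.a_offset)] = A
    return labels


def z_reference_fraction_curve(
    profile: Log2Profile,
    assignment: pd.Series,
    ref_z_id: str,
    cutoffs: np.ndarray,
) -> pd.DataFrame:
    """For each candidate Z cutoff, the fraction of Z-called scaffolds that
    are assigned to the reference Z chromosome.

    ``assignment`` maps scaffold id → reference chromosome (NaN/missing =
    unassigned); the fraction at a cutoff is computed over Z-called scaffolds
    that have any assignment.
    """
    rows = []
    assigned = assignment.dropna()
    r = profile.finite_ratios
    for c in cutoffs:
        called = r.index[r < c]
        called_assigned = assigned.reindex(called).dropna()
        n = len(called_assigned)
        frac = float((called_assigned == ref_z_id).mean()) if n else np.nan
        rows.append({"cutoff": float(c), "n_z_called": n, "frac_on_ref_z": frac})
    return pd.DataFrame(rows)


def calibrate_stringent_cutoff(
    profile: Log2Profile,
    assignment: pd.Series,
    ref_z_id: str,
    start_cutoff: float,
    span: float = 0.1,
    tolerance: float = 0.01,
    step: float = 0.02,
    min_called: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Find the Z cutoff at which the reference-Z concordance curve plateaus.

    Cutoffs are swept from ``start_cutoff`` (typically the lenient cutoff
    A_mode − 0.6) downward in ``step`` decrements.  At each cutoff the
    fraction of Z-called scaffolds assigned to ``ref_z_id`` is measured; the
    returned cutoff is the most lenient one at which the fraction's rise over
    the next ``span`` log2 units falls below ``tolerance`` (plateau onset).
    If the curve is still rising at the strict end, a calibration warning is
    issued and the strictest swept cutoff is returned.

    Returns ``(cutoff, curve)`` where ``curve`` is the swept table, suitable
    for plotting.
    """
    r = profile.finite_ratios
    lo = float(r.min())
    if start_cutoff <= lo:
        raise EstimationError("start_cutoff below all finite ratios; nothing to sweep")
    cutoffs = np.arange(start_cutoff, lo, -step)
    curve = z_reference_fraction_curve(profile, assignment, ref_z_id, cutoffs)
    frac = curve["frac_on_ref_z"].to_numpy()
    n = curve["n_z_called"].to_numpy()
    window = max(1, int(round(span / step)))
    for i in range(len(cutoffs)):
        j = min(i + window, len(cutoffs) - 1)
        if n[i] < min_called or not np.isfinite(frac[i]) or not np.isfinite(frac[j]):
            continue
        if frac[j] - frac[i] < tolerance:
            return float(cutoffs[i]), curve
    warnings.warn(
        "reference-Z concordance never plateaued; returning strictest swept cutoff",
        stacklevel=2,
    )
    return float(cutoffs[-1]), curve


def classify_stringent(
    profile: Log2Profile,
    table: CoverageTable,
    assignment: pd.Series,
    config: StringentConfig,
    ref_z_id: str,
) -> pd.Series:
    """Homology-calibrated classification.

    Z requires the ratio strictly below ``config.z_cutoff`` and (by default)
    the grouped female depth strictly below the median grouped female depth of
    the classified set — females carry one Z, so true Z scaffolds cannot be
    female-coverage-rich.  Autosomal requires the ratio strictly above the
    ``autosome_percentile``-th percentile of ratios among scaffolds assigned
    to reference autosomes.  Everything else, including non-finite ratios, is
    unclassified.
    """
    auto_scaffolds = assignment.dropna()
    auto_scaffolds = auto_scaffolds.index[auto_scaffolds != ref_z_id]
    auto_ratios = profile.finite_ratios.reindex(auto_scaffolds).dropna()
    if auto_ratios.empty:
        raise EstimationError("no scaffolds assigned to reference autosomes")
    a_floor = float(np.percentile(auto_ratios.to_numpy(), config.autosome_percentile))

    labels = pd.Series(UNCLASSIFIED, index=profile.ratio.index, name="label")
    r = profile.ratio
    z_ok = profile.finite & (r < config.z_cutoff)
    if config.require_female_below_median:
        fem = table.summed_depth(FEMALE).reindex(profile.ratio.index)
        z_ok &= fem < fem.median()
    labels[z_ok] = Z
    labels[profile.finite & (r > a_floor) & ~z_ok] = A
    return labels
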