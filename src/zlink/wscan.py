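"""Detection of candidate W-derived scaffolds from female-specific coverage.

The W chromosome of female-heterogametic Lepidoptera is female-limited and
single-copy, so W-derived scaffolds should show (i) essentially no coverage
in any male library and (ii) roughly half-autosomal coverage in every female
library.  The filter implements exactly that: length above a floor, per-male
depth below a small ceiling, and per-female depth strictly between ¼ and 1
times that female library's median depth.

Two presets are provided.  The lenient one (1000 bp, male depth < 1.1)
tolerates stray mismapped male reads; the stringent one (2000 bp, zero male
coverage) is for shortlisting candidates worth wet-lab validation in noisy,
fragmented assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import CoverageTable

#: Length floor applied before computing female medians: the assembly's own
#: minimum scaffold length, not the classification prefilter (which would
#: discard every W scaffold via its male-coverage floor).
MEDIAN_LENGTH_FLOOR = 200


@dataclass
class WFilterConfig:
    """Thresholds of the W-candidate filter.

    ``male_max_per_sample`` of exactly 0 means *null* male coverage (depth
    == 0); any positive value is a strict upper bound.  Female bounds are
    fractions of each female library's median depth.
    """

    min_len: int = 1000
    male_max_per_sample: float = 1.1
    female_lower: float = 0.25
    female_upper: float = 1.0
    grouped_female_median: bool = False

    def __post_init__(self) -> None:
        if self.male_max_per_sample < 0:
            raise ValueError("male_max_per_sample must be >= 0")
        if not self.female_lower < self.female_upper:
            raise ValueError("need female_lower < female_upper")


def lenient_preset() -> WFilterConfig:
    return WFilterConfig()


def stringent_preset() -> WFilterConfig:
    """Stricter shortlisting preset: 2000 bp floor and null male coverage."""
    return WFilterConfig(min_len=2000, male_max_per_sample=0.0)


def detect_w_candidates(
    table: CoverageTable, config: WFilterConfig | None = None
) -> pd.DataFrame:
    """Return the scaffolds passing every W-candidate rule.

    A scaffold is a candidate iff its length exceeds ``min_len``, every male
    library's depth is below ``male_max_per_sample`` (== 0 when the ceiling
    is 0), and every female library's depth lies strictly between
    ``female_lower`` and ``female_upper`` times that library's median depth.
    Medians are computed per female library over all scaffolds of at least
    :data:`MEDIAN_LENGTH_FLOOR` bp, *before* any candidate filtering, so the
    autosomal bulk sets the scale.  With ``grouped_female_median`` the median
    of the summed female depth is used instead, against the summed depth.
    """
    config = config or WFilterConfig()
    frame = table.frame
    median_pop = frame[frame["length"] >= MEDIAN_LENGTH_FLOOR]

    ok = frame["length"] > config.min_len
    for m in table.male_samples:
        if config.male_max_per_sample == 0:
            ok &= frame[m] == 0
        else:
            ok &= frame[m] < config.male_max_per_sample

    if config.grouped_female_median:
        grouped = frame[table.female_samples].sum(axis=1)
        med = float(median_pop[table.female_samples].sum(axis=1).median())
        ok &= (grouped > config.female_lower * med) & (grouped < config.female_upper * med)
    else:
        for f in table.female_samples:
            med = float(median_pop[f].median())
            ok &= (frame[f] > config.female_lower * med) & (frame[f] < config.female_upper * med)

    cols = ["length", *table.male_samples, *table.female_samples]
    out = frame.loc[ok, cols].copy()
    out.insert(0, "scaffold", out.index)
    return out.reset_index(drop=True)
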