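"""Coverage tables, ortholog hit tables and the filters applied to them.

The central container is :class:`CoverageTable`: per-scaffold mean sequencing
depths for a set of male and female libraries, in the style of SOAPcoverage
output.  From it we derive the per-scaffold Log2(F/M) profile — the log2 of
the summed female depth over the summed male depth — which is the signal all
downstream sex-chromosome classification is built on: autosomal scaffolds sit
near 0, Z-linked scaffolds near −1 (half dose in ZW/Z0 females), W-derived
scaffolds have no male coverage at all.

All tabular I/O is plain TSV with a header row and a leading dialect-version
comment line, so files round-trip exactly and stay diffable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DIALECT_COMMENT = "# zlink-tsv v1"

MALE = "male"
FEMALE = "female"
_VALID_SEXES = (MALE, FEMALE)


class FormatError(ValueError):
    """A table violated the expected dialect or an invariant."""


@dataclass
class CoverageTable:
    """Per-scaffold mean depths for a set of sexed libraries.

    Parameters
    ----------
    frame
        Indexed by scaffold id, with a ``length`` column (bp) and one mean-depth
        column per library.
    sample_sex
        Maps each depth column name to ``"male"`` or ``"female"``.
    male_cap
        The grouped-male-depth percentile cap computed by the first
        application of :func:`prefilter_scaffolds`; carried along so the cap
        is computed once, on the pre-filter population, and re-filtering is a
        no-op.
    """

    frame: pd.DataFrame
    sample_sex: dict[str, str]
    male_cap: float | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_sex if s not in self.frame.columns]
        if missing:
            raise FormatError(f"sample sheet names absent depth columns: {missing}")
        bad_sex = {s: x for s, x in self.sample_sex.items() if x not in _VALID_SEXES}
        if bad_sex:
            raise FormatError(f"unknown sex labels: {bad_sex}")
        if "length" not in self.frame.columns:
            raise FormatError("coverage table lacks a 'length' column")
        if (self.frame["length"] < 1).any():
            bad = self.frame.index[self.frame["length"] < 1][0]
            raise FormatError(f"scaffold {bad!r} has length < 1")
        for col in self.sample_sex:
            neg = self.frame[col] < 0
            if neg.any():
                bad = self.frame.index[neg][0]
                raise FormatError(f"scaffold {bad!r} has negative depth in {col!r}")

    @property
    def male_samples(self) -> list[str]:
        return [s for s, x in self.sample_sex.items() if x == MALE]

    @property
    def female_samples(self) -> list[str]:
        return [s for s, x in self.sample_sex.items() if x == FEMALE]

    @property
    def scaffold_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def summed_depth(self, sex: str) -> pd.Series:
        """Per-scaffold depth summed over the libraries of one sex."""
        cols = [s for s, x in self.sample_sex.items() if x == sex]
        if not cols:
            raise FormatError(f"no {sex} samples in table")
        return self.frame[cols].sum(axis=1)

    def subset(self, scaffold_ids) -> "CoverageTable":
        return CoverageTable(self.frame.loc[scaffold_ids], dict(self.sample_sex),
                             male_cap=self.male_cap)


@dataclass
class Log2Profile:
    """Per-scaffold Log2(F/M) ratios with a finiteness flag.

    ``finite`` is False exactly where the summed male or female depth is zero
    (no pseudocount is added); such scaffolds are excluded from histograms and
    classified as unclassified downstream.
    """

    ratio: pd.Series
    finite: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.finite is None:
            self.finite = np.isfinite(self.ratio)
        self.finite = self.finite.astype(bool)

    @property
    def finite_ratios(self) -> pd.Series:
        return self.ratio[self.finite]

    def __len__(self) -> int:
        return len(self.ratio)


# ---------------------------------------------------------------------------
# coverage table I/O


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (library id, sex) into a sample→sex mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample", "sex"} <= set(df.columns):
        raise FormatError(f"sample sheet {path} needs columns 'sample' and 'sex'")
    return dict(zip(df["sample"], df["sex"]))


def write_sample_sheet(sample_sex: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DIALECT_COMMENT + "\n")
        fh.write("sample\tsex\n")
        for s, x in sample_sex.items():
            fh.write(f"{s}\t{x}\n")


def read_coverage_table(path: str | Path, sample_sheet: dict[str, str] | str | Path) -> CoverageTable:
    """Read a per-scaffold coverage TSV plus its sample sheet.

    The file has columns ``scaffold``, ``length`` and one mean-depth column per
    library; every depth column must be assigned a sex by the sample sheet.
    """
    if not isinstance(sample_sheet, dict):
        sample_sheet = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "scaffold" not in df.columns:
        raise FormatError(f"{path}: missing 'scaffold' column")
    df = df.set_index("scaffold")
    depth_cols = [c for c in df.columns if c != "length"]
    unknown = [c for c in depth_cols if c not in sample_sheet]
    if unknown:
        raise FormatError(f"{path}: depth columns not in sample sheet: {unknown}")
    absent = [s for s in sample_sheet if s not in depth_cols]
    if absent:
        raise FormatError(f"{path}: sample-sheet libraries missing from table: {absent}")
    return CoverageTable(df, {c: sample_sheet[c] for c in depth_cols})


def write_coverage_table(table: CoverageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DIALECT_COMMENT + "\n")
        table.frame.to_csv(fh, sep="\t", index_label="scaffold")


# ---------------------------------------------------------------------------
# the classification prefilter


def prefilter_scaffolds(
    table: CoverageTable,
    min_len: int = 1500,
    min_male_cov: float = 5.0,
    male_pct_cap: float | None = 99.5,
) -> CoverageTable:
    """Keep scaffolds usable for Z/autosome classification.

    Retains scaffolds strictly longer than ``min_len`` bp whose grouped
    (summed-over-male-libraries) depth is strictly above ``min_male_cov`` and
    strictly below the ``male_pct_cap``-th percentile of grouped male depth.
    The percentile is computed once, on the unfiltered table, so the filter is
    idempotent.  The low floor removes scaffolds with too little signal; the
    percentile cap removes collapsed repeats, whose inflated depth in both
    sexes would otherwise masquerade as high-confidence autosomes.  Pass
    ``male_pct_cap=None`` to skip the cap — necessary for degenerate depth
    distributions (e.g. noise-free simulations, where every scaffold of a
    class has identical depth and a strict cap would remove them all).
    """
    male = table.summed_depth(MALE)
    keep = (table.frame["length"] > min_len) & (male > min_male_cov)
    cap = table.male_cap
    if male_pct_cap is not None:
        if cap is None:
            cap = float(np.percentile(male.to_numpy(), male_pct_cap))
        keep &= male < cap
    if not keep.any():
        warnings.warn("prefilter removed every scaffold", stacklevel=2)
    out = table.subset(table.frame.index[keep])
    out.male_cap = cap
    return out


def log2_fm(table: CoverageTable) -> Log2Profile:
    """Per-scaffold log2 of summed female depth over summed male depth.

    Scaffolds where either grouped depth is zero get a non-finite ratio and a
    False flag; no pseudocount is added (a pseudocount would drag the Z mode
    toward zero on low-coverage data).
    """
    f = table.summed_depth(FEMALE).to_numpy(dtype=float)
    m = table.summed_depth(MALE).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(f / m)
    finite = (f > 0) & (m > 0)
    ratio[~finite] = np.nan
    idx = table.frame.index
    return Log2Profile(pd.Series(ratio, index=idx, name="log2_fm"),
                       pd.Series(finite, index=idx, name="finite"))


# ---------------------------------------------------------------------------
# ortholog hit tables (PSL-like dialect)

HIT_COLUMNS = ["gene", "scaffold", "start", "end", "score"]


def read_ortholog_hits(path: str | Path) -> pd.DataFrame:
    """Read a PSL-like hit table: one reference gene aligned to one scaffold
    interval with an alignment score.

    Intervals are normalised to 0-based half-open; a hit with ``start >= end``
    is a format error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: hit table missing columns {missing}")
    df = df[HIT_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise FormatError(
            f"{path}: malformed interval for gene {row['gene']!r} "
            f"({row['start']} >= {row['end']})"
        )
    return df


def write_ortholog_hits(hits: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DIALECT_COMMENT + "\n")
        hits[HIT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a reference gene→chromosome map TSV (gene, chromosome, start)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "chromosome": str})
    missing = [c for c in ("gene", "chromosome") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene map missing columns {missing}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise FormatError(f"{path}: gene {dup!r} appears twice in gene map")
    return df


def write_gene_map(gene_map: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DIALECT_COMMENT + "\n")
        gene_map.to_csv(fh, sep="\t", index=False)
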