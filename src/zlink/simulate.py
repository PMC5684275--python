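"""Synthetic Lepidoptera-style assemblies, coverage tables and linkage matrices.

Everything the pipeline consumes can be generated here with known ground
truth: a fragmented assembly whose scaffolds belong to a 31-chromosome
karyotype with a Z, optionally a W and a neo-Z; per-library mean depths that
obey sex-chromosome dosage (half female dose on Z and neo-Z, zero male dose
on W) with negative-binomial overdispersion and a small fraction of
collapsed-repeat depth outliers; ortholog hit tables tying reference genes
to scaffolds; and four-species gene linkage matrices with planted movement
events on the fixed tree (((bmori, cohridella), ndegeerella), tsylvina).

Defaults emulate the study conditions this pipeline targets: a karyotype of
n = 31, ~3.7% of genes Z-linked, per-library autosomal depth of a few tens
of reads, and one library per sex.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .movement import BRANCHES, DITRYSIA_PLUS_ADELIDAE, DITRYSIA_ROOT, SPECIES
from .tables import CoverageTable

READ_LENGTH = 125  # bp, Illumina-style; converts depths to countable reads

CLASS_A, CLASS_Z, CLASS_W, CLASS_NEOZ = "A", "Z", "W", "neoZ"


class ConfigError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class MovementEvent:
    """A planted gene-movement event: ``n_genes`` move onto or off the Z on
    ``branch`` (one of the polarisable branches)."""

    branch: str
    direction: str  # "onto" | "off"
    n_genes: int

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ConfigError(f"unknown branch {self.branch!r}; valid: {BRANCHES}")
        if self.direction not in ("onto", "off"):
            raise ConfigError(f"direction must be 'onto' or 'off', got {self.direction!r}")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and its sequencing.

    ``z_scaffold_fraction``/``z_gene_fraction`` default to the ~3.7% of genes
    a Lepidoptera Z carries; ``depth_mean_per_sample`` is the expected
    autosomal mean depth of one library; ``depth_dispersion`` is the
    negative-binomial overdispersion (variance = μ + α·μ²) of read counts in
    one read-length window.  Windows are effectively independent, so a
    scaffold of length L averages L/read-length windows and its mean depth
    has effective dispersion α·read_length/L — long scaffolds are tight,
    short ones noisy, as in real coverage data.  Dispersion 0 is the exact
    noise-free limit.
    """

    n_chromosomes: int = 31
    z_chrom_id: str = "chr1"
    w_present: bool = True
    neo_z_chrom_id: str | None = None
    n_scaffolds: int = 2000
    scaffold_len_log_mean: float = 8.3   # log-normal of ln(length); median ≈ 4000 bp
    scaffold_len_log_sd: float = 1.0
    min_scaffold_len: int = 200
    z_scaffold_fraction: float = 0.037
    w_scaffold_fraction: float = 0.02
    depth_mean_per_sample: float = 40.0
    depth_dispersion: float = 0.15
    noise_outlier_fraction: float = 0.005
    outlier_multiplier: float = 25.0
    n_males: int = 1
    n_females: int = 1
    n_genes: int = 600
    z_gene_fraction: float = 0.037
    genes_per_scaffold: float = 3.0      # mean genes per gene-bearing scaffold
    spurious_hit_fraction: float = 0.1   # extra low-score hits per gene
    linkage_missing_fraction: float = 0.0
    movement_events: list[MovementEvent] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds <= 0:
            raise ConfigError("n_scaffolds must be > 0")
        if self.depth_mean_per_sample <= 0:
            raise ConfigError("depth_mean_per_sample must be > 0")
        if not (0 <= self.noise_outlier_fraction < 1):
            raise ConfigError("noise_outlier_fraction must be in [0, 1)")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")
        if self.scaffold_len_log_sd <= 0:
            raise ConfigError("scaffold_len_log_sd must be > 0")
        if self.z_chrom_id not in self.chromosome_ids:
            raise ConfigError(f"z_chrom_id {self.z_chrom_id!r} not among chromosomes")
        if self.neo_z_chrom_id is not None:
            if self.neo_z_chrom_id not in self.chromosome_ids:
                raise ConfigError(f"neo_z_chrom_id {self.neo_z_chrom_id!r} unknown")
            if self.neo_z_chrom_id == self.z_chrom_id:
                raise ConfigError("neo-Z cannot be the Z itself")
        if self.n_males < 1 or self.n_females < 1:
            raise ConfigError("need at least one library per sex")

    @property
    def chromosome_ids(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    @property
    def autosome_ids(self) -> list[str]:
        skip = {self.z_chrom_id}
        return [c for c in self.chromosome_ids if c not in skip]

    @property
    def sample_sex(self) -> dict[str, str]:
        samples = {f"male_{i+1}": "male" for i in range(self.n_males)}
        samples.update({f"female_{i+1}": "female" for i in range(self.n_females)})
        return samples


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``scaffolds``: scaffold → (chromosome, class, outlier flag);
    ``genes``: gene × species true linkage states plus the planted event;
    ``planted_moves``: (branch, direction) → gene count.
    """

    scaffolds: pd.DataFrame = None  # type: ignore[assignment]
    genes: pd.DataFrame = None  # type: ignore[assignment]
    planted_moves: dict[tuple[str, str], int] = field(default_factory=dict)
    n_ancestral_z: int = 0

    def scaffold_class(self) -> pd.Series:
        return self.scaffolds["cls"]


def _scaffold_classes(config: SimConfig) -> tuple[list[str], list[str]]:
    """Chromosome id and class for every simulated scaffold (deterministic
    proportional allocation, so realized fractions track the configured ones)."""
    chroms: list[str] = []
    classes: list[str] = []
    weights: list[tuple[str, str, float]] = []
    w_frac = config.w_scaffold_fraction if config.w_present else 0.0
    auto_ids = config.autosome_ids
    auto_frac = (1.0 - config.z_scaffold_fraction - w_frac) / len(auto_ids)
    weights.append((config.z_chrom_id, CLASS_Z, config.z_scaffold_fraction))
    if config.w_present:
        weights.append(("chrW", CLASS_W, w_frac))
    for c in auto_ids:
        cls = CLASS_NEOZ if c == config.neo_z_chrom_id else CLASS_A
        weights.append((c, cls, auto_frac))
    # largest-remainder apportionment of n_scaffolds among chromosomes
    quotas = np.array([w for _, _, w in weights]) * config.n_scaffolds
    counts = np.floor(quotas).astype(int)
    remainder = config.n_scaffolds - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    for (chrom, cls, _), n in zip(weights, counts):
        chroms.extend([chrom] * n)
        classes.extend([cls] * n)
    return chroms, classes


def simulate_assembly(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a fragmented assembly with known chromosome membership.

    Scaffold lengths are log-normal with a hard floor of
    ``min_scaffold_len`` bp, mimicking a short-read assembly that discards
    tiny contigs.  Returns ``(scaffolds, truth)`` where ``scaffolds`` has
    columns scaffold, length, and the truth records chromosome and class
    (A/Z/W/neoZ) per scaffold.
    """
    rng = np.random.default_rng(config.rng_seed)
    chroms, classes = _scaffold_classes(config)
    n = config.n_scaffolds
    lengths = np.maximum(
        rng.lognormal(config.scaffold_len_log_mean, config.scaffold_len_log_sd, n),
        config.min_scaffold_len,
    ).astype(int)
    ids = [f"scaffold_{i+1}" for i in range(n)]
    perm = rng.permutation(n)  # decouple scaffold naming from chromosome blocks
    scaffolds = pd.DataFrame({
        "scaffold": ids,
        "length": lengths,
        "chromosome": np.array(chroms)[perm],
        "cls": np.array(classes)[perm],
    }).set_index("scaffold")
    outlier = rng.random(n) < config.noise_outlier_fraction
    truth = TruthTable(
        scaffolds=scaffolds.assign(outlier=outlier)[["chromosome", "cls", "outlier"]],
    )
    return scaffolds[["length"]].copy(), truth


def _expected_depth(cls: str, sex: str, mean_depth: float) -> float:
    if cls == CLASS_A:
        return mean_depth
    if cls in (CLASS_Z, CLASS_NEOZ):
        return mean_depth / 2 if sex == "female" else mean_depth
    if cls == CLASS_W:
        return mean_depth / 2 if sex == "female" else 0.0
    raise ValueError(f"unknown scaffold class {cls!r}")


def simulate_coverage(
    scaffolds: pd.DataFrame, truth: TruthTable, config: SimConfig
) -> CoverageTable:
    """Per-library mean depths obeying sex-chromosome dosage.

    Autosomal scaffolds expect ``depth_mean_per_sample`` in every library;
    Z and neo-Z scaffolds half that in females; W scaffolds half in females
    and zero in males.  Collapsed-repeat outliers are multiplied by
    ``outlier_multiplier`` in both sexes.  Depth noise draws a
    negative-binomial total read count per scaffold whose variance reflects
    per-window overdispersion ``depth_dispersion`` averaged over
    length/read-length windows, then converts it back to mean depth;
    dispersion 0 returns the exact expectations.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    info = truth.scaffolds.loc[scaffolds.index]
    lengths = scaffolds["length"].to_numpy(dtype=float)
    frame = scaffolds[["length"]].copy()
    for sample, sex in config.sample_sex.items():
        exp = np.array([
            _expected_depth(cls, sex, config.depth_mean_per_sample)
            for cls in info["cls"]
        ])
        exp = np.where(info["outlier"], exp * config.outlier_multiplier, exp)
        if config.depth_dispersion == 0:
            depth = exp
        else:
            mu = exp * lengths / READ_LENGTH
            # per-window dispersion alpha averages to alpha*W/L per scaffold
            nb_n = lengths / (config.depth_dispersion * READ_LENGTH)
            reads = np.where(
                mu > 0,
                rng.negative_binomial(nb_n, nb_n / (nb_n + np.maximum(mu, 1e-12))),
                0,
            )
            depth = reads * READ_LENGTH / lengths
        frame[sample] = depth
    return CoverageTable(frame, config.sample_sex)


def simulate_ortholog_hits(
    scaffolds: pd.DataFrame, truth: TruthTable, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference genes, their chromosome map, and their hits on the assembly.

    Genes are laid out along reference chromosomes (Z carries
    ``z_gene_fraction`` of them; the W carries none, being essentially
    gene-free).  Each gene's best hit lands on a scaffold of its own
    chromosome, chosen length-weighted, with a score in [80, 200]; a
    ``spurious_hit_fraction`` of genes additionally get a lower-scoring hit
    on a random scaffold, exercising best-hit filtering downstream.

    Returns ``(hits, gene_map)``.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    auto_ids = config.autosome_ids
    n_z = int(round(config.n_genes * config.z_gene_fraction))
    gene_chroms = [config.z_chrom_id] * n_z
    gene_chroms += [auto_ids[i % len(auto_ids)] for i in range(config.n_genes - n_z)]
    rng.shuffle(gene_chroms)
    gene_map = pd.DataFrame({
        "gene": [f"gene_{i+1}" for i in range(config.n_genes)],
        "chromosome": gene_chroms,
    })
    # positions: consecutive 10-kb steps within each chromosome
    gene_map["start"] = gene_map.groupby("chromosome").cumcount() * 10_000

    by_chrom = truth.scaffolds.groupby("chromosome").groups
    lengths = scaffolds["length"]
    hit_rows = []
    for row in gene_map.itertuples():
        scafs = by_chrom.get(row.chromosome)
        if scafs is None:
            continue
        scafs = pd.Index(scafs)
        w = lengths.loc[scafs].to_numpy(dtype=float)
        scaf = rng.choice(scafs, p=w / w.sum())
        scaf_len = int(lengths.loc[scaf])
        g_len = min(int(rng.integers(300, 2000)), scaf_len)
        start = int(rng.integers(0, scaf_len - g_len + 1))
        score = int(rng.integers(80, 201))
        hit_rows.append((row.gene, scaf, start, start + g_len, score))
        if rng.random() < config.spurious_hit_fraction:
            other = rng.choice(scaffolds.index)
            o_len = int(lengths.loc[other])
            s_len = min(int(rng.integers(150, 600)), o_len)
            s_start = int(rng.integers(0, o_len - s_len + 1))
            hit_rows.append((row.gene, other, s_start, s_start + s_len,
                             max(50, score - int(rng.integers(20, 60)))))
    hits = pd.DataFrame(hit_rows, columns=["gene", "scaffold", "start", "end", "score"])
    return hits, gene_map


def simulate_linkage_matrix(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Four-species gene linkage matrix with planted movement events.

    ``z_gene_fraction`` of genes are ancestrally Z (state Z in all four
    species), the rest ancestrally autosomal.  Each planted
    :class:`MovementEvent` then flips states on the implicated species:
    gains recruit untouched ancestrally-autosomal genes, losses untouched
    ancestrally-Z genes.  With ``linkage_missing_fraction`` > 0, states are
    independently masked to U, shrinking the classified set.  The truth
    table records per-(branch, direction) planted counts, which movement
    inference recovers exactly in the noise-free (no masking) setting.
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    n = config.n_genes
    genes = [f"gene_{i+1}" for i in range(n)]
    n_z = int(round(n * config.z_gene_fraction))
    ancestral_z = np.zeros(n, dtype=bool)
    ancestral_z[rng.choice(n, size=n_z, replace=False)] = True
    matrix = pd.DataFrame(
        np.where(np.repeat(ancestral_z[:, None], len(SPECIES), axis=1), "Z", "A"),
        index=pd.Index(genes, name="gene"),
        columns=list(SPECIES),
    )

    branch_species = {
        "bmori": ["bmori"],
        "cohridella": ["cohridella"],
        "ndegeerella": ["ndegeerella"],
        DITRYSIA_ROOT: ["bmori", "cohridella"],
        DITRYSIA_PLUS_ADELIDAE: ["bmori", "cohridella", "ndegeerella"],
    }
    untouched = pd.Series(True, index=matrix.index)
    planted: dict[tuple[str, str], int] = {}
    event_col = pd.Series("none", index=matrix.index)
    for ev in config.movement_events:
        want_state = "A" if ev.direction == "onto" else "Z"
        pool = matrix.index[untouched & (matrix["tsylvina"] == want_state)]
        if len(pool) < ev.n_genes:
            raise ConfigError(
                f"not enough untouched {want_state}-background genes for {ev}"
            )
        chosen = rng.choice(pool, size=ev.n_genes, replace=False)
        new_state = "Z" if ev.direction == "onto" else "A"
        matrix.loc[chosen, branch_species[ev.branch]] = new_state
        untouched[chosen] = False
        event_col[chosen] = f"{ev.direction}:{ev.branch}"
        key = (ev.branch, ev.direction)
        planted[key] = planted.get(key, 0) + ev.n_genes

    if config.linkage_missing_fraction > 0:
        mask = rng.random(matrix.shape) < config.linkage_missing_fraction
        matrix = matrix.mask(pd.DataFrame(mask, index=matrix.index,
                                          columns=matrix.columns), "U")

    truth = TruthTable(
        genes=matrix.assign(ancestral_z=ancestral_z, event=event_col),
        planted_moves=planted,
        n_ancestral_z=int(ancestral_z.sum()),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# plain-text config round-trip (key = value, one per line)

_SCALARS = {
    f.name for f in SimConfig.__dataclass_fields__.values()
    if f.name != "movement_events"
}


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# zlink sim config v1\n")
        for name in sorted(_SCALARS):
            fh.write(f"{name} = {getattr(config, name)!r}\n")
        for ev in config.movement_events:
            fh.write(f"movement_event = {ev.branch},{ev.direction},{ev.n_genes}\n")


def read_config(path: str | Path) -> SimConfig:
    kwargs: dict = {}
    events: list[MovementEvent] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "movement_event":
                branch, direction, n = raw.split(",")
                events.append(MovementEvent(branch, direction, int(n)))
            elif key in _SCALARS:
                kwargs[key] = ast.literal_eval(raw)
            else:
                raise ConfigError(f"unknown config key {key!r}")
    return SimConfig(movement_events=events, **kwargs)
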