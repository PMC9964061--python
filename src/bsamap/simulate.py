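"""F2 pool-seq simulator.

Generates the data a mapping-by-sequencing experiment produces, with
the genetic structure the analysis assumes: an F2 from a cross between
a mutagenized line carrying one recessive causal mutation and the
reference accession.  Each individual inherits two gametes; each gamete
is a Markov chain along the ordered markers of a chromosome whose
switch probability between adjacent markers is the Haldane
recombination fraction for their map distance (crossovers without
interference).  Individuals homozygous for the mutant-parent allele at
the causal locus express the mutant phenotype with probability equal to
the penetrance.  Phenotype pools of the configured sizes are drawn
without replacement, and per-marker read counts are sampled with
zero-truncated Poisson depth and binomial allele sampling including a
symmetric per-read error rate.

Defaults mirror the experiment the package is built around: pools of
87 mutant and 170 wild-type plants, ~60x depth per pool, five
chromosomes with Arabidopsis-scale physical and genetic lengths, and a
causal G-to-A lesion near 1.28 Mb on chromosome 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DataError, MarkerTrack
from .io import write_marker_table, write_pooled_vcf

BASES = np.array(["A", "C", "G", "T"])

#: (name, physical length bp, genetic length cM) — Arabidopsis-scale
DEFAULT_CHROMOSOMES = [
    ("chr1", 30_400_000, 135.0),
    ("chr2", 19_700_000, 98.0),
    ("chr3", 23_500_000, 106.0),
    ("chr4", 18_600_000, 123.0),
    ("chr5", 27_000_000, 140.0),
]

DEFAULT_CAUSAL = ("chr2", 1_283_497)


@dataclass
class SimConfig:
    """Parameters of one simulated mapping-by-sequencing experiment."""

    chromosomes: list[tuple[str, int, float]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_CHROMOSOMES]
    )
    markers_per_chromosome: int = 2000
    causal: tuple[str, int] = DEFAULT_CAUSAL
    pool_size_mut: int = 87
    pool_size_wt: int = 170
    n_individuals: int = 600
    mean_depth: float = 60.0
    penetrance: float = 1.0
    sequencing_error: float = 0.001
    mispheno_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.chromosomes = [(str(n), int(l), float(g)) for n, l, g in self.chromosomes]
        self.causal = (str(self.causal[0]), int(self.causal[1]))
        names = [n for n, _, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise DataError("duplicate chromosome names")
        if self.causal[0] not in names:
            raise DataError(f"causal chromosome {self.causal[0]!r} not in config")
        length = dict((n, l) for n, l, _ in self.chromosomes)[self.causal[0]]
        if not (1 <= self.causal[1] <= length):
            raise DataError(f"causal position {self.causal[1]} outside its chromosome")
        if self.pool_size_mut < 1 or self.pool_size_wt < 1:
            raise DataError("pool sizes must be >= 1")
        if self.mean_depth <= 0:
            raise DataError("mean_depth must be > 0")
        if not (0 < self.penetrance <= 1):
            raise DataError("penetrance must be in (0, 1]")
        if not (0 <= self.sequencing_error < 0.5):
            raise DataError("sequencing_error must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosomes" in raw:
            raw["chromosomes"] = [
                (c["name"], c["length_bp"], c["length_cm"]) for c in raw["chromosomes"]
            ]
        if "causal" in raw:
            raw["causal"] = (raw["causal"]["chrom"], raw["causal"]["pos"])
        return cls(**raw)


@dataclass
class F2Cohort:
    """Simulated F2 individuals: genotypes per marker and phenotypes.

    Genotypes count copies (0/1/2) of the mutant-parent allele.
    """

    positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]  # (n_individuals, n_markers) int8
    phenotype_mutant: np.ndarray  # bool per individual
    causal_chrom: str
    causal_index: int

    @property
    def n_individuals(self) -> int:
        return int(self.phenotype_mutant.size)


def haldane_r(d_morgans: float) -> float:
    """Haldane map function: recombination fraction for a map distance.

    Assumes crossovers are a Poisson process (no interference):
    ``r = (1 - exp(-2d)) / 2``, approaching 1/2 for unlinked loci.
    """
    d = np.asarray(d_morgans, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = (1.0 - np.exp(-2.0 * d)) / 2.0
    return float(r) if np.isscalar(d_morgans) else r


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    positions: dict[str, np.ndarray] = {}
    for name, length, _ in config.chromosomes:
        n = min(config.markers_per_chromosome, length)
        pos = np.unique(rng.integers(1, length + 1, size=n))  # rare collisions tolerated
        if name == config.causal[0]:
            pos = np.unique(np.append(pos, config.causal[1]))
        positions[name] = pos.astype(np.int64)
    return positions


def _simulate_gametes(
    pos: np.ndarray, length_bp: int, length_cm: float, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Gamete alleles (0 = reference parent, 1 = mutant parent) per marker."""
    m = pos.size
    out = np.empty((n_gametes, m), dtype=np.int8)
    out[:, 0] = rng.random(n_gametes) < 0.5
    if m > 1:
        d_morgans = np.diff(pos) / length_bp * length_cm / 100.0
        r = (1.0 - np.exp(-2.0 * d_morgans)) / 2.0
        switches = rng.random((n_gametes, m - 1)) < r[None, :]
        parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        out[:, 1:] = out[:, [0]] ^ parity.astype(np.int8)
    return out


def simulate_f2(config: SimConfig, rng: np.random.Generator) -> F2Cohort:
    """Simulate one F2 cohort of ``config.n_individuals`` plants.

    Each individual is the union of two independent gametes per
    chromosome; the phenotype is mutant iff it is homozygous for the
    mutant-parent allele at the causal locus and a penetrance draw
    succeeds.  An optional mis-phenotyping rate flips labels at random.
    """
    positions = _marker_positions(config, rng)
    n = config.n_individuals
    genotypes: dict[str, np.ndarray] = {}
    for name, length, cm in config.chromosomes:
        g1 = _simulate_gametes(positions[name], length, cm, n, rng)
        g2 = _simulate_gametes(positions[name], length, cm, n, rng)
        genotypes[name] = g1 + g2

    causal_chrom, causal_pos = config.causal
    causal_index = int(np.searchsorted(positions[causal_chrom], causal_pos))
    homozygous = genotypes[causal_chrom][:, causal_index] == 2
    expressed = rng.random(n) < config.penetrance
    phenotype = homozygous & expressed
    if config.mispheno_rate > 0:
        flip = rng.random(n) < config.mispheno_rate
        phenotype = phenotype ^ flip
    return F2Cohort(positions, genotypes, phenotype, causal_chrom, causal_index)


def _truncated_poisson(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    depth = rng.poisson(lam, size=size)
    zero = depth == 0
    while zero.any():
        depth[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = depth == 0
    return depth


def pool_and_sequence(
    cohort: F2Cohort, config: SimConfig, rng: np.random.Generator
) -> dict[str, MarkerTrack]:
    """Draw the two phenotype pools and sample read counts per marker.

    Pools are sampled without replacement from each phenotype class
    (an explicit error names the shortfall if a class is too small).
    Per marker and pool the true mutant-allele fraction q is the pooled
    genotype mean; depth is zero-truncated Poisson and alt reads are
    Binomial(depth, q(1-e) + (1-q)e) for error rate e.  The alt allele
    is the mutant-parent allele; the causal site is a G-to-A change.
    """
    mut_idx = np.flatnonzero(cohort.phenotype_mutant)
    wt_idx = np.flatnonzero(~cohort.phenotype_mutant)
    if mut_idx.size < config.pool_size_mut:
        raise DataError(
            f"mutant class has {mut_idx.size} individuals; "
            f"{config.pool_size_mut} needed for the pool"
        )
    if wt_idx.size < config.pool_size_wt:
        raise DataError(
            f"wild-type class has {wt_idx.size} individuals; "
            f"{config.pool_size_wt} needed for the pool"
        )
    mut_pool = rng.choice(mut_idx, size=config.pool_size_mut, replace=False)
    wt_pool = rng.choice(wt_idx, size=config.pool_size_wt, replace=False)

    eps = config.sequencing_error
    tracks: dict[str, MarkerTrack] = {}
    for name, _, _ in config.chromosomes:
        pos = cohort.positions[name]
        m = pos.size
        geno = cohort.genotypes[name]
        q_wt = geno[wt_pool].sum(axis=0) / (2.0 * config.pool_size_wt)
        q_mut = geno[mut_pool].sum(axis=0) / (2.0 * config.pool_size_mut)

        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        ref = BASES[ref_idx]
        alt = BASES[alt_idx]
        if name == cohort.causal_chrom:
            ref[cohort.causal_index] = "G"
            alt[cohort.causal_index] = "A"

        cols = {}
        for pool_name, q in (("wt", q_wt), ("mut", q_mut)):
            depth = _truncated_poisson(config.mean_depth, m, rng)
            p_alt = q * (1 - eps) + (1 - q) * eps
            alt_reads = rng.binomial(depth, p_alt)
            cols[f"{pool_name}_ref"] = depth - alt_reads
            cols[f"{pool_name}_alt"] = alt_reads
        tracks[name] = MarkerTrack(
            name, pos, ref, alt,
            cols["wt_ref"], cols["wt_alt"], cols["mut_ref"], cols["mut_alt"],
        )
    return tracks


def make_scenario(
    config: SimConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Simulate one experiment and write it to disk.

    Writes ``markers.tsv`` (pooled counts), ``pools.vcf`` (two-sample
    VCF with AD fields), ``truth.tsv`` (the causal position, for
    recovery scoring) and ``params.json``.  Byte-identical outputs for
    the same seed.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cohort = simulate_f2(config, rng)
    tracks = pool_and_sequence(cohort, config, rng)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "markers.tsv",
        "vcf": out / "pools.vcf",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    write_marker_table(tracks, paths["markers"])
    write_pooled_vcf(
        tracks,
        paths["vcf"],
        contig_lengths={n: l for n, l, _ in config.chromosomes},
    )
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tn_mutant_class\tn_wt_class\n")
        fh.write(
            f"{config.causal[0]}\t{config.causal[1]}\t"
            f"{int(cohort.phenotype_mutant.sum())}\t"
            f"{int((~cohort.phenotype_mutant).sum())}\n"
        )
    with open(paths["params"], "w") as fh:
        record = {
            "seed": seed,
            "chromosomes": [list(c) for c in config.chromosomes],
            "markers_per_chromosome": config.markers_per_chromosome,
            "causal": list(config.causal),
            "pool_size_mut": config.pool_size_mut,
            "pool_size_wt": config.pool_size_wt,
            "n_individuals": config.n_individuals,
            "mean_depth": config.mean_depth,
            "penetrance": config.penetrance,
            "sequencing_error": config.sequencing_error,
            "mispheno_rate": config.mispheno_rate,
        }
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
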