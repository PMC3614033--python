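"""Forward simulation of the full bulk-segregant experiment.

The generator produces every input the inference stages consume, with
the statistical structure the analysis assumes:

1. **Mutator evolution** — a haploid clone accumulates a handful of
   strongly selected (causal) mutations in designated genes plus on the
   order of a hundred neutral hitchhikers scattered over the genome, on
   top of a few variants already present in the time-zero founder.
2. **Backcross meiosis** — the clone x ancestor diploid is sporulated;
   each spore inherits a per-chromosome mosaic of the two haplotypes.
   Crossovers follow a no-interference (Poisson) model, so the
   probability that two loci ``d`` cM apart are separated is the
   Haldane recombination fraction ``r = (1 - exp(-2d/100)) / 2`` and
   loci on different chromosomes assort independently.
3. **Spore selection** — growth through serial passages is modeled as
   deterministic exponential weighting: a spore's final weight is
   proportional to ``prod(1 + s_i) ** generations`` over the causal
   alleles it carries (34 generations by default, the total implied by
   one 100:1 and three 500:1 dilutions).  An optional stochastic mode
   resamples the population through explicit passage bottlenecks.
4. **Pooled sequencing** — per-variant read totals are Poisson around
   the target coverage and mutant reads are binomial with a symmetric
   per-read error rate.
5. **Depth tracks and Sanger traces** — windowed coverage with planted
   copy-number events, and peak-height time courses with truncated
   Gaussian noise, for the CNV and trace modules.

All randomness flows from a single seed; identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bsakit.cnv import DepthProfile
from bsakit.errors import InvalidInputError
from bsakit.genome import GeneModel, Genome, Variant, VariantEffect, annotate_variant

_BASES = np.frombuffer(b"ACGT", dtype="S1")

ROLE_CAUSAL = "causal"
ROLE_HITCHHIKER = "hitchhiker"
ROLE_TIMEZERO = "timezero"


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction at map distance ``d`` cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study conditions this pipeline targets: a
    yeast-scale 16-chromosome genome (length scaled down to keep
    simulation cheap), a genetic map density of 0.4 cM/kb, five causal
    mutations of selection coefficient 0.1 over ~100 hitchhikers
    (the scale of the most parsimonious evolved clone), 34 generations
    of spore selection, and 90x pool coverage.
    """

    n_chromosomes: int = 16
    chromosome_length_bp: int = 100_000
    cm_per_bp: float = 4e-4
    n_causal: int = 5
    selection_coefficients: float | tuple[float, ...] = 0.1
    n_hitchhikers: int = 110
    n_timezero: int = 5
    evolution_generations: int = 273
    selection_generations: int = 34
    n_spores: int = 10_000
    pool_coverage: float = 90.0
    seq_error_rate: float = 0.001
    seed: int = 0
    # layout knobs
    n_genes: int = 30
    gene_length_bp: int = 1500
    promoter_window: int = 500
    causal_promoter_prob: float = 0.2
    # when set, the hitchhiker count is drawn Poisson(generations * rate)
    mutations_per_generation: Optional[float] = None

    def __post_init__(self):
        if min(self.n_chromosomes, self.chromosome_length_bp) <= 0:
            raise InvalidInputError("genome dimensions must be positive")
        if min(self.n_causal, self.n_hitchhikers, self.n_timezero, self.n_spores) < 0:
            raise InvalidInputError("counts must be non-negative")
        if self.pool_coverage <= 0:
            raise InvalidInputError("coverage must be positive")
        if not 0 <= self.seq_error_rate < 0.5:
            raise InvalidInputError("seq_error_rate must be in [0, 0.5)")
        if self.gene_length_bp % 3:
            raise InvalidInputError("gene_length_bp must be divisible by 3")

    def s_values(self) -> tuple[float, ...]:
        s = self.selection_coefficients
        if isinstance(s, (int, float)):
            return (float(s),) * self.n_causal
        if len(s) != self.n_causal:
            raise InvalidInputError("selection_coefficients length must equal n_causal")
        if any(x < 0 for x in s):
            raise InvalidInputError("selection coefficients must be >= 0")
        return tuple(float(x) for x in s)


@dataclass(frozen=True)
class PlantedVariant:
    """A simulated mutation with its role, genetic-map position, and fitness effect."""

    variant: Variant
    role: str
    map_position_cm: float
    s: float
    effect: Optional[VariantEffect] = None


@dataclass
class CloneGenotype:
    """The evolved clone: genome, gene models, and planted mutations."""

    genome: Genome
    genes: list[GeneModel]
    variants: list[PlantedVariant]
    config: SimConfig

    def by_role(self, role: str) -> list[PlantedVariant]:
        return [pv for pv in self.variants if pv.role == role]

    def variant_list(self, include_timezero: bool = True) -> list[Variant]:
        return [
            pv.variant for pv in self.variants
            if include_timezero or pv.role != ROLE_TIMEZERO
        ]


@dataclass
class SporePool:
    """Per-variant allele frequencies in the selected spore pool."""

    frequencies: np.ndarray  # aligned with CloneGenotype.variants
    spores: Optional[np.ndarray] = None  # (n_spores, n_variants) carrier matrix
    weights: Optional[np.ndarray] = None


@dataclass
class PoolCounts:
    """Pooled-sequencing read counts per variant (mutant / total)."""

    mutant_reads: np.ndarray
    total_reads: np.ndarray

    def __post_init__(self):
        if np.any(self.mutant_reads > self.total_reads) or np.any(self.mutant_reads < 0):
            raise InvalidInputError("mutant reads must lie in [0, total reads]")


def _random_genome(rng: np.random.Generator, config: SimConfig) -> Genome:
    chroms = {}
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chromosome_length_bp)
        chroms[f"chr{i + 1:02d}"] = _BASES[idx].tobytes().decode()
    return Genome(chroms)


def _place_genes(rng: np.random.Generator, config: SimConfig) -> list[GeneModel]:
    """Scatter non-overlapping single-exon genes; the first ``n_causal`` are
    placed on distinct chromosomes so causal loci assort independently."""
    margin = config.promoter_window + 10
    occupied: dict[str, list[tuple[int, int]]] = {}
    genes: list[GeneModel] = []

    def try_place(name: str, chrom: str) -> Optional[GeneModel]:
        lo = margin + 1
        hi = config.chromosome_length_bp - config.gene_length_bp - margin
        if hi <= lo:
            return None
        start = int(rng.integers(lo, hi))
        end = start + config.gene_length_bp - 1
        for a, b in occupied.get(chrom, []):
            if not (end + margin < a or start - margin > b):
                return None
        occupied.setdefault(chrom, []).append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        return GeneModel(name, chrom, strand, start, end, config.promoter_window)

    if config.n_causal > config.n_chromosomes:
        raise InvalidInputError("need at least one chromosome per causal gene")
    causal_chroms = rng.choice(config.n_chromosomes, size=config.n_causal, replace=False)
    for i in range(config.n_genes):
        name = f"GENE{i + 1:03d}"
        for _ in range(200):
            if i < config.n_causal:
                chrom = f"chr{causal_chroms[i] + 1:02d}"
            else:
                chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1:02d}"
            gene = try_place(name, chrom)
            if gene is not None:
                genes.append(gene)
                break
        else:
            raise InvalidInputError("could not place genes without overlap; genome too small")
    return genes


def _substitution_at(rng: np.random.Generator, genome: Genome, chrom: str, pos: int) -> Variant:
    ref = genome.fetch(chrom, pos, pos)
    alt = ref
    while alt == ref:
        alt = chr(_BASES[rng.integers(0, 4)][0])
    return Variant(chrom, pos, ref, alt)


def _plant_causal(
    rng: np.random.Generator, genome: Genome, genes: list[GeneModel],
    gene: GeneModel, promoter_prob: float,
) -> tuple[Variant, VariantEffect]:
    """Draw a protein- or promoter-altering substitution inside ``gene``."""
    for _ in range(500):
        if rng.random() < promoter_prob:
            k = int(rng.integers(1, gene.promoter_window + 1))
            pos = gene.cds_start - k if gene.strand == "+" else gene.cds_end + k
        else:
            off = int(rng.integers(gene.cds_length))
            pos = gene.cds_start + off
        v = _substitution_at(rng, genome, gene.chromosome, pos)
        eff = annotate_variant(genome, genes, v)
        if eff.gene == gene.name and eff.is_nonsynonymous:
            return v, eff
    raise InvalidInputError(f"failed to plant a causal mutation in {gene.name}")


def simulate_evolved_clone(config: SimConfig) -> CloneGenotype:
    """Generate the evolved mutator clone with annotated planted mutations.

    Causal mutations are placed in the CDS or promoter of dedicated
    genes (one per gene, distinct chromosomes); hitchhikers and
    time-zero variants are substitutions at uniform random genomic
    positions, so their coding/synonymous/intergenic mix follows the
    gene density of the simulated genome.  Position collisions are
    regenerated with fresh draws.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config)
    genes = _place_genes(rng, config)
    used: set[tuple[str, int]] = set()
    planted: list[PlantedVariant] = []

    s_vals = config.s_values()
    for i in range(config.n_causal):
        gene = genes[i]
        for _ in range(100):
            v, eff = _plant_causal(rng, genome, genes, gene, config.causal_promoter_prob)
            if (v.chromosome, v.position) not in used:
                break
        used.add((v.chromosome, v.position))
        planted.append(PlantedVariant(v, ROLE_CAUSAL, v.position * config.cm_per_bp, s_vals[i], eff))

    n_hh = config.n_hitchhikers
    if config.mutations_per_generation is not None:
        n_hh = int(rng.poisson(config.evolution_generations * config.mutations_per_generation))
    for role, count in ((ROLE_HITCHHIKER, n_hh), (ROLE_TIMEZERO, config.n_timezero)):
        for _ in range(count):
            while True:
                chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1:02d}"
                pos = int(rng.integers(1, config.chromosome_length_bp + 1))
                if (chrom, pos) not in used:
                    break
            used.add((chrom, pos))
            v = _substitution_at(rng, genome, chrom, pos)
            eff = annotate_variant(genome, genes, v)
            planted.append(PlantedVariant(v, role, pos * config.cm_per_bp, 0.0, eff))
    return CloneGenotype(genome, genes, planted, config)


def simulate_meiosis(
    clone: CloneGenotype,
    n_spores: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Segregate the clone's variants through meiosis.

    Returns a boolean carrier matrix of shape ``(n_spores, n_variants)``
    aligned with ``clone.variants``: entry ``[j, i]`` is True when spore
    ``j`` inherited the evolved allele at locus ``i``.

    Under the no-interference model the haplotype along a chromosome is
    Markov, so it is generated locus-to-locus: the first locus is a fair
    coin and the haplotype switches between adjacent loci ``d`` cM apart
    with probability ``haldane_r(d)``.  This reproduces the Haldane
    recombination fraction between *every* pair of loci, not just
    adjacent ones, because Haldane's function is closed under the
    two-locus composition rule.
    """
    if n_spores is None:
        n_spores = clone.config.n_spores
    if n_spores <= 0:
        raise InvalidInputError("n_spores must be positive")
    if rng is None:
        rng = np.random.default_rng(clone.config.seed + 1 if seed is None else seed)
    n_var = len(clone.variants)
    carriers = np.zeros((n_spores, n_var), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, pv in enumerate(clone.variants):
        by_chrom.setdefault(pv.variant.chromosome, []).append(i)
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda i: clone.variants[i].map_position_cm)
        hap = rng.random(n_spores) < 0.5
        carriers[:, idx[0]] = hap
        for prev, cur in zip(idx, idx[1:]):
            d = clone.variants[cur].map_position_cm - clone.variants[prev].map_position_cm
            switch = rng.random(n_spores) < haldane_r(d)
            hap = hap ^ switch
            carriers[:, cur] = hap
    return carriers


def select_spores(
    clone: CloneGenotype,
    spores: np.ndarray,
    selection_generations: Optional[int] = None,
    stochastic: bool = False,
    dilution_factors: Sequence[float] = (100, 500, 500, 500),
    bottleneck_cells: int = 500_000,
    rng: Optional[np.random.Generator] = None,
) -> SporePool:
    """Grow the spore pool under selection and return pool allele frequencies.

    Deterministic mode (default): spore ``j``'s weight is
    ``prod over carried causal alleles (1 + s) ** g`` with ``g`` the
    total selection generations; the pool frequency of a variant is the
    weight share of its carriers.  Stochastic mode resamples the
    population multinomially at each passage bottleneck, with the
    generations per passage set by ``log2`` of its dilution factor.
    """
    if selection_generations is None:
        selection_generations = clone.config.selection_generations
    causal_idx = [i for i, pv in enumerate(clone.variants) if pv.role == ROLE_CAUSAL]
    log_s = np.array([math.log1p(clone.variants[i].s) for i in causal_idx])
    per_gen_log = spores[:, causal_idx].astype(float) @ log_s if causal_idx else np.zeros(len(spores))

    if not stochastic:
        logw = per_gen_log * selection_generations
        w = np.exp(logw - logw.max())
        freqs = (w @ spores) / w.sum()
        return SporePool(frequencies=freqs, spores=spores, weights=w)

    if rng is None:
        rng = np.random.default_rng(clone.config.seed + 2)
    counts = np.full(len(spores), bottleneck_cells / len(spores))
    for factor in dilution_factors:
        g = math.log2(factor)
        grown = counts * np.exp(per_gen_log * g)
        p = grown / grown.sum()
        counts = rng.multinomial(bottleneck_cells, p).astype(float)
    p = counts / counts.sum()
    freqs = p @ spores
    return SporePool(frequencies=freqs, spores=spores, weights=counts)


def sample_pool_reads(
    pool: SporePool,
    coverage: float = 90.0,
    seq_error_rate: float = 0.001,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PoolCounts:
    """Binomial read sampling of the pool at Poisson-distributed depth.

    Each read reports the mutant allele with probability
    ``f * (1 - e) + (1 - f) * e`` where ``f`` is the true pool frequency
    and ``e`` the per-read error rate.
    """
    if coverage <= 0:
        raise InvalidInputError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    f = np.asarray(pool.frequencies, dtype=float)
    total = rng.poisson(coverage, size=f.shape)
    p = f * (1.0 - seq_error_rate) + (1.0 - f) * seq_error_rate
    mutant = rng.binomial(total, p)
    return PoolCounts(mutant_reads=mutant, total_reads=total)


@dataclass(frozen=True)
class CNVEvent:
    """A planted copy-number event in the evolved clone."""

    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int
    clone_copies: float  # copy number in the clone (ancestor has 1)
    causal: bool = False


def simulate_depth_profiles(
    config: SimConfig,
    cnv_events: Sequence[CNVEvent] = (),
    window_bp: int = 1000,
    seed: Optional[int] = None,
) -> tuple[DepthProfile, DepthProfile, DepthProfile]:
    """Windowed read-depth tracks for ancestor, clone, and selected pool.

    Per-window depths are Poisson around ``coverage x copy number``.
    The ancestor is single-copy everywhere.  A heterozygous-origin event
    that is *not* under selection segregates into half the selected
    spores, so the pool sits midway between ancestor and clone copy
    number (e.g. a clone duplication at 2.0x appears at 1.5x in the
    pool); a causal event is retained by selection and keeps the clone's
    copy number in the pool.
    """
    for i, a in enumerate(cnv_events):
        if a.start > a.end or a.start < 1:
            raise InvalidInputError(f"bad CNV interval {a}")
        for b in cnv_events[i + 1 :]:
            if a.chromosome == b.chromosome and not (a.end < b.start or b.end < a.start):
                raise InvalidInputError("overlapping CNV events rejected")
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    profiles = []
    for which in ("ancestor", "clone", "pool"):
        rows = []
        for c in range(config.n_chromosomes):
            chrom = f"chr{c + 1:02d}"
            starts = np.arange(0, config.chromosome_length_bp, window_bp)
            ends = np.minimum(starts + window_bp, config.chromosome_length_bp)
            copy = np.ones(len(starts))
            if which != "ancestor":
                for ev in cnv_events:
                    if ev.chromosome != chrom:
                        continue
                    cn = ev.clone_copies if (which == "clone" or ev.causal) else (ev.clone_copies + 1) / 2
                    mask = (starts + 1 <= ev.end) & (ends >= ev.start)
                    copy[mask] = cn
            depth = rng.poisson(config.pool_coverage * copy)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": depth}))
        profiles.append(DepthProfile(pd.concat(rows, ignore_index=True), window_bp=window_bp))
    return tuple(profiles)


def simulate_sanger_timecourse(
    frequencies: Sequence[float],
    noise_sd: float = 0.02,
    seed: Optional[int] = None,
    allele: str = "allele1",
    time_points: Optional[Sequence[float]] = None,
    total_height: float = 1000.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Emit mutant/ancestral peak heights whose ratio tracks a frequency trajectory.

    The observed fraction at each time point is the true frequency plus
    Gaussian noise truncated to [0, 1]; peak heights share a fixed total.
    Returns a tidy frame with columns allele, time_point, h_mut, h_anc.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise InvalidInputError("frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape) if noise_sd > 0 else f, 0.0, 1.0)
    if time_points is None:
        time_points = np.arange(len(f))
    return pd.DataFrame({
        "allele": allele,
        "time_point": np.asarray(time_points),
        "h_mut": obs * total_height,
        "h_anc": (1.0 - obs) * total_height,
    })


def logistic_trajectory(
    s: float, generations: Sequence[float], p0: float = 1e-3
) -> np.ndarray:
    """Expected sweep trajectory of an allele with advantage ``s`` from frequency ``p0``."""
    g = np.asarray(generations, dtype=float)
    odds = p0 / (1 - p0) * np.power(1 + s, g)
    return odds / (1 + odds)
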