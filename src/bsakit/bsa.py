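"""Causal-mutation discovery from pooled-segregant allele frequencies.

The backcross pool separates causal mutations from hitchhikers: an
allele that drives the selected phenotype is carried by nearly every
selected spore, while a neutral allele segregates in about half of
them.  A variant is called *putatively causal* when

1. it arose during the evolution (present in the clone, absent from the
   ancestor, and not already present in the time-zero founder),
2. it is protein-altering or within the promoter window of a gene, and
3. its mutant-read fraction in the selected pool is strictly above the
   threshold (default 0.9).

Fractions are kept as exact rationals so the strict >90% boundary never
suffers float round-off.  Linked pairs of causal calls are additionally
screened for hitchhiking: within a configurable genetic-map radius the
lower-fraction allele of a pair is flagged as likely carried along by
its neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from bsakit.errors import DataIntegrityError, MissingDataError
from bsakit.genome import Variant, VariantEffect

logger = logging.getLogger(__name__)

CAUSAL_THRESHOLD = Fraction(9, 10)
LINKAGE_RADIUS_CM = 25.0
MIN_DEPTH = 10

# classification labels
PUTATIVE_CAUSAL = "putative_causal"
NON_CAUSAL = "non_causal"
EXCLUDED_TIMEZERO = "excluded_timezero"
EXCLUDED_SILENT = "excluded_synonymous_or_intergenic"
UNCALLABLE = "uncallable"


@dataclass
class CandidateMutation:
    """One clone variant with its effect, pool fraction, and classification."""

    variant: Optional[Variant]
    effect: VariantEffect
    mutant_reads: int
    total_reads: int
    classification: str = NON_CAUSAL
    hitchhiker_flag: bool = False
    linked_to: Optional[str] = None
    clone: Optional[str] = None

    @property
    def pool_fraction(self) -> Optional[Fraction]:
        if self.total_reads == 0:
            return None
        return Fraction(self.mutant_reads, self.total_reads)

    @property
    def gene(self) -> Optional[str]:
        return self.effect.gene


@dataclass
class CloneReport:
    """Gene-level summary of one clone's candidate mutations."""

    clone: str
    candidates: list[CandidateMutation]
    gene_level_causal_count: int = 0
    distinct_gene_list: list[str] = field(default_factory=list)


def call_clone_mutations(
    ancestor_variants: Sequence[Variant],
    clone_variants: Sequence[Variant],
    timezero_variants: Sequence[Variant] = (),
) -> tuple[list[Variant], set[Variant]]:
    """Variants private to the evolved clone, plus the time-zero exclusion set.

    Returns ``(de_novo, timezero_hits)``: clone variants absent from the
    ancestor, and the subset of those already carried by the time-zero
    founder strain (which segregate above threshold but are not products
    of the evolution and must never be classified causal).
    """
    for name, vs in (("ancestor", ancestor_variants), ("clone", clone_variants), ("timezero", timezero_variants)):
        seen: dict[tuple[str, int], Variant] = {}
        for v in vs:
            key = (v.chromosome, v.position)
            if key in seen and seen[key] != v:
                raise DataIntegrityError(f"{name} set: conflicting alleles at {key}")
            seen[key] = v
    ancestor = set(ancestor_variants)
    timezero = set(timezero_variants)
    de_novo = [v for v in clone_variants if v not in ancestor]
    return de_novo, {v for v in de_novo if v in timezero}


def compute_pool_fraction(mutant_reads: int, total_reads: int) -> Fraction:
    """Exact mutant-read fraction in the selected spore pool."""
    if total_reads == 0:
        raise MissingDataError("variant has zero covering reads; fraction uncallable")
    if not 0 <= mutant_reads <= total_reads:
        raise DataIntegrityError(f"mutant reads {mutant_reads} outside [0, {total_reads}]")
    return Fraction(mutant_reads, total_reads)


def classify_causal(
    effect: VariantEffect,
    fraction: Optional[Fraction],
    threshold: Fraction | float = CAUSAL_THRESHOLD,
    is_timezero: bool = False,
    total_reads: Optional[int] = None,
    min_depth: int = MIN_DEPTH,
) -> str:
    """Apply the three-way selection rule to one annotated variant.

    Strict inequality at the threshold: a fraction exactly equal to it
    is *not* causal.  Time-zero variants are excluded regardless of
    fraction, as are synonymous and intergenic changes.
    """
    if is_timezero:
        return EXCLUDED_TIMEZERO
    if not effect.is_nonsynonymous:
        return EXCLUDED_SILENT
    if fraction is None or (total_reads is not None and total_reads < min_depth):
        return UNCALLABLE
    threshold = Fraction(threshold).limit_denominator(10**9) if not isinstance(threshold, Fraction) else threshold
    return PUTATIVE_CAUSAL if fraction > threshold else NON_CAUSAL


def flag_hitchhikers(
    candidates: Iterable[CandidateMutation],
    map_positions: Mapping[str, tuple[str, float]],
    linkage_radius_cm: float = LINKAGE_RADIUS_CM,
) -> list[CandidateMutation]:
    """Flag the lower-fraction member of each linked pair of causal calls.

    ``map_positions`` maps gene name -> (chromosome, genetic-map
    position in cM).  Two putative-causal candidates on the same
    chromosome within ``linkage_radius_cm`` of each other are unlikely
    to both be causal; the one at lower pool fraction is flagged as a
    probable hitchhiker and records the gene it is linked to.  Exact
    fraction ties flag neither (with a warning).  Flagged candidates
    keep their classification but are separated in reports.
    """
    cands = list(candidates)
    causal = [c for c in cands if c.classification == PUTATIVE_CAUSAL and c.gene in map_positions]
    for i, a in enumerate(causal):
        for b in causal[i + 1 :]:
            chrom_a, cm_a = map_positions[a.gene]
            chrom_b, cm_b = map_positions[b.gene]
            if chrom_a != chrom_b or abs(cm_a - cm_b) > linkage_radius_cm:
                continue
            if a.pool_fraction == b.pool_fraction:
                logger.warning(
                    "linked causal pair %s/%s with identical pool fractions; flagging neither",
                    a.gene, b.gene,
                )
                continue
            low, high = (a, b) if a.pool_fraction < b.pool_fraction else (b, a)
            low.hitchhiker_flag = True
            low.linked_to = high.gene
    return cands


def summarize_clone(clone: str, candidates: Sequence[CandidateMutation]) -> CloneReport:
    """Collapse a clone's causal calls to gene level.

    Multiple causal nucleotide changes in one gene of one clone count as
    a single gene-level mutation.  Hitchhiker-flagged calls are excluded
    from the gene-level count (they are reported separately).
    """
    genes: list[str] = []
    for c in candidates:
        if c.classification == PUTATIVE_CAUSAL and not c.hitchhiker_flag and c.gene:
            if c.gene not in genes:
                genes.append(c.gene)
        c.clone = clone
    return CloneReport(
        clone=clone,
        candidates=list(candidates),
        gene_level_causal_count=len(genes),
        distinct_gene_list=genes,
    )


def cross_clone_summary(
    reports: Sequence[CloneReport],
    pathways: Optional[Mapping[str, Sequence[str]]] = None,
) -> dict:
    """Aggregate clone reports into the study-wide tallies.

    Returns a dict with ``total_causal`` (gene-level, summed over
    clones), ``distinct_genes``, ``gene_clone_counts`` (gene -> number
    of clones carrying a causal mutation in it), ``genes_mutated_once``,
    and, when ``pathways`` maps pathway name -> gene list,
    ``pathway_clone_counts`` (pathway -> clones carrying a causal
    mutation in any member gene).
    """
    if not reports:
        raise MissingDataError("no clone reports to summarize")
    gene_clones: dict[str, set[str]] = {}
    total = 0
    for rep in reports:
        total += rep.gene_level_causal_count
        for gene in rep.distinct_gene_list:
            gene_clones.setdefault(gene, set()).add(rep.clone)
    gene_clone_counts = {g: len(cs) for g, cs in sorted(gene_clones.items())}
    summary = {
        "total_causal": total,
        "distinct_genes": len(gene_clones),
        "gene_clone_counts": gene_clone_counts,
        "genes_mutated_once": sum(1 for n in gene_clone_counts.values() if n == 1),
    }
    if pathways:
        pw_counts = {}
        for pw, members in pathways.items():
            members = set(members)
            pw_counts[pw] = len({
                rep.clone for rep in reports if members & set(rep.distinct_gene_list)
            })
        summary["pathway_clone_counts"] = pw_counts
    return summary


def report_frame(reports: Sequence[CloneReport]) -> pd.DataFrame:
    """Flatten clone reports into a tidy table (one row per nucleotide change)."""
    rows = []
    for rep in reports:
        for c in rep.candidates:
            rows.append({
                "clone": rep.clone,
                "gene": c.gene,
                "nt_name": c.effect.nt_name,
                "aa_name": c.effect.aa_name,
                "mutant_reads": c.mutant_reads,
                "total_reads": c.total_reads,
                "pool_fraction": float(c.pool_fraction) if c.pool_fraction is not None else float("nan"),
                "classification": c.classification,
                "hitchhiker_flag": c.hitchhiker_flag,
                "linked_to": c.linked_to or "",
            })
    return pd.DataFrame(
        rows,
        columns=[
            "clone", "gene", "nt_name", "aa_name", "mutant_reads", "total_reads",
            "pool_fraction", "classification", "hitchhiker_flag", "linked_to",
        ],
    )
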