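"""Genomes, single-exon gene models, variant effects, and mutation names.

Coordinates follow the conventions of classical yeast genetics reports:

* genomic and CDS positions are 1-based and inclusive;
* CDS positions are counted in coding orientation starting at 1 (the A of
  the ATG in a real gene);
* promoter positions are negative, with -1 the base immediately upstream
  of the coding start and no position 0; the promoter window extends
  ``promoter_window`` bp upstream (500 by default, inclusive at -500).

Nucleotide-level names are CDS-relative: ``"703 G->T"`` for a
substitution at CDS base 703, ``"100_100delT"`` / ``"2494_2495insT"``
for indels, and negative coordinates (``"-379 G->A"``) for promoter
variants.  Protein-level names are ``XNY`` (missense), ``XN*``
(nonsense, ``*`` is a stop), ``XNYfsN'`` (frameshift whose new reading
frame terminates at codon ``N'``), or ``"Promoter"``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from bsakit.errors import InvalidInputError, RefMismatchError

_VALID_BASES = frozenset("ACGT")

#: How far past the reference stop the frameshift stop-scan may read.
FRAMESHIFT_SCAN_BP = 300


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise InvalidInputError(f"{what}: empty sequence")
    if set(seq) - _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise InvalidInputError(f"{what}: non-ACGT characters {bad}")
    return seq


class Genome:
    """An ordered collection of named chromosome sequences (A/C/G/T only)."""

    def __init__(self, chromosomes: dict[str, str]):
        self.chromosomes: dict[str, str] = {
            name: _check_seq(seq, f"chromosome {name!r}") for name, seq in chromosomes.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return the sequence of ``name`` from ``start`` to ``end``, 1-based inclusive."""
        if start < 1 or end > self.length(name) or start > end:
            raise InvalidInputError(
                f"fetch {name}:{start}-{end} outside chromosome of length {self.length(name)}"
            )
        return self.chromosomes[name][start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A single-exon CDS with an upstream promoter window.

    Budding-yeast genes are overwhelmingly intronless, so a single
    ``[cds_start, cds_end]`` interval per gene suffices for annotating
    point mutations and small indels.
    """

    name: str
    chromosome: str
    strand: str
    cds_start: int
    cds_end: int
    promoter_window: int = 500

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"gene {self.name}: strand must be '+' or '-'")
        if self.cds_start > self.cds_end:
            raise InvalidInputError(f"gene {self.name}: cds_start > cds_end")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise InvalidInputError(f"gene {self.name}: CDS length not divisible by 3")
        if self.promoter_window < 0:
            raise InvalidInputError(f"gene {self.name}: negative promoter window")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def coding_start(self) -> int:
        """Genomic coordinate of CDS base 1 (strand-aware)."""
        return self.cds_start if self.strand == "+" else self.cds_end

    def cds_sequence(self, genome: Genome) -> str:
        raw = genome.fetch(self.chromosome, self.cds_start, self.cds_end)
        return raw if self.strand == "+" else str(Seq(raw).reverse_complement())


@dataclass(frozen=True)
class Variant:
    """A substitution, insertion, or deletion in genomic coordinates.

    ``position`` is the mutated base for substitutions, the first
    deleted base for deletions, and the base immediately left of the
    insertion point for insertions (ref empty).
    """

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        for allele, what in ((self.ref, "ref"), (self.alt, "alt")):
            if set(allele) - _VALID_BASES:
                raise InvalidInputError(f"variant {what} allele {allele!r} is not ACGT")
        if self.ref and self.alt and len(self.ref) != len(self.alt):
            raise InvalidInputError(
                "complex ref/alt pairs unsupported; use pure substitution, insertion, or deletion"
            )
        if not self.ref and not self.alt:
            raise InvalidInputError("variant with empty ref and alt")
        if self.ref and self.alt and len(self.ref) != 1:
            raise InvalidInputError("multi-base substitutions unsupported")
        if self.position < 1:
            raise InvalidInputError("variant position must be >= 1")

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "substitution"
        return "deletion" if self.ref else "insertion"

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval of affected reference bases (inclusive)."""
        if self.kind == "deletion":
            return self.position, self.position + len(self.ref) - 1
        return self.position, self.position


@dataclass
class VariantEffect:
    """Functional annotation of one variant against one gene set."""

    gene: Optional[str]
    region: str  # coding | promoter | intergenic
    cds_position: Optional[int]  # signed; negative = promoter offset
    codon_index: Optional[int]
    aa_ref: Optional[str]
    aa_alt: Optional[str]
    effect_class: str  # synonymous | missense | nonsense | frameshift | inframe_indel | promoter | intergenic
    nt_name: Optional[str] = None
    aa_name: Optional[str] = None
    fs_stop_codon: Optional[int] = field(default=None, repr=False)
    cds_ref: Optional[str] = field(default=None, repr=False)
    cds_alt: Optional[str] = field(default=None, repr=False)

    @property
    def is_nonsynonymous(self) -> bool:
        """True for protein- or promoter-altering classes (the classifier's criterion)."""
        return self.effect_class in ("missense", "nonsense", "frameshift", "inframe_indel", "promoter")


def translate_codon(codon: str) -> str:
    """Translate a single codon with the standard genetic code ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _VALID_BASES:
        raise InvalidInputError(f"codon must be 3 ACGT bases, got {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def _translate(seq: str) -> str:
    """Translate consecutive complete codons; stops rendered as '*'."""
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def cds_coordinate(gene: GeneModel, variant: Variant | int) -> Optional[int]:
    """Signed CDS coordinate of a genomic position relative to ``gene``.

    Positive 1-based offsets inside the CDS (coding orientation);
    negative offsets ``-k`` for positions ``k`` bp upstream of the coding
    start, out to ``gene.promoter_window``; ``None`` elsewhere.  There is
    no position 0.
    """
    pos = variant.position if isinstance(variant, Variant) else variant
    if gene.strand == "+":
        if gene.cds_start <= pos <= gene.cds_end:
            return pos - gene.cds_start + 1
        k = gene.cds_start - pos
    else:
        if gene.cds_start <= pos <= gene.cds_end:
            return gene.cds_end - pos + 1
        k = pos - gene.cds_end
    if 1 <= k <= gene.promoter_window:
        return -k
    return None


def _variant_in_cds(gene: GeneModel, variant: Variant) -> bool:
    lo, hi = variant.span
    if variant.kind == "insertion":
        # both flanks must be coding for the insertion to be intra-CDS
        return gene.cds_start <= variant.position < gene.cds_end
    return not (hi < gene.cds_start or lo > gene.cds_end)


def _assign_gene(genes: Iterable[GeneModel], variant: Variant) -> tuple[Optional[GeneModel], Optional[str]]:
    """Resolve the gene context: CDS hits beat promoter hits; nearest start breaks ties."""
    cds_hits = [g for g in genes if g.chromosome == variant.chromosome and _variant_in_cds(g, variant)]
    if cds_hits:
        gene = min(cds_hits, key=lambda g: (abs(variant.position - g.coding_start()), g.name))
        return gene, "coding"
    prom_hits = []
    for g in genes:
        if g.chromosome != variant.chromosome:
            continue
        c = cds_coordinate(g, variant)
        if c is not None and c < 0:
            prom_hits.append((abs(c), g))
    if prom_hits:
        _, gene = min(prom_hits, key=lambda t: (t[0], t[1].name))
        return gene, "promoter"
    return None, None


def _to_cds_frame(gene: GeneModel, variant: Variant) -> tuple[int, str, str]:
    """Express a variant in coding-orientation CDS coordinates and alleles.

    Returns ``(cds_pos, ref_cds, alt_cds)``; for insertions ``cds_pos``
    is the CDS base immediately left (5') of the insertion point in
    coding orientation.
    """
    minus = gene.strand == "-"
    if variant.kind == "substitution":
        p = cds_coordinate(gene, variant.position)
        ref = _revcomp(variant.ref) if minus else variant.ref
        alt = _revcomp(variant.alt) if minus else variant.alt
        return p, ref, alt
    if variant.kind == "deletion":
        lo, hi = variant.span
        c1, c2 = cds_coordinate(gene, lo), cds_coordinate(gene, hi)
        if c1 is None or c2 is None:
            raise InvalidInputError("indel extends outside the gene's annotated regions")
        m = min(c1, c2)
        seq = _revcomp(variant.ref) if minus else variant.ref
        return m, seq, ""
    # insertion: between genomic position and position+1
    left = variant.position + 1 if minus else variant.position
    m = cds_coordinate(gene, left)
    if m is None:
        raise InvalidInputError("insertion point outside the gene's annotated regions")
    seq = _revcomp(variant.alt) if minus else variant.alt
    return m, "", seq


def _check_ref(genome: Genome, variant: Variant) -> None:
    if not variant.ref:
        return
    lo, hi = variant.span
    observed = genome.fetch(variant.chromosome, lo, hi)
    if observed != variant.ref:
        raise RefMismatchError(
            f"{variant.chromosome}:{variant.position} ref {variant.ref!r} != genome {observed!r}"
        )


def _nt_name(cds_pos: int, ref: str, alt: str, kind: str, arrow: str = "->") -> str:
    if kind == "substitution":
        return f"{cds_pos} {ref}{arrow}{alt}"
    if kind == "deletion":
        end = cds_pos + len(ref) - 1
        return f"{cds_pos}_{end}del{ref}"
    right = cds_pos + 1 if cds_pos != -1 else 1  # promoter/CDS boundary has no position 0
    return f"{cds_pos}_{right}ins{alt}"


def format_nomenclature(effect: VariantEffect, variant: Variant, unicode_arrow: bool = False) -> tuple[str, str]:
    """Render ``(nt_name, aa_name)`` for an annotated variant.

    ASCII ``"->"`` is used by default in machine outputs; pass
    ``unicode_arrow=True`` for the display glyph.
    """
    if effect.region == "intergenic":
        raise InvalidInputError("intergenic variants have no gene-relative name")
    arrow = "→" if unicode_arrow else "->"
    nt = _nt_name(effect.cds_position, effect.cds_ref, effect.cds_alt, variant.kind, arrow)
    if effect.region == "promoter":
        return nt, "Promoter"
    if effect.effect_class == "frameshift":
        stop = effect.fs_stop_codon if effect.fs_stop_codon is not None else "?"
        aa = f"{effect.aa_ref}{effect.codon_index}{effect.aa_alt}fs{stop}"
    elif effect.effect_class == "inframe_indel":
        aa = f"{effect.aa_ref}{effect.codon_index}del" if variant.kind == "deletion" else \
             f"{effect.aa_ref}{effect.codon_index}ins"
    else:
        aa = f"{effect.aa_ref}{effect.codon_index}{effect.aa_alt}"
    return nt, aa


_SUB_RE = re.compile(r"^(-?\d+)\s?([ACGT])(?:->|→)([ACGT])$")
_INDEL_RE = re.compile(r"^(-?\d+)_(-?\d+)(del|ins)([ACGT]+)$")


def parse_nt_name(name: str) -> tuple[int, str, str, str]:
    """Parse a nucleotide-level name back to ``(cds_position, ref, alt, kind)``.

    The inverse of the nt half of :func:`format_nomenclature`; accepts
    both the ASCII arrow and the display glyph.
    """
    m = _SUB_RE.match(name.strip())
    if m:
        return int(m.group(1)), m.group(2), m.group(3), "substitution"
    m = _INDEL_RE.match(name.strip())
    if not m:
        raise InvalidInputError(f"unparseable mutation name {name!r}")
    start, end, op, seq = int(m.group(1)), int(m.group(2)), m.group(3), m.group(4)
    if op == "del":
        if end - start + 1 != len(seq):
            raise InvalidInputError(f"deletion span disagrees with sequence length in {name!r}")
        return start, seq, "", "deletion"
    return start, "", seq, "insertion"


def _annotate_coding_substitution(effect: VariantEffect, cds_seq: str) -> None:
    p = effect.cds_position
    idx = math.ceil(p / 3)
    codon = cds_seq[(idx - 1) * 3 : idx * 3]
    offset = (p - 1) % 3
    if codon[offset] != effect.cds_ref:
        raise RefMismatchError(
            f"CDS position {p}: coding-strand ref {effect.cds_ref!r} != CDS {codon[offset]!r}"
        )
    mutated = codon[:offset] + effect.cds_alt + codon[offset + 1 :]
    effect.codon_index = idx
    effect.aa_ref = translate_codon(codon)
    effect.aa_alt = translate_codon(mutated)
    if effect.aa_ref == effect.aa_alt:
        effect.effect_class = "synonymous"
    elif effect.aa_alt == "*":
        effect.effect_class = "nonsense"
    else:
        # stop-loss / start-loss deliberately fold into missense
        effect.effect_class = "missense"


def _annotate_coding_indel(effect: VariantEffect, gene: GeneModel, genome: Genome) -> None:
    shift = abs(len(effect.cds_ref) - len(effect.cds_alt)) % 3
    cds_seq = gene.cds_sequence(genome)
    # downstream genomic context lets the stop-scan read past the reference stop
    if gene.strand == "+":
        ext_end = min(genome.length(gene.chromosome), gene.cds_end + FRAMESHIFT_SCAN_BP)
        downstream = genome.fetch(gene.chromosome, gene.cds_end + 1, ext_end) if ext_end > gene.cds_end else ""
    else:
        ext_start = max(1, gene.cds_start - FRAMESHIFT_SCAN_BP)
        downstream = (
            _revcomp(genome.fetch(gene.chromosome, ext_start, gene.cds_start - 1))
            if ext_start < gene.cds_start
            else ""
        )
    extended = cds_seq + downstream
    p = effect.cds_position
    if effect.cds_ref:  # deletion occupies p .. p+len-1
        mutated = extended[: p - 1] + extended[p - 1 + len(effect.cds_ref) :]
        first_affected = p
    else:  # insertion after p
        mutated = extended[:p] + effect.cds_alt + extended[p:]
        first_affected = p + 1
    ref_protein = _translate(cds_seq)
    mut_protein = _translate(mutated)
    start_codon = math.ceil(first_affected / 3)
    k = None
    for i in range(start_codon - 1, len(mut_protein)):
        ref_aa = ref_protein[i] if i < len(ref_protein) else None
        if ref_aa is None or mut_protein[i] != ref_aa:
            k = i + 1
            break
    if k is None:  # indel invisible at protein level within scan range
        k = start_codon
    effect.codon_index = k
    effect.aa_ref = ref_protein[k - 1] if k - 1 < len(ref_protein) else "?"
    effect.aa_alt = mut_protein[k - 1] if k - 1 < len(mut_protein) else "?"
    if shift == 0:
        effect.effect_class = "inframe_indel"
        return
    effect.effect_class = "frameshift"
    stop = mut_protein.find("*", k - 1)
    effect.fs_stop_codon = stop + 1 if stop != -1 else None
    if stop != -1:
        effect.aa_alt = mut_protein[k - 1]


def annotate_variant(genome: Genome, genes: Iterable[GeneModel], variant: Variant) -> VariantEffect:
    """Annotate one variant: region, codon change, effect class, and names.

    The reference allele is validated against the genome; a mismatch
    raises :class:`~bsakit.errors.RefMismatchError`.  Variants inside a
    CDS are annotated in coding orientation (minus-strand alleles are
    complemented); variants within the promoter window of a gene but in
    no CDS are promoter variants; everything else is intergenic.
    """
    _check_ref(genome, variant)
    genes = list(genes)
    gene, region = _assign_gene(genes, variant)
    if gene is None:
        return VariantEffect(
            gene=None, region="intergenic", cds_position=None, codon_index=None,
            aa_ref=None, aa_alt=None, effect_class="intergenic",
        )
    cds_pos, ref_cds, alt_cds = _to_cds_frame(gene, variant)
    effect = VariantEffect(
        gene=gene.name, region=region, cds_position=cds_pos, codon_index=None,
        aa_ref=None, aa_alt=None, effect_class="promoter" if region == "promoter" else "?",
        cds_ref=ref_cds, cds_alt=alt_cds,
    )
    if region == "coding":
        if variant.kind == "substitution":
            _annotate_coding_substitution(effect, gene.cds_sequence(genome))
        else:
            _annotate_coding_indel(effect, gene, genome)
    effect.nt_name, effect.aa_name = format_nomenclature(effect, variant)
    return effect
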