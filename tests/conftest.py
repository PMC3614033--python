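"""Shared builders: genomes with one planted gene, and frameshift constructs."""

from __future__ import annotations

import numpy as np
import pytest

from bsakit.genome import GeneModel, Genome

_BASES = "ACGT"


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def place_gene(
    cds: str,
    strand: str = "+",
    flank: int = 600,
    chrom: str = "chr01",
    name: str = "GENE",
    promoter_window: int = 500,
    seed: int = 0,
) -> tuple[Genome, GeneModel]:
    """Embed a coding-orientation CDS in a random chromosome.

    The CDS occupies the same genomic interval on either strand (the
    minus-strand insert is reverse-complemented), with ``flank`` random
    bases on both sides so promoter windows and frameshift stop-scans
    have sequence to read.
    """
    up = random_seq(flank, seed)
    down = random_seq(flank, seed + 1)
    insert = cds if strand == "+" else revcomp(cds)
    genome = Genome({chrom: up + insert + down})
    gene = GeneModel(name, chrom, strand, flank + 1, flank + len(cds), promoter_window)
    return genome, gene


def genomic_pos(gene: GeneModel, cds_pos: int) -> int:
    """Genomic coordinate of a 1-based CDS position (strand-aware)."""
    if cds_pos < 0:  # promoter offset
        return gene.cds_start + cds_pos if gene.strand == "+" else gene.cds_end - cds_pos
    if gene.strand == "+":
        return gene.cds_start + cds_pos - 1
    return gene.cds_end - cds_pos + 1


def cds_with_codon(codon: str, codon_index: int, n_codons: int, fill: str = "GCT") -> str:
    """A CDS of ``n_codons`` filler codons with ``codon`` at ``codon_index``."""
    codons = [fill] * n_codons
    codons[codon_index - 1] = codon
    return "".join(codons)


def frameshift_deletion_cds() -> str:
    """A 250-codon CDS where deleting CDS base 675 yields G227Vfs249.

    The base deleted is the third G of a GGG glycine codon at 225; the
    shifted frame reads identically through codons 225-226, first
    changes the amino acid at codon 227 (G -> V), and hits a stop at
    codon 249 of the new frame.
    """
    codons = ["GCT"] * 250
    codons[224] = "GGG"  # codon 225, base 675 is its third base
    codons[225] = "AAA"  # codon 226; shifted frame reads AAG, still Lys
    codons[226] = "GGT"  # codon 227; shifted frame reads GTG = Val
    seq = list("".join(codons))
    seq[745:748] = "TAA"  # shifted-frame codon 249 (ref bases 746-748)
    return "".join(seq)


def frameshift_insertion_cds() -> str:
    """An 834-codon CDS where inserting T after CDS base 2494 yields L832Ffs834."""
    codons = ["GCT"] * 834
    codons[831] = "TTA"  # codon 832 = Leu; T insertion makes the new frame read TTT = Phe
    seq = list("".join(codons))
    seq[2499:2502] = "AAA"  # ref codon 834 = AAA (Lys)
    # new-frame codon 834 = ref bases 2499-2501 = T(from GCT at 833) + AA = TAA stop
    return "".join(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
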