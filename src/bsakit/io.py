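"""File formats, the packaged reference dataset, and the pipeline driver.

All tabular formats are tab-separated UTF-8 with a single header line;
lines starting with ``#`` are metadata.  Variant tables use 1-based
inclusive coordinates with ``.`` for an empty allele; depth tracks and
CNV calls use BED conventions (0-based half-open).  Mutation-name
glyphs are ASCII (``->``) in machine outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from bsakit import bsa
from bsakit.bsa import CandidateMutation, CloneReport
from bsakit.cnv import CNVCall, DepthProfile, assess_causality, depth_ratio, segment_cnv
from bsakit.errors import CorruptedFixtureError, DataIntegrityError, InvalidInputError
from bsakit.genome import GeneModel, Genome, Variant, VariantEffect, parse_nt_name

logger = logging.getLogger(__name__)

_FIXTURE_SHA256 = {
    "evolved_clones.tsv": "452dbf217039426d14803314373d3992ed278b50402c6cfbe6c60c647646db4e",
    "evolved_clones_notes.tsv": "bad8a939d9368855fab9f5683d39bc8d75102d9db95beded9e1b10c1fba3016a",
}

# ---------------------------------------------------------------------------
# genome / gene models / variants


def read_fasta(path: str | Path) -> Genome:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InvalidInputError(f"no FASTA records in {path}")
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()]
    SeqIO.write(recs, str(path), "fasta")


_GENE_COLUMNS = ["gene", "chromosome", "strand", "cds_start", "cds_end", "promoter_window"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _GENE_COLUMNS:
        raise DataIntegrityError(f"gene model table must have columns {_GENE_COLUMNS}")
    return [
        GeneModel(r.gene, r.chromosome, r.strand, int(r.cds_start), int(r.cds_end), int(r.promoter_window))
        for r in df.itertuples()
    ]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.name, g.chromosome, g.strand, g.cds_start, g.cds_end, g.promoter_window) for g in genes],
        columns=_GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gff3_genes(path: str | Path, promoter_window: int = 500) -> list[GeneModel]:
    """Import single-exon gene models from a GFF3 file.

    Only ``gene`` and ``CDS`` features are accepted; the gene name is
    taken from the CDS ``Parent`` (or ``ID``/``Name``) attribute.  A
    gene with more than one CDS segment is rejected.
    """
    import gffutils  # local import: only needed for GFF input

    seen: dict[str, GeneModel] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("gene", "CDS"):
            raise InvalidInputError(f"unsupported GFF3 feature type {feat.featuretype!r}")
        if feat.featuretype != "CDS":
            continue
        name = (feat.attributes.get("Parent") or feat.attributes.get("ID")
                or feat.attributes.get("Name") or [None])[0]
        if name is None:
            raise DataIntegrityError("CDS feature without Parent/ID/Name attribute")
        if name in seen:
            raise InvalidInputError(f"gene {name}: multi-exon CDS not supported")
        seen[name] = GeneModel(name, feat.seqid, feat.strand, feat.start, feat.end, promoter_window)
    return list(seen.values())


_VARIANT_COLUMNS = ["chromosome", "position", "ref", "alt"]


def read_variants(path: str | Path) -> list[Variant]:
    """Read a VCF-lite TSV: chromosome, position, ref, alt ('.' = empty allele)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != _VARIANT_COLUMNS:
        raise DataIntegrityError(f"variant table must have columns {_VARIANT_COLUMNS}")
    out = []
    for r in df.itertuples():
        ref = "" if r.ref in (".", "") else r.ref
        alt = "" if r.alt in (".", "") else r.alt
        out.append(Variant(r.chromosome, int(r.position), ref, alt))
    return out


def write_variants(variants: Sequence[Variant], path: str | Path) -> None:
    pd.DataFrame(
        [(v.chromosome, v.position, v.ref or ".", v.alt or ".") for v in variants],
        columns=_VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


_COUNT_COLUMNS = ["chromosome", "position", "mutant_reads", "total_reads"]


def read_pool_counts(path: str | Path) -> dict[tuple[str, int], tuple[int, int]]:
    """Read pooled read counts keyed by (chromosome, position)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _COUNT_COLUMNS:
        raise DataIntegrityError(f"pool counts table must have columns {_COUNT_COLUMNS}")
    return {
        (r.chromosome, int(r.position)): (int(r.mutant_reads), int(r.total_reads))
        for r in df.itertuples()
    }


def write_pool_counts(
    variants: Sequence[Variant], mutant_reads: Sequence[int], total_reads: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (v.chromosome, v.position, int(m), int(t))
            for v, m, t in zip(variants, mutant_reads, total_reads)
        ],
        columns=_COUNT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_depth_bed(path: str | Path, window_bp: Optional[int] = None) -> DepthProfile:
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "start", "end", "depth"], header=0)
    if window_bp is None:
        window_bp = int((df["end"] - df["start"]).mode().iloc[0])
    return DepthProfile(df, window_bp=window_bp)


def write_depth_bed(profile: DepthProfile, path: str | Path) -> None:
    profile.windows.to_csv(path, sep="\t", index=False, header=["chrom", "start", "end", "depth"])


def write_cnv_bed(calls: Sequence[CNVCall], path: str | Path) -> None:
    rows = [
        (
            c.chromosome, c.start, c.end,
            f"{c.call}:{c.causality or 'unassessed'}",
            round(c.clone_ratio, 4),
            "" if c.pool_ratio is None else round(c.pool_ratio, 4),
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "clone_ratio", "pool_ratio"]).to_csv(
        path, sep="\t", index=False
    )


def read_trace_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["allele", "time_point", "h_mut", "h_anc"]
    if list(df.columns) != required:
        raise DataIntegrityError(f"trace series table must have columns {required}")
    return df


# ---------------------------------------------------------------------------
# packaged reference dataset


def _fixture_text(name: str) -> str:
    data = resources.files("bsakit").joinpath("data", name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise CorruptedFixtureError(f"{name}: checksum mismatch ({digest})")
    return data.decode("utf-8")


def _effect_from_names(gene: str, nt_name: str, aa_name: str) -> VariantEffect:
    pos, ref, alt, kind = parse_nt_name(nt_name)
    if aa_name == "Promoter":
        region, klass = "promoter", "promoter"
        codon = aa_ref = aa_alt = None
        fs_stop = None
    else:
        region = "coding"
        import re

        m = re.match(r"^([A-Z*])(\d+)([A-Z*])(?:fs(\d+))?$", aa_name)
        if not m:
            raise DataIntegrityError(f"unparseable amino-acid name {aa_name!r}")
        aa_ref, codon, aa_alt, fs = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        fs_stop = int(fs) if fs else None
        if fs_stop is not None:
            klass = "frameshift"
        elif aa_alt == "*":
            klass = "nonsense"
        elif aa_ref == aa_alt:
            klass = "synonymous"
        else:
            klass = "missense"
        codon = int(codon)
    return VariantEffect(
        gene=gene, region=region, cds_position=pos, codon_index=codon,
        aa_ref=aa_ref, aa_alt=aa_alt, effect_class=klass,
        nt_name=nt_name, aa_name=aa_name, fs_stop_codon=fs_stop,
        cds_ref=ref, cds_alt=alt,
    )


@dataclass
class ReferenceDataset:
    """The bundled worked-example: mutation rows, footnotes, clone metadata."""

    candidates: list[CandidateMutation]
    footnotes: pd.DataFrame
    clone_info: pd.DataFrame  # clone, nominal_generations, total_mutations

    def clones(self) -> list[str]:
        return list(self.clone_info["clone"])


def load_reference_dataset() -> ReferenceDataset:
    """Load the packaged mutation table for the twelve evolved clones.

    Each row becomes a :class:`CandidateMutation` with its effect
    reconstructed from the printed nucleotide and protein names; the
    footnote table carries the linked-hitchhiker, time-zero, and
    low-final-frequency allele lists.  Both files are checksum-verified.
    """
    import io as _io

    rows = pd.read_csv(_io.StringIO(_fixture_text("evolved_clones.tsv")), sep="\t", comment="#")
    notes = pd.read_csv(_io.StringIO(_fixture_text("evolved_clones_notes.tsv")), sep="\t", comment="#")
    notes = notes.fillna("")
    candidates = []
    for r in rows.itertuples():
        eff = _effect_from_names(r.gene, r.nt_name, r.aa_name)
        candidates.append(
            CandidateMutation(
                variant=None, effect=eff,
                mutant_reads=int(r.mutant_reads), total_reads=int(r.total_reads),
                clone=r.clone,
            )
        )
    info = rows[["clone", "nominal_generations", "total_mutations"]].drop_duplicates().reset_index(drop=True)
    return ReferenceDataset(candidates=candidates, footnotes=notes, clone_info=info)


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineConfig:
    """End-to-end run configuration (thresholds plus input/output paths)."""

    genome_fasta: str
    gene_models: str
    clone_variants: str
    pool_counts: str
    out_dir: str
    clone_name: str = "clone"
    ancestor_variants: Optional[str] = None
    timezero_variants: Optional[str] = None
    depth_ancestor: Optional[str] = None
    depth_clone: Optional[str] = None
    depth_pool: Optional[str] = None
    causal_threshold: float = 0.9
    promoter_window: int = 500
    linkage_radius_cm: float = 25.0
    min_depth: int = 10
    cm_per_bp: float = 4e-4
    gain_threshold: float = 1.5
    loss_threshold: float = 0.75
    min_windows: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.causal_threshold < 1:
            raise InvalidInputError("causal threshold must be in (0, 1)")
        if self.promoter_window < 0:
            raise InvalidInputError("promoter window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> tuple[list[CloneReport], dict]:
    """Execute call -> annotate -> classify -> hitchhike-flag -> summarize (-> CNV).

    Writes a mutation report TSV, a cross-clone summary, an optional CNV
    BED, and a log of per-stage counts; returns the clone reports and
    summary dict.  Any stage failure removes partial outputs and
    re-raises with a stage tag.
    """
    from bsakit.genome import annotate_variant

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        genome = read_fasta(config.genome_fasta)
        genes = read_gene_models(config.gene_models)
        genes = [
            GeneModel(g.name, g.chromosome, g.strand, g.cds_start, g.cds_end, config.promoter_window)
            for g in genes
        ]
        clone_vars = read_variants(config.clone_variants)
        anc_vars = read_variants(config.ancestor_variants) if config.ancestor_variants else []
        tz_vars = read_variants(config.timezero_variants) if config.timezero_variants else []
        counts = read_pool_counts(config.pool_counts)

        stage = "call"
        de_novo, tz_hits = bsa.call_clone_mutations(anc_vars, clone_vars, tz_vars)

        stage = "annotate+classify"
        candidates = []
        for v in de_novo:
            eff = annotate_variant(genome, genes, v)
            mut, tot = counts.get((v.chromosome, v.position), (0, 0))
            frac = Fraction(mut, tot) if tot else None
            cls = bsa.classify_causal(
                eff, frac,
                threshold=Fraction(config.causal_threshold).limit_denominator(10**6),
                is_timezero=v in tz_hits, total_reads=tot, min_depth=config.min_depth,
            )
            candidates.append(CandidateMutation(v, eff, mut, tot, classification=cls))

        stage = "hitchhiker-flag"
        # map positions in cM: bp * cM/bp
        map_pos = {g.name: (g.chromosome, g.coding_start() * config.cm_per_bp) for g in genes}
        bsa.flag_hitchhikers(candidates, map_pos, config.linkage_radius_cm)

        stage = "summarize"
        report = bsa.summarize_clone(config.clone_name, candidates)
        summary = bsa.cross_clone_summary([report])
        report_path = out_dir / "mutations.tsv"
        bsa.report_frame([report]).to_csv(report_path, sep="\t", index=False)
        written.append(report_path)
        summary_path = out_dir / "summary.tsv"
        pd.DataFrame(
            [(k, v) for k, v in summary.items() if not isinstance(v, dict)],
            columns=["metric", "value"],
        ).to_csv(summary_path, sep="\t", index=False)
        written.append(summary_path)

        cnv_calls: list[CNVCall] = []
        if config.depth_clone and config.depth_ancestor:
            stage = "cnv"
            anc = read_depth_bed(config.depth_ancestor)
            clo = read_depth_bed(config.depth_clone)
            ratio = depth_ratio(clo, anc)
            cnv_calls = segment_cnv(ratio, config.gain_threshold, config.loss_threshold, config.min_windows)
            if config.depth_pool:
                pool = read_depth_bed(config.depth_pool)
                pool_ratio = depth_ratio(pool, anc)
                for call in cnv_calls:
                    assess_causality(call, pool_ratio)
            cnv_path = out_dir / "cnv_calls.bed"
            write_cnv_bed(cnv_calls, cnv_path)
            written.append(cnv_path)

        stage = "log"
        log_path = out_dir / "pipeline_log.yaml"
        with open(log_path, "w") as fh:
            yaml.safe_dump({
                "clone": config.clone_name,
                "seed": config.seed,
                "causal_threshold": config.causal_threshold,
                "promoter_window": config.promoter_window,
                "linkage_radius_cm": config.linkage_radius_cm,
                "min_depth": config.min_depth,
                "counts": {
                    "clone_variants": len(clone_vars),
                    "de_novo": len(de_novo),
                    "timezero_excluded": len(tz_hits),
                    "putative_causal_rows": sum(
                        1 for c in candidates if c.classification == bsa.PUTATIVE_CAUSAL
                    ),
                    "gene_level_causal": report.gene_level_causal_count,
                    "cnv_calls": len(cnv_calls),
                },
            }, fh, sort_keys=False)
        written.append(log_path)
        if not clone_vars:
            logger.warning("empty clone variant set: reports are empty")
        return [report], summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
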