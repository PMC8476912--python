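"""Readers and writers for the pipeline's external formats.

FASTA (genome / transcripts / miRNAs), GFF3 gene models, VCF v4.x with
per-accession genotypes, and the TSV schemas used between pipeline
stages (target sites, site locations, site variants, traits).  All text
formats use 1-based inclusive coordinates, the GFF3/VCF convention; the
library keeps the same convention internally, so no conversion layer is
needed.

Every writer's output is accepted by the corresponding reader.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from mirvar.errors import ValidationError
from mirvar.mapping import SiteLocation, TranscriptModel
from mirvar.variants import VariantRecord
from mirvar.association import TraitTable

logger = logging.getLogger(__name__)

_DNA_OK = frozenset("ACGTN")
_RNA_OK = frozenset("ACGUN")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: Optional[str] = None) -> Dict[str, str]:
    """FASTA -> {id: uppercase sequence}.

    `alphabet` 'dna' maps U->T, 'rna' maps T->U, None leaves bases as
    read.  Duplicate ids and non-nucleotide characters are errors.
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
            allowed = _DNA_OK
        elif alphabet == "rna":
            seq = seq.replace("T", "U")
            allowed = _RNA_OK
        else:
            allowed = _DNA_OK | _RNA_OK
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: illegal character(s) {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> List[TranscriptModel]:
    """GFF3 gene models -> TranscriptModel list (one per mRNA).

    Requires gene/mRNA/exon/CDS features linked by Parent attributes;
    exon ordering and CDS containment are validated by TranscriptModel.
    Orphan exons or CDS (Parent pointing nowhere) are errors.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True)
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            orphans = [p for p in parents if p not in mrna_ids]
            if orphans or not parents:
                raise ValidationError(
                    f"orphan {ftype} feature {f.id!r} (Parent "
                    f"{orphans or 'missing'})")
    models = []
    for mrna in db.features_of_type("mRNA"):
        gene = (mrna.attributes.get("Parent") or [mrna.id])[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            raise ValidationError(f"mRNA {mrna.id!r} has no exons")
        models.append(TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            cds=tuple(cds),
        ))
    return models


def write_gff3(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(f"{m.chrom}\tmirvar\tgene\t{lo}\t{hi}\t.\t{m.strand}"
                     f"\t.\tID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tmirvar\tmRNA\t{lo}\t{hi}\t.\t{m.strand}"
                     f"\t.\tID={m.transcript_id};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.chrom}\tmirvar\texon\t{s}\t{e}\t.\t{m.strand}"
                         f"\t.\tID={m.transcript_id}.exon{i};"
                         f"Parent={m.transcript_id}\n")
            for i, (s, e) in enumerate(m.cds, 1):
                fh.write(f"{m.chrom}\tmirvar\tCDS\t{s}\t{e}\t.\t{m.strand}"
                         f"\t0\tID={m.transcript_id}.cds{i};"
                         f"Parent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple:
    """VCF -> (accession list, VariantRecord list).

    Multi-allelic records are split into biallelic ones.  GT is mapped
    to alt-allele dosage: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. ->
    missing; phased separators are accepted.  A VCF without genotype
    columns is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError("VCF carries no genotype columns")
    records: List[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        try:
            genos = v.genotypes  # [a0, a1, phased] per sample
            for k, alt in enumerate(v.ALT, start=1):
                dos = np.full(len(samples), np.nan)
                for i, g in enumerate(genos):
                    alleles = [a for a in g[:-1]]
                    if any(a < 0 for a in alleles):
                        continue
                    dos[i] = sum(1 for a in alleles if a == k)
                records.append(VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    dosages=dos))
        except Exception:
            n_skipped += 1
    if n_skipped:
        logger.warning("read_vcf skipped %d malformed records", n_skipped)
    return samples, records


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(records: Sequence[VariantRecord], accessions: Sequence[str],
              path, contigs: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        if contigs:
            for c, ln in contigs.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref,
                                                 r.alt))
        for r in ordered:
            gts = "\t".join(
                "./." if np.isnan(d) else _GT[float(d)] for d in r.dosages)
            fh.write(f"{r.chrom}\t{r.pos}\t{r.key}\t{r.ref}\t{r.alt}\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TSV schemas
# ---------------------------------------------------------------------------

def write_sites_tsv(sites: Sequence, path) -> None:
    """Target-site table: one row per (miRNA, transcript, interval) hit.

    The three-row duplex rendering is stored with '|' as the row
    separator so the table stays one line per site.
    """
    from mirvar.scoring import alignment_text

    rows = []
    for i, s in enumerate(sites, 1):
        a = s.alignment
        rows.append({
            "site_id": f"site{i:03d}",
            "mirna_id": a.mirna_id,
            "transcript_id": a.target_id,
            "start": a.site_start,
            "end": a.site_end,
            "site_seq": s.site_seq_dna,
            "site_seq_rna": s.site_seq,
            "expectation": s.expectation,
            "inhibition": s.inhibition.value,
            "upe_proxy": "" if s.upe_proxy is None else s.upe_proxy,
            "alignment": alignment_text(s).replace("\n", "|"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"site_id": str})


def write_locations_tsv(locations: Sequence[SiteLocation], path) -> None:
    """BED-like site-location table (1-based inclusive, multi-block)."""
    rows = []
    for loc in locations:
        lo, hi = loc.span
        rows.append({
            "chrom": loc.chrom,
            "start": lo,
            "end": hi,
            "site_id": loc.site_id,
            "strand": loc.strand,
            "block_count": len(loc.blocks),
            "block_starts": ",".join(str(b[0]) for b in loc.blocks),
            "block_sizes": ",".join(str(b[1] - b[0] + 1)
                                    for b in loc.blocks),
            "source_transcript": loc.source_transcript,
            "mismatches": loc.mismatches,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locations_tsv(path) -> List[SiteLocation]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})
    out = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["block_starts"]).split(",")]
        sizes = [int(x) for x in str(row["block_sizes"]).split(",")]
        blocks = tuple((s, s + n - 1) for s, n in zip(starts, sizes))
        out.append(SiteLocation(
            site_id=row["site_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            blocks=blocks,
            source_transcript=str(row.get("source_transcript", "") or ""),
            mismatches=int(row.get("mismatches", 0)),
        ))
    return out


def write_site_variants_tsv(site_variants: Sequence, path) -> None:
    rows = []
    for sv in site_variants:
        r = sv.rescore
        rows.append({
            "variant": sv.variant.key,
            "type": sv.variant.variant_type,
            "site_id": sv.site_id,
            "in_site_position": sv.in_site_position,
            "maf": "" if sv.stats.maf is None else sv.stats.maf,
            "integrity": sv.stats.integrity,
            "rare": sv.stats.is_rare,
            "analysis_eligible": sv.stats.analysis_eligible,
            "substitution": sv.substitution or "",
            "region": sv.region or "",
            "delta_e": "" if r is None else r.delta_e,
            "effect": "" if r is None else r.effect.value,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_traits_tsv(path) -> TraitTable:
    """Trait TSV (accession, trait, year, value) -> TraitTable.

    Replicate rows for one (accession, trait, year) are averaged on
    load.
    """
    df = pd.read_csv(path, sep="\t")
    return TraitTable.from_long(df)
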