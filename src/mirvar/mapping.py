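"""Transcript-to-genome coordinate projection and gene-region annotation.

Target sites are predicted in transcript coordinates; associating them
with population variants requires their genomic footprint.  Projection
walks the exon chain of a gene model (sites spanning splice junctions
become multi-block locations), and a near-exact scanner re-locates a site
sequence anywhere in the genome, tolerating a small number of
substitutions.  A simplified region classifier assigns each genomic
position to one of seven gene-relative categories.

Coordinates are 1-based inclusive externally (GFF3/VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from mirvar.errors import ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One mRNA's exon/CDS structure on the genome.

    Exons are 1-based inclusive genomic intervals, non-overlapping, sorted
    ascending regardless of strand.  Transcript position 1 is the first
    base of the first exon on + strand, the last base of the last exon on
    - strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # ((start, end), ...) ascending
    cds: tuple = ()  # ((start, end), ...) ascending, may be empty

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        ex = tuple(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{self.transcript_id}: exons not sorted/disjoint"
                )
        for s, e in ex:
            if e < s:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s},{e}) reversed")
        object.__setattr__(self, "exons", ex)
        cds = tuple(tuple(c) for c in self.cds)
        for s, e in cds:
            if not any(xs <= s and e <= xe for xs, xe in ex):
                raise ValidationError(
                    f"{self.transcript_id}: CDS ({s},{e}) outside exons")
        object.__setattr__(self, "cds", cds)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tts(self) -> int:
        """Transcription termination site (strand-aware)."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def genomic_to_transcript(self, position: int) -> Optional[int]:
        """1-based transcript coordinate of a genomic position, or None."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= position <= e:
                    return offset + (position - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= position <= e:
                    return offset + (e - position) + 1
                offset += e - s + 1
        return None

    def utr5(self) -> list:
        """Genomic intervals of the 5' UTR (exonic, before the CDS)."""
        return self._utr(five_prime=True)

    def utr3(self) -> list:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> list:
        if not self.cds:
            return []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        out = []
        for s, e in self.exons:
            if five_prime == (self.strand == "+"):
                lo, hi = s, min(e, cds_lo - 1)
            else:
                lo, hi = max(s, cds_hi + 1), e
            if lo <= hi:
                out.append((lo, hi))
        return out


@dataclass(frozen=True)
class SiteLocation:
    """Genomic footprint of one target site (possibly spliced).

    Blocks are 1-based inclusive intervals in transcript order: ascending
    genomic coordinates for + strand, descending for - strand (each block
    itself stored as (low, high)).
    """

    site_id: str
    chrom: str
    strand: str
    blocks: tuple
    source_transcript: str = ""
    mismatches: int = 0

    def __post_init__(self):
        object.__setattr__(self, "blocks",
                           tuple(tuple(b) for b in self.blocks))

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)

    @property
    def span(self) -> tuple:
        los = [b[0] for b in self.blocks]
        his = [b[1] for b in self.blocks]
        return (min(los), max(his))

    def in_site_position(self, genomic_pos: int) -> Optional[int]:
        """1-based position along the site (mRNA 5'->3') of a genomic base."""
        offset = 0
        for s, e in self.blocks:
            if s <= genomic_pos <= e:
                if self.strand == "+":
                    return offset + (genomic_pos - s) + 1
                return offset + (e - genomic_pos) + 1
            offset += e - s + 1
        return None


# ---------------------------------------------------------------------------

def map_transcript_to_genome(
    model: TranscriptModel, t_start: int, t_end: int
) -> list:
    """Project a 1-based inclusive transcript interval onto the genome.

    Returns the minimal list of genomic (start, end) blocks, in transcript
    order (for - strand the blocks descend in genomic coordinates).
    """
    if not (1 <= t_start <= t_end <= model.length):
        raise ValidationError(
            f"transcript interval ({t_start}, {t_end}) outside "
            f"{model.transcript_id} of length {model.length}"
        )
    blocks = []
    offset = 0
    exon_iter = model.exons if model.strand == "+" else reversed(model.exons)
    for s, e in exon_iter:
        elen = e - s + 1
        lo = max(t_start, offset + 1)
        hi = min(t_end, offset + elen)
        if lo <= hi:
            if model.strand == "+":
                blocks.append((s + (lo - offset - 1), s + (hi - offset - 1)))
            else:
                blocks.append((e - (hi - offset - 1), e - (lo - offset - 1)))
        offset += elen
    return blocks


def find_site_occurrences(
    site_seq: str,
    genome: Dict[str, str],
    max_mismatches: int = 1,
    site_id: str = "",
) -> list:
    """Locate a site sequence in a genome, tolerating substitutions.

    Scans both strands of every chromosome for windows within
    `max_mismatches` substitutions of `site_seq` (no indels).  Results
    are ordered by (chromosome, position, strand) with + before -.
    """
    query = site_seq.upper().replace("U", "T")
    L = len(query)
    if L < 15:
        raise ValidationError(
            f"site sequence of length {L} too short to localize (min 15)")
    out = []
    q_fwd = np.frombuffer(query.encode(), dtype=np.uint8)
    q_rev = np.frombuffer(reverse_complement(query).encode(), dtype=np.uint8)
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        if n < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_win = n - L + 1
        mm_fwd = np.zeros(n_win, dtype=np.int32)
        mm_rev = np.zeros(n_win, dtype=np.int32)
        for k in range(L):
            col = arr[k:k + n_win]
            mm_fwd += col != q_fwd[k]
            mm_rev += col != q_rev[k]
        hits = []
        for pos0 in np.nonzero(mm_fwd <= max_mismatches)[0]:
            hits.append((int(pos0) + 1, "+", int(mm_fwd[pos0])))
        for pos0 in np.nonzero(mm_rev <= max_mismatches)[0]:
            hits.append((int(pos0) + 1, "-", int(mm_rev[pos0])))
        hits.sort(key=lambda h: (h[0], h[1] == "-"))
        for start, strand, mm in hits:
            out.append(
                SiteLocation(
                    site_id=site_id,
                    chrom=chrom,
                    strand=strand,
                    blocks=((start, start + L - 1),),
                    mismatches=mm,
                )
            )
    return out


_REGION_PRECEDENCE = [
    "exonic", "5'UTR", "3'UTR", "intronic", "upstream1kb", "downstream1kb",
    "intergenic",
]


def annotate_position(
    models: Sequence[TranscriptModel],
    chrom: str,
    position: int,
    flank: int = 1000,
) -> str:
    """Gene-region label of one genomic position.

    Classifies against every transcript on the chromosome and returns the
    highest-precedence label: exonic (CDS) > 5'UTR > 3'UTR > intronic >
    upstream1kb > downstream1kb > intergenic.  Upstream/downstream are
    measured from the TSS/TTS respecting strand.  Exonic positions of a
    CDS-less transcript count as exonic.
    """
    labels = set()
    seen_chrom = False
    for m in models:
        if m.chrom != chrom:
            continue
        seen_chrom = True
        lo, hi = m.span
        if lo <= position <= hi:
            in_exon = any(s <= position <= e for s, e in m.exons)
            if in_exon:
                if any(s <= position <= e for s, e in m.cds) or not m.cds:
                    labels.add("exonic")
                elif any(s <= position <= e for s, e in m.utr5()):
                    labels.add("5'UTR")
                elif any(s <= position <= e for s, e in m.utr3()):
                    labels.add("3'UTR")
                else:  # exonic but outside annotated CDS/UTR split
                    labels.add("exonic")
            else:
                labels.add("intronic")
        else:
            if m.strand == "+":
                if m.tss - flank <= position < m.tss:
                    labels.add("upstream1kb")
                elif m.tts < position <= m.tts + flank:
                    labels.add("downstream1kb")
            else:
                if m.tss < position <= m.tss + flank:
                    labels.add("upstream1kb")
                elif m.tts - flank <= position < m.tts:
                    labels.add("downstream1kb")
    if not seen_chrom:
        logger.warning("annotate_position: unknown chromosome %r", chrom)
    for label in _REGION_PRECEDENCE:
        if label in labels:
            return label
    return "intergenic"
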