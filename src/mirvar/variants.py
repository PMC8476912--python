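"""Population variants inside miRNA target sites.

Intersects variant records with site locations, computes per-variant
allele statistics (alt-allele frequency, minor-allele frequency,
integrity = call rate) and the rare / analysis-eligible classifications,
builds descriptive profiles (in-site position spectrum, substitution
spectrum, alt-base composition), and re-scores each site's alleles for
their effect on miRNA binding.

The accession panel is assumed to be inbred (selfed lines), so simulated
dosages take values {0, 2}; heterozygous calls in real data are retained
in the allele-frequency arithmetic and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from mirvar.config import ScoringConfig, DEFAULT_CONFIG
from mirvar.errors import ValidationError
from mirvar.mapping import SiteLocation, TranscriptModel, annotate_position, \
    reverse_complement
from mirvar.scoring import AlleleEdit, RescoreResult, TargetSite, \
    rescore_with_alleles, to_rna, to_dna

logger = logging.getLogger(__name__)


@dataclass
class VariantRecord:
    """One biallelic variant with per-accession alt-allele dosages.

    Dosages are floats in {0, 1, 2} with NaN for missing calls.
    Multi-allelic records are split upstream into biallelic ones.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)

    @property
    def key(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def variant_type(self) -> str:
        return "SNP" if self.is_snp else "INDEL"

    @property
    def ref_span(self) -> tuple:
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass(frozen=True)
class VariantStats:
    """Allele statistics and filter classification for one variant."""

    alt_freq: Optional[float]
    maf: Optional[float]
    integrity: float
    is_rare: bool
    analysis_eligible: bool


def compute_variant_stats(
    dosages: np.ndarray, config: ScoringConfig = DEFAULT_CONFIG
) -> VariantStats:
    """MAF / integrity / rare / eligible from a dosage vector.

    f = sum(dosage) / (2 * n_called); integrity = n_called / n_total.
    rare: MAF <= 0.05 and integrity >= 0.7 (both boundaries inclusive);
    eligible: MAF > 0.05 and integrity >= 0.7.  An all-missing vector
    yields integrity 0 and undefined MAF.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValidationError("empty dosage vector")
    called = ~np.isnan(d)
    n_called = int(called.sum())
    integrity = n_called / d.size
    if n_called == 0:
        return VariantStats(None, None, 0.0, False, False)
    f = float(d[called].sum()) / (2 * n_called)
    maf = min(f, 1 - f)
    ok = integrity >= config.integrity_threshold
    return VariantStats(
        alt_freq=f,
        maf=maf,
        integrity=integrity,
        is_rare=ok and maf <= config.maf_threshold,
        analysis_eligible=ok and maf > config.maf_threshold,
    )


@dataclass
class GenotypeMatrix:
    """Accessions x variants alt-allele dosage matrix (NaN = missing)."""

    df: pd.DataFrame  # index: accession ids, columns: variant keys

    @classmethod
    def from_records(
        cls, records: Sequence[VariantRecord], accessions: Sequence[str]
    ) -> "GenotypeMatrix":
        data = {r.key: r.dosages for r in records}
        return cls(pd.DataFrame(data, index=list(accessions)))

    @property
    def accessions(self) -> list:
        return list(self.df.index)

    @property
    def variant_keys(self) -> list:
        return list(self.df.columns)

    def dosages(self, key: str) -> np.ndarray:
        return self.df[key].to_numpy()

    def stats(self, config: ScoringConfig = DEFAULT_CONFIG) -> pd.DataFrame:
        """Per-variant MAF/integrity/classification table."""
        rows = {}
        for key in self.df.columns:
            s = compute_variant_stats(self.df[key].to_numpy(), config)
            rows[key] = {
                "alt_freq": s.alt_freq,
                "maf": s.maf,
                "integrity": s.integrity,
                "rare": s.is_rare,
                "analysis_eligible": s.analysis_eligible,
            }
        return pd.DataFrame.from_dict(rows, orient="index")


_SUB_CLASSES = ("A-C", "A-G", "A-T", "C-G", "C-T", "G-T")


def substitution_class(ref: str, alt: str, strand: str = "+") -> str:
    """Unordered, mRNA-strand-normalized substitution class of a SNP.

    Variants on - strand sites are complemented before classification, so
    a genomic G>A under a - strand site reports as C-T.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValidationError("substitution class is defined for SNPs only")
    r, a = ref.upper(), alt.upper()
    if strand == "-":
        r = reverse_complement(r)
        a = reverse_complement(a)
    return "-".join(sorted((r, a)))


@dataclass
class SiteVariant:
    """A population variant falling inside one target site."""

    variant: VariantRecord
    site_id: str
    location: SiteLocation
    in_site_position: int  # 1-based along the mRNA; first overlapped base
    stats: VariantStats
    substitution: Optional[str] = None  # SNPs only
    region: Optional[str] = None
    rescore: Optional[RescoreResult] = None

    @property
    def mrna_ref(self) -> str:
        """Ref allele on the mRNA (site) strand."""
        return self.variant.ref if self.location.strand == "+" \
            else reverse_complement(self.variant.ref)

    @property
    def mrna_alt(self) -> str:
        return self.variant.alt if self.location.strand == "+" \
            else reverse_complement(self.variant.alt)


def intersect_variants_with_sites(
    variants,
    locations: Sequence[SiteLocation],
    models: Optional[Sequence[TranscriptModel]] = None,
    config: ScoringConfig = DEFAULT_CONFIG,
):
    """Intersect a variant stream with target-site locations.

    A SNP is included when its position lies in a site block; an INDEL
    when its reference span overlaps any block.  A variant hitting two
    overlapping sites yields one SiteVariant per site.  The in-site
    position is the first overlapped site base along the mRNA 5'->3'.
    """
    by_chrom: Dict[str, list] = {}
    for loc in locations:
        by_chrom.setdefault(loc.chrom, []).append(loc)

    out: List[SiteVariant] = []
    n_skipped = 0
    for var in variants:
        if var is None:
            n_skipped += 1
            continue
        for loc in by_chrom.get(var.chrom, []):
            lo, hi = var.ref_span
            in_positions = [
                p for p in (loc.in_site_position(g)
                            for g in range(lo, hi + 1))
                if p is not None
            ]
            if not in_positions:
                continue
            stats = compute_variant_stats(var.dosages, config)
            sub = None
            if var.is_snp:
                sub = substitution_class(var.ref, var.alt, loc.strand)
            region = None
            if models is not None:
                region = annotate_position(models, var.chrom, var.pos)
            out.append(
                SiteVariant(
                    variant=var,
                    site_id=loc.site_id,
                    location=loc,
                    in_site_position=min(in_positions),
                    stats=stats,
                    substitution=sub,
                    region=region,
                )
            )
    if n_skipped:
        logger.warning("skipped %d malformed variant records", n_skipped)
    return out


def site_position_profile(
    site_variants: Sequence[SiteVariant], site_length: int
) -> np.ndarray:
    """Percentage of SNPs at each in-site position 1..site_length."""
    counts = np.zeros(site_length, dtype=float)
    for sv in site_variants:
        if not sv.variant.is_snp:
            raise ValidationError(
                "site_position_profile expects SNP records only")
        if not 1 <= sv.in_site_position <= site_length:
            raise ValidationError(
                f"in-site position {sv.in_site_position} outside 1.."
                f"{site_length}")
        counts[sv.in_site_position - 1] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return 100.0 * counts / total


def substitution_spectrum(site_variants: Sequence[SiteVariant]):
    """Percentages over the six substitution classes and over alt bases.

    Both spectra are computed on the mRNA (site) strand and reported in
    DNA letters.  INDELs are skipped with a warning.  Returns
    (class -> pct, alt base -> pct) dicts; percentages sum to 100 each
    when any SNP is present.
    """
    cls_counts = {c: 0 for c in _SUB_CLASSES}
    alt_counts = {b: 0 for b in "ACGT"}
    n_indel = 0
    total = 0
    for sv in site_variants:
        if not sv.variant.is_snp:
            n_indel += 1
            continue
        cls_counts[sv.substitution] += 1
        alt_counts[to_dna(sv.mrna_alt)] += 1
        total += 1
    if n_indel:
        logger.warning("substitution_spectrum skipped %d INDELs", n_indel)
    if total == 0:
        return ({c: 0.0 for c in _SUB_CLASSES}, {b: 0.0 for b in "ACGT"})
    return (
        {c: 100.0 * n / total for c, n in cls_counts.items()},
        {b: 100.0 * n / total for b, n in alt_counts.items()},
    )


@dataclass
class SiteRescore:
    """Joint and per-variant (marginal) re-scores for one site."""

    site_id: str
    joint: RescoreResult
    marginals: Dict[str, RescoreResult]  # variant key -> result

    @property
    def joint_delta_e(self) -> float:
        return self.joint.delta_e

    @property
    def joint_delta_upe(self) -> Optional[float]:
        if self.joint.upe_ref is None or self.joint.upe_alt is None:
            return None
        return self.joint.upe_alt - self.joint.upe_ref


def _site_edit(sv: SiteVariant, site_seq_rna: str) -> Optional[AlleleEdit]:
    """Translate a genomic variant into an in-site mRNA-strand edit.

    Fully contained edits are applied exactly (reverse-complemented for -
    strand sites).  An indel whose reference span extends past the site
    boundary is reduced to a deletion of its in-site bases; an insertion
    anchored outside the site leaves the site unchanged (returns None).
    """
    var, loc = sv.variant, sv.location
    lo, hi = var.ref_span
    in_pos = [loc.in_site_position(g) for g in range(lo, hi + 1)]
    inside = [p for p in in_pos if p is not None]
    if not inside:
        return None
    if len(inside) == len(var.ref):
        start = min(inside)
        mref = sv.mrna_ref
        malt = sv.mrna_alt
        return AlleleEdit(start, mref, malt)
    if len(var.alt) > len(var.ref):
        # insertion anchored outside the site: no site-sequence change
        return None
    start = min(inside)
    span = len(inside)
    mref = site_seq_rna[start - 1:start - 1 + span]
    logger.warning(
        "variant %s extends past site %s; applied as in-site deletion",
        var.key, sv.site_id)
    return AlleleEdit(start, mref, "")


def rescore_all(
    site_variants: Sequence[SiteVariant],
    sites: Dict[str, TargetSite],
    contexts: Optional[Dict[str, str]] = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> List[SiteRescore]:
    """Re-score every site carrying variants, jointly and marginally.

    All of a site's variants are applied together (the joint effect) and
    each alone (marginal effects); edits within one site must not
    overlap.  `sites` maps site id -> TargetSite; `contexts` optionally
    maps transcript id -> transcript sequence for the accessibility
    proxy.  Results are stored back onto each SiteVariant.rescore.
    """
    grouped: Dict[str, list] = {}
    for sv in site_variants:
        grouped.setdefault(sv.site_id, []).append(sv)

    out = []
    for site_id in sorted(grouped):
        group = grouped[site_id]
        site = sites[site_id]
        ctx = None
        if contexts is not None:
            ctx = contexts.get(site.alignment.target_id)
        edits = []
        for sv in group:
            e = _site_edit(sv, site.site_seq)
            edits.append((sv, e))
        spans = [e.ref_span for _, e in edits if e is not None]
        for (a, b), (c, d) in zip(sorted(spans), sorted(spans)[1:]):
            if c <= b:
                raise ValidationError(
                    f"site {site_id}: overlapping allele edits at in-site "
                    f"positions {a}-{b} and {c}-{d}"
                )
        joint = rescore_with_alleles(
            site, [e for _, e in edits if e is not None], ctx, config=config)
        marginals = {}
        for sv, e in edits:
            res = rescore_with_alleles(
                site, [e] if e is not None else [], ctx, config=config)
            marginals[sv.variant.key] = res
            sv.rescore = res
        out.append(SiteRescore(site_id=site_id, joint=joint,
                               marginals=marginals))
    return out
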