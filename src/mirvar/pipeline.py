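"""End-to-end orchestration: predict -> locate -> extract -> associate.

Thin glue over the library modules, shared by the command-line interface
and the examples.  Sites are assigned stable ids ("site001", ...) in
scan order: miRNAs and transcripts in input order, hits sorted by
(expectation, position) within each pair.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from mirvar.config import ScoringConfig, DEFAULT_CONFIG
from mirvar.mapping import SiteLocation, TranscriptModel, \
    map_transcript_to_genome
from mirvar.scoring import MiRNA, TargetSite, find_sites, upe_proxy
from mirvar.variants import SiteVariant, intersect_variants_with_sites


def predict_sites(
    mirnas: Sequence[MiRNA],
    transcripts: Dict[str, str],
    max_expectation: Optional[float] = None,
    flank: Optional[int] = None,
    with_upe: bool = True,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> Dict[str, TargetSite]:
    """Scan every miRNA against every transcript; returns {site_id: site}."""
    catalog: Dict[str, TargetSite] = {}
    i = 0
    for mirna in mirnas:
        for tid, seq in transcripts.items():
            for site in find_sites(mirna, seq, max_expectation,
                                   transcript_id=tid, config=config):
                i += 1
                if with_upe:
                    site.upe_proxy = upe_proxy(
                        seq, site.alignment.site_start,
                        site.alignment.site_end, flank, config)
                catalog[f"site{i:03d}"] = site
    return catalog


def locate_sites(
    catalog: Dict[str, TargetSite],
    models: Sequence[TranscriptModel],
) -> List[SiteLocation]:
    """Project every predicted site to the genome through its gene model."""
    by_tid = {m.transcript_id: m for m in models}
    out = []
    for site_id, site in catalog.items():
        a = site.alignment
        model = by_tid[a.target_id]
        blocks = map_transcript_to_genome(model, a.site_start, a.site_end)
        ordered = blocks if model.strand == "+" else blocks
        out.append(SiteLocation(
            site_id=site_id,
            chrom=model.chrom,
            strand=model.strand,
            blocks=tuple(ordered),
            source_transcript=model.transcript_id,
        ))
    return out


def extract_site_variants(
    variants,
    locations: Sequence[SiteLocation],
    models: Optional[Sequence[TranscriptModel]] = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> List[SiteVariant]:
    return intersect_variants_with_sites(variants, locations, models,
                                         config)
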