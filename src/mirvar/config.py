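"""Tunable scoring and filtering parameters, pinned in one place.

The duplex penalty table follows the convention of plant miRNA target
predictors: mismatches cost 1, G:U wobbles half a mismatch, bulged
nucleotides a full 2, and every penalty is doubled inside the seed region
(miRNA positions 2-13, numbered from the miRNA 5' end).  Candidate sites
are retained up to a maximum expectation score of 3.5.  Population-variant
filters use the field's standard minor-allele-frequency and call-rate
(integrity) cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the target-site expectation score and variant filters.

    Attributes
    ----------
    mismatch_penalty, wobble_penalty, bulge_penalty
        Per-position penalties: Watson-Crick pair 0, G:U wobble 0.5,
        mismatch 1.0, bulged nucleotide 2.0 (charged to its anchor miRNA
        position).
    seed_start, seed_end
        miRNA positions (1-based, 5' end = 1) whose penalties are doubled.
    seed_multiplier
        Weight applied inside the seed region.
    max_expectation
        Sites with expectation score E above this are discarded.
    central_start, central_end
        miRNA positions of the central window; a mismatch or bulge anchor
        here switches the predicted inhibition mode from cleavage to
        translational repression.
    upe_flank
        Nucleotides of transcript context added on each side of a site
        when computing the accessibility (unpairing-cost) proxy.
    maf_threshold, integrity_threshold
        A variant is *rare* when MAF <= maf_threshold with integrity >=
        integrity_threshold, and *analysis-eligible* (enters the
        association scan) when MAF > maf_threshold with integrity >=
        integrity_threshold.
    """

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    bulge_penalty: float = 2.0
    seed_start: int = 2
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_expectation: float = 3.5
    central_start: int = 9
    central_end: int = 11
    upe_flank: int = 50
    maf_threshold: float = 0.05
    integrity_threshold: float = 0.7
    # Nussinov-style pair weights for the accessibility proxy.
    pair_weights: tuple = (("GC", 3.0), ("CG", 3.0), ("AU", 2.0), ("UA", 2.0),
                           ("GU", 1.0), ("UG", 1.0))
    min_hairpin_loop: int = 3

    def pair_weight(self, a: str, b: str) -> float:
        """Weight of the base pair (a, b), 0 if not pairable."""
        key = a + b
        for pair, w in self.pair_weights:
            if key == pair:
                return w
        return 0.0

    def seed_weight(self, mirna_pos: int) -> float:
        """Positional weight of miRNA position `mirna_pos` (1-based)."""
        if self.seed_start <= mirna_pos <= self.seed_end:
            return self.seed_multiplier
        return 1.0


DEFAULT_CONFIG = ScoringConfig()
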