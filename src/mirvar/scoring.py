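"""miRNA:mRNA duplex scoring and target-site prediction.

The expectation score E of a duplex is a weighted penalty sum over miRNA
positions: Watson-Crick pairs cost 0, G:U wobbles 0.5, mismatches 1.0 and
bulged nucleotides 2.0, with every penalty doubled in the seed region
(miRNA positions 2-13 counted from the miRNA 5' end).  Lower E means
stronger predicted targeting; candidate sites are kept at E <= 3.5.

Coordinate conventions
----------------------
Duplexes are antiparallel: miRNA position 1 (its 5' end) pairs with the
3'-most base of the target site.  In-site positions are numbered
1..site_length along the mRNA 5'->3', so for an ungapped duplex the target
position i pairs with miRNA position L - i + 1.  At most one bulge is
allowed per duplex, which confines site lengths to {L-1, L, L+1} — for
21-nt miRNAs the observed 20-22 nt range.  A target-strand bulge is
anchored at the miRNA position 5'-adjacent (on the miRNA) to the bulge; a
miRNA-strand bulge is charged at the bulged miRNA position itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from mirvar.config import ScoringConfig, DEFAULT_CONFIG
from mirvar.errors import ValidationError, RefAlleleMismatch

_RNA_BASES = frozenset("ACGU")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def to_rna(seq: str) -> str:
    """Uppercase a sequence and convert T to U; reject other characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_BASES
    if bad:
        pos = next(i for i, c in enumerate(s, start=1) if c in bad)
        raise ValidationError(
            f"non-nucleotide character {s[pos - 1]!r} at position {pos}"
        )
    return s


def to_dna(seq: str) -> str:
    """RNA -> DNA spelling (U -> T)."""
    return seq.upper().replace("U", "T")


def classify_pair(mirna_base: str, target_base: str) -> str:
    """Classify one miRNA:target base pair as match / wobble / mismatch."""
    key = (mirna_base, target_base)
    if key in _WC:
        return "match"
    if key in _WOBBLE:
        return "wobble"
    return "mismatch"


class Inhibition(str, Enum):
    CLEAVAGE = "cleavage"
    TRANSLATION = "translation"


class AlleleEffect(str, Enum):
    IMPAIRED = "impaired"
    ENHANCED = "enhanced"
    NEUTRAL = "neutral"
    SITE_DESTROYED = "site_destroyed"


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet (T accepted on input)."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        L = len(self.sequence)
        if not 18 <= L <= 25:
            raise ValidationError(
                f"miRNA {self.id!r} length {L} outside the mature-miRNA "
                f"range 18-25 nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Bulge:
    """A single unpaired nucleotide in the duplex.

    strand='target': one extra mRNA base between the site positions that
    pair with miRNA positions `anchor` and `anchor`+1 (penalty charged to
    `anchor`).  strand='mirna': the miRNA base at position `anchor` itself
    is unpaired.
    """

    strand: str  # "target" | "mirna"
    anchor: int  # miRNA position, 1-based
    base: str


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position pairing of one miRNA against one target site.

    ``pairs[i-1]`` is the pair class of miRNA position i: one of
    "match", "wobble", "mismatch", or "bulge" (miRNA-strand bulge only).
    `site_start`/`site_end` are 1-based inclusive on the transcript.
    """

    mirna_id: str
    target_id: str
    site_start: int
    site_end: int
    pairs: tuple
    bulges: tuple = ()

    @property
    def mirna_length(self) -> int:
        return len(self.pairs)

    @property
    def site_length(self) -> int:
        return self.site_end - self.site_start + 1

    def pairing_map(self) -> dict:
        """miRNA position (1-based) -> in-site position (1-based, mRNA 5'->3').

        Bulged miRNA positions are absent from the map.
        """
        L = self.mirna_length
        M = self.site_length
        if not self.bulges:
            return {i: L - i + 1 for i in range(1, L + 1)}
        (b,) = self.bulges
        if b.strand == "target":
            a = b.anchor
            out = {}
            for i in range(1, L + 1):
                out[i] = (M - i + 1) if i <= a else (M - i)
            return out
        # miRNA-strand bulge at position b.anchor
        out = {}
        for i in range(1, L + 1):
            if i == b.anchor:
                continue
            out[i] = (M - i + 1) if i < b.anchor else (M - i + 2)
        return out

    def bulged_site_position(self) -> Optional[int]:
        """In-site position of a target-strand bulged base, if any."""
        for b in self.bulges:
            if b.strand == "target":
                return self.site_length - b.anchor
        return None


@dataclass
class TargetSite:
    """A scored miRNA-complementary region on a transcript."""

    alignment: DuplexAlignment
    site_seq: str  # RNA spelling, mRNA 5'->3'
    mirna_seq: str
    expectation: float
    inhibition: Inhibition
    upe_proxy: Optional[float] = None

    @property
    def site_seq_dna(self) -> str:
        return to_dna(self.site_seq)


@dataclass(frozen=True)
class RescoreResult:
    """Outcome of re-scoring a site under one or more allele edits."""

    e_ref: float
    e_alt: float
    delta_e: float
    upe_ref: Optional[float]
    upe_alt: Optional[float]
    effect: AlleleEffect


# ---------------------------------------------------------------------------
# expectation score
# ---------------------------------------------------------------------------

def _penalty(cls: str, config: ScoringConfig) -> float:
    if cls == "match":
        return 0.0
    if cls == "wobble":
        return config.wobble_penalty
    if cls == "mismatch":
        return config.mismatch_penalty
    if cls == "bulge":
        return config.bulge_penalty
    raise ValidationError(f"unknown pair class {cls!r}")


def score_duplex(
    mirna: MiRNA,
    site_seq: str,
    alignment: DuplexAlignment,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Expectation score of a duplex, verifying the alignment on the way.

    Every pair class in the alignment is checked against the actual bases
    of `mirna` and `site_seq`; the first inconsistency raises a
    ValidationError naming the miRNA position.
    """
    site = to_rna(site_seq)
    L = len(mirna)
    if alignment.mirna_length != L:
        raise ValidationError(
            f"alignment covers {alignment.mirna_length} miRNA positions "
            f"but miRNA {mirna.id!r} has {L}"
        )
    if alignment.site_length != len(site):
        raise ValidationError(
            f"alignment site interval length {alignment.site_length} != "
            f"site sequence length {len(site)}"
        )
    n_bulges = len(alignment.bulges)
    if n_bulges > 1:
        raise ValidationError("at most one bulge per duplex is supported")
    expect_len = L + sum(1 for b in alignment.bulges if b.strand == "target") \
        - sum(1 for b in alignment.bulges if b.strand == "mirna")
    if len(site) != expect_len:
        raise ValidationError(
            f"site length {len(site)} inconsistent with bulge structure "
            f"(expected {expect_len})"
        )

    pmap = alignment.pairing_map()
    E = 0.0
    for i in range(1, L + 1):
        cls = alignment.pairs[i - 1]
        if cls == "bulge":
            if not any(b.strand == "mirna" and b.anchor == i
                       for b in alignment.bulges):
                raise ValidationError(
                    f"miRNA position {i} marked bulge but no miRNA-strand "
                    f"bulge is declared there"
                )
            E += config.seed_weight(i) * config.bulge_penalty
            continue
        j = pmap[i]
        true_cls = classify_pair(mirna.sequence[i - 1], site[j - 1])
        if true_cls != cls:
            raise ValidationError(
                f"pair class mismatch at miRNA position {i}: alignment "
                f"says {cls!r} but bases {mirna.sequence[i - 1]}:"
                f"{site[j - 1]} are {true_cls!r}"
            )
        E += config.seed_weight(i) * _penalty(cls, config)
    for b in alignment.bulges:
        if b.strand == "target":
            j = alignment.bulged_site_position()
            if site[j - 1] != to_rna(b.base):
                raise ValidationError(
                    f"bulged base at in-site position {j} is {site[j - 1]} "
                    f"but alignment records {b.base}"
                )
            E += config.seed_weight(b.anchor) * config.bulge_penalty
    return E


# ---------------------------------------------------------------------------
# site scanning
# ---------------------------------------------------------------------------

def _align_window(
    mirna_seq: str,
    window: str,
    bulge: Optional[tuple],
    cutoff: float,
    config: ScoringConfig,
):
    """Score one candidate window; return (E, pairs, bulges) or None.

    `bulge` is None (ungapped), ("target", anchor) or ("mirna", pos).
    Accumulation stops early once E exceeds `cutoff`.
    """
    L = len(mirna_seq)
    M = len(window)
    pairs = []
    bulges = ()
    E = 0.0
    if bulge is None:
        for i in range(1, L + 1):
            cls = classify_pair(mirna_seq[i - 1], window[L - i])
            pairs.append(cls)
            E += config.seed_weight(i) * _penalty(cls, config)
            if E > cutoff:
                return None
    elif bulge[0] == "target":
        a = bulge[1]
        E = config.seed_weight(a) * config.bulge_penalty
        if E > cutoff:
            return None
        for i in range(1, L + 1):
            j = (M - i + 1) if i <= a else (M - i)
            cls = classify_pair(mirna_seq[i - 1], window[j - 1])
            pairs.append(cls)
            E += config.seed_weight(i) * _penalty(cls, config)
            if E > cutoff:
                return None
        bulges = (Bulge("target", a, window[M - a - 1]),)
    else:
        bpos = bulge[1]
        E = config.seed_weight(bpos) * config.bulge_penalty
        if E > cutoff:
            return None
        for i in range(1, L + 1):
            if i == bpos:
                pairs.append("bulge")
                continue
            j = (M - i + 1) if i < bpos else (M - i + 2)
            cls = classify_pair(mirna_seq[i - 1], window[j - 1])
            pairs.append(cls)
            E += config.seed_weight(i) * _penalty(cls, config)
            if E > cutoff:
                return None
        bulges = (Bulge("mirna", bpos, mirna_seq[bpos - 1]),)
    return E, tuple(pairs), bulges


def _candidate_windows(L: int, n: int):
    """Yield (start0, window_len, bulge_spec) for every candidate duplex."""
    for s in range(0, n - L + 1):
        yield s, L, None
    for s in range(0, n - (L + 1) + 1):
        for a in range(1, L):
            yield s, L + 1, ("target", a)
    for s in range(0, n - (L - 1) + 1):
        for b in range(2, L):
            yield s, L - 1, ("mirna", b)


def find_sites(
    mirna: MiRNA,
    transcript_seq: str,
    max_expectation: float = None,
    transcript_id: str = "",
    config: ScoringConfig = DEFAULT_CONFIG,
) -> list:
    """Scan a transcript for target sites of one miRNA.

    Enumerates every ungapped window of length L plus every single-bulge
    variant (site lengths L-1 and L+1), scores each implied alignment and
    returns all sites with E <= max_expectation, sorted by (E, position).
    Overlapping hits are all reported.
    """
    if max_expectation is None:
        max_expectation = config.max_expectation
    seq = to_rna(transcript_seq) if transcript_seq else ""
    L = len(mirna)
    n = len(seq)
    out = []
    for start0, wlen, bulge in _candidate_windows(L, n):
        window = seq[start0:start0 + wlen]
        hit = _align_window(mirna.sequence, window, bulge, max_expectation,
                            config)
        if hit is None:
            continue
        E, pairs, bulges = hit
        aln = DuplexAlignment(
            mirna_id=mirna.id,
            target_id=transcript_id,
            site_start=start0 + 1,
            site_end=start0 + wlen,
            pairs=pairs,
            bulges=bulges,
        )
        out.append(
            TargetSite(
                alignment=aln,
                site_seq=window,
                mirna_seq=mirna.sequence,
                expectation=E,
                inhibition=classify_inhibition(aln, config),
            )
        )
    out.sort(key=lambda s: (s.expectation, s.alignment.site_start,
                            s.alignment.site_end))
    return out


def classify_inhibition(
    alignment: DuplexAlignment, config: ScoringConfig = DEFAULT_CONFIG
) -> Inhibition:
    """Cleavage vs translational repression from central-region pairing.

    A mismatch or bulge anchored at miRNA positions 9-11 predicts
    translational repression; Watson-Crick pairs and G:U wobbles there
    leave the site in cleavage mode.
    """
    lo, hi = config.central_start, config.central_end
    for i in range(lo, hi + 1):
        if i <= len(alignment.pairs) and alignment.pairs[i - 1] in (
                "mismatch", "bulge"):
            return Inhibition.TRANSLATION
    for b in alignment.bulges:
        if b.strand == "target" and lo <= b.anchor <= hi:
            return Inhibition.TRANSLATION
    return Inhibition.CLEAVAGE


# ---------------------------------------------------------------------------
# accessibility proxy
# ---------------------------------------------------------------------------

def _nussinov(seq: str, config: ScoringConfig):
    """Max-weight nested structure DP; returns (score matrix, n)."""
    n = len(seq)
    minloop = config.min_hairpin_loop
    N = [[0.0] * n for _ in range(n)]
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = 0.0
            w = config.pair_weight(seq[i], seq[j])
            if w > 0:
                inner = N[i + 1][j - 1] if i + 1 <= j - 1 else 0.0
                best = inner + w
            for k in range(i, j):
                v = N[i][k] + N[k + 1][j]
                if v > best:
                    best = v
            N[i][j] = best
    return N


def _traceback(seq: str, N, i: int, j: int, config: ScoringConfig, pairs: list):
    """Canonical traceback: diagonal first, then smallest bifurcation."""
    while i < j:
        if N[i][j] == 0.0:
            return
        w = config.pair_weight(seq[i], seq[j])
        if (
            w > 0
            and j - i > config.min_hairpin_loop
            and N[i][j] == (N[i + 1][j - 1] if i + 1 <= j - 1 else 0.0) + w
        ):
            pairs.append((i, j))
            i, j = i + 1, j - 1
            continue
        for k in range(i, j):
            if N[i][j] == N[i][k] + N[k + 1][j]:
                _traceback(seq, N, i, k, config, pairs)
                i = k + 1
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("traceback failed to reproduce DP optimum")


def upe_proxy(
    context_seq: str,
    site_start: int,
    site_end: int,
    flank: int = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Cost to unpair a target site, from a max-weight folding of its window.

    Folds the site plus `flank` nt of context on each side (clipped to the
    context bounds) with Nussinov-style dynamic programming (pair weights
    G:C=3, A:U=2, G:U=1, minimum hairpin loop 3) and returns the summed
    weight of predicted pairs having at least one endpoint inside the
    site.  Higher values mean a less accessible site.  Reported in score
    units, not kcal/mol.
    """
    if flank is None:
        flank = config.upe_flank
    seq = to_rna(context_seq)
    n = len(seq)
    if not (1 <= site_start <= site_end <= n):
        raise ValidationError(
            f"site interval ({site_start}, {site_end}) outside context "
            f"of length {n}"
        )
    w_start = max(1, site_start - flank)
    w_end = min(n, site_end + flank)
    window = seq[w_start - 1:w_end]
    N = _nussinov(window, config)
    pairs: list = []
    if len(window) > 1:
        _traceback(window, N, 0, len(window) - 1, config, pairs)
    total = 0.0
    for i0, j0 in pairs:
        gi = w_start + i0  # 1-based context coordinate
        gj = w_start + j0
        if site_start <= gi <= site_end or site_start <= gj <= site_end:
            total += config.pair_weight(window[i0], window[j0])
    return total


# ---------------------------------------------------------------------------
# allele re-scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleEdit:
    """One edit applied to a site sequence, mRNA 5'->3' coordinates.

    `position` is the 1-based in-site position of the first reference
    base; `ref`/`alt` are the replaced and replacement strings (VCF-style:
    unequal lengths encode indels).
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "ref", to_rna(self.ref))
        object.__setattr__(self, "alt", to_rna(self.alt) if self.alt else "")

    @property
    def ref_span(self) -> tuple:
        return (self.position, self.position + len(self.ref) - 1)


def apply_edits(site_seq: str, edits: Sequence[AlleleEdit]) -> str:
    """Apply non-overlapping edits jointly; validates every ref base."""
    seq = to_rna(site_seq)
    ordered = sorted(edits, key=lambda e: e.position)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.position <= prev.ref_span[1]:
            raise ValidationError(
                f"overlapping edits at in-site positions {prev.position} "
                f"and {nxt.position}"
            )
    for e in ordered:
        lo, hi = e.ref_span
        if hi > len(seq) or lo < 1:
            raise ValidationError(
                f"edit ref span ({lo}, {hi}) outside site of length "
                f"{len(seq)}"
            )
        found = seq[lo - 1:hi]
        if found != e.ref:
            raise RefAlleleMismatch(lo, to_dna(e.ref), to_dna(found))
    for e in sorted(ordered, key=lambda e: -e.position):
        lo, hi = e.ref_span
        seq = seq[:lo - 1] + e.alt + seq[hi:]
    return seq


def best_alignment_for(
    mirna_seq: str,
    site_seq: str,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple:
    """Best (lowest-E) single-duplex alignment of a miRNA to a sequence
    exactly the length of one candidate site (L-1, L or L+1).

    Returns (E, pairs, bulges); E is inf when no duplex geometry fits.
    Ties resolve to the ungapped alignment, then the smallest anchor.
    """
    mirna_seq = to_rna(mirna_seq)
    site = to_rna(site_seq)
    L = len(mirna_seq)
    M = len(site)
    if M == L:
        cands = [None]
    elif M == L + 1:
        cands = [("target", a) for a in range(1, L)]
    elif M == L - 1:
        cands = [("mirna", b) for b in range(2, L)]
    else:
        return float("inf"), (), ()
    best = None
    for bulge in cands:
        hit = _align_window(mirna_seq, site, bulge, float("inf"), config)
        E, pairs, bulges = hit
        if best is None or E < best[0]:
            best = (E, pairs, bulges)
    return best


def rescore_with_alleles(
    site: TargetSite,
    edits: Sequence,
    context_seq: Optional[str] = None,
    flank: int = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> RescoreResult:
    """Re-score a target site after applying allele edits jointly.

    Edits may be AlleleEdit objects or (position, ref, alt) tuples in
    in-site coordinates (1-based, mRNA 5'->3').  The miRNA is re-aligned
    against the edited site sequence over all admissible single-bulge
    geometries; delta_e = E_alt - E_ref.  When `context_seq` (typically
    the transcript) is supplied the accessibility proxy is computed for
    both alleles over the site +- flank window.

    effect: site_destroyed when E_alt exceeds the retention cutoff,
    otherwise impaired (delta_e > 0), enhanced (< 0) or neutral (= 0).
    """
    if flank is None:
        flank = config.upe_flank
    edits = [e if isinstance(e, AlleleEdit) else AlleleEdit(*e) for e in edits]
    e_ref = site.expectation
    alt_seq = apply_edits(site.site_seq, edits)
    e_alt, _, _ = best_alignment_for(site.mirna_seq, alt_seq, config)

    upe_ref = upe_alt = None
    if context_seq is not None:
        ctx = to_rna(context_seq)
        s0, s1 = site.alignment.site_start, site.alignment.site_end
        upe_ref = upe_proxy(ctx, s0, s1, flank, config)
        shifted = [AlleleEdit(e.position + s0 - 1, e.ref, e.alt)
                   for e in edits]
        ctx_alt = apply_edits(ctx, shifted)
        alt_len = len(alt_seq)
        upe_alt = upe_proxy(ctx_alt, s0, s0 + alt_len - 1, flank, config) \
            if alt_len > 0 else 0.0

    delta = e_alt - e_ref
    if e_alt > config.max_expectation:
        effect = AlleleEffect.SITE_DESTROYED
    elif delta > 0:
        effect = AlleleEffect.IMPAIRED
    elif delta < 0:
        effect = AlleleEffect.ENHANCED
    else:
        effect = AlleleEffect.NEUTRAL
    return RescoreResult(
        e_ref=e_ref,
        e_alt=e_alt,
        delta_e=delta,
        upe_ref=upe_ref,
        upe_alt=upe_alt,
        effect=effect,
    )


def alignment_text(site: TargetSite) -> str:
    """Three-row text rendering of a duplex (target 5'->3' on top)."""
    aln = site.alignment
    pmap = aln.pairing_map()
    M = aln.site_length
    mid = [" "] * M
    bottom = ["."] * M
    for i, j in pmap.items():
        cls = aln.pairs[i - 1]
        mid[j - 1] = "|" if cls == "match" else (
            "o" if cls == "wobble" else " ")
        bottom[j - 1] = site.mirna_seq[i - 1]
    top = to_dna(site.site_seq)
    return (
        f"target 5' {top} 3'\n"
        f"          {''.join(mid)}\n"
        f"miRNA  3' {''.join(bottom)} 5'"
    )
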