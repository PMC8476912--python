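"""Synthetic genotype-phenotype cohorts with planted miRNA target sites.

Generates a complete, internally consistent study cohort: a small genome
with spliced and minus-strand gene models, transcripts carrying planted
miRNA-complementary sites at known expectation scores, a population VCF
of effectively homozygous inbred accessions with a controlled
minor-allele-frequency spectrum and missingness, and multi-year
quantitative traits with planted per-variant effects, additive year
effects and Gaussian noise.  Every quantity is recorded in truth tables
so each pipeline stage can be checked against what was planted.

The defaults emulate the design of a rapeseed re-sequencing panel:
210 selfed accessions (dosages {0, 2}), three consecutive trial years,
and planted causal variants parameterized by the marginal phenotypic
variance they explain (marker R-squared), with effect sizes around 0.15
for the strongest marker.  Each output stream draws from its own
pseudo-random generator derived from the master seed, so regenerating
one file never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mirvar.config import ScoringConfig, DEFAULT_CONFIG
from mirvar.errors import ValidationError
from mirvar.mapping import TranscriptModel, map_transcript_to_genome, \
    reverse_complement
from mirvar.scoring import MiRNA, to_dna
from mirvar.variants import GenotypeMatrix, VariantRecord
from mirvar.association import TraitTable

_DNA = np.array(list("ACGT"))
_RNA_COMPLEMENT_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass
class CausalVariant:
    """A planted trait effect: which variant, which trait, how strong.

    `target_r2` is the marginal fraction of phenotypic variance the
    variant explains within each year (marker R-squared scale).
    """

    variant_key: str
    trait: str
    target_r2: float


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; same seed => identical outputs."""

    seed: int = 0
    # panel
    n_accessions: int = 210
    missing_rate: float = 0.03
    # genotype MAF spectrum: ("uniform", lo, hi) or
    # ("mixture", rare_fraction) with rare f ~ U(0.005, 0.048) and
    # common f ~ U(0.06, 0.5); the target rare fraction follows the
    # ~33.5% observed for target-site variants in resequenced rapeseed.
    maf_spec: tuple = ("mixture", 0.335)
    # sequences
    n_mirnas: int = 6
    mirna_length: int = 21
    n_transcripts: int = 12
    transcript_length: int = 600
    sites_per_transcript: int = 1
    spacer_length: int = 200
    intron_length: int = 90
    n_chromosomes: int = 2
    # variants
    site_snp_positions: tuple = (1, 10, 15, 20)  # cycled over sites
    n_second_site_snps: int = 3   # sites also carrying a second SNP
    second_snp_position: int = 13
    n_site_indels: int = 2        # sites carrying a 1-nt deletion
    site_indel_position: int = 5
    n_offsite_variants: int = 150
    # phenotypes
    traits: tuple = ("trait_a", "trait_b", "trait_c")
    years: tuple = (2016, 2017, 2018)
    year_effects: tuple = (0.0, 0.5, -0.3)
    residual_sd: float = 1.0
    trait_mean: float = 10.0
    causal_r2: float = 0.15       # per-trait planted marginal R-squared
    n_causal_per_trait: int = 1

    def __post_init__(self):
        for r in (self.missing_rate,):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate {r} outside [0, 1]")
        if not 0.0 < self.causal_r2 < 1.0:
            raise ValidationError("causal_r2 must be in (0, 1)")
        if len(self.year_effects) != len(self.years):
            raise ValidationError("year_effects must match years")


def _draw_allele_freq(rng: np.random.Generator, maf_spec: tuple) -> float:
    if maf_spec[0] == "uniform":
        return float(rng.uniform(maf_spec[1], maf_spec[2]))
    if maf_spec[0] == "mixture":
        rare_fraction = maf_spec[1]
        if rng.uniform() < rare_fraction:
            return float(rng.uniform(0.005, 0.048))
        return float(rng.uniform(0.06, 0.5))
    raise ValidationError(f"unknown MAF spec {maf_spec!r}")


def simulate_genotype_matrix(
    config: SimulationConfig,
    n_variants: int = None,
    rng: Optional[np.random.Generator] = None,
    keys: Optional[Sequence[str]] = None,
    freqs: Optional[Sequence[float]] = None,
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Homozygous-inbred dosage matrix with masked missing calls.

    Per variant, an alt-allele frequency f is drawn from the MAF spec and
    each accession receives dosage 2 with probability f, else 0 (selfed
    lines carry no heterozygotes).  Entries are then masked missing at
    the configured rate.  Returns the masked GenotypeMatrix plus the
    unmasked (true) dosage frame used for phenotype simulation.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0])
    if n_variants is None:
        n_variants = config.n_offsite_variants
    if keys is None:
        keys = [f"m{i:05d}" for i in range(1, n_variants + 1)]
    if freqs is None:
        freqs = [_draw_allele_freq(rng, config.maf_spec)
                 for _ in range(n_variants)]
    accessions = [f"acc{i:04d}" for i in range(1, config.n_accessions + 1)]
    true = np.zeros((config.n_accessions, n_variants))
    for j, f in enumerate(freqs):
        true[:, j] = 2.0 * (rng.uniform(size=config.n_accessions) < f)
    masked = true.copy()
    if config.missing_rate > 0:
        mask = rng.uniform(size=true.shape) < config.missing_rate
        masked[mask] = np.nan
    true_df = pd.DataFrame(true, index=accessions, columns=list(keys))
    return GenotypeMatrix(pd.DataFrame(masked, index=accessions,
                                       columns=list(keys))), true_df


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_DNA, size=n))


def _site_seq_for(mirna: MiRNA, defect: str,
                  config: ScoringConfig = DEFAULT_CONFIG) -> Tuple[str, float]:
    """DNA site sequence complementary to a miRNA, with a planted defect.

    defect: "perfect" (E=0), "wobble" (one G:U outside the seed, E=0.5)
    or "mismatch" (one non-seed mismatch, E=1.0).  Returns the site in
    DNA letters (mRNA 5'->3') and its planted expectation score.
    """
    L = len(mirna)
    site = [_RNA_COMPLEMENT_DNA[b] for b in reversed(mirna.sequence)]
    # in-site position j pairs miRNA position L - j + 1
    if defect == "perfect":
        return "".join(site), 0.0
    outside_seed = [p for p in range(config.seed_end + 1, L + 1)]
    if defect == "wobble":
        for p in outside_seed:
            m = mirna.sequence[p - 1]
            if m in "GU":
                j = L - p + 1
                site[j - 1] = "T" if m == "G" else "G"
                return "".join(site), config.wobble_penalty
        defect = "mismatch"  # miRNA tail cannot wobble; fall through
    if defect == "mismatch":
        p = outside_seed[-1]
        m = mirna.sequence[p - 1]
        partner = _RNA_COMPLEMENT_DNA[m]
        wobble_partner = {"G": "T", "U": "G"}.get(m)
        choice = next(b for b in "ACGT"
                      if b != partner and b != wobble_partner)
        j = L - p + 1
        site[j - 1] = choice
        return "".join(site), config.mismatch_penalty
    raise ValidationError(f"unknown planted defect {defect!r}")


@dataclass
class Cohort:
    """All in-memory products of one simulated cohort."""

    config: SimulationConfig
    genome: Dict[str, str]
    transcripts: Dict[str, str]
    mirnas: List[MiRNA]
    models: List[TranscriptModel]
    variants: List[VariantRecord]
    accessions: List[str]
    genotypes: GenotypeMatrix
    true_dosages: pd.DataFrame
    sites_truth: pd.DataFrame
    variants_truth: pd.DataFrame
    causal: List[CausalVariant]
    traits: TraitTable

    def write(self, out_dir) -> dict:
        """Write genome/transcripts/miRNA FASTA, GFF3, VCF and TSVs."""
        from mirvar import io_formats as io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "transcripts": out / "transcripts.fa",
            "mirnas": out / "mirnas.fa",
            "gff3": out / "genes.gff3",
            "vcf": out / "population.vcf",
            "traits": out / "traits.tsv",
            "sites_truth": out / "sites_truth.tsv",
            "variants_truth": out / "variants_truth.tsv",
        }
        io.write_fasta(self.genome, paths["genome"])
        io.write_fasta(self.transcripts, paths["transcripts"])
        io.write_fasta({m.id: to_dna(m.sequence) for m in self.mirnas},
                       paths["mirnas"])
        io.write_gff3(self.models, paths["gff3"])
        io.write_vcf(self.variants, self.accessions, paths["vcf"])
        self.traits.df.to_csv(paths["traits"], sep="\t", index=False)
        self.sites_truth.to_csv(paths["sites_truth"], sep="\t", index=False)
        self.variants_truth.to_csv(paths["variants_truth"], sep="\t",
                                   index=False)
        return paths


def simulate_target_cohort(
    config: SimulationConfig,
    scoring: ScoringConfig = DEFAULT_CONFIG,
) -> Cohort:
    """Build a full synthetic cohort (see module docstring).

    Transcripts embed, for each planted site, the reverse complement of a
    simulated miRNA — optionally with a controlled wobble or mismatch to
    hit a chosen expectation score.  Gene models include spliced and
    minus-strand genes; variants are placed at chosen in-site positions
    and at random off-site positions; per-accession genotypes follow the
    homozygous-inbred model.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_mirna = np.random.default_rng(streams[0])
    rng_tx = np.random.default_rng(streams[1])
    rng_genome = np.random.default_rng(streams[2])
    rng_var = np.random.default_rng(streams[3])
    rng_geno = np.random.default_rng(streams[4])
    rng_pheno = np.random.default_rng(streams[5])

    # --- miRNAs
    mirnas = [
        MiRNA(f"mir{i:03d}", _random_dna(rng_mirna, config.mirna_length))
        for i in range(1, config.n_mirnas + 1)
    ]

    # --- transcripts with planted sites
    defects = ["perfect", "wobble", "mismatch"]
    transcripts: Dict[str, str] = {}
    site_rows = []
    for t in range(1, config.n_transcripts + 1):
        tid = f"t{t:03d}"
        seq = _random_dna(rng_tx, config.transcript_length)
        for s in range(config.sites_per_transcript):
            k = (t - 1) * config.sites_per_transcript + s
            mirna = mirnas[k % len(mirnas)]
            defect = defects[k % len(defects)]
            site_dna, planted_e = _site_seq_for(mirna, defect, scoring)
            margin = 60
            hi = config.transcript_length - margin - len(site_dna)
            start = int(rng_tx.integers(margin, hi))  # 0-based
            seq = seq[:start] + site_dna + seq[start + len(site_dna):]
            site_rows.append({
                "site_id": f"site{k + 1:03d}",
                "mirna_id": mirna.id,
                "transcript_id": tid,
                "t_start": start + 1,
                "t_end": start + len(site_dna),
                "planted_e": planted_e,
                "defect": defect,
            })
        transcripts[tid] = seq

    # --- genome and gene models
    genome_parts: Dict[str, list] = {
        f"chr{c}": [] for c in range(1, config.n_chromosomes + 1)}
    genome_len: Dict[str, int] = {c: 0 for c in genome_parts}
    models: List[TranscriptModel] = []
    sites_by_tid: Dict[str, list] = {}
    for row in site_rows:
        sites_by_tid.setdefault(row["transcript_id"], []).append(row)

    for t, (tid, tseq) in enumerate(transcripts.items()):
        chrom = f"chr{(t % config.n_chromosomes) + 1}"
        strand = "+" if t % 2 == 0 else "-"
        spliced = t % 3 == 2
        spacer = _random_dna(rng_genome, config.spacer_length)
        genome_parts[chrom].append(spacer)
        genome_len[chrom] += len(spacer)
        g0 = genome_len[chrom] + 1  # 1-based start of the gene

        n = len(tseq)
        if spliced:
            # cut point outside every planted site
            blocked = [(r["t_start"], r["t_end"])
                       for r in sites_by_tid.get(tid, [])]
            cut = None
            for cand in range(n // 2, n - 50):
                if all(not (s <= cand < e) for s, e in blocked):
                    cut = cand  # exon1 = 1..cut (transcript coords)
                    break
            intron = _random_dna(rng_genome, config.intron_length)
            t_exon1, t_exon2 = tseq[:cut], tseq[cut:]
            if strand == "+":
                gene_seq = t_exon1 + intron + t_exon2
                exons = (
                    (g0, g0 + cut - 1),
                    (g0 + cut + len(intron), g0 + n + len(intron) - 1),
                )
            else:
                gene_seq = (reverse_complement(t_exon2) + intron
                            + reverse_complement(t_exon1))
                exons = (
                    (g0, g0 + (n - cut) - 1),
                    (g0 + (n - cut) + len(intron),
                     g0 + n + len(intron) - 1),
                )
        else:
            gene_seq = tseq if strand == "+" else reverse_complement(tseq)
            exons = ((g0, g0 + n - 1),)

        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"gene_{tid}",
            chrom=chrom,
            strand=strand,
            exons=exons,
        )
        cds_blocks = tuple(
            tuple(b) for b in map_transcript_to_genome(model, 61, n - 60))
        cds_blocks = tuple(sorted(cds_blocks))
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"gene_{tid}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=cds_blocks,
        )
        models.append(model)
        genome_parts[chrom].append(gene_seq)
        genome_len[chrom] += len(gene_seq)

    for chrom in genome_parts:
        tail = _random_dna(rng_genome, config.spacer_length)
        genome_parts[chrom].append(tail)
    genome = {c: "".join(parts) for c, parts in genome_parts.items()}
    models_by_tid = {m.transcript_id: m for m in models}

    # genomic footprint of every planted site
    site_blocks: Dict[str, list] = {}
    for row in site_rows:
        model = models_by_tid[row["transcript_id"]]
        blocks = map_transcript_to_genome(model, row["t_start"],
                                          row["t_end"])
        site_blocks[row["site_id"]] = (model.chrom, model.strand, blocks)
        row["chrom"] = model.chrom
        row["strand"] = model.strand

    def genomic_of_in_site(site_id: str, in_pos: int) -> int:
        chrom, strand, blocks = site_blocks[site_id]
        offset = 0
        for lo, hi in blocks:
            blen = hi - lo + 1
            if in_pos <= offset + blen:
                k = in_pos - offset - 1
                return lo + k if strand == "+" else hi - k
            offset += blen
        raise ValidationError(f"in-site position {in_pos} outside "
                              f"{site_id}")

    # off-site variants stay clear of site blocks plus a 1-nt fringe:
    # single-bulge variants of a planted site reach one base beyond it
    occupied = {c: set() for c in genome}
    for site_id, (chrom, _, blocks) in site_blocks.items():
        for lo, hi in blocks:
            occupied[chrom].update(range(lo - 1, hi + 2))

    # --- variants
    var_rows = []
    for idx, row in enumerate(site_rows):
        site_len = row["t_end"] - row["t_start"] + 1
        in_pos = config.site_snp_positions[
            idx % len(config.site_snp_positions)]
        in_pos = min(in_pos, site_len)
        gpos = genomic_of_in_site(row["site_id"], in_pos)
        ref = genome[row["chrom"]][gpos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        var_rows.append({"chrom": row["chrom"], "pos": gpos, "ref": ref,
                         "alt": alt, "site_id": row["site_id"],
                         "in_site_position": in_pos})
        if idx < config.n_second_site_snps:
            p2 = min(config.second_snp_position, site_len)
            if p2 != in_pos:
                g2 = genomic_of_in_site(row["site_id"], p2)
                r2b = genome[row["chrom"]][g2 - 1]
                a2 = next(b for b in "ACGT" if b != r2b)
                var_rows.append({"chrom": row["chrom"], "pos": g2,
                                 "ref": r2b, "alt": a2,
                                 "site_id": row["site_id"],
                                 "in_site_position": p2})
    # 1-nt in-site deletions on the last few sites
    for idx in range(max(0, len(site_rows) - config.n_site_indels),
                     len(site_rows)):
        row = site_rows[idx]
        chrom, strand, blocks = site_blocks[row["site_id"]]
        p = config.site_indel_position
        g_anchor = genomic_of_in_site(row["site_id"], p)
        g_del = genomic_of_in_site(row["site_id"], p + 1)
        gpos = min(g_anchor, g_del)
        ref = genome[chrom][gpos - 1:gpos + 1]
        alt = ref[0]
        # the deleted span covers in-site positions p and p+1 on either
        # strand; the first overlapped mRNA base is p
        var_rows.append({"chrom": chrom, "pos": gpos, "ref": ref,
                         "alt": alt, "site_id": row["site_id"],
                         "in_site_position": p})

    used_positions = {(v["chrom"], g)
                      for v in var_rows
                      for g in range(v["pos"],
                                     v["pos"] + len(v["ref"]))}
    n_placed = 0
    while n_placed < config.n_offsite_variants:
        chrom = f"chr{int(rng_var.integers(1, config.n_chromosomes + 1))}"
        gpos = int(rng_var.integers(1, len(genome[chrom]) + 1))
        if gpos in occupied[chrom] or (chrom, gpos) in used_positions:
            continue
        ref = genome[chrom][gpos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        var_rows.append({"chrom": chrom, "pos": gpos, "ref": ref,
                         "alt": alt, "site_id": "", "in_site_position": 0})
        used_positions.add((chrom, gpos))
        n_placed += 1

    var_rows.sort(key=lambda v: (v["chrom"], v["pos"], v["ref"], v["alt"]))

    # --- genotypes
    freqs = []
    for v in var_rows:
        freqs.append(_draw_allele_freq(rng_geno, config.maf_spec))
    keys = [f"{v['chrom']}_{v['pos']}_{v['ref']}_{v['alt']}"
            for v in var_rows]
    genotypes, true_df = simulate_genotype_matrix(
        config, n_variants=len(var_rows), rng=rng_geno, keys=keys,
        freqs=freqs)
    accessions = genotypes.accessions
    variants = [
        VariantRecord(chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                      alt=v["alt"],
                      dosages=genotypes.df[keys[i]].to_numpy())
        for i, v in enumerate(var_rows)
    ]

    # --- causal variants: pick common off-site markers, one per trait
    causal: List[CausalVariant] = []
    offsite = [i for i, v in enumerate(var_rows) if v["site_id"] == ""]
    common = [i for i in offsite
              if 0.1 <= true_df[keys[i]].mean() / 2 <= 0.9]
    picks = list(rng_pheno.choice(common,
                                  size=config.n_causal_per_trait
                                  * len(config.traits),
                                  replace=False))
    for ti, trait in enumerate(config.traits):
        for c in range(config.n_causal_per_trait):
            i = picks[ti * config.n_causal_per_trait + c]
            causal.append(CausalVariant(keys[i], trait, config.causal_r2))

    traits = simulate_phenotypes(
        true_df, causal, config.years, config.year_effects,
        residual_sd=config.residual_sd, mean=config.trait_mean,
        trait_names=config.traits, rng=rng_pheno)

    causal_by_key = {c.variant_key: c for c in causal}
    for i, v in enumerate(var_rows):
        c = causal_by_key.get(keys[i])
        v["key"] = keys[i]
        v["is_causal"] = c is not None
        v["trait"] = c.trait if c else ""
        v["target_r2"] = c.target_r2 if c else 0.0
        v["planted_freq"] = freqs[i]

    sites_truth = pd.DataFrame(site_rows)
    variants_truth = pd.DataFrame(var_rows)[
        ["key", "chrom", "pos", "ref", "alt", "site_id",
         "in_site_position", "is_causal", "trait", "target_r2",
         "planted_freq"]
    ]
    return Cohort(
        config=config,
        genome=genome,
        transcripts=transcripts,
        mirnas=mirnas,
        models=models,
        variants=variants,
        accessions=accessions,
        genotypes=genotypes,
        true_dosages=true_df,
        sites_truth=sites_truth,
        variants_truth=variants_truth,
        causal=causal,
        traits=traits,
    )


def simulate_phenotypes(
    dosages: pd.DataFrame,
    causal: Sequence[CausalVariant],
    years: Sequence,
    year_effects: Sequence[float],
    residual_sd: float = 1.0,
    mean: float = 10.0,
    trait_names: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TraitTable:
    """Multi-year traits with planted variant effects.

    y[a, year] = mean + sum_c beta_c * g[a, c] + delta_year + eps,
    eps ~ N(0, residual_sd^2) independently per accession and year.
    Each beta_c is derived from the configured marginal R-squared and the
    realized dosage variance: with s = sum of a trait's target R-squared
    values, total variance sigma_tot^2 = residual_sd^2 / (1 - s) and
    beta_c = sqrt(target_r2 * sigma_tot^2 / var(g_c)).
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    if trait_names is None:
        trait_names = sorted({c.trait for c in causal}) or ["trait_a"]
    if len(year_effects) != len(years):
        raise ValidationError("year_effects must align with years")

    by_trait: Dict[str, list] = {t: [] for t in trait_names}
    for c in causal:
        if c.trait not in by_trait:
            raise ValidationError(
                f"causal variant targets unknown trait {c.trait!r}")
        by_trait[c.trait].append(c)

    accessions = list(dosages.index)
    n = len(accessions)
    rows = []
    for trait in trait_names:
        cset = by_trait[trait]
        s = sum(c.target_r2 for c in cset)
        if s >= 1.0:
            raise ValidationError(
                f"trait {trait!r}: summed target R-squared {s} >= 1")
        sigma_tot2 = residual_sd ** 2 / (1.0 - s)
        genetic = np.zeros(n)
        for c in cset:
            g = dosages[c.variant_key].to_numpy(dtype=float)
            vg = g.var()
            if vg <= 0:
                raise ValidationError(
                    f"causal variant {c.variant_key} is monomorphic; "
                    f"target R-squared unattainable")
            beta = np.sqrt(c.target_r2 * sigma_tot2 / vg)
            genetic = genetic + beta * g
        for year, delta in zip(years, year_effects):
            eps = rng.normal(0.0, residual_sd, size=n)
            y = mean + genetic + delta + eps
            for a, v in zip(accessions, y):
                rows.append({"accession": a, "trait": trait, "year": year,
                             "value": float(v)})
    return TraitTable(pd.DataFrame(rows))
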