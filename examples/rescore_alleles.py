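"""Re-score a target site under alternate alleles.

Starting from a perfect miRNA:site duplex, applies (a) a single SNP at
the base pairing miRNA position 10 and (b) two SNPs jointly — the
two-variants-in-one-site pattern — and prints the change in expectation
score (delta E > 0 weakens predicted binding) and in the accessibility
proxy (higher = costlier to unpair = less accessible site).
"""

from mirvar import MiRNA, find_sites, rescore_with_alleles

mirna = MiRNA("mir_demo", "UGACAGAAGAGAGUGAGCACA")
site = "UGUGCUCACUCUCUUCUGUCA"  # perfect complement, mRNA 5'->3'
transcript = "GCAAUC" * 10 + site + "ACGGUA" * 10

hit = find_sites(mirna, transcript, 0.0)[0]
print(f"reference site E = {hit.expectation}")

# SNP at in-site position 12, which pairs miRNA position 10 (seed)
one = rescore_with_alleles(hit, [(12, site[11], "A")],
                           context_seq=transcript)
print(f"A12 SNP : dE = {one.delta_e:+.1f} ({one.effect.value}), "
      f"upe {one.upe_ref} -> {one.upe_alt}")

# two SNPs applied jointly: in-site positions 7 and 13
joint = rescore_with_alleles(hit, [(7, site[6], "G"), (13, site[12], "A")],
                             context_seq=transcript)
print(f"joint   : dE = {joint.delta_e:+.1f} ({joint.effect.value}), "
      f"upe {joint.upe_ref} -> {joint.upe_alt}")

# A positive delta E means the alternate allele impairs miRNA binding;
# site_destroyed would mean the edited site no longer clears the
# retention cutoff (E <= 3.5) at all.
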