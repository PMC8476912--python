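"""Predict and score miRNA target sites on a transcript.

Builds a transcript carrying one perfect-complement site and one site
with a seed defect, scans it, and prints the retained sites with their
expectation scores (E), inhibition mode, and accessibility proxy.
Lower E means tighter predicted complementarity; sites are kept at
E <= 3.5.  The inhibition label switches from cleavage to translational
repression when miRNA positions 9-11 pair imperfectly.
"""

from mirvar import MiRNA, find_sites, upe_proxy
from mirvar.scoring import alignment_text

mirna = MiRNA("mir_demo", "UGACAGAAGAGAGUGAGCACA")  # 21 nt, 5'->3'

# the reverse complement (in mRNA letters) is a perfect site
perfect = "UGUGCUCACUCUCUUCUGUCA"
# a second copy with a mismatch at the base pairing miRNA position 10
central = perfect[:11] + "A" + perfect[12:]

transcript = "GCAAUC" * 10 + perfect + "ACGGUA" * 10 + central + "CUAGGC" * 10

for site in find_sites(mirna, transcript):
    a = site.alignment
    upe = upe_proxy(transcript, a.site_start, a.site_end)
    print(f"{a.site_start:>4}-{a.site_end:<4} E={site.expectation:<4}"
          f" {site.inhibition.value:<12} upe={upe}")
    if site.expectation == 0.0:
        print(alignment_text(site))

# Expected: the perfect site at E=0 (cleavage) plus the edited copy at
# E=2.0 labelled translation (central mismatch, seed-doubled penalty),
# and their single-bulge shoulder variants that stay under the cutoff.
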