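"""Design a knock-in cassette for a synthetic missense variant.

Builds a random 2 kb locus with a central coding region, picks a coding
SNV, and runs the full designer: guide selection (variant in PAM/seed),
synonymous WT' placement, 45-nt-arm ssODNs, and target-site primers.
"""

from crisprselect.fixtures import design_fixtures
from crisprselect.io import format_design_report

# design_fixtures draws random coding SNVs and keeps the designable ones
# (random sites without an NGG guide placing the edit in PAM/seed are real
# failures the designer reports and skips)
locus, variant, cassette = design_fixtures(1, seed=7)[0]

print(f"variant:        {variant.label}")
print(f"guide:          {cassette.guide.protospacer} PAM={cassette.guide.pam} "
      f"strand={cassette.guide.strand}")
print(f"cut distance:   {cassette.guide.variant_distance_to_cut} nt "
      "(variant to blunt cut; closer promotes knock-in)")
print(f"WT':            {cassette.wtprime_spec.label} "
      "(synonymous internal normalization edit)")
print(f"variant ssODN:  {len(cassette.variant_ssodn.sequence)} nt, "
      f"{cassette.variant_ssodn.polarity} (45-nt homology arms)")
print(f"primers:        product {cassette.primers.product_length} bp, offsets "
      f"{cassette.primers.forward_offset}/{cassette.primers.reverse_offset} nt "
      "outside the ssODN-covered region")
print()
print(format_design_report(cassette))
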