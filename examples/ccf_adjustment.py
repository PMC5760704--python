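"""Convert observed allele fractions to cancer cell fractions.

Shows the purity/copy-number adjustment on three archetypal loci: a
diploid heterozygous mutation, a mutation on the remaining copy of
chromosome 3 after LOH, and a super-clonal inconsistency.
"""

from umclone import ccf_from_vaf, estimate_multiplicity, expected_vaf
from umclone.ccf import estimate_ccf

purity = 0.8

print("expected VAF of a clonal diploid het mutation at purity 0.8:",
      expected_vaf(ccf=1.0, purity=purity, tumor_total_cn=2))
print("expected VAF of a clonal mutation under LOH (1 tumor copy):",
      round(expected_vaf(ccf=1.0, purity=purity, tumor_total_cn=1), 4))

# invert an observed VAF on a diploid locus
vaf = 0.2
print(f"VAF {vaf} on a diploid locus at purity {purity} -> CCF",
      ccf_from_vaf(vaf, purity, 2))

# a VAF too high for one copy implies multiplicity 2 on a 2+0 segment
m = estimate_multiplicity(vaf=0.9, purity=1.0, major_cn=2, minor_cn=0)
print("VAF 0.90 on a copy-neutral LOH segment -> multiplicity", m)

# full estimate with a Wilson 95% interval propagated to the CCF scale
est = estimate_ccf("BAP1", alt_count=40, ref_count=60, purity=purity,
                   major_cn=1, minor_cn=0)
print(f"BAP1 40/100 reads on LOH3: m={est.multiplicity}, CCF={est.ccf:.3f}, "
      f"95% CI ({est.ccf_ci[0]:.3f}, {est.ccf_ci[1]:.3f})")
# A CCF near 0.6 with an interval excluding 1 marks BAP1 as subclonal here.
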