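"""The screening funnel on the packaged 13-candidate table.

Thirteen adduct-bearing proteins enter; the funnel applies the
charge-specific XCorr reliability thresholds (z=2 needs >2.2, z=3 needs
>3.75, other charges fail), requires the same cysteine to be seen
alkylated in controls and adducted in treated samples ("identified
both"), and requires a mitochondrial localization to match the
phenotype arm.  One protein survives.
"""

from adductscreen.screen import apply_funnel, prioritize, reliability_filter
from adductscreen.synthetic_data import reference_candidates

records = reference_candidates()
print(f"candidates entering the funnel: {len(records)}")

scored = reliability_filter(records)
reliable = [r.protein for r in scored if r.passes_reliability]
print(f"pass reliability thresholds  : {reliable}")

both = [r.protein for r in records if r.identified_both]
print(f"identified in both arms      : {both}")

survivors = apply_funnel(records)
for r in survivors:
    print(f"funnel survivor: {r.protein}  charge {r.charge}  "
          f"XCorr {r.xcorr}  location '{r.location}'")

ranked = prioritize(reliability_filter(records))
print("priority ranking (top 3):",
      [(r.priority_rank, r.protein) for r in ranked[:3]])
# The survivor's XCorr is the reliability score of its best
# peptide-spectrum match; higher means a more trustworthy identification.
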