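"""ATP ledgers of carbon-fixation pathways.

Computes the net stoichiometry of each registered pathway from its flux
distribution and counts direct ATP hydrolysis (ATP->ADP = 1, ATP->AMP = 2)
plus the full ATP-equivalent cost with redox cofactors valued at
respiratory ATP yields (NADH 2.5, quinol 1.5, NADPH 2.75).
"""

import pathcost as pc

print(f"{'pathway':<18} {'product':<8} {'ATP':>5} {'ATP-equiv':>10}")
for name in ["CBB", "CBB_PTS", "C4_CBB_PEPS", "C4_CBB_PyrC", "rCCC",
             "HG_rTCA", "HP4HB_thaum", "HP4HB_cren", "MCG_like", "MCG_glycerate"]:
    entry = pc.get_pathway(name)
    net = entry.normalized_net
    print(f"{name:<18} {entry.product:<8} {pc.atp_count(net):>5g} "
          f"{pc.atp_equivalent_cost(net):>10.2f}")

print()
print("cofactor interconversion values:")
print("  NADPH regenerated from NADH:",
      pc.atp_equivalent_cost({"NADPH": -1, "NADP": 1, "NADH": 1, "NAD": -1}), "ATP")
print("  quinol electron pair to NADPH:",
      pc.atp_equivalent_cost({"UQH2": 1, "UQ": -1, "NADPH": -1, "NADP": 1}), "ATP")

# The ATP column reproduces the published integers: 9 per C3 for the CBB
# cycle (15 via the C4 malic-enzyme shuttle, 12 with pyruvate carboxylase,
# 7 for the phosphatase-less variant), 3 per acetyl-CoA for the rCCC and
# 4 for the thaumarchaeal 3-HP/4-HB cycle.  The ATP-equivalent column adds
# the respiratory value of the redox cofactors each pathway consumes.
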