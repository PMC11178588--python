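"""Decay-chain constants and ²¹³Bi ingrowth after sample collection.

Prints the effective decay constants of the ²²⁵Ac chain, the secular-
equilibrium ²¹³Bi/²²⁵Ac ratio, and the time needed to reach equilibrium —
the quantities that control how long a urine aliquot must be counted.
"""

import numpy as np

from acdose.chain import (
    bateman_bi_activity,
    default_chain,
    equilibrium_ratio,
    time_to_equilibrium,
)

chain = default_chain()
for name in ("Ac-225", "Fr-221", "Bi-213"):
    nuc = chain[name]
    print(f"{name}: T1/2 = {nuc.half_life:8.4f} h, lambda = {nuc.decay_constant:.5f} /h")

print(f"\nsecular-equilibrium Bi-213/Ac-225 activity ratio: {equilibrium_ratio(chain):.4f}")
print(f"time to reach equilibrium (0.3% residual transient): {time_to_equilibrium(0.003):.1f} h")

# a urine sample containing 100 Bq Ac-225 and 90 Bq Bi-213 at collection
print("\nBi-213 activity after collection (A_Ac0=100 Bq, A_Bi0=90 Bq):")
for t in np.array([0.0, 1.0, 3.0, 6.0]):
    print(f"  t = {t:3.0f} h: {bateman_bi_activity(t, 100.0, 90.0, chain):7.2f} Bq")
# the curve dips as the initial Bi-213 decays, then tracks the Ac-225 parent
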