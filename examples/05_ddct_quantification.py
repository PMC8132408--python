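"""ΔΔCt relative quantification of qPCR measurements.

Builds a small Ct table (two reference genes, one target, four
developmental-stage samples) and computes comparative-CT relative
quantities: ΔCt = Ct_target − mean(Ct_references),
ΔΔCt = ΔCt_sample − ΔCt_calibrator, quantity = 2^(−ΔΔCt).
"""

import pandas as pd

from testisscreen import CtTable, ddct_quantity

ct = pd.DataFrame(
    {
        "rpl6": [18.2, 18.0, 18.6, 18.4],
        "rpl7": [19.1, 18.9, 19.5, 19.3],
        "tektin1": [24.6, 23.4, 22.9, 25.6],
    },
    index=["white", "red_eye", "bicolor", "black"],
)
table = CtTable(
    ct=ct, reference_genes=("rpl6", "rpl7"), calibrator_sample="white"
)

quantities = ddct_quantity(table)
print("relative quantity of tektin1 (white stage = 1):")
for sample, q in quantities["tektin1"].items():
    print(f"  {sample:>8}: {q:6.2f}")
# Values above 1 mean more transcript than in the calibrator stage after
# normalizing to the two ribosomal-protein reference genes; one qPCR
# cycle corresponds to a factor of 2.
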