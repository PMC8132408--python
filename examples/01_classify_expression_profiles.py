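"""Classify tissue-expression profiles into relative categories.

Builds a tiny ordinal gene × tissue table and classifies each gene with
respect to the testis: exclusive (expressed essentially only there),
predominant (strictly highest there), ubiquitous, or not expressed.
"""

import pandas as pd

from testisscreen import (
    AbsoluteLevel,
    ClassificationRule,
    ExpressionTable,
    classify_table,
)

profiles = pd.DataFrame(
    {
        "testis": [5, 4, 3, 0, 6],
        "accessory_gland": [3, 0, 0, 2, 0],
        "imaginal_disc": [0, 0, 0, 0, 0],
        "head": [0, 2, 5, 4, 6],
        "gut": [0, 1, 1, 1, 2],
    },
    index=["bol-like", "klhl10-like", "housekeeping-a", "silent-in-testis",
           "tie-case"],
)
table = ExpressionTable(species="fly", values=profiles, dialect="ordinal")

rule = ClassificationRule()  # testis focal; accessory gland + disc tolerated
categories = classify_table(table, rule)

print("relative categories (testis focal tissue):")
for gene, category in categories.items():
    level = AbsoluteLevel(int(profiles.loc[gene, "testis"]))
    print(f"  {gene:>18}: {category:<13} (testis level: "
          f"{level.name.lower().replace('_', ' ')})")

# A gene tied with another tissue is NOT predominant: predominance
# requires strictly higher testicular expression, so "tie-case" above is
# classified ubiquitous.
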