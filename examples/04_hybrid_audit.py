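"""Audit hybrid floral colours against their progenitors.

A hybrid's colour category is *expected* if it matches at least one
progenitor and *unexpected* (transgressive, for synthetic hybrids) if it
differs from both. Chlorophyll follows a dominance rule: expected present
whenever at least one progenitor carries it. The example recomputes every
verdict of the published Nicotiana polyploid/homoploid audit from its raw
category labels and summarises the outcome.
"""

import floravision as fv
from floravision.hybrids import reference_verdicts

table = reference_verdicts()
agreement = (table["verdict"] == "unexpected") == table["published_unexpected"]
print(f"published verdicts reproduced: {agreement.sum()}/{len(table)}")

print("\nunexpected phenotypes per character:")
for character, block in table.groupby("character"):
    n_unexpected = (block["verdict"] == "unexpected").sum()
    print(f"  {character:12s} {n_unexpected:2d} of {len(block)}")

print("\ntransgressive examples (unexpected in a perceptual space):")
odd = table[(table["verdict"] == "unexpected") & (table["character"] != "chlorophyll")]
print(odd[["species", "character", "observed", "expected"]].head(8).to_string(index=False))
# Chlorophyll losses are the commonest unexpected outcome: over half the
# polyploids lack petal chlorophyll although a progenitor carries it.
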