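"""Score gene sets per sample with single-sample GSEA.

Builds a tiny five-gene matrix, scores two sets, and prints the enrichment
scores: a positive ES means the set's genes sit near the top of that
sample's expression ranking, a negative ES near the bottom.
"""

import ferrocup as fc

expr = fc.ExpressionMatrix(
    [[9.1, 4.2], [8.3, 5.0], [6.7, 8.9], [4.1, 8.1], [2.2, 7.5]],
    ["HMOX1", "LCN2", "CYP1A1", "HMGCS2", "MTTP"],
    ["treated", "control"],
)
sets = [
    fc.GeneSet("iron_handlers", frozenset({"HMOX1", "LCN2"})),
    fc.GeneSet("lipid_transport", frozenset({"HMGCS2", "MTTP"})),
]
table = fc.ssgsea_scores(expr, sets, alpha=0.25)
print(table.to_string(index=False))
print(
    "\nThe iron-handling set tops the treated sample's ranking (ES > 0) and "
    "sinks in the control (ES < 0); the lipid set mirrors that."
)
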