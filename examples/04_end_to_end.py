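"""The full experiment: simulate, index, modify, align, evaluate.

Simulates a 100 kb genome with repeat families, a donor carrying 500
SNVs + 50 short indels, and 30x of 150 bp reads; aligns every read with
the plain and the variant-modified index and scores placements against
the simulation truth, stratified by the variants each read overlaps.
Takes ~half a minute.
"""

from varmin.pipeline import run_standard_experiment

result = run_standard_experiment(seed=7)

for label in ("plain", "modified"):
    print(f"== {label} index ==")
    print(result[label].summary())
    print()

plain, modified = result["plain"], result["modified"]
var_plain = plain.strata["snv"]["correct"] + plain.strata["indel"]["correct"]
var_mod = modified.strata["snv"]["correct"] + modified.strata["indel"]["correct"]
print(f"variant minimizers added:            {result['modify_report'].minimizers_added}")
print(f"adjusted occurrence filter:          n={result['adjusted_filter_n']}")
print(f"correct variant-overlapping reads:   {var_plain} -> {var_mod} "
      f"(+{var_mod - var_plain})")
print(f"multi-mapped reads:                  {plain.multimapped} -> {modified.multimapped}")
print("-> the modified index rescues variant reads in repetitive context and")
print("   reduces multi-mapping, leaving variant-free reads untouched")
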