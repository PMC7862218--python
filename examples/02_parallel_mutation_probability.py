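"""How unlikely is it that all eight evolved cheaters hit fusion genes?

Eight independently evolved lines each accumulated ~15 mutations, and in
every line the cheater carried a mutation in one of the ~75 known
hyphal-fusion genes (of ~10,000 protein-coding genes). The exact
binomial test asks how probable eight class hits are under random
mutation placement.
"""

from cheatkit.parallelism import exact_binomial_pvalue, parallel_fusion_test

p = parallel_fusion_test(
    k_lines_hit=8, n_lines=8, mut_per_line=15, class_genes=75, total_genes=10000
)
print(f"P(8 fusion-gene hits | 120 draws, p = 75/10000) = {p:.4g}")

p_complement = exact_binomial_pvalue(8, 120, (10000 - 75) / 10000)
print(f"Complementary construction (p = 9925/10000):      {p_complement:.4g}")

print(
    "\nA p-value around 4e-06 rules out chance placement: convergent "
    "loss of fusion genes is driven by selection for cheating."
)
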