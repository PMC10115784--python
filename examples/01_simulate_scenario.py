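"""Simulate a reticulate allopolyploid species trio with known truth.

Builds the default scenario — a diploid outgroup, four diverged progenitor
subgenomes (A, B, C, D), two allotetraploids (AC, BD) and an allooctoploid
(AC x BD) — and prints what the simulator planted.
"""
from polyploidkit import simulate

spec = simulate.reticulate_scenario(
    n_chromosomes_per_subgenome=2, chrom_length=120_000, n_gene_families=30, seed=1
)
result = simulate.simulate_scenario(spec)

for genome, seqs in result.genomes.items():
    total = sum(len(s) for s in seqs.values())
    print(f"{genome}: {len(seqs)} chromosomes, {total:,} bp")

n_anchor = sum(1 for t in result.truth.genes if t["kind"] == "anchor")
print(f"planted gene copies: {n_anchor} (1:2:4 anchor families x 7 copies)")
print(f"planted LTR elements: {len(result.truth.ltrs)}")
print("true copy split ages (MY):")
for pair in [
    (("tetraploid", "A"), ("octoploid", "A")),
    (("octoploid", "A"), ("octoploid", "B")),
    (("octoploid", "D"), ("outgroup", "outgroup")),
]:
    print(" ", pair, "->", result.truth.true_divergence(*pair))
# The split ages drive sequence divergence under a Jukes-Cantor clock, so
# every downstream estimate (trees, Ks, LTR ages) has a known right answer.
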