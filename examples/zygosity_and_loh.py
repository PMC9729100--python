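"""Tabulate biallelic outcomes across single cells and quantify LOH.

Uses a genotype table in which 90 cells carry the variant knock-in on one
allele; the conditional distribution of the other allele shows the built-in
loss of heterozygosity: most second alleles are disrupted, so recessive
loss-of-function variants become phenotypically visible.
"""

from crisprselect import AlleleCategory, SingleCellGenotype, loh_assessment, tabulate_zygosity

V, F, I, W = (AlleleCategory.VARIANT_KI, AlleleCategory.FRAMESHIFT_INDEL,
              AlleleCategory.INFRAME_INDEL, AlleleCategory.WT)

cells = (
    [SingleCellGenotype(f"c{i}", V, F) for i in range(59)]
    + [SingleCellGenotype(f"h{i}", V, V) for i in range(10)]
    + [SingleCellGenotype(f"i{i}", V, I) for i in range(3)]
    + [SingleCellGenotype(f"w{i}", V, W) for i in range(18)]
    + [SingleCellGenotype(f"x{i}", W, W) for i in range(300)]
)

table = tabulate_zygosity(cells)
loh = loh_assessment(table)

print(f"cells with a variant knock-in allele: {table.cells_with(V)}")
print("second-allele distribution among them:")
for cat, frac in sorted(table.conditional(V).items(), key=lambda kv: -kv[1]):
    print(f"  {cat.value:<18}{frac:6.1%}")
print(f"\nbuilt-in LOH fraction (disruptive second allele): {loh.fraction:.1%}")
print("i.e. this share of knock-in cells has lost the remaining intact copy,")
print("so a recessive loss-of-function variant can show a selection phenotype.")
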