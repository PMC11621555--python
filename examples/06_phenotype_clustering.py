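"""Cluster strains by their swimming phenotypes (Ward linkage + k-means).

Uses the built-in synthetic strain-by-phenotype table: columns are
z-scored, hierarchically clustered with Ward linkage, and labeled with
k-means on the same standardized matrix.
"""

from chemolane.datasets import synthetic_phenotype_table
from chemolane.pipeline import PhenotypeTable, cluster_phenotypes

table = synthetic_phenotype_table()
print(table.round(3), "\n")

res = cluster_phenotypes(PhenotypeTable(table), k=3)
for row, ward, km in zip(res.row_names, res.ward_labels, res.kmeans_labels):
    print(f"{row:10s} ward cluster {ward}  k-means cluster {km}")

print()
print("Wild-type-like strains group together; chemotaxis-deficient strains")
print("with intact motility form their own cluster; the paralyzed strain is")
print("an outlier on every axis.")
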