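"""Gene-set analyses of screen hits.

Hypergeometric over-representation of a planted gene set among significant
genes, preranked GSEA on the Rs-ranked gene list, and a high- vs low-ROR
group comparison of per-sample set-activity scores.
"""

import warnings

import pandas as pd

from irsplice.enrichment import (
    group_compare, hypergeom_overlap, preranked_gsea, sample_set_score,
)
from irsplice.pharmacovigilance import compute_ror, filter_cancer_types, split_high_low
from irsplice.pipeline import run_screen
from irsplice.synthetic import SimConfig, simulate_study

warnings.filterwarnings("ignore")
study = simulate_study(SimConfig(seed=7))
res = run_screen(study)

gene_rows = res[res["class"] == "gene_expr"]
hits = {f.split(":")[1] for f in gene_rows.index[gene_rows["selected"]]}
universe = [f.split(":")[1] for f in gene_rows.index]
category = [g for g in study.gene_sets.sets["planted_enriched"] if g in set(universe)]
enr = hypergeom_overlap(hits, category, universe)
print(f"planted set overlap {enr.n_overlap}/{len(category)}: p = {enr.p_value:.3g}")
# small p: hit genes are concentrated in the planted-enriched set.

ranked = pd.Series({f.split(":")[1]: r for f, r in gene_rows["rs"].items()})
gsea = preranked_gsea(ranked, category, n_perm=500, seed=0, set_name="planted")
print(f"GSEA: ES = {gsea.statistic:.3f}, NES = {gsea.nes:.2f}, p = {gsea.p_value:.3g}")

records = filter_cancer_types([compute_ror(t) for t in study.reports])
groups = pd.Series(split_high_low(records))
scores = sample_set_score(study.expr_gene, category)
per_type = scores.groupby(study.sample_map).median()
stat, p = group_compare(per_type, groups)
print(f"set activity, high vs low ROR types: rank-sum p = {p:.3g}")
# the planted set is mostly positive-direction genes, so high-ROR types
# show higher set activity.
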