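"""From PSI/TPM matrices to per-cancer-type splicing descriptors.

Applies the event and abundance filters, computes splicing load per sample,
and assembles the full cancer-type x feature descriptor table.
"""

from irsplice.descriptors import filter_as_events, splicing_load
from irsplice.pipeline import build_descriptor_table
from irsplice.synthetic import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=7))

psi = filter_as_events(study.psi)  # >10-sample detection, 0.05/0.95 masking
print(f"events kept: {psi.psi.shape[0]} of {study.psi.psi.shape[0]}")

load = splicing_load(psi)
s = load.index[0]
print(f"sample {s}: total load {load.loc[s, 'total']} "
      f"(= sum of 5 mode counts = sum of 4 PSI-category counts)")

table = build_descriptor_table(
    study.psi, study.expr_gene, study.expr_isoform, study.expr_sf,
    study.sample_map, study.neojunction_counts, study.autoantigens,
    study.covariates,
)
print(f"descriptor table: {len(table.cancer_types)} cancer types x "
      f"{len(table.features)} features")
print(table.classes.value_counts().to_string())
# Each row is one cancer type; the columns span splicing-factor, gene and
# isoform expression medians, loads, frequencies and external covariates.
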