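"""Generate a synthetic pan-cancer study with planted irAE signal.

Builds 19 cancer-type cohorts (PSI, TPM, adverse-event reports, covariates)
in which a known 10% of features have a monotone link to the latent log
reporting odds ratio, then prints what was planted.
"""

from irsplice.synthetic import SimConfig, simulate_study

config = SimConfig(seed=42)
study = simulate_study(config)

print(f"cancer types : {len(study.truth.true_log_ror)}")
print(f"samples      : {len(study.sample_map)}")
print(f"PSI events   : {study.psi.psi.shape[0]}")
print(f"genes/isoforms/factors: {study.expr_gene.tpm.shape[0]}/"
      f"{study.expr_isoform.tpm.shape[0]}/{study.expr_sf.tpm.shape[0]}")
print(f"planted features: {len(study.truth.planted_features)}")
print("true log-ROR range:",
      f"{study.truth.true_log_ror.min():.2f} .. {study.truth.true_log_ror.max():.2f}")
# Each planted feature's cancer-type-level location shifts with the true
# log-ROR; everything else is exchangeable across types (pure null).
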