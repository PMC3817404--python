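# Small end-to-end pipeline config: 200-gene screen family with planted
# essentials (5%), SSL genes (5% per query) and not-expressed genes (10%).
simulate:
  n_genes: 200
  n_queries: 1
  seed: 11
alpha: 0.05
B: 200
n_perm: 1999
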