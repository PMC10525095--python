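# Canonical 18-configuration grid of downscaled base 3D vision transformers.
# Columns: P = patch edge, d = MLP hidden size, L = encoder layers,
# D = embedding size, k = attention heads.  D always equals P^2*C/k (C=1).
- {config_id: 1,  P: 16, d: 2048, L: 4, D: 64, k: 4}
- {config_id: 2,  P: 16, d: 2048, L: 4, D: 32, k: 8}
- {config_id: 3,  P: 16, d: 2048, L: 4, D: 16, k: 16}
- {config_id: 4,  P: 16, d: 2048, L: 6, D: 64, k: 4}
- {config_id: 5,  P: 16, d: 2048, L: 6, D: 32, k: 8}
- {config_id: 6,  P: 16, d: 2048, L: 6, D: 16, k: 16}
- {config_id: 7,  P: 16, d: 2048, L: 8, D: 64, k: 4}
- {config_id: 8,  P: 16, d: 2048, L: 8, D: 32, k: 8}
- {config_id: 9,  P: 16, d: 2048, L: 8, D: 16, k: 16}
- {config_id: 10, P: 16, d: 3072, L: 4, D: 64, k: 4}
- {config_id: 11, P: 16, d: 3072, L: 4, D: 32, k: 8}
- {config_id: 12, P: 16, d: 3072, L: 4, D: 16, k: 16}
- {config_id: 13, P: 16, d: 3072, L: 6, D: 64, k: 4}
- {config_id: 14, P: 16, d: 3072, L: 6, D: 32, k: 8}
- {config_id: 15, P: 16, d: 3072, L: 6, D: 16, k: 16}
- {config_id: 16, P: 16, d: 3072, L: 8, D: 64, k: 4}
- {config_id: 17, P: 16, d: 3072, L: 8, D: 32, k: 8}
- {config_id: 18, P: 16, d: 3072, L: 8, D: 16, k: 16}
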