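"""Disease-wise hold-out: rank candidate miRNAs for an unseen disease.

Removes every association of one disease, retrains from scratch, and ranks
all miRNAs for it. With the planted-block ground truth we can check how
many of the top candidates come from the disease's own block.
"""

import numpy as np

from mvhagcn.model import ModelConfig
from mvhagcn.synthetic import SyntheticConfig, generate_bundle, planted_truth
from mvhagcn.train_eval import TrainConfig, disease_holdout_rank

cfg = SyntheticConfig(
    n_mirna=45, n_disease=15, n_blocks=3,
    within_block_assoc_prob=0.4, background_assoc_prob=0.02, seed=21,
)
bundle = generate_bundle(cfg)
labels = planted_truth(cfg)
mirna_blocks = labels[: cfg.n_mirna]
disease_blocks = labels[cfg.n_mirna :]

target = bundle.index.disease_ids[0]
block = disease_blocks[0]
ranked = disease_holdout_rank(
    bundle, target, 15,
    ModelConfig(embed_dim=64, n_heads=2, mlp_hidden=64, seed=9),
    TrainConfig(epochs=400),
    seed=9,
)

pos = {m: i for i, m in enumerate(bundle.index.mirna_ids)}
print(f"top 15 candidates for held-out disease {target} (block {block}):")
in_block = 0
for rank, (mirna, score) in enumerate(ranked, 1):
    b = mirna_blocks[pos[mirna]]
    in_block += b == block
    print(f"  {rank:>2}. {mirna}  score {score:.3f}  block {b}"
          f"{'  <-- matching block' if b == block else ''}")
n_block = int((mirna_blocks == block).sum())
print(f"\n{in_block}/15 candidates are from the matching block "
      f"(a uniform draw would give ~{15 * n_block / cfg.n_mirna:.1f}).")
print("The held-out disease is scored purely through its similarity edges; "
      "enrichment of matching-block miRNAs shows the protocol works.")
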