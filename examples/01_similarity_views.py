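"""Compute the eight similarity views on a small synthetic bundle.

Builds a 30-miRNA x 20-disease bundle, derives every miRNA and disease
similarity view, and prints each view's mean within-block vs between-block
similarity: a view is informative when the within-block mean is higher.
"""

import numpy as np

from mvhagcn.synthetic import SyntheticConfig, generate_bundle, planted_truth
from mvhagcn.train_eval import _ordered_views, compute_static_views

cfg = SyntheticConfig(n_mirna=30, n_disease=20, seed=7)
bundle = generate_bundle(cfg)
labels = planted_truth(cfg)
mirna_blocks = labels[: cfg.n_mirna]
disease_blocks = labels[cfg.n_mirna :]

static = compute_static_views(bundle)
mirna_views, disease_views = _ordered_views(static, bundle.associations)

print(f"{'view':<18}{'within-block':>14}{'between-block':>15}")
for views, blocks in ((mirna_views, mirna_blocks), (disease_views, disease_blocks)):
    same = blocks[:, None] == blocks[None, :]
    off_diag = ~np.eye(len(blocks), dtype=bool)
    for v in views:
        within = v.values[same & off_diag].mean()
        between = v.values[~same].mean()
        print(f"{v.view_name:<18}{within:>14.3f}{between:>15.3f}")

print(
    "\nEvery view separates the planted blocks to a different degree; the"
    "\nmodel's adaptive fusion learns how much to trust each one."
)
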