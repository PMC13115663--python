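"""Training and evaluation protocol.

Implements leakage-aware k-fold cross-validation over the known
associations: test-fold positives are removed from the association matrix
before the GIP kernels, the heterogeneous adjacency and the RWR features
are computed, so no test link can influence any training-time quantity.
Negative pairs are sampled 1:1 from unknown pairs, disjoint across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._tensor import Adam, Tensor, concat
from .data_io import AssociationMatrix, ContractError, InputBundle, SimilarityMatrix
from .model import ModelConfig, bce_loss, embed, init_params, score_pairs
from .network import (
    DISEASE_VIEW_ORDER,
    MIRNA_VIEW_ORDER,
    FusionWeights,
    RwrConfig,
    build_adjacency,
    fuse_views,
    rwr_features,
)
from .similarity import (
    GipConfig,
    SemanticConfig,
    disease_semantic_similarity,
    family_similarity,
    gip_kernel,
    profile_edit_similarity,
    sequence_similarity,
)

__all__ = [
    "TrainConfig",
    "Fold",
    "FoldPlan",
    "Metrics",
    "MetricReport",
    "make_folds",
    "mask_test_associations",
    "evaluate",
    "compute_static_views",
    "train_model",
    "TrainedModel",
    "run_cv",
    "run_ablation",
    "disease_holdout_rank",
    "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = {
    "none": (),
    "w/o AT": ("attention",),
    "w/o EGCN": ("egcn",),
    "w/o MS": ("multisource",),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings: Adam with L2-coupled weight decay, full-batch
    (one step per epoch over all training pairs)."""

    lr: float = 5e-4
    weight_decay: float = 5e-4
    epochs: int = 2000
    fusion_lr: float = 0.05
    rwr: RwrConfig = field(default_factory=RwrConfig)


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class Fold:
    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    k: int
    seed: int


def make_folds(A: AssociationMatrix, k: int, seed: int) -> FoldPlan:
    """Shuffle the positives with the seed and split as evenly as possible;
    sample an equal number of negatives uniformly without replacement from
    the zero entries, disjoint across folds."""
    if k < 2:
        raise ContractError("k must be at least 2")
    positives = np.argwhere(A.values == 1)
    if len(positives) < k:
        raise ContractError(f"need at least {k} positives for {k} folds")
    zeros = np.argwhere(A.values == 0)
    if len(zeros) < len(positives):
        raise ContractError("not enough zero entries for 1:1 negative sampling")
    rng = np.random.default_rng(seed)
    positives = positives[rng.permutation(len(positives))]
    neg_idx = rng.choice(len(zeros), size=len(positives), replace=False)
    negatives = zeros[neg_idx]
    pos_chunks = np.array_split(positives, k)
    neg_chunks = np.array_split(negatives, k)
    folds = []
    for i in range(k):
        train_pos = np.concatenate([c for j, c in enumerate(pos_chunks) if j != i])
        train_neg = np.concatenate([c for j, c in enumerate(neg_chunks) if j != i])
        folds.append(
            Fold(
                train_pos=train_pos,
                test_pos=pos_chunks[i],
                train_neg=train_neg,
                test_neg=neg_chunks[i],
            )
        )
    return FoldPlan(tuple(folds), k, seed)


def mask_test_associations(A: AssociationMatrix, fold: Fold) -> AssociationMatrix:
    """Zero the test-fold positives; the masked matrix feeds GIP, the
    adjacency and RWR for that fold."""
    values = A.values.copy()
    values[fold.test_pos[:, 0], fold.test_pos[:, 1]] = 0.0
    return AssociationMatrix(values, A.index)


def audit_fold(A: AssociationMatrix, fold: Fold, masked: AssociationMatrix) -> None:
    """Assert the leakage-control invariants for one fold."""
    assert (masked.values[fold.test_pos[:, 0], fold.test_pos[:, 1]] == 0).all()
    train_set = {tuple(p) for p in fold.train_pos} | {tuple(p) for p in fold.train_neg}
    test_set = {tuple(p) for p in fold.test_pos} | {tuple(p) for p in fold.test_neg}
    assert not train_set & test_set, "a pair appears in both train and test"
    assert masked.values.sum() == len(fold.train_pos)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class Metrics:
    auc: float
    aupr: float
    acc: float


@dataclass
class MetricReport:
    """Per-fold metrics with mean and standard deviation, plus the per-fold
    training logs (per-epoch loss and fusion-weight trajectories)."""

    fold_metrics: list[Metrics]
    loss_histories: list[np.ndarray] = field(default_factory=list)
    weight_histories: list[np.ndarray] = field(default_factory=list)

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(m, attr) for m in self.fold_metrics])
        return float(vals.mean()), float(vals.std())

    @property
    def auc(self) -> float:
        return self._agg("auc")[0]

    @property
    def aupr(self) -> float:
        return self._agg("aupr")[0]

    @property
    def acc(self) -> float:
        return self._agg("acc")[0]

    def summary(self) -> dict[str, float]:
        out = {}
        for attr in ("auc", "aupr", "acc"):
            mean, sd = self._agg(attr)
            out[attr] = mean
            out[f"{attr}_sd"] = sd
        return out


def evaluate(scores: np.ndarray, labels: np.ndarray) -> Metrics:
    """AUC (rank statistic, average ties), AUPR (precision-recall step
    integration) and accuracy at threshold 0.5."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ContractError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ContractError("evaluation requires both classes present")
    return Metrics(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        acc=float(((scores >= 0.5) == (labels == 1)).mean()),
    )


# ---------------------------------------------------------------------------
# views


def compute_static_views(
    bundle: InputBundle, semantic_config: SemanticConfig | None = None
) -> dict[str, dict[str, SimilarityMatrix]]:
    """All similarity views that do not depend on the association matrix
    (everything except the two GIP kernels)."""
    idx = bundle.index
    seqs = {m: bundle.sequences[m] for m in idx.mirna_ids}
    return {
        "mirna": {
            "functional": bundle.functional,
            "lncrna": profile_edit_similarity(
                bundle.mirna_lnc, idx.mirna_ids, "lncrna_mirna"
            ),
            "sequence": sequence_similarity(seqs),
            "family": family_similarity(bundle.families, idx.mirna_ids),
        },
        "disease": {
            "semantic": disease_semantic_similarity(bundle.dag_set, semantic_config),
            "lncrna": profile_edit_similarity(
                bundle.disease_lnc, idx.disease_ids, "lncrna_disease"
            ),
        },
    }


def _ordered_views(
    static: dict[str, dict[str, SimilarityMatrix]],
    A: AssociationMatrix,
    gip_config: GipConfig | None = None,
) -> tuple[list[SimilarityMatrix], list[SimilarityMatrix]]:
    gm = gip_kernel(A, "mirna", gip_config)
    gd = gip_kernel(A, "disease", gip_config)
    mirna = [gm if name == "gip" else static["mirna"][name] for name in MIRNA_VIEW_ORDER]
    disease = [
        gd if name == "gip" else static["disease"][name] for name in DISEASE_VIEW_ORDER
    ]
    return mirna, disease


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained model plus the constants needed to score new pairs."""

    params: dict[str, Tensor]
    fusion: FusionWeights
    model_config: ModelConfig
    n_mirna: int
    _Sm: list[Tensor]
    _Sd: list[Tensor]
    _A_block: Tensor
    _X: Tensor
    loss_history: np.ndarray
    weight_history: np.ndarray

    def _adjacency(self) -> Tensor:
        alpha = self.fusion.alpha_raw.softmax()
        beta = self.fusion.beta_raw.softmax()
        if len(self._Sm) == 1:
            Mm, Md = self._Sm[0], self._Sd[0]
        else:
            Mm = _weighted_sum(self._Sm, alpha)
            Md = _weighted_sum(self._Sd, beta)
        top = concat([Mm, self._A_block], axis=1)
        bottom = concat([self._A_block.T, Md], axis=1)
        M = concat([top, bottom], axis=0)
        if self.model_config.normalize_adjacency:
            # symmetric normalization with degrees treated as constants
            deg = M.data.sum(axis=1)
            deg[deg == 0] = 1.0
            inv = (1.0 / np.sqrt(deg)).astype(M.dtype)
            M = M * Tensor(np.outer(inv, inv))
        return M

    def score(self, pairs: np.ndarray) -> np.ndarray:
        gamma = self.fusion.gamma_raw.softmax()
        H = embed(self._adjacency(), self._X, self.params, gamma, self.model_config)
        return score_pairs(H, pairs, self.params, self.n_mirna).data

    def score_matrix(self) -> np.ndarray:
        nd = self._A_block.shape[1]
        pairs = np.array(
            [(i, j) for i in range(self.n_mirna) for j in range(nd)], dtype=np.intp
        )
        return self.score(pairs).reshape(self.n_mirna, nd)


def _weighted_sum(mats: list[Tensor], weights: Tensor) -> Tensor:
    out = mats[0] * weights.take_rows(np.array([0])).reshape(1, 1)
    for i in range(1, len(mats)):
        out = out + mats[i] * weights.take_rows(np.array([i])).reshape(1, 1)
    return out


def train_model(
    mirna_views: list[SimilarityMatrix],
    disease_views: list[SimilarityMatrix],
    A_train: AssociationMatrix,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
) -> TrainedModel:
    """Train the model full-batch on the given pairs.

    RWR features are computed once from the uniform-weight fused adjacency
    and held constant; the adjacency itself is rebuilt from the current
    (softmax-mapped) fusion weights at every epoch so that gradients flow
    through the view fusion.
    """
    tc = train_config or TrainConfig()
    dt = model_config.np_dtype
    nm = A_train.index.n_mirna

    if "multisource" in model_config.ablate:
        mirna_views = [v for v in mirna_views if v.view_name.startswith("gip")]
        disease_views = [v for v in disease_views if v.view_name.startswith("gip")]

    # constant RWR features from the uniform-weight fusion
    w_m = np.full(len(mirna_views), 1.0 / len(mirna_views))
    w_d = np.full(len(disease_views), 1.0 / len(disease_views))
    Mm0 = fuse_views(mirna_views, w_m)
    Md0 = fuse_views(disease_views, w_d)
    het0 = build_adjacency(Mm0, Md0, A_train)
    X0 = rwr_features(het0, tc.rwr)
    # precondition: drop the restart self-mass (a pure node-identity channel
    # that invites memorization) and rescale the diffusion profiles to O(1)
    np.fill_diagonal(X0, 0.0)
    X = Tensor((X0 * X0.shape[0]).astype(dt))

    fusion = FusionWeights(
        alpha_raw=Tensor(np.zeros(len(mirna_views), dtype=dt), requires_grad=True),
        beta_raw=Tensor(np.zeros(len(disease_views), dtype=dt), requires_grad=True),
        gamma_raw=Tensor(np.zeros(2, dtype=dt), requires_grad=True),
    )
    params = init_params(model_config, in_dim=X.shape[1])
    model = TrainedModel(
        params=params,
        fusion=fusion,
        model_config=model_config,
        n_mirna=nm,
        _Sm=[Tensor(v.values.astype(dt)) for v in mirna_views],
        _Sd=[Tensor(v.values.astype(dt)) for v in disease_views],
        _A_block=Tensor(A_train.values.astype(dt)),
        _X=X,
        loss_history=np.zeros(tc.epochs),
        weight_history=np.zeros((tc.epochs, len(mirna_views) + len(disease_views) + 2)),
    )

    # the few fusion weights see gradients averaged over the whole adjacency
    # and need a larger step to adapt within a practical epoch budget
    opt = Adam(list(params.values()), lr=tc.lr, weight_decay=tc.weight_decay)
    opt_fusion = Adam(fusion.parameters(), lr=tc.fusion_lr)
    pairs = np.asarray(train_pairs, dtype=np.intp)
    labels = np.asarray(train_labels, dtype=np.float64)

    for epoch in range(tc.epochs):
        # cosine-annealed fusion step: most view adaptation happens early,
        # and the mixing weights genuinely converge by the final epochs
        opt_fusion.lr = tc.fusion_lr * 0.5 * (
            1.0 + np.cos(np.pi * epoch / max(tc.epochs - 1, 1))
        )
        opt.zero_grad()
        opt_fusion.zero_grad()
        gamma = fusion.gamma_raw.softmax()
        M = model._adjacency()
        H = embed(M, X, params, gamma, model_config)
        scores = score_pairs(H, pairs, params, nm)
        loss = bce_loss(labels, scores)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training loss became non-finite at epoch {epoch}"
            )
        loss.backward()
        opt.step()
        opt_fusion.step()
        model.loss_history[epoch] = float(loss.data)
        model.weight_history[epoch] = np.concatenate(
            [fusion.alpha, fusion.beta, fusion.gamma]
        )
    return model


# ---------------------------------------------------------------------------
# protocols


def _pairs_and_labels(pos: np.ndarray, neg: np.ndarray):
    pairs = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return pairs, labels


def run_cv(
    bundle: InputBundle,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    static_views: dict | None = None,
    gip_config: GipConfig | None = None,
) -> MetricReport:
    """Leakage-aware k-fold cross-validation on the bundle's associations."""
    tc = train_config or TrainConfig()
    static = static_views or compute_static_views(bundle)
    plan = make_folds(bundle.associations, k, seed)
    report = MetricReport([])
    for fold_id, fold in enumerate(plan.folds):
        masked = mask_test_associations(bundle.associations, fold)
        audit_fold(bundle.associations, fold, masked)
        mirna_views, disease_views = _ordered_views(static, masked, gip_config)
        train_pairs, train_labels = _pairs_and_labels(fold.train_pos, fold.train_neg)
        fold_seed = int(
            np.random.SeedSequence([model_config.seed, fold_id]).generate_state(1)[0]
            % (2**31)
        )
        fold_cfg = replace(model_config, seed=fold_seed)
        model = train_model(
            mirna_views, disease_views, masked, train_pairs, train_labels, fold_cfg, tc
        )
        test_pairs, test_labels = _pairs_and_labels(fold.test_pos, fold.test_neg)
        scores = model.score(test_pairs)
        report.fold_metrics.append(evaluate(scores, test_labels))
        report.loss_histories.append(model.loss_history)
        report.weight_histories.append(model.weight_history)
    return report


def run_ablation(
    bundle: InputBundle,
    variant: str,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    static_views: dict | None = None,
) -> MetricReport:
    """Cross-validate one ablation variant: 'none', 'w/o AT' (no ECA and no
    self-attention), 'w/o EGCN' (plain graph convolutions), or 'w/o MS'
    (single GIP view per node type)."""
    if variant not in ABLATION_VARIANTS:
        raise ContractError(
            f"unknown variant {variant!r}; choose from {sorted(ABLATION_VARIANTS)}"
        )
    cfg = replace(model_config, ablate=ABLATION_VARIANTS[variant])
    return run_cv(bundle, cfg, train_config, k=k, seed=seed, static_views=static_views)


def disease_holdout_rank(
    bundle: InputBundle,
    disease_id: str,
    top_n: int,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    static_views: dict | None = None,
) -> list[tuple[str, float]]:
    """Disease-wise hold-out: remove every association of the target disease
    before any similarity or graph construction, retrain from scratch, and
    return the top_n candidate miRNAs for that disease by descending score
    (ties broken by lexicographically smaller miRNA id)."""
    idx = bundle.index
    if disease_id not in idx.disease_ids:
        raise ContractError(f"unknown disease {disease_id!r}")
    j = idx.disease_ids.index(disease_id)
    values = bundle.associations.values.copy()
    values[:, j] = 0.0
    if values.sum() == 0:
        raise ContractError("no positives remain after removing the target disease")
    masked = AssociationMatrix(values, idx)

    rng = np.random.default_rng(seed)
    pos = np.argwhere(masked.values == 1)
    zeros = np.argwhere(masked.values == 0)
    zeros = zeros[zeros[:, 1] != j]  # no training pair involves the target
    assert not (pos[:, 1] == j).any()
    neg = zeros[rng.choice(len(zeros), size=len(pos), replace=False)]
    train_pairs, train_labels = _pairs_and_labels(pos, neg)

    static = static_views or compute_static_views(bundle)
    mirna_views, disease_views = _ordered_views(static, masked)
    model = train_model(
        mirna_views, disease_views, masked, train_pairs, train_labels,
        model_config, train_config,
    )
    cand = np.array([(i, j) for i in range(idx.n_mirna)], dtype=np.intp)
    scores = model.score(cand)
    order = sorted(
        range(idx.n_mirna), key=lambda i: (-scores[i], idx.mirna_ids[i])
    )
    return [(idx.mirna_ids[i], float(scores[i])) for i in order[: min(top_n, idx.n_mirna)]]
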