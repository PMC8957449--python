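"""Training of the seven one-vs-rest breakpoint classifiers.

Labeled sites (candidate sites annotated with an SV type or NONE) are split
by cyclic 8:2 cross-validation; normalization statistics are fitted on the
training fold only.  For each SV type, sites of that type are positives and
every other site — other-type breakpoints plus NONE-labeled noise sites —
forms the negative pool, subsampled to a fixed negatives-per-positive
ratio.  Each classifier minimizes binary cross-entropy with Adam and early
stopping on an internal validation split carved from the training fold, so
no test-fold row ever influences weights or statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .features import (
    NormalizationStats,
    fit_normalization,
    normalize_matrix,
)
from .model import (
    ModelBundle,
    ModelConfig,
    SVType,
    SV_TYPES,
    build_model,
    build_windows,
    stats_fingerprint,
)

CV_BLOCKS = 5        # 8:2 train:test ratio -> five cyclic 20% test blocks


@dataclass
class LabeledSiteSet:
    """Candidate sites with raw (un-normalized) feature rows and labels.

    ``groups`` identifies the originating genome/replicate so that
    classification windows never mix rows across genomes.
    """

    matrix: np.ndarray       # (n, 12) raw ternary features
    sites: np.ndarray        # (n,) 0-based coordinates
    labels: np.ndarray       # (n,) SVType integer values (0 = NONE)
    groups: np.ndarray       # (n,) genome ids

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if not (self.sites.shape[0] == self.labels.shape[0] == self.groups.shape[0] == n):
            raise ValueError("length mismatch in LabeledSiteSet")

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @staticmethod
    def concatenate(parts: "list[LabeledSiteSet]") -> "LabeledSiteSet":
        return LabeledSiteSet(
            matrix=np.concatenate([p.matrix for p in parts]),
            sites=np.concatenate([p.sites for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            groups=np.concatenate([p.groups for p in parts]),
        )


def label_sites(
    sites: np.ndarray,
    truth_breakpoints: list[tuple[int, SVType]],
    tolerance: int = 5,
) -> np.ndarray:
    """Label each site with the type of the nearest truth breakpoint within
    ``tolerance`` bp (NONE otherwise)."""
    sites = np.asarray(sites, dtype=np.int64)
    labels = np.zeros(sites.shape[0], dtype=np.int64)
    if not truth_breakpoints:
        return labels
    bkps = sorted(truth_breakpoints)
    bp_pos = np.array([b[0] for b in bkps], dtype=np.int64)
    bp_type = np.array([int(b[1]) for b in bkps], dtype=np.int64)
    idx = np.searchsorted(bp_pos, sites)
    left = np.clip(idx - 1, 0, len(bp_pos) - 1)
    right = np.clip(idx, 0, len(bp_pos) - 1)
    d_left = np.abs(sites - bp_pos[left])
    d_right = np.abs(bp_pos[right] - sites)
    nearest = np.where(d_right < d_left, right, left)   # ties break left
    dist = np.minimum(d_left, d_right)
    labels = np.where(dist <= tolerance, bp_type[nearest], labels)
    return labels


@dataclass(frozen=True)
class TrainConfig:
    """Training-study conditions.

    ``n_groups`` is the number of labeled sites assembled for training (the
    desk-scale counterpart of the 50,000-group study design); sets larger
    than ``n_groups`` are subsampled, smaller sets are used as-is.
    """

    n_groups: int = 80000
    cv_ratio: tuple[int, int] = (8, 2)
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    negative_ratio: int = 4
    patience: int = 8
    val_fraction: float = 0.15
    all_folds: bool = False

    def __post_init__(self) -> None:
        if self.n_groups < 10:
            raise ValueError("n_groups must be >= 10")
        if (self.cv_ratio[0] + self.cv_ratio[1]) % self.cv_ratio[1] != 0:
            raise ValueError("cv_ratio must define an integer number of blocks")


def make_binary_labels(
    labels: np.ndarray,
    target: SVType,
    negative_ratio: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest dataset for one SV type.

    Positives are the sites labeled ``target``; negatives are drawn (seeded)
    from all other sites — other SV breakpoints and NONE-labeled noise sites
    alike — up to ``negative_ratio`` per positive.  When the pool is smaller
    than the quota, every non-target site is used.

    Returns (positive indices, negative indices).
    """
    if target is SVType.NONE:
        raise ValueError("target must be a concrete SV type")
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.asarray(labels)
    pos = np.nonzero(labels == int(target))[0]
    if pos.size == 0:
        raise ValueError(f"no positive sites for type {target.name}")
    pool = np.nonzero(labels != int(target))[0]
    quota = negative_ratio * pos.size
    if pool.size > quota:
        neg = np.sort(rng.choice(pool, size=quota, replace=False))
    else:
        neg = pool
    return pos, neg


def cyclic_cv_split(
    n: int,
    fold_index: int,
    seed: int,
    ratio: tuple[int, int] = (8, 2),
) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic cross-validation: a seeded shuffle partitioned into equal
    blocks; fold i's test set is block i, the rest train.

    With the 8:2 ratio this is a 5-fold rotation of the 20% test block.
    The five test sets are disjoint and cover all ``n`` indices.
    """
    n_blocks = (ratio[0] + ratio[1]) // ratio[1]
    if n < n_blocks:
        raise ValueError(f"dataset of size {n} is smaller than {n_blocks} blocks")
    if not (0 <= fold_index < n_blocks):
        raise ValueError(f"fold_index must be in 0..{n_blocks - 1}")
    perm = np.random.default_rng(seed).permutation(n)
    blocks = np.array_split(perm, n_blocks)
    test = np.sort(blocks[fold_index])
    train = np.sort(np.concatenate([b for i, b in enumerate(blocks) if i != fold_index]))
    return train, test


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    sens = tp / (tp + fn)
    return 2 * prec * sens / (prec + sens)


def fit_binary(
    net: nn.Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> dict:
    """Minibatch Adam training with early stopping on a validation split."""
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    opt = nn.Adam(net, lr=config.learning_rate)
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    bad = 0
    for epoch in range(config.epochs):
        order = rng.permutation(Xtr.shape[0])
        for lo in range(0, order.size, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            z = net.forward(Xtr[sel], train=True)
            loss, dz = nn.bce_with_logits(z, ytr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input features"
                )
            net.backward(dz)
            opt.step()
        zval = net.forward(Xval)
        val_loss, _ = nn.bce_with_logits(zval, yval)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad > config.patience:
                break
    net.set_weights(best_weights)
    return {"val_loss": float(best_loss), "best_epoch": int(best_epoch),
            "epochs_run": int(epoch + 1)}


def train_all(
    siteset: LabeledSiteSet,
    train_config: TrainConfig,
    model_config: ModelConfig,
) -> ModelBundle:
    """Fit the seven one-vs-rest classifiers on the fold-0 cyclic split.

    Every SV type must have at least one positive site.  Returns a bundle
    holding the classifiers, the normalization statistics (fitted on the
    training fold only), and a per-type held-out report.
    """
    n = len(siteset)
    if n < 10:
        raise ValueError("need at least 10 labeled sites")
    root = np.random.default_rng(train_config.seed)
    if n > train_config.n_groups:
        keep = np.sort(root.choice(n, size=train_config.n_groups, replace=False))
        siteset = LabeledSiteSet(
            matrix=siteset.matrix[keep], sites=siteset.sites[keep],
            labels=siteset.labels[keep], groups=siteset.groups[keep],
        )
        n = len(siteset)

    folds = range((train_config.cv_ratio[0] + train_config.cv_ratio[1])
                  // train_config.cv_ratio[1]) if train_config.all_folds else [0]
    report: dict = {"folds": {}, "n_sites": n}
    bundle: ModelBundle | None = None
    for fold in folds:
        tr_idx, te_idx = cyclic_cv_split(n, fold, train_config.seed,
                                         ratio=train_config.cv_ratio)
        stats = fit_normalization(siteset.matrix[tr_idx].astype(float))
        M = normalize_matrix(siteset.matrix, stats)
        windows = build_windows(M, model_config.window, groups=siteset.groups)
        fp = stats_fingerprint(stats)
        fold_report = {}
        models = {}
        for t in SV_TYPES:
            if not np.any(siteset.labels[tr_idx] == int(t)):
                raise ValueError(f"no positive sites for type {t.name}")
            t_rng = np.random.default_rng(
                np.random.SeedSequence([train_config.seed, fold, int(t)]))
            pos, neg = make_binary_labels(siteset.labels[tr_idx], t,
                                          train_config.negative_ratio, t_rng)
            sel = tr_idx[np.concatenate([pos, neg])]
            X = windows[sel]
            y = (siteset.labels[sel] == int(t)).astype(float)
            net = build_model(model_config,
                              seed=int(t_rng.integers(0, 2**31)))
            fit_info = fit_binary(net, X, y, train_config, t_rng)
            net.stats_fingerprint = fp
            # held-out evaluation on the untouched test fold
            y_te = siteset.labels[te_idx] == int(t)
            scores = net.predict_scores(windows[te_idx])
            pred = scores >= model_config.score_threshold
            acc = float(np.mean(pred == y_te)) if te_idx.size else 0.0
            fold_report[t.name] = {
                **fit_info,
                "n_pos_train": int(pos.size),
                "n_neg_train": int(neg.size),
                "heldout_accuracy": acc,
                "heldout_f1": _binary_f1(y_te, pred),
            }
            models[t] = net
        report["folds"][fold] = fold_report
        if fold == 0:
            bundle = ModelBundle(
                models=models, config=model_config, stats=stats,
                manifest={
                    "seed": train_config.seed,
                    "train_config": asdict(train_config),
                    "n_sites": n,
                    "fold": 0,
                    "stats_fingerprint": fp,
                },
            )
    assert bundle is not None
    bundle.manifest["report"] = report
    return bundle
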