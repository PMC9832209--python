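"""Joint training, cross-validated evaluation and biomarker ranking.

The full model — GSA stack, sliding-window recurrence, Bayesian region
selector and MLP head — is trained end-to-end with Adam on the summed
BCE + KL objective, full batch (the cohorts here are tens of subjects).
Evaluation uses stratified k-fold cross-validation with reshuffled folds
per repeat; selection probabilities and hard masks from every run are
pooled into a cumulative biomarker ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Tensor, use_dtype
from .encoder import (
    GSALayerParams,
    RecurrentUnitParams,
    SpatialEncodingTable,
    assemble_batch,
    encode_sequence_arrays,
    init_gsa_stack,
    init_recurrent_unit,
    init_spatial_table,
)
from .head import MLPParams, classify, init_mlp, readout, total_loss
from .netbuild import DynamicBrainNetwork, ROITimeSeries, build_network
from .selector import (
    Mask,
    SelectionState,
    apply_mask,
    expected_mask,
    hard_mask,
    sample_mask,
)

__all__ = [
    "TrainConfig",
    "ModelParams",
    "MetricsReport",
    "RunReport",
    "init_model",
    "forward",
    "train",
    "predict",
    "compute_metrics",
    "cross_validate",
    "rank_biomarkers",
    "build_networks",
]


@dataclass
class TrainConfig:
    """All knobs of the training/evaluation pipeline.

    The paper-fidelity profile uses 1000 epochs; 200 is the scaled-down
    default suited to desk-scale experiments.
    """

    lr: float = 0.001
    epochs: int = 200
    weight_decay: float = 0.01
    folds: int = 4
    repeats: int = 10
    seed: int = 0
    # model dims
    gsa_dims: tuple[int, ...] = (64, 64, 32)  # hidden dims after the input D
    d_k: int = 32
    window: int = 3
    mlp_hidden: int = 64
    # selector
    use_selector: bool = True
    r: float = 0.5
    s: float = 0.1
    kl_weight: float = 1.0
    # gates get their own Adam learning rate so selection probabilities can
    # traverse the (0, 1) range on the same timescale the encoder trains
    gate_lr: float = 0.05
    # network construction
    n_steps: int = 4
    knn: int = 10
    max_dist: int = 5
    # model input per region: "connectivity" (FC profile) or "signal" (raw window)
    feature_mode: str = "connectivity"
    # where the selection mask acts: "input" zeroes region rows of the model
    # input (true region selection); "embedding" masks the encoder output H
    mask_stage: str = "input"
    # ablations / options
    use_recurrence: bool = True
    class_weighting: bool = False
    # training numerics; float32 matches deep-learning practice and halves
    # memory traffic, float64 is available for diagnostics
    dtype: str = "float32"

    def validate(self) -> None:
        if self.lr < 0 or self.epochs < 1 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1 or self.window < 1:
            raise ValueError("repeats and window must be positive")


@dataclass
class ModelParams:
    stack: list[GSALayerParams]
    table: SpatialEncodingTable
    unit: RecurrentUnitParams
    selection: SelectionState | None
    mlp: MLPParams

    def all_tensors(self) -> list[Tensor]:
        ts: list[Tensor] = []
        for layer in self.stack:
            ts += [layer.W, layer.c]
        ts.append(self.table.s)
        u = self.unit
        ts += [u.W_q, u.W_k, u.W_f, u.U_f, u.W_h, u.U_h, u.b_f, u.b_h]
        if self.selection is not None:
            ts.append(self.selection.logits)
        ts += [self.mlp.W1, self.mlp.b1, self.mlp.W2, self.mlp.b2]
        return ts


@dataclass
class MetricsReport:
    """ACC/PREC/Recall/F1 as percentages, with per-run spread when pooled."""

    acc: float
    prec: float
    recall: float
    f1: float
    acc_sd: float = 0.0
    prec_sd: float = 0.0
    recall_sd: float = 0.0
    f1_sd: float = 0.0

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "PREC": self.prec,
            "Recall": self.recall,
            "F1": self.f1,
            "ACC_sd": self.acc_sd,
            "PREC_sd": self.prec_sd,
            "Recall_sd": self.recall_sd,
            "F1_sd": self.f1_sd,
        }


@dataclass
class RunReport:
    metrics: MetricsReport
    biomarkers: pd.DataFrame
    fold_metrics: list[MetricsReport] = field(default_factory=list)


def build_networks(
    subjects: list[ROITimeSeries], config: TrainConfig
) -> list[DynamicBrainNetwork]:
    return [
        build_network(s, n_steps=config.n_steps, k=config.knn, max_dist=config.max_dist)
        for s in subjects
    ]


def init_model(
    n_regions: int, feat_dim: int, config: TrainConfig, rng: np.random.Generator
) -> ModelParams:
    dims = (feat_dim,) + tuple(config.gsa_dims)
    d = dims[-1]
    return ModelParams(
        stack=init_gsa_stack(dims, rng),
        table=init_spatial_table(config.max_dist),
        unit=init_recurrent_unit(d, config.d_k, config.window, rng),
        selection=(
            SelectionState.init(n_regions, s=config.s, r=config.r)
            if config.use_selector
            else None
        ),
        mlp=init_mlp(d, config.mlp_hidden, rng),
    )


def forward(
    model: ModelParams,
    features: np.ndarray,
    masks: np.ndarray,
    sidx: np.ndarray,
    region_mask: Mask | None,
    use_recurrence: bool = True,
    mask_stage: str = "input",
):
    """Full forward pass on a (T, B, N, D) batch; returns (logit, prob)."""
    if mask_stage not in ("input", "embedding"):
        raise ValueError(f"unknown mask_stage {mask_stage!r}")
    x = features
    if region_mask is not None and mask_stage == "input":
        x = apply_mask(Tensor(features), region_mask)
    H = encode_sequence_arrays(
        x, masks, sidx, model.stack, model.table, model.unit, use_recurrence
    )
    if region_mask is not None and mask_stage == "embedding":
        H = apply_mask(H, region_mask)
    g = readout(H)
    return classify(g, model.mlp)


def train(
    nets: list[DynamicBrainNetwork],
    config: TrainConfig,
    seed: int | None = None,
) -> tuple[ModelParams, list[float]]:
    """Full-batch Adam training; returns the model and the loss log."""
    config.validate()
    if not nets:
        raise ValueError("dataset is empty")
    features, masks, sidx, labels = assemble_batch(nets, config.feature_mode)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    with use_dtype(config.dtype):
        return _train_loop(nets, config, features, masks, sidx, labels, rng)


def _train_loop(nets, config, features, masks, sidx, labels, rng):
    model = init_model(nets[0].n_regions, features.shape[-1], config, rng)
    gate_params = [] if model.selection is None else [model.selection.logits]
    main_params = [t for t in model.all_tensors() if all(t is not g for g in gate_params)]
    opt = Adam(main_params, lr=config.lr, weight_decay=config.weight_decay)
    opt_gate = Adam(gate_params, lr=config.gate_lr, weight_decay=config.weight_decay)
    sample_weights = _subject_weights(labels, config)
    log: list[float] = []
    eps = 1e-6
    n_subj = features.shape[1]
    for _ in range(config.epochs):
        if model.selection is not None:
            # independent relaxed mask per subject each epoch
            u = rng.uniform(eps, 1.0 - eps, size=(n_subj, model.selection.n_regions))
            region_mask = sample_mask(model.selection, u)
        else:
            region_mask = None
        _, prob = forward(
            model, features, masks, sidx, region_mask,
            config.use_recurrence, config.mask_stage,
        )
        if sample_weights is not None:
            prob_w = prob  # weighting handled inside the loss below
            loss = _weighted_loss(prob_w, labels, sample_weights, model, config)
        else:
            loss = total_loss(prob, labels, model.selection, config.kl_weight)
        opt.zero_grad()
        opt_gate.zero_grad()
        loss.backward()
        opt.step()
        opt_gate.step()
        log.append(float(loss.data))
    return model, log


def _subject_weights(labels: np.ndarray, config: TrainConfig) -> np.ndarray | None:
    if not config.class_weighting:
        return None
    n = len(labels)
    n1 = labels.sum()
    w1, w0 = n / (2.0 * n1), n / (2.0 * (n - n1))
    return np.where(labels == 1, w1, w0)


def _weighted_loss(prob, labels, weights, model, config):
    from .autodiff import clip, log as tlog, tsum
    from .head import EPS
    from .selector import kl_sparsity

    p = clip(prob, EPS, 1.0 - EPS)
    y = labels
    bce = -tsum(Tensor(weights) * (y * tlog(p) + (1.0 - y) * tlog(1.0 - p)))
    if model.selection is None:
        return bce
    return bce + config.kl_weight * kl_sparsity(model.selection)


def predict(
    model: ModelParams,
    nets: list[DynamicBrainNetwork],
    config: TrainConfig,
) -> np.ndarray:
    """Probabilities under the deterministic mean-field mask (inference).

    The gate expectation z replaces sampling at test time; hard selection
    (z > 0.5) is reported separately for biomarker statistics."""
    features, masks, sidx, _ = assemble_batch(nets, config.feature_mode)
    with use_dtype(config.dtype):
        region_mask = (
            expected_mask(model.selection) if model.selection is not None else None
        )
        _, prob = forward(
            model, features, masks, sidx, region_mask,
            config.use_recurrence, config.mask_stage,
        )
    return np.atleast_1d(prob.data.astype(np.float64))


def compute_metrics(y_prob: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """ACC/PREC/Recall/F1 (percent) at threshold 0.5, positive = addicted.

    Zero-denominator precision or recall is reported as 0 with a warning.
    """
    y_prob = np.asarray(y_prob, dtype=float)
    y = np.asarray(labels).astype(int)
    if y_prob.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    pred = (y_prob > 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    acc = (tp + tn) / len(y)
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall set to 0", stacklevel=2)
        rec = 0.0
    else:
        rec = tp / (tp + fn)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return MetricsReport(acc=100 * acc, prec=100 * prec, recall=100 * rec, f1=100 * f1)


def rank_biomarkers(
    selection_records: list[tuple[np.ndarray, np.ndarray]],
    region_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cumulative region ranking over pooled runs.

    Each record is (z, hard_mask) from one completed training run. Score =
    selection frequency x mean z, descending; score ties are ordered by
    mean z (the cumulative probability weight), then by region index.
    """
    if not selection_records:
        raise ValueError("need at least one completed run")
    zs = np.stack([z for z, _ in selection_records])
    hards = np.stack([h for _, h in selection_records])
    mean_z = zs.mean(axis=0)
    freq = hards.mean(axis=0)
    score = freq * mean_z
    n = len(mean_z)
    ids = region_ids if region_ids is not None else [f"R{i:03d}" for i in range(n)]
    order = np.lexsort((np.arange(n), -mean_z, -score))
    return pd.DataFrame(
        {
            "region": np.arange(n)[order],
            "region_id": np.asarray(ids)[order],
            "mean_z": mean_z[order],
            "selection_frequency": freq[order],
            "score": score[order],
        }
    ).reset_index(drop=True)


def cross_validate(
    nets: list[DynamicBrainNetwork],
    config: TrainConfig,
    collect_folds: bool = True,
) -> RunReport:
    """Stratified k-fold CV, reshuffled per repeat, metrics pooled.

    Fold shuffling, parameter initialization and mask sampling all derive
    from ``config.seed``; repeat ``j`` uses ``seed + j`` so the repeats
    reshuffle deterministically.
    """
    config.validate()
    labels = np.array([net.label for net in nets])
    counts = np.bincount(labels, minlength=2)
    if counts.min() < config.folds:
        raise ValueError(
            f"each class needs >= folds members (counts {counts.tolist()}, folds {config.folds})"
        )
    fold_reports: list[MetricsReport] = []
    records: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(config.repeats):
        rep_seed = config.seed + rep
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=rep_seed)
        for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(nets)), labels)):
            model, _ = train(
                [nets[i] for i in tr], config, seed=rep_seed * 1009 + fold_i
            )
            prob = predict(model, [nets[i] for i in te], config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold_reports.append(compute_metrics(prob, labels[te]))
            if model.selection is not None:
                records.append(
                    (model.selection.z.data.copy(), hard_mask(model.selection).b.data.copy())
                )
    def agg(vals):
        v = np.array(vals)
        return float(v.mean()), float(v.std())

    acc, acc_sd = agg([m.acc for m in fold_reports])
    prec, prec_sd = agg([m.prec for m in fold_reports])
    rec, rec_sd = agg([m.recall for m in fold_reports])
    f1, f1_sd = agg([m.f1 for m in fold_reports])
    metrics = MetricsReport(acc, prec, rec, f1, acc_sd, prec_sd, rec_sd, f1_sd)
    if records:
        ranking = rank_biomarkers(records, nets[0].region_ids or None)
    else:
        ranking = pd.DataFrame(
            columns=["region", "region_id", "mean_z", "selection_frequency", "score"]
        )
    return RunReport(
        metrics=metrics,
        biomarkers=ranking,
        fold_metrics=fold_reports if collect_folds else [],
    )
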