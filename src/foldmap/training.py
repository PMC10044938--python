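"""Training loop and cross-validation harness for the pairing-score network.

The objective is class-weighted binary cross-entropy on the score-map logits
over the valid cells — the upper triangle at separation |i - j| >= 4 inside
each sample's un-padded square. Paired cells are a tiny minority of an
L x L map, so positives are up-weighted; by default the weight is the
valid/positive cell ratio of each batch, capped at 300.

Optimization is Adam over mini-batches of length-sorted records, each batch
zero-padded to its own rounded-up maximum length. All shuffling and
initialization is driven by the configured seed; bitwise run-to-run
stability of floating-point reductions is a property of the BLAS in use and
is not asserted.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .encoding import build_input_conformation, N_CHANNELS
from .io_formats import StructureRecord
from .metrics import (ConfusionCounts, MetricsReport, aggregate_metrics,
                      confusion_per_base, crossval_split)
from .network import NetworkConfig, PairScoreNet, save_checkpoint
from .nn.autograd import weighted_bce_with_logits
from .nn.layers import Adam
from .postprocess import MIN_SEPARATION, SolverConfig, predict_structure

logger = logging.getLogger("foldmap.training")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    #: None -> per-batch valid/positive ratio, capped at positive_weight_cap.
    positive_weight: Optional[float] = None
    positive_weight_cap: float = 300.0
    max_length: int = 720
    seed: int = 0
    checkpoint_dir: Optional[str] = None
    #: Evaluate (and checkpoint on improvement) every this many epochs.
    eval_every: int = 25

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def target_from_record(record: StructureRecord) -> np.ndarray:
    """Symmetric binary L x L contact map from a record's 1-based pairs."""
    L = record.length
    P = np.zeros((L, L), dtype=np.uint8)
    for i, j in record.pairs:
        if not (1 <= i <= L and 1 <= j <= L):
            raise ValueError(f"pair ({i}, {j}) out of range for L={L}")
        P[i - 1, j - 1] = P[j - 1, i - 1] = 1
    return P


def _valid_mask(L: int, H: int) -> np.ndarray:
    """Upper-triangle cells at separation >= MIN_SEPARATION, inside L x L."""
    m = np.zeros((H, H), dtype=np.float32)
    iu, ju = np.triu_indices(L, k=MIN_SEPARATION)
    m[iu, ju] = 1.0
    return m


def loss_on_batch(scores, targets: np.ndarray, lengths: Sequence[int],
                  positive_weight: float):
    """Masked weighted BCE between batch logits and batch targets."""
    n, _, H, W = scores.shape
    if targets.shape != (n, 1, H, W):
        raise ValueError(f"target shape {targets.shape} != scores {scores.shape}")
    mask = np.zeros((n, 1, H, W), dtype=np.float32)
    for b, L in enumerate(lengths):
        mask[b, 0] = _valid_mask(L, H)
    return weighted_bce_with_logits(scores, targets, mask, positive_weight)


def _make_batches(records: Sequence[StructureRecord], batch_size: int,
                  pad_multiple: int) -> List[Tuple[np.ndarray, np.ndarray, List[int]]]:
    """Length-sorted batches of (conformation stack, target stack, lengths)."""
    ordered = sorted(records, key=lambda r: r.length)
    batches = []
    for lo in range(0, len(ordered), batch_size):
        chunk = ordered[lo : lo + batch_size]
        Lmax = max(r.length for r in chunk)
        H = ((Lmax + pad_multiple - 1) // pad_multiple) * pad_multiple
        x = np.zeros((len(chunk), N_CHANNELS, H, H), dtype=np.float32)
        t = np.zeros((len(chunk), 1, H, H), dtype=np.float32)
        lengths = []
        for b, rec in enumerate(chunk):
            L = rec.length
            x[b, :, :L, :L] = build_input_conformation(rec.sequence).tensor
            t[b, 0, :L, :L] = target_from_record(rec)
            lengths.append(L)
        batches.append((x, t, lengths))
    return batches


def evaluate_model(model: PairScoreNet, records: Sequence[StructureRecord],
                   solver_cfg: Optional[SolverConfig] = None,
                   macro: bool = False) -> MetricsReport:
    """Full-pipeline evaluation: score, decode, per-base confusion, aggregate."""
    solver_cfg = solver_cfg or SolverConfig()
    counts = []
    for rec in records:
        S = model.predict(rec.sequence)
        P = predict_structure(rec.sequence, S, solver_cfg)
        counts.append(confusion_per_base(target_from_record(rec), P))
    return aggregate_metrics(counts, macro=macro)


def train(records: Sequence[StructureRecord], net_cfg: NetworkConfig,
          train_cfg: TrainConfig,
          val_records: Optional[Sequence[StructureRecord]] = None,
          solver_cfg: Optional[SolverConfig] = None
          ) -> Tuple[PairScoreNet, List[dict]]:
    """Train a fresh network; returns (model, per-epoch history).

    Records longer than ``train_cfg.max_length`` are skipped with a warning
    (long outliers are excluded rather than truncated). The model with the
    best validation F-score (validation defaults to the training set) is
    kept and also written to ``checkpoint_dir`` when one is configured.
    """
    usable = [r for r in records if r.length <= train_cfg.max_length]
    skipped = len(records) - len(usable)
    if skipped:
        logger.warning("skipping %d records over max_length=%d",
                       skipped, train_cfg.max_length)
    if not usable:
        raise ValueError("no trainable records (empty dataset after filtering)")

    rng = np.random.default_rng(train_cfg.seed)
    model = PairScoreNet(net_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    batches = _make_batches(usable, train_cfg.batch_size, net_cfg.pad_multiple)
    val = list(val_records) if val_records is not None else usable

    history: List[dict] = []
    best_f, best_state = -1.0, None
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(len(batches))
        epoch_loss = 0.0
        for bi in order:
            x, t, lengths = batches[bi]
            if train_cfg.positive_weight is not None:
                pw = train_cfg.positive_weight
            else:
                n_pos = float(t.sum()) / 2.0  # each pair appears twice
                n_valid = sum(
                    max(0, (L - MIN_SEPARATION) * (L - MIN_SEPARATION + 1) // 2)
                    for L in lengths
                )
                pw = min(train_cfg.positive_weight_cap,
                         max(1.0, n_valid / max(n_pos, 1.0)))
            opt.zero_grad()
            scores = model.forward_batch(x, lengths)
            loss = loss_on_batch(scores, t, lengths, pw)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        epoch_loss /= len(batches)
        entry = {"epoch": epoch, "loss": epoch_loss}

        last = epoch == train_cfg.epochs - 1
        if last or (epoch + 1) % train_cfg.eval_every == 0:
            report = evaluate_model(model, val, solver_cfg)
            entry["val_fscore"] = report.fscore
            if report.fscore > best_f:
                best_f = report.fscore
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                if train_cfg.checkpoint_dir:
                    ckdir = Path(train_cfg.checkpoint_dir)
                    ckdir.mkdir(parents=True, exist_ok=True)
                    save_checkpoint(model, ckdir / "best.npz")
        logger.info("epoch %d: loss=%.4f%s", epoch, epoch_loss,
                    f" val_F={entry.get('val_fscore'):.3f}"
                    if "val_fscore" in entry else "")
        history.append(entry)

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def run_crossval(records: Sequence[StructureRecord], k: int,
                 net_cfg: NetworkConfig, train_cfg: TrainConfig,
                 solver_cfg: Optional[SolverConfig] = None,
                 seed: int = 0) -> Tuple[List[MetricsReport], MetricsReport]:
    """k-fold cross-validation: each fold is held out once for testing.

    Returns per-fold test reports and the overall micro-aggregated report
    (summed counts across folds).
    """
    folds = crossval_split(list(records), k, seed)
    fold_reports: List[MetricsReport] = []
    total = ConfusionCounts()
    for fi, test_fold in enumerate(folds):
        train_set = [r for fj, fold in enumerate(folds) if fj != fi for r in fold]
        model, _ = train(train_set, net_cfg, train_cfg, solver_cfg=solver_cfg)
        report = evaluate_model(model, test_fold, solver_cfg)
        fold_reports.append(report)
        total = total + report.counts
        logger.info("fold %d: F=%.3f", fi, report.fscore)
    from .metrics import compute_metrics

    return fold_reports, compute_metrics(total)
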