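"""Training loop: Adam, binary cross-entropy, per-epoch accuracy curves.

The recipe mirrors the segmentation setup the network was designed for:
minibatches of 8, learning rate 10⁻³, Adam, sigmoid output trained with
binary cross-entropy (Dice and BCE+Dice selectable), no learning-rate
schedule and no early stopping; training runs the configured number of
epochs (defaults: 200 for the organ task, 100 for the lesion task) and the
best-validation-loss checkpoint is restored at the end.  Per-epoch history
records loss and pixel accuracy at the prediction threshold on both sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .ct_io import DatasetSplit, MaskSlice
from .errors import ParameterError
from .metrics import confusion_counts, accuracy
from .model import RDAUNet, NetConfig

__all__ = ["TrainConfig", "TrainHistory", "train_model", "predict_mask",
           "save_checkpoint", "load_checkpoint", "ORGAN_EPOCHS", "LESION_EPOCHS"]

ORGAN_EPOCHS = 200
LESION_EPOCHS = 100
_LOSSES = ("bce", "dice", "bce+dice")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = ORGAN_EPOCHS
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "bce"
    seed: int = 0
    prediction_threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if not 0.0 < self.prediction_threshold < 1.0:
            raise ParameterError("prediction_threshold must be in (0,1)")
        if self.loss not in _LOSSES:
            raise ParameterError(f"loss must be one of {_LOSSES}")
        if self.optimizer.lower() != "adam":
            raise ParameterError("only the adam optimizer is provided")


@dataclass
class TrainHistory:
    """One record per completed epoch plus the best-validation epoch index."""

    records: list = field(default_factory=list)
    best_epoch: int = -1

    def append(self, **kw):
        self.records.append(kw)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def _stack(pairs):
    imgs = np.stack([p.image for p in pairs])[:, None, :, :]
    masks = np.stack([p.mask.pixels for p in pairs])[:, None, :, :].astype(np.float64)
    return imgs, masks


def _loss_fn(name, prob, target):
    if name == "bce":
        return nn.bce_loss(prob, target)
    if name == "dice":
        return nn.dice_loss(prob, target)
    both = nn.add(nn.bce_loss(prob, target), nn.dice_loss(prob, target))
    return both


def _epoch_eval(net, imgs, masks, cfg, batch):
    """Mean loss and pixel accuracy over a set, in evaluation mode."""
    net.eval()
    losses, accs = [], []
    with nn.no_grad():
        for i in range(0, len(imgs), batch):
            xb, yb = imgs[i:i + batch], masks[i:i + batch]
            prob = net.forward(xb)
            losses.append(float(_loss_fn(cfg.loss, prob, yb).data) * len(xb))
            pred = prob.data >= cfg.prediction_threshold
            accs.append(accuracy(confusion_counts(pred, yb.astype(bool))) * len(xb))
    return sum(losses) / len(imgs), sum(accs) / len(imgs)


def train_model(net: RDAUNet, split: DatasetSplit, config: TrainConfig | None = None,
                log=None):
    """Train on a DatasetSplit; returns (net, TrainHistory).

    Seeded shuffling each epoch; the epoch with the lowest validation loss
    is checkpointed and its weights are restored into `net` before return.
    Diverging (NaN) loss aborts with a diagnostic.
    """
    config = config or TrainConfig()
    if not split.train or not split.val:
        raise ParameterError("split must have non-empty train and val sets")
    rng = np.random.default_rng(config.seed)
    train_imgs, train_masks = _stack(split.train)
    val_imgs, val_masks = _stack(split.val)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = None
    n = len(train_imgs)
    for epoch in range(config.epochs):
        net.train()
        order = rng.permutation(n)
        run_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = train_imgs[idx], train_masks[idx]
            opt.zero_grad()
            prob = net.forward(xb)
            loss = _loss_fn(config.loss, prob, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss ({loss.data}) at epoch {epoch}, batch {i}; "
                    "lower the learning rate or check input normalisation")
            loss.backward()
            opt.step()
            run_loss += float(loss.data) * len(idx)
        train_loss, train_acc = run_loss / n, None
        _, train_acc = _epoch_eval(net, train_imgs, train_masks, config,
                                   config.batch_size)
        val_loss, val_acc = _epoch_eval(net, val_imgs, val_masks, config,
                                        config.batch_size)
        history.append(epoch=epoch, train_loss=train_loss, train_acc=train_acc,
                       val_loss=val_loss, val_acc=val_acc)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            history.best_epoch = epoch
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} "
                f"loss {train_loss:.4f} acc {train_acc:.4f} "
                f"val_loss {val_loss:.4f} val_acc {val_acc:.4f}")
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return net, history


def predict_mask(net: RDAUNet, image: np.ndarray, threshold: float = 0.5) -> MaskSlice:
    """Threshold the network's probability map into a binary mask."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must be in (0,1)")
    net.eval()
    with nn.no_grad():
        prob = net.forward(np.asarray(image, dtype=np.float64)[None, None])
    return MaskSlice((prob.data[0, 0] >= threshold).astype(np.uint8))


def save_checkpoint(net: RDAUNet, path) -> None:
    """Serialize weights + running stats + an embedded NetConfig copy."""
    state = net.state_dict()
    np.savez_compressed(path, __config__=json.dumps(net.config.to_dict()), **state)


def load_checkpoint(path) -> RDAUNet:
    data = np.load(path, allow_pickle=False)
    cfg = NetConfig.from_dict(json.loads(str(data["__config__"])))
    net = RDAUNet(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    net.load_state_dict(state)
    net.eval()
    return net
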