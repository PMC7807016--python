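"""Model/Results facade over the training and evaluation machinery.

Mirrors the familiar statistical-modelling workflow: construct a
:class:`CycleDeblurModel` from aligned slice pairs, call :meth:`fit`, and
work with the returned :class:`CycleDeblurResults` — translate slices,
evaluate against references, print a summary of the fit.
"""

from __future__ import annotations

import numpy as np

from . import metrics as M
from . import preprocess as pp
from . import training as T
from .training import TrainConfig


class CycleDeblurModel:
    """Bidirectional CBCT<->FBCT translation model on aligned slice pairs.

    Parameters
    ----------
    pairs : list of (cbct_hu, fbct_hu)
        Aligned 2-D slices in Hounsfield units.
    config : TrainConfig, optional
        Training regimen; defaults to the full profile.
    """

    def __init__(self, pairs, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.pairs_hu = list(pairs)
        self.pairs_norm = [(pp.normalize_hu(cb), pp.normalize_hu(fb))
                           for cb, fb in self.pairs_hu]

    @classmethod
    def from_dataset(cls, data_dir, config: TrainConfig | None = None):
        """Build from a directory written by the phantom simulator."""
        from .phantom import load_dataset
        triples, _ = load_dataset(data_dir)
        return cls([(cb, fb) for fb, cb, _ in triples], config=config)

    def fit(self, out_dir=None) -> "CycleDeblurResults":
        nets, history = T.train(self.pairs_norm, self.config, out_dir=out_dir)
        return CycleDeblurResults(self, nets, history)


class CycleDeblurResults:
    """Fitted networks, training history, and evaluation helpers."""

    def __init__(self, model: CycleDeblurModel, nets: dict, history: list):
        self.model = model
        self.nets = nets
        self.history = history

    def translate(self, cbct_hu) -> np.ndarray:
        """CBCT-like HU slice -> FBCT-like HU slice."""
        return T.infer(cbct_hu, self.nets["G_CF"])

    def translate_back(self, fbct_hu) -> np.ndarray:
        return T.infer(fbct_hu, self.nets["G_FC"])

    def evaluate(self, pairs, rois_per_pair, include_input: bool = True) -> M.MetricReport:
        """MetricReport on held-out (cbct, fbct) pairs with ROI masks."""
        methods = {"model": [self.translate(cb) for cb, _ in pairs]}
        if include_input:
            methods["input"] = [np.asarray(cb, dtype=np.float64) for cb, _ in pairs]
        return M.evaluate(pairs, rois_per_pair, methods)

    def save(self, path) -> None:
        T.save_checkpoint(path, self.nets, self.model.config,
                          epoch=self.model.config.epochs)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cycle-Deblur GAN fit",
            "=" * 52,
            f"pairs: {len(self.model.pairs_hu)}   epochs: {cfg.epochs}   "
            f"batch: {cfg.batch_size}   lr: {cfg.lr:g}",
            f"generator: {cfg.generator.base_channels} base ch, "
            f"{cfg.generator.n_residual_blocks} residual blocks",
            f"iterations recorded: {len(self.history)}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append("final losses (unweighted):")
            for k, v in last["terms"].items():
                lines.append(f"  {k:>10s}: {v: .5f}")
            lines.append(f"  critic    : {last['critic_loss']: .5f}")
        return "\n".join(lines)
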