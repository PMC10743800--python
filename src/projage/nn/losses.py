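"""Regression losses returning (value, gradient w.r.t. predictions)."""

from __future__ import annotations

import numpy as np


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    resid = pred - target
    return float(np.mean(resid**2)), 2.0 * resid / resid.size


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    resid = pred - target
    return float(np.mean(np.abs(resid))), np.sign(resid) / resid.size
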