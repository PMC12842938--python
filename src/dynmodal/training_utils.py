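"""Gumbel-Softmax sampling with straight-through gradients.

Kept in its own module so the model can import it without pulling in the
training loop.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigError
from .nn import Tensor

__all__ = ["gumbel_softmax_sample"]


def gumbel_softmax_sample(logits, tau: float, rng: np.random.Generator,
                          hard: bool = False) -> Tensor:
    """Sample g_k = softmax((logits_k + b_k)/tau) with b_k ~ Gumbel(0, 1).

    With ``hard=True`` the forward value is one-hot(argmax(soft sample))
    while gradients route through the soft sample (straight-through
    estimator). The argmax of logits + Gumbel noise is a draw from
    categorical(softmax(logits)) — the Gumbel-max trick — so hard samples
    are calibrated to the gate probabilities at any temperature.
    """
    if tau <= 0:
        raise ConfigError("temperature must be positive")
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    k = logits.shape[-1]
    noise = rng.gumbel(size=logits.shape)
    soft = nn.softmax((logits + Tensor(noise)) * (1.0 / tau), axis=-1)
    if not hard:
        return soft
    idx = np.asarray(soft.data.argmax(axis=-1))
    onehot = np.eye(k)[idx]
    # forward: one-hot; backward: d(soft)
    return soft + Tensor(onehot - soft.data)
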