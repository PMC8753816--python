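"""Gradient verification: analytic backpropagation vs central differences.

For every parameter group of a model, a seeded sample of entries (always
including the largest-magnitude analytic gradient of the group) is perturbed
by +-h and the central difference of the loss is compared against the
backpropagated gradient.  The relative error uses a small absolute floor in
the denominator because entries whose true gradient sits below the
finite-difference noise floor (~1e-11 at h = 1e-5 in float64) carry no
meaningful relative error.
"""

from __future__ import annotations

import numpy as np

from . import cpi_model
from .cpi_model import ModelParams, PreparedExample

FD_STEP = 1e-5
DENOM_FLOOR = 1e-6


def check_gradients(ex: PreparedExample, params: ModelParams,
                    samples_per_group: int = 8, seed: int = 0,
                    step: float = FD_STEP) -> dict[str, float]:
    """Max relative error per parameter group for one example's loss."""
    loss_t, _ = cpi_model.training_loss(ex, params)
    params.zero_grad()
    loss_t.backward()
    analytic = {name: (np.zeros_like(t.data) if t.grad is None else t.grad.copy())
                for name, t in params.named_tensors()}

    rng = np.random.default_rng(seed)
    report: dict[str, float] = {}
    for name, tensor in params.named_tensors():
        flat = tensor.data.ravel()
        gflat = analytic[name].ravel()
        idxs = set(rng.choice(flat.size, size=min(samples_per_group, flat.size),
                              replace=False).tolist())
        nz = np.flatnonzero(np.abs(gflat) > 1e-12)
        if nz.size:
            idxs.add(int(nz[np.argmax(np.abs(gflat[nz]))]))
        worst = 0.0
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + step
            lp = float(cpi_model.training_loss(ex, params)[0].data)
            flat[i] = orig - step
            lm = float(cpi_model.training_loss(ex, params)[0].data)
            flat[i] = orig
            fd = (lp - lm) / (2 * step)
            a = gflat[i]
            rel = abs(a - fd) / max(abs(a) + abs(fd), DENOM_FLOOR)
            worst = max(worst, rel)
        report[name] = worst
    return report


def max_relative_error(ex: PreparedExample, params: ModelParams,
                       **kwargs) -> float:
    return max(check_gradients(ex, params, **kwargs).values())
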