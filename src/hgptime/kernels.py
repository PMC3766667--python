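"""Squared-exponential covariance function and its hyperparameter gradients.

The package models latent expression profiles with the stationary
squared-exponential (SE) kernel

    k(t, t') = amplitude * exp(-inv_lengthscale * (t - t')**2)

``amplitude`` (often written alpha) is the signal variance in squared
expression units; ``inv_lengthscale`` (gamma) has units 1/hours**2 and
inversely controls how quickly correlation decays with the time lag.
Each layer of a hierarchy carries its own independent SE kernel.

Only the SE kernel is provided; it is kept behind a small functional
interface (evaluate + gradients on a parameter dataclass) so that other
stationary kernels could be added without touching the hierarchy code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["KernelParams", "sq_exp_cov", "sq_exp_grad"]


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of one squared-exponential kernel layer.

    Parameters
    ----------
    amplitude
        Signal variance (> 0), in squared units of the modelled values.
    inv_lengthscale
        Inverse squared length-scale (>= 0), in 1/hours**2. Zero yields a
        constant (perfectly correlated) function.
    """

    amplitude: float
    inv_lengthscale: float

    def __post_init__(self) -> None:
        amp = float(self.amplitude)
        gam = float(self.inv_lengthscale)
        if not np.isfinite(amp) or amp <= 0.0:
            raise ValueError(f"amplitude must be a finite positive real, got {self.amplitude!r}")
        if not np.isfinite(gam) or gam < 0.0:
            raise ValueError(
                f"inv_lengthscale must be a finite non-negative real, got {self.inv_lengthscale!r}"
            )
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "inv_lengthscale", gam)

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "inv_lengthscale": self.inv_lengthscale}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelParams":
        return cls(amplitude=d["amplitude"], inv_lengthscale=d["inv_lengthscale"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "KernelParams":
        return cls.from_dict(json.loads(s))


def _as_time_vector(t, name: str) -> np.ndarray:
    arr = np.asarray(t, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one time point")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite time values")
    return arr


def sq_exp_cov(t1, t2, params: KernelParams) -> np.ndarray:
    """Evaluate the SE kernel on the grid of two time vectors.

    Returns the |t1| x |t2| matrix with entries
    ``amplitude * exp(-inv_lengthscale * (t1[i] - t2[j])**2)``.
    """
    a = _as_time_vector(t1, "t1")
    b = _as_time_vector(t2, "t2")
    delta = a[:, None] - b[None, :]
    return params.amplitude * np.exp(-params.inv_lengthscale * delta * delta)


def sq_exp_grad(t1, t2, params: KernelParams) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`sq_exp_cov` with respect to the natural parameters.

    Returns ``(dK/d amplitude, dK/d inv_lengthscale)`` where

        dK/d amplitude       = exp(-gamma * delta**2)
        dK/d inv_lengthscale = -delta**2 * amplitude * exp(-gamma * delta**2)
    """
    a = _as_time_vector(t1, "t1")
    b = _as_time_vector(t2, "t2")
    delta2 = (a[:, None] - b[None, :]) ** 2
    e = np.exp(-params.inv_lengthscale * delta2)
    return e, -delta2 * params.amplitude * e
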