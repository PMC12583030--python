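"""Phase response curves: analytic families and Fourier representations.

The infinitesimal phase response curve (PRC) ``Z(theta)`` of a limit-cycle
oscillator gives the phase shift per unit impulsive input delivered at phase
``theta``.  Under phase reduction a stimulated oscillator obeys

    dtheta/dt = omega + Z(theta) * u(t),

so ``Z`` is all that the optimal-control machinery needs to know about the
underlying neuron.  Three families are supported:

* ``sinusoidal`` — ``Z = Zd sin(theta)``, the normal form near a supercritical
  Hopf bifurcation (Type II: sign-changing).
* ``sniper`` — ``Z = Zd (1 - cos(theta))``, the normal form near a
  saddle-node-on-invariant-circle bifurcation (Type I: non-negative).
* ``fourier`` — ``Z = a0 + sum_k (ak cos(k theta) + bk sin(k theta))``,
  typically a least-squares fit to a numerically computed (adjoint) PRC.

All curves are 2*pi-periodic in phase; phases are wrapped with a floored
modulo so negative inputs are handled consistently.  Derivatives are exact
(analytic, or term-wise for the Fourier family).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "PhaseResponseCurve",
    "sinusoidal_prc",
    "sniper_prc",
    "fit_fourier",
    "load_prc_json",
    "read_prc_samples",
    "write_prc_samples",
]

TWO_PI = 2.0 * np.pi

_FAMILIES = ("sinusoidal", "sniper", "fourier")


def _wrap(theta):
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("phase must be finite")
    return np.mod(theta, TWO_PI)


@dataclass(frozen=True)
class PhaseResponseCurve:
    """A 2*pi-periodic PRC with exact first and second derivatives.

    Parameters
    ----------
    family:
        One of ``"sinusoidal"``, ``"sniper"``, ``"fourier"``.
    Zd:
        Amplitude of the analytic families (ignored for ``fourier``).
    a0, a, b:
        Fourier coefficients ``Z = a0 + sum a[k-1] cos(k th) + b[k-1] sin(k th)``.
        ``a0`` is the mean of the curve.
    T:
        Period of the source oscillator in its own time units (2*pi for the
        analytic examples with omega = 1).
    fit_rms:
        RMS residual of the least-squares fit that produced a Fourier curve
        (0 for analytic families).
    """

    family: str
    Zd: float = 1.0
    a0: float = 0.0
    a: np.ndarray = field(default_factory=lambda: np.zeros(0))
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))
    T: float = TWO_PI
    fit_rms: float = 0.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown PRC family {self.family!r}")
        if not self.T > 0:
            raise ValueError("period T must be positive")
        object.__setattr__(self, "a", np.atleast_1d(np.asarray(self.a, dtype=float)))
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, dtype=float)))
        if self.family == "fourier" and self.a.shape != self.b.shape:
            raise ValueError("cosine and sine coefficient arrays must have equal length")

    @property
    def omega(self) -> float:
        return TWO_PI / self.T

    @property
    def K(self) -> int:
        """Number of harmonics (0 for the analytic families)."""
        return len(self.a) if self.family == "fourier" else 0

    # -- evaluation ---------------------------------------------------------

    def Z(self, theta):
        th = _wrap(theta)
        if self.family == "sinusoidal":
            return self.Zd * np.sin(th)
        if self.family == "sniper":
            return self.Zd * (1.0 - np.cos(th))
        k = np.arange(1, self.K + 1)
        kth = np.multiply.outer(th, k)
        return self.a0 + np.cos(kth) @ self.a + np.sin(kth) @ self.b

    def dZ(self, theta):
        th = _wrap(theta)
        if self.family == "sinusoidal":
            return self.Zd * np.cos(th)
        if self.family == "sniper":
            return self.Zd * np.sin(th)
        k = np.arange(1, self.K + 1)
        kth = np.multiply.outer(th, k)
        return -np.sin(kth) @ (k * self.a) + np.cos(kth) @ (k * self.b)

    def d2Z(self, theta):
        th = _wrap(theta)
        if self.family == "sinusoidal":
            return -self.Zd * np.sin(th)
        if self.family == "sniper":
            return self.Zd * np.cos(th)
        k = np.arange(1, self.K + 1)
        kth = np.multiply.outer(th, k)
        return -np.cos(kth) @ (k**2 * self.a) - np.sin(kth) @ (k**2 * self.b)

    __call__ = Z

    def eval_all(self, theta: float):
        """(Z, Z', Z'') at a scalar phase with one trigonometric evaluation.

        Fast path for ODE right-hand sides, where all three are needed at
        every integrator step.
        """
        if not np.isfinite(theta):
            raise ValueError("phase must be finite")
        if self.family == "sinusoidal":
            s, c = np.sin(theta), np.cos(theta)
            return self.Zd * s, self.Zd * c, -self.Zd * s
        if self.family == "sniper":
            s, c = np.sin(theta), np.cos(theta)
            return self.Zd * (1.0 - c), self.Zd * s, self.Zd * c
        k, ka, kb, k2a, k2b = self._karrays()
        ck = np.cos(k * theta)
        sk = np.sin(k * theta)
        Z = self.a0 + ck @ self.a + sk @ self.b
        dZ = ck @ kb - sk @ ka
        d2Z = -(ck @ k2a + sk @ k2b)
        return Z, dZ, d2Z

    def _karrays(self):
        cached = getattr(self, "_kcache", None)
        if cached is None:
            k = np.arange(1.0, self.K + 1.0)
            cached = (k, k * self.a, k * self.b, k**2 * self.a, k**2 * self.b)
            object.__setattr__(self, "_kcache", cached)
        return cached

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "family": self.family,
            "Zd": self.Zd,
            "a0": self.a0,
            "a": list(self.a),
            "b": list(self.b),
            "T": self.T,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def sinusoidal_prc(Zd: float = 0.5, T: float = TWO_PI) -> PhaseResponseCurve:
    """``Z(theta) = Zd sin(theta)`` (Type II, Hopf normal form)."""
    return PhaseResponseCurve(family="sinusoidal", Zd=Zd, T=T)


def sniper_prc(Zd: float = 0.5, T: float = TWO_PI) -> PhaseResponseCurve:
    """``Z(theta) = Zd (1 - cos(theta))`` (Type I, SNIC normal form)."""
    return PhaseResponseCurve(family="sniper", Zd=Zd, T=T)


def fit_fourier(theta, Z, K: int, T: float = TWO_PI) -> PhaseResponseCurve:
    """Least-squares Fourier fit of PRC samples.

    Parameters
    ----------
    theta, Z:
        Sample phases (radians, spanning ``[0, 2*pi)``) and PRC values.
    K:
        Number of harmonics; the fit has ``2K + 1`` free coefficients and
        requires at least that many samples.
    T:
        Period of the source oscillator, carried on the returned curve.

    Returns
    -------
    PhaseResponseCurve
        Fourier-family curve; ``fit_rms`` holds the residual RMS, which is
        non-increasing in ``K`` on fixed samples (projection property).
    """
    theta = np.asarray(theta, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if theta.ndim != 1 or theta.shape != Z.shape:
        raise ValueError("theta and Z must be 1-D arrays of equal length")
    n = len(theta)
    if n < 2 * K + 1:
        raise ValueError(f"need at least {2 * K + 1} samples for K={K}, got {n}")
    k = np.arange(1, K + 1)
    kth = np.multiply.outer(theta, k)
    design = np.hstack([np.ones((n, 1)), np.cos(kth), np.sin(kth)])
    coef, *_ = np.linalg.lstsq(design, Z, rcond=None)
    resid = Z - design @ coef
    return PhaseResponseCurve(
        family="fourier",
        a0=float(coef[0]),
        a=coef[1 : K + 1],
        b=coef[K + 1 :],
        T=T,
        fit_rms=float(np.sqrt(np.mean(resid**2))),
    )


def load_prc_json(path: Union[str, Path]) -> PhaseResponseCurve:
    d = json.loads(Path(path).read_text())
    return PhaseResponseCurve(
        family=d["family"], Zd=d.get("Zd", 1.0), a0=d.get("a0", 0.0),
        a=np.asarray(d.get("a", [0.0])), b=np.asarray(d.get("b", [0.0])),
        T=d.get("T", TWO_PI),
    )


def read_prc_samples(path: Union[str, Path]):
    """Read (theta, Z) samples from 2-column delimited text (header optional)."""
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError:  # plain (non-#) header line
        data = np.loadtxt(path, ndmin=2, skiprows=1)
    if data.shape[1] < 2:
        raise ValueError("expected two columns: theta, Z")
    return data[:, 0], data[:, 1]


def write_prc_samples(path: Union[str, Path], theta, Z) -> None:
    np.savetxt(path, np.column_stack([theta, Z]), header="theta Z")
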