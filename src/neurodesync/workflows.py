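"""End-to-end experiment plumbing: PRC -> OCP -> pair validation -> tables.

These helpers tie the library modules into reproducible runs: build (or load)
a PRC, solve the constrained optimal-control problem over a list of umax
values, validate each stimulus on an event-triggered oscillator pair, and
emit tidy tables with provenance metadata.  They are what the command-line
interface calls; everything is deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import (
    compute_adjoint_prc,
    find_limit_cycle,
    hodgkin_huxley,
    reduced_hodgkin_huxley,
)
from .ocp import ControlProblem, ShootingError, solve_ocp
from .pair import PairSimConfig, fit_lyapunov, simulate_pair
from .prc import PhaseResponseCurve, fit_fourier, sinusoidal_prc, sniper_prc

__all__ = ["RunConfig", "build_prc", "run_table_experiment", "run_umax_curve",
           "load_config"]

# adjoint-PRC pipeline settings per conductance model: (harmonics, phase grid)
_MODEL_PIPELINES = {
    "hh": (hodgkin_huxley, 10, 1024),
    "rhh": (reduced_hodgkin_huxley, 200, 4096),
}


@dataclass
class RunConfig:
    """Declarative description of one table/sweep experiment."""

    experiment: str = "table"
    prc: str = "sinusoidal"              # sinusoidal | sniper | hh | rhh
    Zd: float = 0.5
    beta: float = 2.0
    umax: Sequence[float] = field(default_factory=lambda: [0.5, 0.35, 0.2])
    t1: Optional[float] = None           # defaults to one period
    phi0: float = 0.1
    n_cycles: int = 10
    seed: int = 0
    out_dir: str = "."

    def validated(self) -> "RunConfig":
        if self.prc not in ("sinusoidal", "sniper", "hh", "rhh"):
            raise ValueError(f"unknown PRC spec {self.prc!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.phi0 < np.pi:
            raise ValueError("phi0 must lie in (0, pi)")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        for u in self.umax:
            if not u > 0:
                raise ValueError("umax values must be positive (inf allowed)")
        return self


def load_config(path: Union[str, Path]) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data).validated()


def build_prc(name: str, Zd: float = 0.5):
    """Construct a PRC by name; conductance models run the full adjoint pipeline.

    Returns ``(prc, limit_cycle_or_None)``.
    """
    if name == "sinusoidal":
        return sinusoidal_prc(Zd), None
    if name == "sniper":
        return sniper_prc(Zd), None
    if name in _MODEL_PIPELINES:
        factory, K, M = _MODEL_PIPELINES[name]
        model = factory()
        lc = find_limit_cycle(model, M=M)
        thetas, Z_V, _ = compute_adjoint_prc(model, lc)
        return fit_fourier(thetas, Z_V, K=K, T=lc.T), lc
    raise ValueError(f"unknown PRC spec {name!r}")


def _one_row(prc: PhaseResponseCurve, beta, umax, t1, phi0, n_cycles):
    row = {"umax": umax}
    try:
        sol = solve_ocp(ControlProblem(prc=prc, beta=beta, umax=umax, t1=t1))
        pair = simulate_pair(PairSimConfig(prc=prc, u_t=sol.t, u=sol.u,
                                           phi0=phi0, n_cycles=n_cycles))
        lam_fit, r2 = fit_lyapunov(pair)
        row.update(lambda_calc=sol.lyap_calc, lambda_fit=lam_fit,
                   energy=sol.energy, fit_r2=r2,
                   boundary_residual=sol.boundary_residual, failed=False)
    except (ShootingError, RuntimeError) as exc:  # keep partial tables usable
        row.update(lambda_calc=np.nan, lambda_fit=np.nan, energy=np.nan,
                   fit_r2=np.nan, boundary_residual=np.nan, failed=True,
                   error=str(exc))
    return row


def run_table_experiment(config: RunConfig, prc: Optional[PhaseResponseCurve] = None,
                         write: bool = False) -> pd.DataFrame:
    """Solve/validate one row per umax: (umax, lambda_fit, lambda_calc, energy).

    ``prc`` may be supplied to reuse an already-built curve; otherwise it is
    constructed from the config.  With ``write=True`` the table is saved as
    CSV next to a JSON sidecar recording the full configuration and package
    version.
    """
    config = config.validated()
    if prc is None:
        prc, _ = build_prc(config.prc, config.Zd)
    rows = [_one_row(prc, config.beta, u, config.t1, config.phi0, config.n_cycles)
            for u in config.umax]
    table = pd.DataFrame(rows)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"{config.experiment}_{config.prc}"
        table.to_csv(out / f"{stem}.csv", index=False)
        sidecar = {"config": asdict(config), "version": __version__}
        (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1, default=float))
    return table


def run_umax_curve(config: RunConfig, n_points: int = 10,
                   prc: Optional[PhaseResponseCurve] = None) -> pd.DataFrame:
    """Dense umax sweep from strongly constrained to unconstrained.

    Sweeps ``n_points`` umax values log-spaced up to the unconstrained peak
    input amplitude (plus the unconstrained endpoint itself) and returns the
    same columns as :func:`run_table_experiment`.
    """
    config = config.validated()
    if prc is None:
        prc, _ = build_prc(config.prc, config.Zd)
    free = solve_ocp(ControlProblem(prc=prc, beta=config.beta, umax=np.inf,
                                    t1=config.t1))
    peak = float(np.max(np.abs(free.u)))
    umaxes = list(np.geomspace(0.15 * peak, 1.05 * peak, n_points - 1)) + [np.inf]
    cfg = RunConfig(**{**asdict(config), "umax": umaxes})
    return run_table_experiment(cfg, prc=prc)
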