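"""Parameter-sweep tables, file I/O and synthetic walker cohorts.

Two sweep modes back the model's characteristic plots: the braking-adjusted
cost epsilon as a function of gradient for a handful of step parameters
(a family of V-shaped curves whose minima sit at each k's optimal downhill
slope), and the optimal gradient as a function of k (a monotone curve from
about -13% at k=1 to about -8% at k=1.5).

Tables are pandas DataFrames wrapped with a metadata echo of every physical
parameter (m, l, g, efficiency factor, grid), since the curves' absolute
scale depends on choices the plots alone do not pin down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .params import (
    COMFORT_K_RANGE,
    G_DEFAULT,
    BodyParams,
    DomainError,
    GaitParams,
)
from .energetics import compute_geometry
from .optimum import (
    optimal_gradient_closed_form,
    optimal_gradient_exact,
    optimal_gradient_numeric,
)
from . import optimum as _optimum

__all__ = [
    "SweepTable",
    "WalkerCohortFixture",
    "sweep_epsilon_vs_gradient",
    "sweep_optimum_vs_k",
    "write_table",
    "read_table",
    "generate_cohort",
]

_ROUNDTRIP_FMT = "%.12g"   # 12 significant digits in CSV bodies


@dataclass(frozen=True)
class SweepTable:
    """A sweep result: mode tag, column data and a parameter echo."""

    mode: str                 # "epsilon_vs_gradient" or "optimum_vs_k"
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WalkerCohortFixture:
    """Reproducible synthetic cohort of walkers for sweep/property tests."""

    n: int
    seed: int
    leg_lengths: np.ndarray   # metres
    k_values: np.ndarray      # dimensionless

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"leg_length": self.leg_lengths, "k": self.k_values}
        )


def _metadata(body: BodyParams, g: float, efficiency_factor: float,
              **extra) -> dict:
    md = {
        "m": body.mass,
        "l": body.leg_length,
        "g": g,
        "efficiency_factor": efficiency_factor,
    }
    md.update(extra)
    return md


def sweep_epsilon_vs_gradient(
    ks: list[float],
    i_lo: float = -0.3,
    i_hi: float = 0.3,
    n: int = 601,
    body: BodyParams | None = None,
    g: float = G_DEFAULT,
    efficiency_factor: float = 5.0,
) -> SweepTable:
    """Braking-adjusted cost epsilon over a gradient grid, one series per k.

    Each series is V-shaped: cost falls as the downhill slope approaches
    that k's optimum (where the descent exactly pays for the
    centre-of-mass lift and epsilon touches zero) and rises beyond it as
    braking work grows.
    """
    if not ks:
        raise DomainError("ks must be a non-empty list of step parameters")
    if n < 2:
        raise DomainError(f"need at least 2 grid points, got {n}")
    if not i_lo < i_hi:
        raise DomainError(f"degenerate gradient grid [{i_lo}, {i_hi}]")
    body = body if body is not None else BodyParams()
    grid = np.linspace(i_lo, i_hi, n)
    cols: dict[str, np.ndarray] = {"gradient": grid}
    for k in ks:
        gait = GaitParams(k=k, efficiency_factor=efficiency_factor)
        cols[f"epsilon_k={k:g}"] = _optimum._epsilon_curve(
            grid, body, gait, g
        )
    meta = _metadata(
        body, g, efficiency_factor,
        ks=list(ks), i_lo=i_lo, i_hi=i_hi, n=n,
    )
    return SweepTable(
        mode="epsilon_vs_gradient", data=pd.DataFrame(cols), metadata=meta
    )


def sweep_optimum_vs_k(
    k_lo: float,
    k_hi: float,
    n: int,
    method: str = "closed_form",
    body: BodyParams | None = None,
    g: float = G_DEFAULT,
    efficiency_factor: float = 5.0,
) -> SweepTable:
    """Optimal gradient as a function of the step parameter k.

    ``method`` selects the solver: ``closed_form``, ``exact``, ``numeric``
    or ``all`` (every solver plus their maximum pairwise disagreement).
    """
    if not (0.5 <= k_lo < k_hi):
        raise DomainError(
            f"need 0.5 <= k_lo < k_hi, got [{k_lo}, {k_hi}]"
        )
    if n < 2:
        raise DomainError(f"need at least 2 k values, got {n}")
    methods = {"closed_form", "exact", "numeric", "all"}
    if method not in methods:
        raise DomainError(f"method must be one of {sorted(methods)}")
    body = body if body is not None else BodyParams()
    ks = np.linspace(k_lo, k_hi, n)
    cols: dict[str, np.ndarray] = {"k": ks}

    def _numeric(k: float) -> float:
        gait = GaitParams(k=k, efficiency_factor=efficiency_factor)
        return optimal_gradient_numeric(body, gait, g=g)

    if method in ("closed_form", "all"):
        cols["i_closed_form"] = np.array(
            [optimal_gradient_closed_form(k) for k in ks]
        )
    if method in ("exact", "all"):
        cols["i_exact"] = np.array(
            [optimal_gradient_exact(k) for k in ks]
        )
    if method in ("numeric", "all"):
        cols["i_numeric"] = np.array([_numeric(k) for k in ks])
    if method == "all":
        trio = np.vstack(
            [cols["i_closed_form"], cols["i_exact"], cols["i_numeric"]]
        )
        cols["max_disagreement"] = trio.max(axis=0) - trio.min(axis=0)
    meta = _metadata(
        body, g, efficiency_factor,
        k_lo=k_lo, k_hi=k_hi, n=n, method=method,
    )
    return SweepTable(mode="optimum_vs_k", data=pd.DataFrame(cols),
                      metadata=meta)


def write_table(table: SweepTable, path: str | Path, format: str = "csv") -> None:
    """Write a sweep table to CSV ('#'-commented metadata header + RFC-4180
    body at 12 significant digits) or to a flat JSON object."""
    if table.data.empty:
        raise DomainError("refusing to write an empty sweep table")
    path = Path(path)
    if format == "csv":
        try:
            with path.open("w", newline="") as fh:
                fh.write(f"# mode = {table.mode}\n")
                for key, val in table.metadata.items():
                    fh.write(f"# {key} = {val}\n")
                table.data.to_csv(fh, index=False,
                                  float_format=_ROUNDTRIP_FMT)
        except OSError as exc:
            raise OSError(f"cannot write sweep table to {path}: {exc}") from exc
    elif format == "json":
        payload = {
            "mode": table.mode,
            "metadata": table.metadata,
            "columns": {
                name: table.data[name].tolist() for name in table.data
            },
        }
        try:
            path.write_text(json.dumps(payload, indent=1))
        except OSError as exc:
            raise OSError(f"cannot write sweep table to {path}: {exc}") from exc
    else:
        raise DomainError(f"format must be 'csv' or 'json', got {format!r}")


def read_table(path: str | Path, format: str = "csv") -> SweepTable:
    """Companion reader for :func:`write_table`; round-trips to 1e-10."""
    path = Path(path)
    if format == "csv":
        mode = "unknown"
        metadata: dict = {}
        with path.open() as fh:
            header_lines = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                key, _, val = line[1:].partition("=")
                key, val = key.strip(), val.strip()
                if key == "mode":
                    mode = val
                else:
                    metadata[key] = _parse_meta_value(val)
        data = pd.read_csv(path, comment="#")
        return SweepTable(mode=mode, data=data, metadata=metadata)
    if format == "json":
        payload = json.loads(path.read_text())
        return SweepTable(
            mode=payload["mode"],
            data=pd.DataFrame(payload["columns"]),
            metadata=payload["metadata"],
        )
    raise DomainError(f"format must be 'csv' or 'json', got {format!r}")


def _parse_meta_value(val: str):
    """Best-effort typed parse of a metadata value echoed through CSV."""
    for parser in (int, float):
        try:
            return parser(val)
        except ValueError:
            pass
    return val


def generate_cohort(
    n: int,
    seed: int,
    leg_range: tuple[float, float] = (0.75, 1.00),
    k_range: tuple[float, float] = COMFORT_K_RANGE,
) -> WalkerCohortFixture:
    """Synthetic cohort of walkers with uniform leg length and k.

    Defaults emulate adult humans: leg length 0.75-1.00 m and k drawn from
    the comfortable range [1.15, 1.55].  Fully determined by ``seed``.
    """
    if n < 1:
        raise DomainError(f"cohort size must be >= 1, got {n}")
    if not (0 < leg_range[0] < leg_range[1]):
        raise DomainError(f"invalid leg_range {leg_range}")
    if not (0.5 <= k_range[0] < k_range[1]):
        raise DomainError(f"invalid k_range {k_range}")
    rng = np.random.default_rng(seed)
    legs = rng.uniform(*leg_range, size=n)
    ks = rng.uniform(*k_range, size=n)
    return WalkerCohortFixture(n=n, seed=seed, leg_lengths=legs, k_values=ks)
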