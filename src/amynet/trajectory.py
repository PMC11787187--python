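"""Trajectory containers and tidy-CSV serialization shared by all solvers."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrajectoryResult", "TruncationError", "IntegrationError"]


class TruncationError(RuntimeError):
    """Mass accumulated too close to the size cutoff N; rerun with larger N."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or returned unphysical (negative) concentrations."""


@dataclass
class TrajectoryResult:
    """Time-resolved output of a kinetic simulation.

    For size-resolved runs ``p`` holds the concentrations of aggregates of
    size 2..N, shape (T, N-1); moment-only runs store ``P``/``M`` directly
    and leave ``p`` as None.  ``m`` is the monomer concentration (constant in
    the in vivo models).  ``clearance`` optionally records a time-varying
    clearance series (damage model), shape (T,) or (T, N-1).
    """

    t: np.ndarray
    m: np.ndarray
    p: np.ndarray | None = None
    P_series: np.ndarray | None = None
    M_series: np.ndarray | None = None
    clearance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def sizes(self) -> np.ndarray:
        if self.p is None:
            raise ValueError("moment-only trajectory has no size axis")
        return np.arange(2, self.p.shape[1] + 2)

    @property
    def P(self) -> np.ndarray:
        """Total aggregate number concentration P(t)."""
        if self.P_series is not None:
            return self.P_series
        return self.p.sum(axis=1)

    @property
    def M(self) -> np.ndarray:
        """Total aggregate mass concentration M(t)."""
        if self.M_series is not None:
            return self.M_series
        return self.p @ self.sizes.astype(float)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: columns time, size, concentration.

        Size 1 rows are the monomer; moment-only runs use pseudo-sizes
        "P" and "M" in a wide frame instead.
        """
        if self.p is None:
            return pd.DataFrame({"time": self.t, "m": self.m, "P": self.P, "M": self.M})
        frames = [pd.DataFrame({"time": self.t, "size": 1, "concentration": self.m})]
        for j, i in enumerate(self.sizes):
            frames.append(
                pd.DataFrame(
                    {"time": self.t, "size": int(i), "concentration": self.p[:, j]}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save(self, path: str | Path) -> None:
        """Write a tidy CSV plus a JSON metadata sidecar (path + '.meta.json')."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


def clip_small_negatives(y: np.ndarray, floor_scale: float) -> np.ndarray:
    """Clip tiny negative solver excursions to zero.

    Values in [-floor_scale, 0) are set to 0 with a warning; anything more
    negative indicates genuine solver failure.
    """
    neg = y < 0
    if not np.any(neg):
        return y
    worst = y.min()
    if worst < -floor_scale:
        raise IntegrationError(
            f"negative concentration {worst:.3e} beyond tolerance {-floor_scale:.3e}"
        )
    warnings.warn(
        f"clipped negative concentrations (min {worst:.3e}) to zero",
        RuntimeWarning,
        stacklevel=2,
    )
    out = y.copy()
    out[neg] = 0.0
    return out


def check_tail_mass(t, p, sizes, frac: float = 0.01) -> None:
    """Raise TruncationError if sizes >= N-1 ever hold more than ``frac`` of M."""
    M = p @ sizes.astype(float)
    tail = p[:, -2:] @ sizes[-2:].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(M > 0, tail / np.maximum(M, 1e-300), 0.0)
    if np.any(ratio > frac):
        k = int(np.argmax(ratio > frac))
        raise TruncationError(
            f"truncation overflow: {100 * ratio[k]:.2f}% of aggregate mass in the "
            f"top two size classes at t={t[k]:.4g}; rerun with a larger N"
        )
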