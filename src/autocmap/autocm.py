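r"""Auto-contractive map (AutoCM): training and weight-to-distance conversion.

The auto-contractive map is a three-layer auto-associative network with N
units per layer.  Input→hidden connections are mono-dedicated (a vector
``v``); hidden→output connections are a full N×N matrix ``w``.  Both transfer
steps apply the same contraction ``x · (1 − weight/C)`` where ``C ≥ 1`` is
the contraction parameter, and both learning steps trap the residual signal
energy:

.. math::

    h_{ip} &= s_{ip}\,(1 - v_i/C) \\
    \Delta v_i &= \sum_p (s_{ip} - h_{ip})\,(1 - v_i/C)\, s_{ip} \\
    \mathrm{net}_{ip} &= \sum_j h_{jp}\,(1 - w_{ij}/C) \\
    t_{ip} &= h_{ip}\,(1 - \mathrm{net}_{ip}/C) \\
    \Delta w_{ij} &= \sum_p (h_{ip} - t_{ip})\,(1 - w_{ij}/C)\, h_{jp}

with batch updates ``v ← v + α Δv``, ``w ← w + α Δw`` applied once per
epoch, learning coefficient ``α = 1/M`` (M = number of patterns).  Inputs
must lie in [0, 1].  Each ``v_i`` grows monotonically toward ``C`` (a
discrete logistic), at which point the hidden layer is silent and training
has converged; the trained ``w`` is then read as a similarity structure and
converted to distances ``d = C − (w + wᵀ)/2`` (zero diagonal).

The network deliberately has many more free parameters than a correlation
matrix: ``w_{ij}`` absorbs joint, not merely pairwise, co-activation, which
is what makes the resulting distance matrix worth mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset, minmax_scale, transpose_records
from .exceptions import NotScaledError

__all__ = ["AutoCM", "AutoCMResults", "TrainingTrace", "variable_map", "record_map"]


@dataclass
class TrainingTrace:
    """Per-epoch training diagnostics."""

    dv_max: list[float] = field(default_factory=list)  # max |α·Δv|/C per epoch
    dw_max: list[float] = field(default_factory=list)  # max |α·Δw| per epoch
    converged: bool = False

    @property
    def epochs(self) -> int:
        return len(self.dv_max)


class AutoCM:
    """Auto-contractive map over the variables of a scaled dataset.

    Parameters
    ----------
    data : Dataset or pandas.DataFrame
        P patterns × N units, all entries in [0, 1].  Use
        :func:`autocmap.minmax_scale` first for raw tables.
    C : float or {"half_n", "n_squared"}
        Contraction parameter (≥ 1).  Defaults to ``N/2``; ``N²`` is the
        common alternative convention and is exposed because the mapped
        topology should be (and is tested to be) insensitive to the choice.
    init : float
        Constant positive initial value for every connection.
    """

    def __init__(self, data, C: float | str = "half_n", init: float = 1e-4):
        if isinstance(data, Dataset):
            if not data.scaled:
                # accept unflagged data only if numerically in range
                arr = data.to_numpy()
                if arr.size and (arr.min() < 0 or arr.max() > 1):
                    raise NotScaledError("AutoCM requires inputs scaled to [0, 1]")
            frame = data.values
        else:
            frame = pd.DataFrame(data)
            arr = frame.to_numpy(float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise NotScaledError("AutoCM requires inputs scaled to [0, 1]")
        if frame.shape[1] < 2:
            raise ValueError("AutoCM needs at least 2 units (variables)")
        if frame.shape[0] < 2:
            raise ValueError("AutoCM needs at least 2 patterns (records)")
        self.patterns = frame.to_numpy(float)
        self.unit_names = [str(c) for c in frame.columns]
        self.n_units = frame.shape[1]
        self.n_patterns = frame.shape[0]
        if C == "half_n":
            self.C = self.n_units / 2
        elif C == "n_squared":
            self.C = float(self.n_units**2)
        else:
            self.C = float(C)
        if self.C < 1:
            raise ValueError("contraction parameter C must be ≥ 1")
        if not 0 < init < self.C:
            raise ValueError("init must lie in (0, C)")
        self.init = float(init)

    def fit(self, tol: float = 1e-6, max_epochs: int = 20000) -> "AutoCMResults":
        """Train to convergence (batch updates, one update per epoch).

        Stopping: the per-epoch relative change of ``v`` follows a logistic
        profile — tiny at the start, peaking mid-training, vanishing as
        ``v → C`` — so training stops once the change is below ``tol`` *and*
        no longer increasing, or at ``max_epochs``.
        """
        S = self.patterns
        C, alpha = self.C, 1.0 / self.n_patterns
        v = np.full(self.n_units, self.init)
        w = np.full((self.n_units, self.n_units), self.init)
        trace = TrainingTrace()
        prev_change = None
        for _ in range(max_epochs):
            contraction = 1.0 - v / C
            hidden = S * contraction
            dv = ((S - hidden) * contraction * S).sum(axis=0)
            net = hidden @ (1.0 - w / C).T
            out = hidden * (1.0 - net / C)
            dw = ((hidden - out).T @ hidden) * (1.0 - w / C)
            v = v + alpha * dv
            w = w + alpha * dw
            if not (np.isfinite(v).all() and np.isfinite(w).all()):
                raise FloatingPointError("AutoCM weights became non-finite")
            change = float(np.abs(alpha * dv).max() / C)
            trace.dv_max.append(change)
            trace.dw_max.append(float(np.abs(alpha * dw).max()))
            if prev_change is not None and change < tol and change <= prev_change:
                trace.converged = True
                break
            prev_change = change
        return AutoCMResults(self, v, w, trace)


@dataclass
class AutoCMResults:
    """Trained AutoCM state: mono-dedicated vector ``v``, full matrix ``w``."""

    model: AutoCM
    v: np.ndarray
    w: np.ndarray
    trace: TrainingTrace

    @property
    def C(self) -> float:
        return self.model.C

    @property
    def alpha(self) -> float:
        return 1.0 / self.model.n_patterns

    def distances(self) -> pd.DataFrame:
        """Symmetric unit-to-unit distance matrix ``d = C − (w + wᵀ)/2``.

        Diagonal forced to zero; tiny negative round-off is clamped at 0.
        Small distance = strong learned association.
        """
        d = self.C - (self.w + self.w.T) / 2
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        return pd.DataFrame(d, index=self.model.unit_names,
                            columns=self.model.unit_names)

    def to_json_dict(self) -> dict:
        return {
            "unit_names": self.model.unit_names,
            "C": self.C,
            "alpha": self.alpha,
            "epochs": self.trace.epochs,
            "converged": self.trace.converged,
            "v": self.v.tolist(),
            "w": self.w.tolist(),
        }

    def summary(self) -> str:
        lines = [
            "Auto-contractive map",
            "====================",
            f"units:        {self.model.n_units}",
            f"patterns:     {self.model.n_patterns}",
            f"C:            {self.C:g}",
            f"alpha:        {self.alpha:g}",
            f"epochs:       {self.trace.epochs}",
            f"converged:    {self.trace.converged}",
            f"min v/C:      {float(self.v.min()) / self.C:.6f}",
            f"max v/C:      {float(self.v.max()) / self.C:.6f}",
        ]
        d = self.distances().to_numpy()
        off = d[~np.eye(len(d), dtype=bool)]
        if off.size:
            lines.append(f"d range:      [{off.min():.4f}, {off.max():.4f}]")
        return "\n".join(lines)


def variable_map(ds: Dataset, **kwargs) -> pd.DataFrame:
    """Distance matrix over the *variables* of a raw dataset
    (scale → train → distances)."""
    return AutoCM(minmax_scale(ds), **kwargs).fit().distances()


def record_map(ds: Dataset, **kwargs) -> pd.DataFrame:
    """Distance matrix over the *records* of a raw dataset.

    Variables are min–max scaled first, then the transposed table (records
    as units, variables as patterns) is trained directly: after per-variable
    scaling every entry already lies in [0, 1], and re-scaling each record
    would erase the between-record level differences the map is meant to
    capture.
    """
    t = transpose_records(minmax_scale(ds))
    return AutoCM(t, **kwargs).fit().distances()
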