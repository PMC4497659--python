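"""Activation and Competition System (ACS): a multi-matrix associative
memory that turns a static dataset into a dynamic query engine.

ACS connects every pair of variables not by one weight but by a *vector* of
weights, one per metric.  Three metrics are built here, each a symmetric
N×N matrix with zero diagonal and entries in [−1, 1]:

* **linear** — the Pearson correlation of every variable pair;
* **prior**  — a co-occurrence log-odds for unit-interval data,
  ``ln[(Σ x_i x_j)(Σ (1−x_i)(1−x_j)) / (Σ x_i(1−x_j))(Σ (1−x_i)x_j)]``,
  smoothed and rescaled (sensitive to the frequency/distribution of the
  variables, which plain correlation is not);
* **autocm** — the trained auto-contractive-map weight matrix, rescaled
  (carries joint, not merely pairwise, structure).

Querying: an external drive (typically +1 on one target unit) is applied
and all units negotiate their activation in [−1, 1].  Per cycle, unit i
receives excitation through positive weights and inhibition through
negative ones, fan-in averaged per matrix and summed over matrices, scaled
by ``alpha``; the external drive adds ``beta · input`` on its own sign
side.  The update is the interactive-activation rule

``net_i = (Max−u_i)·E_i + (u_i−Min)·I_i − Dec_i·(u_i − Rest)``,
``δ_i = net_i (1 − u_i²)``, ``u_i ← clamp(u_i + δ_i)``,

with a per-unit decay that itself decays, ``Dec_i ← Dec_i·exp(−u_i²)``.
The cost ``H = Σ δ_i²`` decreases into an ε-ball; the fixed point is the
*prototype profile* of the queried target — the fuzzy membership of every
variable in the queried condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autocm import AutoCM, AutoCMResults
from .dataset import Dataset, minmax_scale
from .exceptions import NotScaledError

__all__ = [
    "MetricMatrix",
    "ACSConfig",
    "ActivationCompetitionSystem",
    "Prototype",
    "weights_linear_correlation",
    "weights_prior_probability",
    "weights_from_autocm",
    "build_metric_matrices",
    "acs_query_class",
]


@dataclass(frozen=True)
class MetricMatrix:
    """One symmetric association metric over the variables.

    Invariants: symmetric, zero diagonal, entries in [−1, 1].
    """

    kind: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("metric matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("metric matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise ValueError("metric matrix diagonal must be zero")
        if arr.size and (arr.min() < -1 - 1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("metric entries must lie in [-1, 1]")

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.values.columns]


def _centered_unit_scale(W: np.ndarray) -> np.ndarray:
    """Linear map of the off-diagonal entries into [−1, 1].

    Entries are centred at their mean and divided by the largest absolute
    deviation, so above-average associations come out positive and
    below-average ones negative.  (Mapping [min, max] onto [−1, 1] instead
    leaves a matrix with one extreme minimum — e.g. a complementary
    indicator pair — almost entirely positive, and a network with only
    excitation saturates uniformly.)  A constant off-diagonal maps to 0.
    """
    W = (W + W.T) / 2
    n = len(W)
    off = ~np.eye(n, dtype=bool)
    out = np.zeros_like(W, dtype=float)
    dev = W[off] - W[off].mean()
    peak = np.abs(dev).max() if dev.size else 0.0
    if peak > 1e-15:
        out[off] = dev / peak
    return out


def weights_linear_correlation(ds: Dataset) -> MetricMatrix:
    """Pearson correlation of every variable pair; zero diagonal.

    Zero-variance variables get an all-zero row/column (with a warning)
    rather than NaNs.
    """
    if ds.n_records < 2:
        raise ValueError("need at least 2 records")
    arr = ds.to_numpy()
    sd = arr.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance variables set to zero association: "
            f"{[n for n, f in zip(ds.variable_names, flat) if f]}", stacklevel=2)
    safe = arr.copy()
    safe[:, flat] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe.T)
    corr[np.isnan(corr)] = 0.0
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    frame = pd.DataFrame(corr, index=ds.variable_names, columns=ds.variable_names)
    return MetricMatrix("linear", frame)


def weights_prior_probability(ds: Dataset, smoothing: float | None = None) -> MetricMatrix:
    """Co-occurrence log-odds metric for unit-interval data.

    ``smoothing`` (default ``1/P²`` for P records) is added to each of the
    four co-occurrence sums to avoid log(0); the resulting matrix is then
    linearly rescaled into [−1, 1] so it is commensurable with the
    correlation metric.
    """
    arr = ds.to_numpy()
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise NotScaledError("prior-probability metric requires values in [0, 1]")
    p = ds.n_records
    s = 1.0 / p**2 if smoothing is None else float(smoothing)
    if s <= 0:
        raise ValueError("smoothing must be positive")
    both = arr.T @ arr + s
    neither = (1 - arr).T @ (1 - arr) + s
    only_i = arr.T @ (1 - arr) + s
    only_j = (1 - arr).T @ arr + s
    logodds = np.log((both * neither) / (only_i * only_j))
    frame = pd.DataFrame(_centered_unit_scale(logodds),
                         index=ds.variable_names, columns=ds.variable_names)
    return MetricMatrix("prior", frame)


def weights_from_autocm(result: AutoCMResults) -> MetricMatrix:
    """Trained auto-contractive-map weights rescaled into [−1, 1].

    The symmetrized hidden→output matrix is rescaled by the same centred
    linear map as the prior metric; the rank order of the associations is
    preserved.
    """
    if result.trace.epochs == 0:
        raise ValueError("AutoCM model has not been trained")
    frame = pd.DataFrame(_centered_unit_scale(result.w),
                         index=result.model.unit_names,
                         columns=result.model.unit_names)
    return MetricMatrix("autocm", frame)


# ---------------------------------------------------------------------------
# dynamics


@dataclass(frozen=True)
class ACSConfig:
    """Tunable constants of the ACS dynamics.

    ``max_activation``/``min_activation`` bound every unit; ``rest`` is the
    starting (and decay-target) activation; ``decay0`` the initial per-unit
    decay; ``alpha`` scales the internal net input, ``beta`` the external
    drive; iteration stops when the cost H drops below ``epsilon``.
    """

    alpha: float = 0.1
    beta: float = 1.0
    max_activation: float = 1.0
    min_activation: float = -1.0
    rest: float = -0.1
    decay0: float = 0.1
    epsilon: float = 1e-6
    max_cycles: int = 20000

    def __post_init__(self) -> None:
        if not self.min_activation < self.rest < self.max_activation:
            raise ValueError("need min < rest < max")
        if self.alpha <= 0 or self.beta <= 0 or self.epsilon <= 0:
            raise ValueError("alpha, beta and epsilon must be positive")


@dataclass
class Prototype:
    """Converged ACS state for one query."""

    activations: pd.Series        # final u per unit
    cycles: int
    energy: list[float]           # H per cycle
    converged: bool
    excitation: np.ndarray        # final E_i
    inhibition: np.ndarray        # final I_i
    decay: np.ndarray             # final Dec_i

    def summary(self) -> str:
        lines = ["ACS prototype", "=============",
                 f"cycles:    {self.cycles}",
                 f"converged: {self.converged}",
                 f"final H:   {self.energy[-1]:.3e}", ""]
        for name, val in self.activations.items():
            lines.append(f"  {name:<12s} {val:+.2f}")
        return "\n".join(lines)


class ActivationCompetitionSystem:
    """ACS over Q metric matrices of identical dimension and variable order."""

    def __init__(self, matrices: list[MetricMatrix], config: ACSConfig | None = None):
        if not matrices:
            raise ValueError("need at least one metric matrix")
        names = matrices[0].names
        for m in matrices[1:]:
            if m.names != names:
                raise ValueError("metric matrices disagree on variables")
        self.matrices = matrices
        self.names = names
        self.config = config or ACSConfig()

    def run(self, external_input) -> Prototype:
        """Iterate the dynamics under a persistent external drive.

        ``external_input`` is a mapping/Series/array of per-unit drives in
        [−1, 1]; unnamed units default to 0.  Non-convergence within
        ``max_cycles`` flags the result rather than raising.
        """
        cfg = self.config
        n = len(self.names)
        ext = np.zeros(n)
        if isinstance(external_input, dict):
            for key, val in external_input.items():
                if key not in self.names:
                    raise KeyError(f"unknown unit {key!r}")
                ext[self.names.index(key)] = val
        else:
            ext = np.asarray(pd.Series(external_input).reindex(self.names).fillna(0.0)
                             if isinstance(external_input, pd.Series)
                             else external_input, dtype=float)
            if ext.shape != (n,):
                raise ValueError("external input has wrong length")
        if np.abs(ext).max() > 1:
            raise ValueError("external input must lie in [-1, 1]")

        mats = [m.values.to_numpy(float) for m in self.matrices]
        positive = [np.where(w > 0, w, 0.0) for w in mats]
        negative = [np.where(w < 0, w, 0.0) for w in mats]
        n_exc = [(w > 0).sum(axis=1) for w in mats]   # positive fan-in counts
        n_inh = [(w < 0).sum(axis=1) for w in mats]

        u = np.full(n, cfg.rest)
        dec = np.full(n, cfg.decay0)
        ext_pos = np.where(ext > 0, cfg.beta * ext, 0.0)
        ext_neg = np.where(ext < 0, cfg.beta * ext, 0.0)
        energy: list[float] = []
        converged = False
        exc = inh = np.zeros(n)
        for cycle in range(1, cfg.max_cycles + 1):
            ecc = np.zeros(n)
            ini = np.zeros(n)
            for pos, neg, ne, ni in zip(positive, negative, n_exc, n_inh):
                ecc += np.where(ne > 0, (pos @ u) / np.where(ne > 0, ne, 1), 0.0)
                ini += np.where(ni > 0, (neg @ u) / np.where(ni > 0, ni, 1), 0.0)
            exc = cfg.alpha * ecc + ext_pos
            inh = cfg.alpha * ini + ext_neg
            net = ((cfg.max_activation - u) * exc
                   + (u - cfg.min_activation) * inh
                   - dec * (u - cfg.rest))
            delta = net * (1.0 - u**2)
            h = float(delta @ delta)
            energy.append(h)
            u = np.clip(u + delta, cfg.min_activation, cfg.max_activation)
            dec = dec * np.exp(-(u**2))
            if h < cfg.epsilon:
                converged = True
                break
        return Prototype(
            activations=pd.Series(u, index=self.names, name="activation"),
            cycles=cycle,
            energy=energy,
            converged=converged,
            excitation=exc,
            inhibition=inh,
            decay=dec,
        )

    def equilibrium_residual(self, proto: Prototype,
                             boundary_margin: float = 1e-3) -> np.ndarray:
        """Per-unit gap between the final activation and the closed-form
        interior fixed point ``u* = (Max·E − Min·I + Rest·Dec)/(E − I + Dec)``
        (the root of the net input).

        Units in a *boundary* equilibrium — net input still pushing outward
        while the activation sits within ``boundary_margin`` of its bound,
        where the barrier factor (1 − u²) silences the update — have no
        interior fixed point to compare against and report 0.
        """
        cfg = self.config
        u = proto.activations.to_numpy()
        e, i, dec = proto.excitation, proto.inhibition, proto.decay
        net = ((cfg.max_activation - u) * e + (u - cfg.min_activation) * i
               - dec * (u - cfg.rest))
        denom = e - i + dec
        with np.errstate(divide="ignore", invalid="ignore"):
            ustar = (cfg.max_activation * e - cfg.min_activation * i
                     + cfg.rest * dec) / denom
        res = np.abs(u - ustar)
        res[np.abs(denom) < 1e-12] = np.abs(net)[np.abs(denom) < 1e-12]
        boundary = (((net > 0) & (u >= cfg.max_activation - boundary_margin))
                    | ((net < 0) & (u <= cfg.min_activation + boundary_margin)))
        res[boundary] = 0.0
        return res


def build_metric_matrices(ds: Dataset, config: ACSConfig | None = None,
                          autocm_kwargs: dict | None = None) -> list[MetricMatrix]:
    """The three standard ACS metrics for a raw dataset: linear correlation,
    co-occurrence prior (on the scaled data) and trained AutoCM weights."""
    scaled = minmax_scale(ds)
    linear = weights_linear_correlation(ds)
    prior = weights_prior_probability(scaled)
    fit = AutoCM(scaled, **(autocm_kwargs or {})).fit()
    return [linear, prior, weights_from_autocm(fit)]


def acs_query_class(ds: Dataset, target: str,
                    config: ACSConfig | None = None,
                    autocm_kwargs: dict | None = None) -> Prototype:
    """Prototype profile of ``target``: build the three metrics from the
    dataset, drive the target unit with +1 and run to the attractor."""
    if target not in ds.variable_names:
        raise KeyError(f"unknown target variable {target!r}")
    matrices = build_metric_matrices(ds, config, autocm_kwargs)
    system = ActivationCompetitionSystem(matrices, config)
    return system.run({target: 1.0})
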