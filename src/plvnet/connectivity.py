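"""Phase-locking value (PLV) connectivity estimation.

The PLV between two signals is the modulus of the mean unit phasor of
their instantaneous phase difference,

    PLV = | (1/T) sum_t exp( i (phi_i(t) - phi_j(t)) ) |,

1 for perfect locking, ~1/sqrt(T) for independent phases.  Instantaneous
phase comes from the analytic (Hilbert) signal of band-limited input.  One
symmetric node x node matrix is produced per subject x condition x emotion
cell, averaging per-epoch time-resolved PLV across epochs (default) or,
optionally, cross-trial PLV across epochs at each time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .simulate import EpochArray

__all__ = ["PhaseArray", "ConnectivityMatrix", "instantaneous_phase", "plv", "plv_matrix"]


class DegenerateInputError(ValueError):
    """Raised when a phase estimate is requested for an all-zero signal."""


@dataclass
class PhaseArray:
    """Instantaneous phase in radians, wrapped to (-pi, pi]."""

    phase: np.ndarray  # epochs x nodes x samples
    fs_hz: float
    t0_s: float
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be epochs x nodes x samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.phase.shape[2]) / self.fs_hz


@dataclass
class ConnectivityMatrix:
    """Symmetric PLV matrix for one design cell."""

    plv: np.ndarray
    node_labels: list[str]
    cell: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        self.plv = np.asarray(self.plv, dtype=float)
        n = self.plv.shape[0]
        if self.plv.shape != (n, n):
            raise ValueError("plv must be square")
        if not np.allclose(self.plv, self.plv.T, atol=1e-10):
            raise ValueError("plv must be symmetric")
        if not np.allclose(np.diag(self.plv), 1.0, atol=1e-10):
            raise ValueError("plv diagonal must be 1")
        if self.plv.min() < -1e-12 or self.plv.max() > 1 + 1e-12:
            raise ValueError("plv entries must lie in [0, 1]")
        if len(self.node_labels) != n:
            raise ValueError("one label per node required")

    @property
    def n_nodes(self) -> int:
        return self.plv.shape[0]


def instantaneous_phase(epochs: EpochArray) -> PhaseArray:
    """Analytic-signal phase per epoch and node.

    Input must already be band-limited to the analysis band; for a pure
    cosine the unwrapped phase advances at 2*pi*f rad/s.  All-zero traces
    have undefined phase and raise ``DegenerateInputError``.
    """
    data = epochs.data
    if np.any(np.ptp(data, axis=2) == 0.0):
        raise DegenerateInputError("constant (e.g. all-zero) trace has undefined phase")
    analytic = hilbert(data, axis=2)
    return PhaseArray(
        phase=np.angle(analytic),
        fs_hz=epochs.fs_hz,
        t0_s=epochs.t0_s,
        node_labels=epochs.node_labels,
    )


def plv(phases_i: np.ndarray, phases_j: np.ndarray) -> float:
    """PLV between two equal-length phase series."""
    pi_, pj = np.asarray(phases_i, float), np.asarray(phases_j, float)
    if pi_.shape != pj.shape:
        raise ValueError("phase series must have equal length")
    if pi_.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (pi_ - pj)))))


def plv_matrix(
    phases: PhaseArray,
    window: tuple[float, float] | None = None,
    edge_trim_s: float = 0.0,
    mode: str = "time",
) -> ConnectivityMatrix:
    """All-pairs PLV matrix, averaged across epochs.

    Parameters
    ----------
    window
        (start, end) in seconds on the epoch time axis; defaults to the
        full epoch.  Samples with ``start <= t <= end`` enter the estimate.
    edge_trim_s
        Additional margin removed from each epoch border before applying
        the window, suppressing Hilbert edge artifacts.
    mode
        ``"time"`` (default): PLV over time within each epoch, then the
        arithmetic mean across epochs.  ``"trials"``: PLV across epochs at
        each retained time point, then the mean over time.
    """
    if mode not in ("time", "trials"):
        raise ValueError("mode must be 'time' or 'trials'")
    t = phases.times
    lo = t[0] + edge_trim_s
    hi = t[-1] - edge_trim_s
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("window selects fewer than 2 samples")

    ph = phases.phase[:, :, mask]
    z = np.exp(1j * ph)  # epochs x nodes x T
    if mode == "time":
        # per-epoch Gram matrix of unit phasors, |.| then mean over epochs
        gram = np.einsum("ent,emt->enm", z, z.conj()) / ph.shape[2]
        mat = np.abs(gram).mean(axis=0)
    else:
        gram = np.einsum("ent,emt->tnm", z, z.conj()) / ph.shape[0]
        mat = np.abs(gram).mean(axis=0)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    labels = phases.node_labels or [f"node{i}" for i in range(mat.shape[0])]
    return ConnectivityMatrix(plv=mat, node_labels=list(labels))
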