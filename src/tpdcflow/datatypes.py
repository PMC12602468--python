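"""Core containers for network time series and connectivity matrices.

Orientation convention, fixed project-wide: for every N x N connectivity
matrix, **columns index the source j and rows index the target i**, so entry
(i, j) is the directed influence j -> i. Every file this package writes
states this convention in its header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Yeo-7 cortical network labels, in the fixed column order used throughout:
#: visual, somatomotor, dorsal attention, ventral attention (salience),
#: limbic, frontoparietal control, default mode.
YEO7_CHANNELS = ("VIS", "SMN", "DAN", "VAN", "LIN", "FPN", "DMN")

#: Resting-state BOLD band of interest (Hz).
DEFAULT_BAND = (0.009, 0.08)

MATRIX_KINDS = ("tpdc", "binary", "threshold", "frequency")


@dataclass
class TimeSeriesSet:
    """One subject's T x N multivariate series.

    Rows are time points sampled every ``tr`` seconds; columns are named
    channels (brain networks).
    """

    subject_id: str
    data: np.ndarray
    channels: tuple[str, ...]
    tr: float
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(str(c) for c in self.channels)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x N), got shape {self.data.shape}")
        t, n = self.data.shape
        if n < 2:
            raise ValueError(f"need at least 2 channels, got {n}")
        if len(self.channels) != n:
            raise ValueError(
                f"{len(self.channels)} channel names for {n} data columns"
            )
        if len(set(self.channels)) != n:
            raise ValueError(f"channel names not unique: {self.channels}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column "
                f"{self.channels[bad[1]]!r}"
            )
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 0.5 / self.tr

    def check_length(self, order: int) -> None:
        """Require T >= 2*order + 10, the minimum for a meaningful AR fit."""
        if self.n_times < 2 * order + 10:
            raise ValueError(
                f"series too short: T={self.n_times} < 2*{order}+10 "
                f"(subject {self.subject_id!r})"
            )


@dataclass
class MatrixRecord:
    """A labelled N x N connectivity matrix of a declared kind.

    ``kind`` is one of 'tpdc' (nonnegative directed-influence strengths),
    'binary' (0/1 significance), 'threshold' (per-cell cutoffs) or
    'frequency' (integer counts across subjects). Entry (i, j) is always
    the influence of column-channel j on row-channel i. The tpdc diagonal
    is reported for completeness but carries no inferential meaning
    downstream (self-influence dominates the column normalization).
    """

    subject_id: str
    values: np.ndarray
    kind: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channels = tuple(str(c) for c in self.channels)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} channels"
            )
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains non-finite values")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary matrix must contain only 0 and 1")
        if self.kind in ("tpdc", "threshold", "frequency") and (self.values < 0).any():
            raise ValueError(f"{self.kind} matrix must be nonnegative")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class TVARModel:
    """Time-resolved MVAR(p) model: one set of lag matrices per time point.

    ``coeffs`` has shape (T_est, p, N, N): coeffs[t, k-1] is A_k at the
    t-th estimated time point. The estimation range covers original sample
    indices p .. T-1 (the first p samples only seed the lags).
    """

    order: int
    coeffs: np.ndarray
    innovation_cov: np.ndarray
    channels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        n = len(self.channels)
        if self.coeffs.ndim != 4 or self.coeffs.shape[1:] != (self.order, n, n):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} incompatible with "
                f"p={self.order}, N={n}"
            )
        if not np.isfinite(self.coeffs).all():
            raise ValueError("coefficient trajectory contains non-finite values")
        if self.innovation_cov.shape != (n, n):
            raise ValueError("innovation_cov must be N x N")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T, atol=1e-10):
            raise ValueError("innovation_cov must be symmetric")
        eigs = np.linalg.eigvalsh(0.5 * (self.innovation_cov + self.innovation_cov.T))
        if eigs.min() < -1e-10:
            raise ValueError("innovation_cov must be positive semidefinite")

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def time_average(self) -> np.ndarray:
        """Mean coefficient matrices over the estimation range, (p, N, N)."""
        return self.coeffs.mean(axis=0)


@dataclass
class SpectralTransfer:
    """Complex transfer matrices Abar(f, t) = I - sum_k A_k(t) e^{-i 2 pi f k TR}.

    ``values`` has shape (F, T_est, N, N); ``freqs`` are in Hz.
    """

    freqs: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        n = len(self.channels)
        if self.values.ndim != 4 or self.values.shape[-2:] != (n, n):
            raise ValueError(f"values shape {self.values.shape} incompatible with N={n}")
        if self.values.shape[0] != self.freqs.size:
            raise ValueError("frequency axis does not match freqs grid")


@dataclass
class TPDCMatrix:
    """Band- and time-averaged TPDC: entry (i, j) = mean pi_ij over the band."""

    values: np.ndarray
    band: tuple[float, float]
    channels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} for {n} channels")
        if (self.values < 0).any() or (self.values > 1 + 1e-9).any():
            raise ValueError("TPDC values must lie in [0, 1]")

    def to_record(self) -> MatrixRecord:
        return MatrixRecord(
            subject_id=self.subject_id,
            values=self.values,
            kind="tpdc",
            channels=self.channels,
        )


@dataclass
class BootstrapNull:
    """Subject-level surrogate null for TPDC thresholds.

    ``surrogates`` holds one TPDC matrix per window-shuffle, shape
    (n_shuffles, N, N); ``threshold`` is the per-cell percentile cutoff.
    """

    n_shuffles: int
    window_len: int
    percentile: float
    surrogates: np.ndarray
    threshold: np.ndarray
    channels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.surrogates = np.asarray(self.surrogates, dtype=float)
        self.threshold = np.asarray(self.threshold, dtype=float)
        n = len(self.channels)
        if self.surrogates.shape != (self.n_shuffles, n, n):
            raise ValueError("surrogate stack shape mismatch")
        if self.threshold.shape != (n, n):
            raise ValueError("threshold shape mismatch")
        if (self.threshold < 0).any():
            raise ValueError("thresholds must be nonnegative")


@dataclass
class GroupNull:
    """Group-level permutation null over a stack of binary adjacencies."""

    n_perm: int
    percentile: float
    observed_frequency: np.ndarray
    null_frequencies: np.ndarray
    threshold: np.ndarray
    significant: np.ndarray
    channels: tuple[str, ...]
    n_subjects: int = 0

    def __post_init__(self) -> None:
        n = len(self.channels)
        for name in ("observed_frequency", "threshold", "significant"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n, n):
                raise ValueError(f"{name} shape {arr.shape} for {n} channels")
        self.null_frequencies = np.asarray(self.null_frequencies, dtype=float)
        if self.null_frequencies.shape != (self.n_perm, n, n):
            raise ValueError("null_frequencies shape mismatch")
        if self.n_subjects and (
            (self.observed_frequency < 0).any()
            or (self.observed_frequency > self.n_subjects).any()
        ):
            raise ValueError("observed frequency outside [0, n_subjects]")
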