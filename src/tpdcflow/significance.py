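"""Significance thresholding of TPDC matrices.

Two levels of inference:

*Subject level* — window-shuffle bootstrap. The series is cut into
non-overlapping blocks whose order is randomly permuted, the full TPDC
pipeline is recomputed on each surrogate, and the per-cell percentile
(default 99th over 100 shuffles) of the surrogate TPDC values becomes the
significance threshold. Cells whose observed TPDC strictly exceeds the
threshold are set to 1, all others to 0.

Block shuffling is applied independently per channel by default: that
destroys the cross-channel lag alignment the TPDC measures while keeping
each channel's local autocorrelation, which is exactly the null the
threshold needs. (A joint shuffle, which permutes the same block order in
every channel, leaves within-block cross-lag structure intact and is
available via ``per_channel=False`` for surrogate schemes that only target
slow nonstationarity.)

*Group level* — permutation test on the stack of binary subject matrices.
The observed frequency matrix counts, per directed connection, how many
subjects show it. Each permutation shuffles every subject's off-diagonal
cells (preserving that subject's edge count), re-aggregates, and the
per-cell percentile of the permuted frequencies (default 99th over 1,000
permutations) is the group threshold; observed frequencies strictly above
it mark group-significant directed connections.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    DEFAULT_BAND,
    BootstrapNull,
    GroupNull,
    MatrixRecord,
    TimeSeriesSet,
    TPDCMatrix,
)
from .tpdc import EKFConfig, estimate_tpdc_batch


def surrogate_series(
    x: TimeSeriesSet,
    window_len: int,
    seed: int | np.random.Generator = 0,
    per_channel: bool = True,
) -> TimeSeriesSet:
    """Window-shuffled surrogate: permute non-overlapping blocks of the series.

    The series is partitioned into floor(T / window_len) consecutive blocks
    (trailing remainder dropped) and the block order is uniformly permuted —
    independently for every channel by default, or jointly across channels
    with ``per_channel=False``. Deterministic given the seed.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if x.n_times < 2 * window_len:
        raise ValueError(
            f"window too long: T={x.n_times} < 2*window_len={2 * window_len}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = _shuffle_blocks(x.data[None], window_len, rng, per_channel)[0]
    return TimeSeriesSet(
        subject_id=f"{x.subject_id}_surrogate",
        data=data,
        channels=x.channels,
        tr=x.tr,
        group=x.group,
    )


def _shuffle_blocks(
    data: np.ndarray, window_len: int, rng: np.random.Generator, per_channel: bool
) -> np.ndarray:
    """Block-permute a (B, T, N) stack; one independent permutation per (b[, n])."""
    b, t, n = data.shape
    n_blocks = t // window_len
    blocks = data[:, : n_blocks * window_len].reshape(b, n_blocks, window_len, n)
    if per_channel:
        out = np.empty_like(blocks)
        for i in range(b):
            for c in range(n):
                perm = rng.permutation(n_blocks)
                out[i, :, :, c] = blocks[i, perm, :, c]
    else:
        out = np.empty_like(blocks)
        for i in range(b):
            perm = rng.permutation(n_blocks)
            out[i] = blocks[i, perm]
    return out.reshape(b, n_blocks * window_len, n)


def bootstrap_threshold(
    x: TimeSeriesSet,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    window_len: int = 10,
    seed: int | np.random.Generator = 0,
    order: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    cfg: EKFConfig | None = None,
    per_channel: bool = True,
) -> tuple[TPDCMatrix, BootstrapNull]:
    """Observed TPDC plus its window-shuffle bootstrap null for one subject.

    The full TPDC pipeline is recomputed on every surrogate (all shuffles
    are filtered in one batched pass together with the observed series);
    the per-cell threshold is the requested percentile of that cell's
    n_shuffles surrogate values.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if x.n_times < 2 * window_len:
        raise ValueError(
            f"window too long: T={x.n_times} < 2*window_len={2 * window_len}"
        )
    n_blocks = x.n_times // window_len
    t_sur = n_blocks * window_len
    # batch: observed series first (truncated to the surrogate length so all
    # members share T and see the same estimation conditions), then surrogates
    stack = np.empty((n_shuffles + 1, t_sur, x.n_channels))
    stack[0] = x.data[:t_sur]
    stack[1:] = _shuffle_blocks(
        np.broadcast_to(x.data[:t_sur], (n_shuffles, t_sur, x.n_channels)),
        window_len,
        rng,
        per_channel,
    )
    mats = estimate_tpdc_batch(
        stack, tr=x.tr, p=order, band=band, cfg=cfg, channels=x.channels
    )
    observed = mats[0]
    observed.subject_id = x.subject_id
    surrogates = np.stack([m.values for m in mats[1:]])
    threshold = np.percentile(surrogates, percentile, axis=0)
    null = BootstrapNull(
        n_shuffles=n_shuffles,
        window_len=window_len,
        percentile=percentile,
        surrogates=surrogates,
        threshold=threshold,
        channels=x.channels,
        subject_id=x.subject_id,
    )
    return observed, null


def binarize(tpdc: TPDCMatrix, null: BootstrapNull) -> MatrixRecord:
    """1 where observed TPDC strictly exceeds the threshold, else 0; diagonal 0."""
    if tpdc.channels != null.channels:
        raise ValueError(
            f"channel mismatch: {tpdc.channels} vs {null.channels}"
        )
    binary = (tpdc.values > null.threshold).astype(float)
    np.fill_diagonal(binary, 0.0)
    return MatrixRecord(
        subject_id=tpdc.subject_id or null.subject_id,
        values=binary,
        kind="binary",
        channels=tpdc.channels,
    )


def subject_binary_adjacency(
    x: TimeSeriesSet,
    n_shuffles: int = 100,
    percentile: float = 99.0,
    window_len: int = 10,
    seed: int | np.random.Generator = 0,
    order: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    cfg: EKFConfig | None = None,
) -> tuple[TPDCMatrix, MatrixRecord]:
    """Convenience: observed TPDC and its bootstrap-thresholded binary matrix."""
    observed, null = bootstrap_threshold(
        x,
        n_shuffles=n_shuffles,
        percentile=percentile,
        window_len=window_len,
        seed=seed,
        order=order,
        band=band,
        cfg=cfg,
    )
    return observed, binarize(observed, null)


def group_significance(
    binaries: list[MatrixRecord],
    n_perm: int = 1000,
    percentile: float = 99.0,
    seed: int | np.random.Generator = 0,
    mode: str = "flat",
) -> GroupNull:
    """Permutation test on the cellwise sum of binary subject matrices.

    mode='flat' (default): each permutation independently shuffles each
    subject's 42 off-diagonal cells uniformly, preserving that subject's
    total edge count. mode='margins': shuffles within each target row
    (preserving per-target in-degrees as well). The per-cell threshold is
    the requested percentile of the n_perm permuted frequencies; observed
    frequency strictly above it marks a significant group edge. The
    diagonal is excluded throughout.
    """
    if len(binaries) < 2:
        raise ValueError("need at least 2 subjects")
    if mode not in ("flat", "margins"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    channels = binaries[0].channels
    n = len(channels)
    stack = np.empty((len(binaries), n, n))
    for s, rec in enumerate(binaries):
        if rec.kind != "binary":
            raise ValueError(
                f"subject {rec.subject_id!r} matrix kind {rec.kind!r}, expected binary"
            )
        if rec.channels != channels:
            raise ValueError(f"channel mismatch for subject {rec.subject_id!r}")
        stack[s] = rec.values
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    off_mask = ~np.eye(n, dtype=bool)
    observed = stack.sum(axis=0)
    observed[~off_mask] = 0.0

    n_sub = len(binaries)
    null = np.empty((n_perm, n, n))
    if mode == "flat":
        cells = stack[:, off_mask]  # (S, n*(n-1))
        for r in range(n_perm):
            permuted = rng.permuted(cells, axis=1)
            freq = np.zeros((n, n))
            freq[off_mask] = permuted.sum(axis=0)
            null[r] = freq
    else:  # margins: permute within each target row's off-diagonal cells
        for r in range(n_perm):
            freq = np.zeros((n, n))
            for s in range(n_sub):
                for i in range(n):
                    idx = np.flatnonzero(off_mask[i])
                    freq[i, idx[rng.permutation(idx.size)]] += stack[s, i, idx]
            null[r] = freq
    threshold = np.percentile(null, percentile, axis=0)
    threshold[~off_mask] = 0.0
    significant = (observed > threshold).astype(float)
    significant[~off_mask] = 0.0
    return GroupNull(
        n_perm=n_perm,
        percentile=percentile,
        observed_frequency=observed,
        null_frequencies=null,
        threshold=threshold,
        significant=significant,
        channels=channels,
        n_subjects=n_sub,
    )


def cohort_binary_adjacencies(
    subjects: list[TimeSeriesSet],
    n_shuffles: int = 100,
    percentile: float = 99.0,
    window_len: int = 10,
    seed: int | np.random.Generator = 0,
    order: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    cfg: EKFConfig | None = None,
) -> tuple[list[TPDCMatrix], list[MatrixRecord]]:
    """Bootstrap-threshold a whole cohort in one batched filter pass.

    Equivalent to calling :func:`bootstrap_threshold` + :func:`binarize`
    per subject, but the (observed + n_shuffles surrogates) stacks of all
    subjects are filtered together, which is substantially faster when
    subjects share T, N and TR.
    """
    if not subjects:
        raise ValueError("empty cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = subjects[0].n_times
    n = subjects[0].n_channels
    channels = subjects[0].channels
    tr = subjects[0].tr
    for s in subjects[1:]:
        if s.n_times != t or s.channels != channels or s.tr != tr:
            raise ValueError("cohort subjects must share T, channels and TR")
    if t < 2 * window_len:
        raise ValueError(f"window too long: T={t} < 2*window_len={2 * window_len}")
    n_blocks = t // window_len
    t_sur = n_blocks * window_len
    per = n_shuffles + 1
    stack = np.empty((len(subjects) * per, t_sur, n))
    for k, s in enumerate(subjects):
        stack[k * per] = s.data[:t_sur]
        stack[k * per + 1 : (k + 1) * per] = _shuffle_blocks(
            np.broadcast_to(s.data[:t_sur], (n_shuffles, t_sur, n)),
            window_len,
            rng,
            per_channel=True,
        )
    mats = estimate_tpdc_batch(
        stack, tr=tr, p=order, band=band, cfg=cfg, channels=channels
    )
    observed_list, binary_list = [], []
    for k, s in enumerate(subjects):
        observed = mats[k * per]
        observed.subject_id = s.subject_id
        surrogates = np.stack(
            [m.values for m in mats[k * per + 1 : (k + 1) * per]]
        )
        null = BootstrapNull(
            n_shuffles=n_shuffles,
            window_len=window_len,
            percentile=percentile,
            surrogates=surrogates,
            threshold=np.percentile(surrogates, percentile, axis=0),
            channels=channels,
            subject_id=s.subject_id,
        )
        observed_list.append(observed)
        binary_list.append(binarize(observed, null))
    return observed_list, binary_list


def edge_recovery_scores(
    significant: np.ndarray, truth_adjacency: np.ndarray
) -> tuple[float, float]:
    """(sensitivity, false-positive rate) of a significant-edge set vs truth.

    Both matrices are off-diagonal binary; sensitivity = detected true
    edges / true edges, FPR = detected non-edges / non-edges.
    """
    n = truth_adjacency.shape[0]
    off = ~np.eye(n, dtype=bool)
    sig = significant[off].astype(bool)
    tru = truth_adjacency[off].astype(bool)
    sens = float(sig[tru].mean()) if tru.any() else float("nan")
    fpr = float(sig[~tru].mean()) if (~tru).any() else float("nan")
    return sens, fpr
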