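"""Time-varying MVAR estimation (dual extended Kalman filter) and TPDC.

The estimation model is a vector autoregression whose coefficients drift
over time,

    x(t) = sum_{k=1..p} A_k(t) x(t-k) + e(t),

fit by two Kalman filters run forward in parallel: a *state* filter that
estimates the signal given the current coefficients, and a *parameter*
filter whose state is the vectorized coefficients with random-walk
dynamics, driven by the state filter's output. Coefficients are
initialized from a stationary ordinary-least-squares AR fit.

From the coefficient trajectory, the spectral transfer matrix

    Abar(f, t) = I - sum_k A_k(t) exp(-i 2 pi f k TR)

yields temporal partial directed coherence (TPDC),

    pi_ij(f, t) = |Abar_ij(f, t)| / sqrt(sum_m |Abar_mj(f, t)|^2),

the column-normalized directed influence of channel j on channel i, with
sum_i pi_ij^2 = 1 for every source column j at each (f, t). Band-averaged
matrices take the arithmetic mean of pi over the frequency bins inside the
band of interest (default 0.009-0.08 Hz, the resting-state BOLD range) and
over time after an initial burn fraction.

All heavy routines are batched over a leading axis so a subject and its
window-shuffled surrogates (or a whole cohort) are filtered in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    DEFAULT_BAND,
    SpectralTransfer,
    TimeSeriesSet,
    TPDCMatrix,
    TVARModel,
)


@dataclass
class EKFConfig:
    """Tuning constants for the dual extended Kalman filter.

    process_noise
        Variance of the coefficient random walk per step (drives how fast
        the parameter filter can track changes; larger = faster, noisier).
    init_param_cov
        Initial coefficient covariance around the OLS initialization.
    state_noise
        Observation-noise variance assumed by the state filter.
    n_freqs
        Uniform frequency-grid size over (0, Nyquist].
    burn_fraction
        Fraction of the initial estimation range excluded from time
        averaging (filter transient).
    divergence_cap
        Hard cap on the mean parameter-covariance trace; exceeding it
        raises with the offending time index.
    """

    process_noise: float = 3e-7
    init_param_cov: float = 1e-4
    state_noise: float = 1e-2
    n_freqs: int = 128
    burn_fraction: float = 0.1
    divergence_cap: float = 1e6

    def __post_init__(self) -> None:
        for name in ("process_noise", "init_param_cov", "state_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_freqs < 8:
            raise ValueError("n_freqs must be >= 8")
        if not 0.0 <= self.burn_fraction <= 0.5:
            raise ValueError("burn_fraction must be in [0, 0.5]")


class EKFDivergenceError(RuntimeError):
    """Raised when the parameter-filter covariance blows up."""

    def __init__(self, t: int, trace: float, cap: float):
        self.t = t
        super().__init__(
            f"dual EKF diverged at time index {t}: parameter covariance "
            f"trace {trace:.3g} exceeds cap {cap:.3g}"
        )


# ---------------------------------------------------------------------------
# stationary OLS initialization


def _lag_design(y: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched lag design: Z[b, t] = [y_{t-1}, ..., y_{t-p}], targets y_t."""
    b, t, n = y.shape
    z = np.concatenate([y[:, p - k - 1 : t - k - 1, :] for k in range(p)], axis=2)
    return z, y[:, p:, :]


def _ols_var_batch(y: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS multivariate AR(p) per batch member.

    Returns (A, sigma): A with shape (B, N, N*p) where A[:, i, k*N+c] is the
    lag-(k+1) influence of channel c on channel i, and sigma the (B, N, N)
    residual covariance.
    """
    b, t, n = y.shape
    z, x = _lag_design(y, p)
    m = t - p
    gram = z.transpose(0, 2, 1) @ z
    cross = z.transpose(0, 2, 1) @ x
    try:
        beta = np.linalg.solve(gram, cross)  # (B, N*p, N)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "rank-deficient regressor matrix in stationary AR fit"
        ) from None
    resid = x - z @ beta
    dof = max(m - n * p, 1)
    sigma = resid.transpose(0, 2, 1) @ resid / dof
    return beta.transpose(0, 2, 1), sigma


def fit_stationary_var(x: TimeSeriesSet, p: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Stationary least-squares MVAR(p) fit (each channel on all p lags).

    Channels are demeaned before fitting. Returns stacked coefficient
    matrices with shape (p, N, N) — element (k, i, j) is the lag-(k+1)
    influence of channel j on channel i — and the residual covariance.
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    if x.n_times <= x.n_channels * p + 10:
        raise ValueError(
            f"series too short for OLS AR({p}) fit: T={x.n_times} <= "
            f"N*p+10={x.n_channels * p + 10}"
        )
    y = x.data - x.data.mean(axis=0)
    a, sigma = _ols_var_batch(y[None], p)
    n = x.n_channels
    coeffs = a[0].reshape(n, p, n).transpose(1, 0, 2)
    return coeffs, sigma[0]


# ---------------------------------------------------------------------------
# dual EKF core (batched)


def _band_phases(freqs: np.ndarray, p: int, tr: float) -> np.ndarray:
    """exp(-i 2 pi f k TR) for k = 1..p; shape (F, p)."""
    k = np.arange(1, p + 1)
    return np.exp(-2j * np.pi * freqs[:, None] * k[None, :] * tr)


def _pi_from_coeff_batch(a: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """TPDC from batched coefficient matrices.

    a: (B, N, N*p) stacked coefficients; phases: (F, p).
    Returns pi with shape (B, F, N, N).
    """
    b, n, np_ = a.shape
    p = np_ // n
    ak = a.reshape(b, n, p, n).transpose(0, 2, 1, 3)  # (B, p, N, N)
    abar = np.eye(n) - np.einsum("fk,bkic->bfic", phases, ak)
    mag2 = abar.real**2 + abar.imag**2
    colsum = mag2.sum(axis=2)  # (B, F, N), sum over targets i
    if (colsum <= 0).any():
        bad = np.argwhere(colsum <= 0)[0]
        raise ZeroDivisionError(
            f"degenerate transfer column {bad[2]} at frequency index {bad[1]}"
        )
    return np.sqrt(mag2 / colsum[:, :, None, :])


def _dual_ekf_batch(
    y: np.ndarray,
    p: int,
    cfg: EKFConfig,
    store_coeffs: bool = True,
    band_freqs: np.ndarray | None = None,
    tr: float = 2.0,
) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Run the dual EKF forward once over a batch of series.

    y: (B, T, N), already demeaned. Returns (coeffs, band_pi, sigma):
    coeffs (B, T-p, N, N*p) if store_coeffs, else None; band_pi (B, N, N)
    band- and time-averaged TPDC if band_freqs given, else None; sigma the
    (B, N, N) OLS innovation covariance used by the filters.

    The parameter filter's random-walk and observation covariances are
    structured as Sigma (x) q*I and Sigma respectively (Sigma = innovation
    covariance), which makes the full N^2*p-dimensional Kalman recursion
    collapse exactly to a single (N*p)-dimensional covariance Pi shared by
    all target channels: P_w(t) = Sigma (x) Pi(t). The update is then the
    classic shared-regressor recursive-least-squares form, identical for
    every row of A, and invariant to the overall signal scale.
    """
    b, t, n = y.shape
    npl = n * p  # lag-stack / regressor dimension

    a, sigma = _ols_var_batch(y, p)  # (B, N, NP), (B, N, N)

    # parameter filter: coefficients A and shared regressor covariance Pi
    pi_cov = np.broadcast_to(np.eye(npl) * cfg.init_param_cov, (b, npl, npl)).copy()
    q = cfg.process_noise
    q_eye = np.eye(npl) * q

    # state filter: lag-stack z = [x_t; x_{t-1}; ...], covariance P_z
    z = y[:, :p][:, ::-1].reshape(b, npl).copy()  # [y_{p-1}, ..., y_0]
    p_z = np.broadcast_to(np.eye(npl) * cfg.state_noise, (b, npl, npl)).copy()
    r_eye = np.eye(n) * cfg.state_noise

    coeffs = np.empty((b, t - p, n, npl))

    shift = np.zeros((npl, npl))  # companion lower block: identity shift
    if p > 1:
        shift[n:, :-n] = np.eye(npl - n)

    for ti in range(p, t):
        obs = y[:, ti, :]  # (B, N)

        # --- parameter filter: random-walk predict, then RLS-form update
        pi_cov += q_eye
        g = np.einsum("bmn,bn->bm", pi_cov, z)  # Pi z, (B, NP)
        c = 1.0 + np.einsum("bm,bm->b", z, g)
        innov = obs - np.einsum("bim,bm->bi", a, z)
        a = a + innov[:, :, None] * (g / c[:, None])[:, None, :]
        pi_cov -= g[:, :, None] * g[:, None, :] / c[:, None, None]
        pi_cov += pi_cov.transpose(0, 2, 1)
        pi_cov *= 0.5

        tr_pw = np.einsum("bmm->b", pi_cov).mean()
        if not np.isfinite(tr_pw) or tr_pw > cfg.divergence_cap:
            raise EKFDivergenceError(ti, float(tr_pw), cfg.divergence_cap)

        coeffs[:, ti - p] = a

        # --- state filter: predict with updated A (companion form), update
        zp = np.einsum("bim,bm->bi", a, z)  # top block
        if p > 1:
            zp = np.concatenate([zp, z[:, :-n]], axis=1)
            f_mat = np.broadcast_to(shift, (b, npl, npl)).copy()
            f_mat[:, :n, :] = a
        else:
            f_mat = a
        pzp = f_mat @ p_z @ f_mat.transpose(0, 2, 1)
        pzp[:, :n, :n] += sigma
        s_z = pzp[:, :n, :n] + r_eye
        k_z = pzp[:, :, :n] @ np.linalg.inv(s_z)  # (B, NP, N)
        z = zp + np.einsum("bmn,bn->bm", k_z, obs - zp[:, :n])
        p_z = pzp - k_z @ pzp[:, :n, :]
        p_z += p_z.transpose(0, 2, 1)
        p_z *= 0.5

    band_pi = None
    if band_freqs is not None:
        burn = int(np.floor(cfg.burn_fraction * (t - p)))
        post = coeffs[:, burn:]
        n_post = post.shape[1]
        freqs = np.asarray(band_freqs, float)
        if p == 1:
            band_pi = _band_pi_var1(post, freqs, tr)
        else:
            phases = _band_phases(freqs, p, tr)
            accum = np.zeros((b, n, n))
            chunk = max(1, int(2e5 // max(b, 1)))
            for s0 in range(0, n_post, chunk):
                blk = post[:, s0 : s0 + chunk]
                bb, tt = blk.shape[:2]
                pi_blk = _pi_from_coeff_batch(
                    blk.reshape(bb * tt, n, npl), phases
                ).reshape(bb, tt, phases.shape[0], n, n)
                accum += pi_blk.mean(axis=2).sum(axis=1)
            band_pi = accum / n_post
    return (coeffs if store_coeffs else None), band_pi, sigma


def _band_pi_var1(coeffs: np.ndarray, freqs: np.ndarray, tr: float) -> np.ndarray:
    """Band- and time-averaged TPDC for p=1, exact closed form.

    With Abar(f) = I - A e^{-i theta_f}, |Abar_ij|^2 = a_ij^2 off the
    diagonal (frequency-independent) and 1 - 2 a_jj cos(theta_f) + a_jj^2
    on it, so the frequency mean factorizes and no complex arithmetic is
    needed. coeffs: (B, T', N, N); returns (B, N, N).
    """
    b, tpts, n, _ = coeffs.shape
    cos_t = np.cos(2.0 * np.pi * freqs * tr)  # (F,)
    nf = cos_t.size
    ii = np.arange(n)
    accum = np.zeros((b, n, n))
    # chunk over time so the (B, chunk, N, F) temporaries stay small
    chunk = max(1, int(5e6 // max(b * n * nf, 1)))
    for s0 in range(0, tpts, chunk):
        blk = coeffs[:, s0 : s0 + chunk]  # (B, tt, N, N)
        colsq = (blk**2).sum(axis=2)  # (B, tt, N): sum over targets i
        diag = np.einsum("btjj->btj", blk)
        # denom_j(f) = colsq_j + 1 - 2 a_jj cos(theta_f) (diagonal term included)
        denom = colsq[..., None] + 1.0 - 2.0 * diag[..., None] * cos_t
        if (denom <= 0).any():
            bad = np.argwhere(denom <= 0)[0]
            raise ZeroDivisionError(
                f"degenerate transfer column {bad[2]} at band frequency "
                f"index {bad[3]}"
            )
        inv_root = 1.0 / np.sqrt(denom)  # (B, tt, N, F)
        w_off = inv_root.mean(axis=3)
        # off-diagonal: pi_ij(f) = |a_ij| / sqrt(denom_j(f)), |a_ij| f-independent
        pi_t = np.abs(blk) * w_off[:, :, None, :]
        # diagonal: pi_jj(f) = sqrt(1 - 2 a_jj cos + a_jj^2) / sqrt(denom_j(f))
        num_d = np.sqrt(1.0 - 2.0 * diag[..., None] * cos_t + diag[..., None] ** 2)
        pi_t[:, :, ii, ii] = (num_d * inv_root).mean(axis=3)
        accum += pi_t.sum(axis=1)
    return accum / tpts


def dual_ekf_tvar(
    x: TimeSeriesSet, p: int = 1, cfg: EKFConfig | None = None
) -> TVARModel:
    """Estimate a time-varying MVAR(p) model with the dual EKF.

    A state filter (signal estimate under the current coefficients) feeds a
    parameter filter whose state is the vectorized coefficient matrices
    with random-walk dynamics; both run forward once. Initialized from the
    stationary OLS fit; deterministic given inputs.
    """
    cfg = cfg or EKFConfig()
    if p < 1:
        raise ValueError("order p must be >= 1")
    x.check_length(p)
    n = x.n_channels
    y = (x.data - x.data.mean(axis=0))[None]
    coeffs, _, sigma = _dual_ekf_batch(y, p, cfg, store_coeffs=True)
    traj = coeffs[0].reshape(-1, n, p, n).transpose(0, 2, 1, 3)  # (T-p, p, N, N)
    return TVARModel(
        order=p,
        coeffs=traj,
        innovation_cov=0.5 * (sigma[0] + sigma[0].T),
        channels=x.channels,
        tr=x.tr,
    )


# ---------------------------------------------------------------------------
# spectral transfer and TPDC


def frequency_grid(tr: float, n_freqs: int) -> np.ndarray:
    """Uniform grid of n_freqs frequencies over (0, Nyquist]."""
    nyq = 0.5 / tr
    return np.arange(1, n_freqs + 1) * nyq / n_freqs


def spectral_transfer(model: TVARModel, n_freqs: int = 128) -> SpectralTransfer:
    """Abar(f, t) = I - sum_k A_k(t) exp(-i 2 pi f k TR) on the uniform grid."""
    if n_freqs < 8:
        raise ValueError("n_freqs must be >= 8")
    freqs = frequency_grid(model.tr, n_freqs)
    phases = _band_phases(freqs, model.order, model.tr)  # (F, p)
    n = model.n_channels
    values = np.eye(n) - np.einsum("fk,tkic->ftic", phases, model.coeffs)
    return SpectralTransfer(
        freqs=freqs, values=values, channels=model.channels, tr=model.tr
    )


def compute_tpdc(transfer: SpectralTransfer) -> np.ndarray:
    """TPDC tensor pi_ij(f, t) = |Abar_ij| / sqrt(sum_m |Abar_mj|^2).

    Shape (F, T, N, N); for every source column j, frequency and time,
    sum_i pi_ij^2 = 1.
    """
    mag2 = transfer.values.real**2 + transfer.values.imag**2
    colsum = mag2.sum(axis=2)  # sum over targets i
    if (colsum <= 0).any():
        f_idx, _, j = np.argwhere(colsum <= 0)[0]
        raise ZeroDivisionError(
            f"degenerate transfer: column {transfer.channels[j]!r} has zero "
            f"norm at frequency {transfer.freqs[f_idx]:.4g} Hz"
        )
    return np.sqrt(mag2 / colsum[:, :, None, :])


def band_average(
    pi: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    burn_fraction: float = 0.0,
    channels: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> TPDCMatrix:
    """Mean of pi over grid frequencies in [f_lo, f_hi] and post-burn time.

    The first floor(burn_fraction * T) time points of the estimation range
    are excluded (filter transient).
    """
    freqs = np.asarray(freqs, float)
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(
            f"no grid frequency inside band [{lo}, {hi}] Hz "
            f"(grid spans {freqs[0]:.4g}-{freqs[-1]:.4g} Hz)"
        )
    t = pi.shape[1]
    t0 = int(np.floor(burn_fraction * t))
    values = pi[sel, t0:].mean(axis=(0, 1))
    n = values.shape[0]
    channels = channels or tuple(f"ch{i}" for i in range(n))
    return TPDCMatrix(
        values=np.clip(values, 0.0, 1.0),
        band=(lo, hi),
        channels=channels,
        subject_id=subject_id,
    )


def static_pdc(
    coeffs: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
    n_freqs: int = 128,
    channels: tuple[str, ...] | None = None,
) -> TPDCMatrix:
    """Band-averaged PDC of fixed coefficient matrices (p, N, N).

    Closed-form oracle for the stationary limit: no filtering involved.
    """
    coeffs = np.asarray(coeffs, float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, n, _ = coeffs.shape
    channels = channels or tuple(f"ch{i}" for i in range(n))
    model = TVARModel(
        order=p,
        coeffs=coeffs[None],
        innovation_cov=np.eye(n),
        channels=channels,
        tr=tr,
    )
    transfer = spectral_transfer(model, n_freqs)
    pi = compute_tpdc(transfer)
    return band_average(pi, transfer.freqs, band=band, channels=channels)


# ---------------------------------------------------------------------------
# high-level single-subject and batched entry points


def estimate_tpdc(
    x: TimeSeriesSet,
    p: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    cfg: EKFConfig | None = None,
) -> TPDCMatrix:
    """Full pipeline for one subject: dual EKF -> TPDC -> band/time average."""
    out = estimate_tpdc_batch(
        x.data[None], tr=x.tr, p=p, band=band, cfg=cfg, channels=x.channels
    )
    out[0].subject_id = x.subject_id
    return out[0]


def estimate_tpdc_batch(
    data: np.ndarray,
    tr: float,
    p: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    cfg: EKFConfig | None = None,
    channels: tuple[str, ...] | None = None,
) -> list[TPDCMatrix]:
    """Batched full pipeline over a (B, T, N) stack of series.

    All series must share T, N and TR; the dual EKF and the band-averaged
    TPDC are computed in one vectorized forward pass. Used by the bootstrap
    (one subject plus its surrogates) and by cohort-level estimation.
    """
    cfg = cfg or EKFConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (B, T, N) stack")
    b, t, n = data.shape
    if t < 2 * p + 10:
        raise ValueError(f"series too short: T={t}")
    channels = channels or tuple(f"ch{i}" for i in range(n))
    freqs = frequency_grid(tr, cfg.n_freqs)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"no grid frequency inside band [{lo}, {hi}] Hz")
    y = data - data.mean(axis=1, keepdims=True)
    # sub-batch to bound the stored coefficient-trajectory memory
    sub = max(1, int(2e7 // (t * n * n * p)))
    parts = []
    for s0 in range(0, b, sub):
        _, band_pi, _ = _dual_ekf_batch(
            y[s0 : s0 + sub], p, cfg, store_coeffs=False, band_freqs=freqs[sel], tr=tr
        )
        parts.append(band_pi)
    band_pi = np.concatenate(parts, axis=0)
    return [
        TPDCMatrix(
            values=np.clip(band_pi[i], 0.0, 1.0),
            band=(lo, hi),
            channels=channels,
            subject_id=f"batch_{i}",
        )
        for i in range(b)
    ]


# ---------------------------------------------------------------------------
# scikit-learn estimator surfaces


class TimeVaryingVAR(BaseEstimator):
    """Dual-EKF time-varying MVAR estimator with a scikit-learn interface.

    Parameters mirror :class:`EKFConfig`; ``fit`` takes one subject's
    (T, N) array (or TimeSeriesSet) and exposes the coefficient trajectory
    as fitted attributes.
    """

    def __init__(
        self,
        order: int = 1,
        tr: float = 2.0,
        process_noise: float = 3e-7,
        init_param_cov: float = 1e-4,
        state_noise: float = 1e-2,
    ):
        self.order = order
        self.tr = tr
        self.process_noise = process_noise
        self.init_param_cov = init_param_cov
        self.state_noise = state_noise

    def _config(self) -> EKFConfig:
        return EKFConfig(
            process_noise=self.process_noise,
            init_param_cov=self.init_param_cov,
            state_noise=self.state_noise,
        )

    def fit(self, X, y=None):
        if isinstance(X, TimeSeriesSet):
            ts = X
        else:
            X = np.asarray(X, dtype=float)
            ts = TimeSeriesSet(
                subject_id="fit",
                data=X,
                channels=tuple(f"ch{i}" for i in range(X.shape[1])),
                tr=self.tr,
            )
        model = dual_ekf_tvar(ts, p=self.order, cfg=self._config())
        self.model_ = model
        self.coeffs_ = model.coeffs
        self.innovation_cov_ = model.innovation_cov
        self.channels_ = model.channels
        self.n_features_in_ = model.n_channels
        return self


class TPDCTransformer(BaseEstimator, TransformerMixin):
    """Transform a stack of subjects' series into flattened TPDC features.

    Input: (S, T, N) array or a list of TimeSeriesSet / (T, N) arrays with
    a common shape. Output: (S, N*N) row-major flattened band-averaged
    TPDC matrices (or (S, N*(N-1)) with ``include_diagonal=False``),
    composable with scikit-learn pipelines and classifiers.
    """

    def __init__(
        self,
        order: int = 1,
        tr: float = 2.0,
        band: tuple[float, float] = DEFAULT_BAND,
        include_diagonal: bool = True,
        process_noise: float = 3e-7,
        init_param_cov: float = 1e-4,
        state_noise: float = 1e-2,
        n_freqs: int = 128,
        burn_fraction: float = 0.1,
    ):
        self.order = order
        self.tr = tr
        self.band = band
        self.include_diagonal = include_diagonal
        self.process_noise = process_noise
        self.init_param_cov = init_param_cov
        self.state_noise = state_noise
        self.n_freqs = n_freqs
        self.burn_fraction = burn_fraction

    def _config(self) -> EKFConfig:
        return EKFConfig(
            process_noise=self.process_noise,
            init_param_cov=self.init_param_cov,
            state_noise=self.state_noise,
            n_freqs=self.n_freqs,
            burn_fraction=self.burn_fraction,
        )

    def _stack(self, X) -> tuple[np.ndarray, tuple[str, ...]]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return X.astype(float), tuple(f"ch{i}" for i in range(X.shape[2]))
        arrays, channels = [], None
        for item in X:
            if isinstance(item, TimeSeriesSet):
                arrays.append(item.data)
                channels = item.channels
            else:
                arrays.append(np.asarray(item, dtype=float))
        data = np.stack(arrays)
        if channels is None:
            channels = tuple(f"ch{i}" for i in range(data.shape[2]))
        return data, channels

    def fit(self, X, y=None):
        data, channels = self._stack(X)
        self.channels_ = channels
        self.n_features_in_ = data.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        data, channels = self._stack(X)
        mats = estimate_tpdc_batch(
            data,
            tr=self.tr,
            p=self.order,
            band=self.band,
            cfg=self._config(),
            channels=channels,
        )
        rows = []
        n = data.shape[2]
        mask = (
            np.ones((n, n), bool)
            if self.include_diagonal
            else ~np.eye(n, dtype=bool)
        )
        for m in mats:
            rows.append(m.values[mask])
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        from .staging import feature_names

        return np.asarray(
            feature_names(self.channels_, include_diagonal=self.include_diagonal)
        )
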