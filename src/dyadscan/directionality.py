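"""Directed interbrain coupling: MVAR models and generalized partial
directed coherence (GPDC).

A k-variate autoregressive model of order p,

    x_t = sum_{r=1..p} A_r x_{t-r} + e_t,   cov(e) = SIG,

is fit by multivariate least squares to the dyad's (demeaned) region
power-envelope series at 1 sample/s.  In the frequency domain, with

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r),

the GPDC from source j to target i is the innovation-variance-weighted,
column-normalized quantity

    G_ij(f) = (|Abar_ij(f)| / sigma_i) / sqrt( sum_m |Abar_mj(f)|^2 / sigma_m^2 ),

with sigma_m^2 = SIG_mm, so that sum_i G_ij(f)^2 = 1 at every frequency --
an algebraic identity that doubles as a self-check.  The transfer function
H = Abar^{-1}, the spectral matrix S = H SIG H^H and the ordinary coherence
C_ij = |S_ij|^2 / (S_ii S_jj) are computed alongside.

Because the envelope series are sampled at 1 Hz, GPDC's frequency axis is
0-0.5 cycles/s of *envelope fluctuation*; band summaries default to
0.01-0.4 cycles/s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.01, 0.4)  # cycles per envelope sample


@dataclass
class MVARModel:
    A: np.ndarray  # (p, k, k) coefficient matrices
    sig: np.ndarray  # (k, k) innovation covariance
    p: int
    k: int
    nobs: int
    stable: bool
    diagnostics: dict = field(default_factory=dict)

    def companion_spectral_radius(self) -> float:
        if self.p == 0:
            return 0.0
        kp = self.k * self.p
        comp = np.zeros((kp, kp))
        comp[: self.k] = np.concatenate(list(self.A), axis=1)
        if self.p > 1:
            comp[self.k :, : self.k * (self.p - 1)] = np.eye(self.k * (self.p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    n, k = x.shape
    rows = n - p
    X = np.empty((rows, k * p))
    for r in range(1, p + 1):
        X[:, (r - 1) * k : r * k] = x[p - r : n - r]
    return X, x[p:]


def fit_mvar(
    series: np.ndarray,
    p: int | str = "auto",
    pmax: int = 20,
) -> MVARModel:
    """Least-squares MVAR fit on (n, k) demeaned series.

    ``p="auto"`` selects the order in [1, pmax] by BIC on a common
    effective sample, then refits at the chosen order on the full sample.
    An unstable fit is flagged (and warned about), not rejected;
    rank-deficient lag regressors are an error.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    x = x - x.mean(axis=0)
    if p == "auto":
        pmax_eff = min(pmax, max(1, n // (10 * k) ))
        bics = {}
        ncommon = n - pmax_eff
        for cand in range(1, pmax_eff + 1):
            Xc, Yc = _lagged_design(x[pmax_eff - cand :], cand)
            beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
            resid = Yc - Xc @ beta
            sig_mle = resid.T @ resid / ncommon
            sign, logdet = np.linalg.slogdet(sig_mle)
            if sign <= 0:
                continue
            bics[cand] = logdet + (k * k * cand) * np.log(ncommon) / ncommon
        if not bics:
            raise np.linalg.LinAlgError("no admissible order: singular residual covariance")
        p = min(bics, key=bics.get)
        logger.debug("fit_mvar: BIC selected order %d", p)
    p = int(p)
    if n < 10 * k * p:
        raise ValueError(f"series too short ({n}) for k={k}, p={p}; need >= {10 * k * p}")
    X, Y = _lagged_design(x, p)
    rank = np.linalg.matrix_rank(X)
    if rank < k * p:
        raise np.linalg.LinAlgError(f"rank-deficient lag regressors (rank {rank} < {k * p})")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(X.shape[0] - k * p, 1)
    sig = resid.T @ resid / dof
    A = np.stack([beta[(r - 1) * k : r * k].T for r in range(1, p + 1)])
    model = MVARModel(A=A, sig=sig, p=p, k=k, nobs=n, stable=True)
    radius = model.companion_spectral_radius()
    model.stable = radius < 1.0
    model.diagnostics = {"spectral_radius": radius, "resid_sd": resid.std(axis=0)}
    if not model.stable:
        warnings.warn(
            f"fitted MVAR is unstable (companion spectral radius {radius:.3f}); "
            "GPDC values are unreliable",
            stacklevel=2,
        )
    return model


@dataclass
class GPDCResult:
    G: np.ndarray  # (n_freqs, k, k), G[f, i, j] = influence j -> i
    freqs: np.ndarray  # cycles/sample
    H: np.ndarray  # (n_freqs, k, k) transfer function
    S: np.ndarray  # (n_freqs, k, k) spectral density matrix
    C: np.ndarray  # (n_freqs, k, k) magnitude-squared coherence
    singular_freqs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def band_mean(self, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
        lo, hi = band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {band} contains no frequency grid points")
        return self.G[sel].mean(axis=0)


def gpdc(model: MVARModel, freqs: np.ndarray | None = None, n_freqs: int = 128) -> GPDCResult:
    """GPDC (plus H, S, C) on a frequency grid in cycles/sample [0, 0.5]."""
    if freqs is None:
        freqs = np.linspace(0.0, 0.5, n_freqs)
    freqs = np.asarray(freqs, dtype=float)
    k = model.k
    sigma2 = np.diag(model.sig).copy()
    if (sigma2 <= 0).any():
        raise ValueError("innovation variances must be positive for GPDC")
    r = np.arange(1, model.p + 1)
    # Abar(f) = I - sum_r A_r e^{-i 2 pi f r}
    phase = np.exp(-2j * np.pi * freqs[:, None] * r[None, :])  # (nf, p)
    Abar = np.eye(k)[None] - np.einsum("fp,pij->fij", phase, model.A)
    w = 1.0 / np.sqrt(sigma2)  # 1/sigma_i
    num = np.abs(Abar) * w[None, :, None]
    denom = np.sqrt((num**2).sum(axis=1, keepdims=True))
    G = num / denom
    H = np.full_like(Abar, np.nan)
    singular = []
    for fi in range(len(freqs)):
        try:
            H[fi] = np.linalg.inv(Abar[fi])
        except np.linalg.LinAlgError:
            singular.append(freqs[fi])
            logger.warning("gpdc: Abar singular at f=%g cycles/sample", freqs[fi])
    S = np.einsum("fij,jk,flk->fil", H, model.sig, np.conj(H))
    diag = np.real(np.einsum("fii->fi", S))
    C = np.abs(S) ** 2 / (diag[:, :, None] * diag[:, None, :])
    return GPDCResult(G=G, freqs=freqs, H=H, S=S, C=C, singular_freqs=np.asarray(singular))


@dataclass
class DyadGPDC:
    human_to_dog: float
    dog_to_human: float
    band: tuple[float, float]
    order: int
    model: MVARModel
    result: GPDCResult


def dyad_gpdc(
    human_series: np.ndarray,
    dog_series: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int | str = "auto",
    pmax: int = 20,
    min_windows: int = 120,
) -> DyadGPDC:
    """Directed coupling between one human region envelope and one dog
    region envelope (bivariate MVAR at 1 sample/s; band-mean GPDC both
    ways)."""
    h = np.asarray(human_series, dtype=float)
    d = np.asarray(dog_series, dtype=float)
    n = min(len(h), len(d))
    if n < min_windows:
        raise ValueError(f"only {n} aligned windows; need >= {min_windows}")
    x = np.column_stack([h[:n], d[:n]])
    model = fit_mvar(x, p=order, pmax=pmax)
    res = gpdc(model)
    bm = res.band_mean(band)
    # series order is [human, dog]; G[i, j] is j -> i
    return DyadGPDC(
        human_to_dog=float(bm[1, 0]),
        dog_to_human=float(bm[0, 1]),
        band=band,
        order=model.p,
        model=model,
        result=res,
    )
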