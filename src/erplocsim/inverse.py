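"""eLORETA source reconstruction with noise pre-whitening.

eLORETA is a weighted minimum-norm inverse whose per-source weights are
defined by the fixed point

    W_i = [ K_i^T (K W^-1 K^T + alpha H)^+ K_i ]^(1/2),

with K the (whitened, average-referenced) leadfield, K_i its 3-column block
for source i, H a regularization metric, and ^+ the Moore-Penrose
pseudo-inverse. The resulting kernel W^-1 K^T (K W^-1 K^T + alpha H)^+ has
zero localization error for single point sources in noise-free data, which
is the property that motivates its use here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, NumericalError, RankDeficiencyError
from .headmodel import Leadfield, SourceSpace
from .simulate import EpochSet

_EIG_FLOOR = 1e-12  # relative eigenvalue floor for pseudo-inverses


@dataclass(frozen=True)
class NoiseCovariance:
    matrix: np.ndarray
    n_samples_used: int
    loading: float

    def whitener(self) -> np.ndarray:
        """Symmetric inverse matrix square root of the covariance."""
        lam, v = np.linalg.eigh(self.matrix)
        if lam.min() <= 0:
            raise NumericalError("covariance is not positive definite")
        return (v / np.sqrt(lam)) @ v.T

    def unwhitener(self) -> np.ndarray:
        lam, v = np.linalg.eigh(self.matrix)
        return (v * np.sqrt(lam)) @ v.T


@dataclass
class InverseOperator:
    kernel: np.ndarray  # (3*n_sources, n_sensors), applies to whitened data
    weights: np.ndarray  # (n_sources, 3, 3) symmetric PD blocks
    alpha: float  # requested regularization fraction
    alpha_eff: float  # final trace-normalized regularization
    iterations_run: int
    converged: bool
    rel_changes: tuple[float, ...] = ()
    whitener: np.ndarray | None = None  # applied to data before the kernel
    source_space_id: str = ""
    montage_id: str = ""
    shell_model_id: str = ""


@dataclass
class SourceEstimate:
    """Orientation-free current source density over time (non-negative)."""

    csd: np.ndarray  # (n_sources, n_samples)
    fs: float
    t0_ms: float
    condition: str = ""
    source_space_id: str = ""

    def time_axis_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.csd.shape[1]) * 1000.0 / self.fs


def estimate_noise_covariance(
    epochs: EpochSet, source: str = "noise_epochs", loading: float = 0.05
) -> NoiseCovariance:
    """Sample noise covariance with diagonal loading.

    ``source='noise_epochs'`` pools all samples of the noise-only epochs;
    ``source='prestim'`` pools the pre-stimulus windows of all epochs.
    Loading adds ``loading * mean(diag)`` to the diagonal.
    """
    if source == "noise_epochs":
        segs = epochs.epochs_of("noise")
        if segs.shape[0] == 0:
            raise InvalidArgumentError("no noise-only epochs available")
        x = segs.transpose(1, 0, 2).reshape(epochs.n_sensors, -1)
    elif source == "prestim":
        mask = epochs.time_axis_ms() < 0.0
        if not mask.any():
            raise InvalidArgumentError("no pre-stimulus samples available")
        x = epochs.data[:, :, mask].transpose(1, 0, 2).reshape(epochs.n_sensors, -1)
    else:
        raise InvalidArgumentError("source must be 'noise_epochs' or 'prestim'")
    n = x.shape[1]
    if n <= x.shape[0] and loading == 0.0:
        raise RankDeficiencyError(
            f"{n} samples for {x.shape[0]} sensors: the covariance is rank "
            "deficient; use nonzero diagonal loading"
        )
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (n - 1)
    cov = cov + loading * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    return NoiseCovariance(matrix=cov, n_samples_used=n, loading=loading)


def whiten_leadfield(leadfield: Leadfield, cov: NoiseCovariance) -> Leadfield:
    w = cov.whitener()
    if w.shape[0] != leadfield.n_sensors:
        raise InvalidArgumentError("covariance and leadfield dimensions differ")
    return Leadfield(
        gain=w @ leadfield.gain,
        reference="whitened",
        source_space_id=leadfield.source_space_id,
        montage_id=leadfield.montage_id,
        shell_model_id=leadfield.shell_model_id,
    )


def whiten_data(epochs: EpochSet, cov: NoiseCovariance) -> EpochSet:
    w = cov.whitener()
    if w.shape[0] != epochs.n_sensors:
        raise InvalidArgumentError("covariance and data dimensions differ")
    data = np.einsum("ab,ebt->eat", w, epochs.data)
    clean = None if epochs.clean_erp is None else w @ epochs.clean_erp
    return EpochSet(
        data=data,
        condition=epochs.condition,
        fs=epochs.fs,
        t0_ms=epochs.t0_ms,
        montage_id=epochs.montage_id,
        clean_erp=clean,
        meta={**epochs.meta, "whitened": True},
    )


def _pinv_psd(a: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    lam, v = np.linalg.eigh(a)
    cut = lam.max() * floor
    inv = np.where(lam > cut, 1.0 / np.where(lam > cut, lam, 1.0), 0.0)
    return (v * inv) @ v.T


def _sqrtm_psd_blocks(s: np.ndarray) -> np.ndarray:
    """Principal square roots of a stack of symmetric 3x3 PSD matrices."""
    lam, v = np.linalg.eigh(s)
    lam = np.clip(lam, 0.0, None)
    return np.einsum("nij,nj,nkj->nik", v, np.sqrt(lam), v)


def eloreta_weights(
    leadfield: Leadfield,
    alpha: float = 1.0 / 9.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    whitener: np.ndarray | None = None,
) -> InverseOperator:
    """Fixed-point iteration for the eLORETA per-source weight blocks.

    ``alpha`` is a fraction of ``trace(K W^-1 K^T)/n_sensors`` (recomputed
    each iteration), so the effective regularization is scale invariant.
    The regularization metric H is the average-reference centering operator
    for an average-referenced leadfield and the identity for a whitened
    one. Non-convergence is reported through ``converged=False``, never
    silently.
    """
    if alpha < 0:
        raise InvalidArgumentError("alpha must be non-negative")
    K = np.asarray(leadfield.gain, dtype=float)
    M = K.shape[0]
    N = K.shape[1] // 3
    # joint scale guard: unit median column norm
    scale = np.median(np.linalg.norm(K, axis=0))
    if scale <= 0:
        raise InvalidArgumentError("leadfield has zero columns")
    K = K / scale
    Kr = K.reshape(M, N, 3)
    if leadfield.reference == "average":
        H = np.eye(M) - np.full((M, M), 1.0 / M)
    else:
        H = np.eye(M)

    w_inv = np.tile(np.eye(3), (N, 1, 1))
    weights = np.tile(np.eye(3), (N, 1, 1))
    rel_changes: list[float] = []
    converged = False
    alpha_eff = 0.0
    m_alpha = None
    for it in range(max_iter):
        t1 = np.einsum("anj,njk->ank", Kr, w_inv)
        c_s = np.einsum("ank,bnk->ab", t1, Kr)
        alpha_eff = alpha * np.trace(c_s) / M
        m_alpha = _pinv_psd(c_s + alpha_eff * H)
        t2 = (m_alpha @ K).reshape(M, N, 3)
        s = np.einsum("anj,ank->njk", Kr, t2)
        w_new = _sqrtm_psd_blocks(s)
        num = np.linalg.norm(w_new - weights, axis=(1, 2))
        den = np.linalg.norm(weights, axis=(1, 2))
        rel = float((num / np.where(den > 0, den, 1.0)).max())
        rel_changes.append(rel)
        weights = w_new
        w_inv = _inv_blocks(weights)
        if rel < tol:
            converged = True
            break
    kernel_rows = np.einsum("nij,njm->nim", w_inv, (K.T @ m_alpha).reshape(N, 3, M))
    kernel = kernel_rows.reshape(3 * N, M)
    return InverseOperator(
        kernel=kernel,
        weights=weights,
        alpha=alpha,
        alpha_eff=float(alpha_eff),
        iterations_run=len(rel_changes),
        converged=converged,
        rel_changes=tuple(rel_changes),
        whitener=whitener,
        source_space_id=leadfield.source_space_id,
        montage_id=leadfield.montage_id,
        shell_model_id=leadfield.shell_model_id,
    )


def _inv_blocks(s: np.ndarray) -> np.ndarray:
    """Pseudo-inverses of a stack of symmetric 3x3 PSD matrices."""
    lam, v = np.linalg.eigh(s)
    cut = lam.max(axis=1, keepdims=True) * 1e-10
    inv = np.where(lam > cut, 1.0 / np.where(lam > cut, lam, 1.0), 0.0)
    return np.einsum("nij,nj,nkj->nik", v, inv, v)


def apply_inverse(epochs: EpochSet, op: InverseOperator) -> list[SourceEstimate]:
    """Per-epoch CSD: Euclidean norm of the 3-vector moment per source.

    If the operator carries a whitener, it is applied to the data first.
    """
    if op.kernel.shape[1] != epochs.n_sensors:
        raise InvalidArgumentError("operator and data dimensions differ")
    data = epochs.data
    if op.whitener is not None:
        data = np.einsum("ab,ebt->eat", op.whitener, data)
    n_src = op.kernel.shape[0] // 3
    out = []
    # one GEMM over all epochs
    j = op.kernel @ data.transpose(1, 0, 2).reshape(epochs.n_sensors, -1)
    j = j.reshape(n_src, 3, epochs.n_epochs, epochs.n_samples)
    csd_all = np.sqrt((j**2).sum(axis=1))  # (n_src, n_epochs, n_samples)
    for e in range(epochs.n_epochs):
        out.append(
            SourceEstimate(
                csd=csd_all[:, e, :],
                fs=epochs.fs,
                t0_ms=epochs.t0_ms,
                condition=str(epochs.condition[e]),
                source_space_id=op.source_space_id,
            )
        )
    return out


def apply_inverse_evoked(
    epochs: EpochSet, op: InverseOperator, chunk: int = 8
) -> dict[str, SourceEstimate]:
    """Condition-averaged CSD without holding per-epoch estimates in memory.

    Equivalent to ``condition_evoked(apply_inverse(...))`` but processes
    epochs in chunks, keeping memory at O(n_sources * n_samples * chunk).
    """
    if op.kernel.shape[1] != epochs.n_sensors:
        raise InvalidArgumentError("operator and data dimensions differ")
    n_src = op.kernel.shape[0] // 3
    labels = sorted(set(epochs.condition))
    sums = {lab: np.zeros((n_src, epochs.n_samples)) for lab in labels}
    counts = {lab: 0 for lab in labels}
    for start in range(0, epochs.n_epochs, chunk):
        block = epochs.data[start : start + chunk]
        if op.whitener is not None:
            block = np.einsum("ab,ebt->eat", op.whitener, block)
        j = op.kernel @ block.transpose(1, 0, 2).reshape(epochs.n_sensors, -1)
        j = j.reshape(n_src, 3, block.shape[0], epochs.n_samples)
        csd = np.sqrt((j**2).sum(axis=1))
        for k, lab in enumerate(epochs.condition[start : start + chunk]):
            sums[lab] += csd[:, k, :]
            counts[lab] += 1
    out = {}
    for lab in labels:
        if counts[lab] == 0:
            raise InvalidArgumentError(f"no epochs with condition {lab!r}")
        out[lab] = SourceEstimate(
            csd=sums[lab] / counts[lab],
            fs=epochs.fs,
            t0_ms=epochs.t0_ms,
            condition=lab,
            source_space_id=op.source_space_id,
        )
    return out


def condition_evoked(estimates: list[SourceEstimate]) -> dict[str, SourceEstimate]:
    """Pointwise mean CSD within each condition label."""
    if not estimates:
        raise InvalidArgumentError("no estimates to average")
    labels = sorted({e.condition for e in estimates})
    out = {}
    for lab in labels:
        members = [e for e in estimates if e.condition == lab]
        csd = np.mean([e.csd for e in members], axis=0)
        ref = members[0]
        out[lab] = SourceEstimate(
            csd=csd,
            fs=ref.fs,
            t0_ms=ref.t0_ms,
            condition=lab,
            source_space_id=ref.source_space_id,
        )
    return out
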