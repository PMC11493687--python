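"""ERP network simulation: waveforms, pink noise, SNR calibration, epochs.

The simulated dataset mirrors a two-condition ERP experiment: 80 epochs of
1000 ms (200 ms pre-stimulus) at 250 Hz, half containing a four-ROI ERP
network plus pink noise and half containing only the noise. Each ROI is a
10 mm sphere of dipoles carrying a 5 Hz half-cycle sinusoid (100 ms lobe);
activity starts in ROIs 1-2 at 100/110 ms and in ROIs 3-4 at 120 ms with
80% amplitude. Noise is independent pink noise per channel, scaled so the
ratio of the ERP component's peak to the mean pre-stimulus peak-to-peak
amplitude hits a target value in dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyROIError,
    InvalidArgumentError,
    NumericalError,
    ProvenanceError,
)
from .headmodel import Leadfield, SourceSpace


@dataclass(frozen=True)
class ROISpec:
    name: str
    center: np.ndarray  # meters
    radius_mm: float = 10.0
    onset_ms: float = 100.0
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise InvalidArgumentError("ROI radius must be positive")
        if self.onset_ms < 0:
            raise InvalidArgumentError("ROI onset must be non-negative")
        if not 0.0 < self.amplitude_scale <= 1.0:
            raise InvalidArgumentError("amplitude_scale must lie in (0, 1]")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    rois: tuple[ROISpec, ROISpec, ROISpec, ROISpec]

    def __post_init__(self) -> None:
        if len(self.rois) != 4:
            raise InvalidArgumentError("a network has exactly 4 ROIs")


#: Unit directions of the ROI centers on the source sphere (x right,
#: y anterior, z superior; left hemisphere has x < 0). The four sites are
#: sphere analogues of occipital-pole, inferior-temporal, inferior-frontal
#: and supramarginal parcels: occipital sites posterior and slightly
#: inferior, temporal sites lateral and deep (inferior), frontal sites
#: anterior-lateral-inferior, parietal sites superior-lateral.
_ROI_DIRECTIONS = {
    "occipital_pole": (0.25, -0.94, -0.23),
    "inferior_temporal": (0.80, -0.35, -0.49),
    "inferior_frontal": (0.62, 0.70, -0.35),
    "supramarginal": (0.75, -0.25, 0.61),
}

#: ROI name sequences per named network (hemisphere suffix lh/rh).
NETWORK_ROIS = {
    "temporo_occipital": (
        ("occipital_pole", "lh"),
        ("occipital_pole", "rh"),
        ("inferior_temporal", "lh"),
        ("inferior_temporal", "rh"),
    ),
    "fronto_parietal": (
        ("inferior_frontal", "rh"),
        ("inferior_frontal", "lh"),
        ("supramarginal", "lh"),
        ("supramarginal", "rh"),
    ),
    "fronto_occipital": (
        ("occipital_pole", "lh"),
        ("occipital_pole", "rh"),
        ("inferior_frontal", "rh"),
        ("inferior_frontal", "lh"),
    ),
    "temporo_parietal": (
        ("inferior_temporal", "lh"),
        ("inferior_temporal", "rh"),
        ("supramarginal", "lh"),
        ("supramarginal", "rh"),
    ),
}

_DEFAULT_ONSETS = (100.0, 110.0, 120.0, 120.0)
_DEFAULT_SCALES = (1.0, 1.0, 0.8, 0.8)


def roi_direction(site: str, hemi: str) -> np.ndarray:
    d = np.asarray(_ROI_DIRECTIONS[site], dtype=float)
    if hemi == "lh":
        d = d * np.array([-1.0, 1.0, 1.0])
    elif hemi != "rh":
        raise InvalidArgumentError("hemisphere must be 'lh' or 'rh'")
    return d / np.linalg.norm(d)


def make_network(
    name: str,
    sources: SourceSpace,
    radius_mm: float = 10.0,
    rotation: np.ndarray | None = None,
) -> NetworkSpec:
    """Instantiate a named four-ROI network on a given source grid.

    ROI centers sit at the preset angular positions on the grid's own
    source sphere, so that the network is defined in the anatomy (grid) it
    is simulated in. ``rotation`` rotates the ROI sites with a subject's
    anatomy (it must match the rotation applied to the grid).
    """
    if name not in NETWORK_ROIS:
        raise InvalidArgumentError(
            f"unknown network {name!r}; choose from {sorted(NETWORK_ROIS)}"
        )
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    r_src = float(np.median(np.linalg.norm(sources.positions, axis=1)))
    rois = tuple(
        ROISpec(
            name=f"{site}_{hemi}",
            center=rot @ roi_direction(site, hemi) * r_src,
            radius_mm=radius_mm,
            onset_ms=_DEFAULT_ONSETS[k],
            amplitude_scale=_DEFAULT_SCALES[k],
        )
        for k, (site, hemi) in enumerate(NETWORK_ROIS[name])
    )
    return NetworkSpec(name=name, rois=rois)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SimulationConfig:
    n_epochs: int = 80
    epoch_length_ms: float = 1000.0
    prestim_ms: float = 200.0
    fs: float = 250.0
    snr_db: float = -10.0
    erp_freq_hz: float = 5.0
    erp_duration_ms: float | None = None  # default: half cycle of erp_freq
    seed: int = 0
    noise_in_source_space: bool = False

    def __post_init__(self) -> None:
        if self.n_epochs % 2 != 0 or self.n_epochs < 2:
            raise InvalidArgumentError("n_epochs must be even and >= 2")
        if not 0 < self.prestim_ms < self.epoch_length_ms:
            raise InvalidArgumentError("prestim must lie within the epoch")
        if self.erp_duration_ms is None:
            object.__setattr__(self, "erp_duration_ms", 1000.0 / (2.0 * self.erp_freq_hz))

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length_ms * self.fs / 1000.0))

    @property
    def t0_ms(self) -> float:
        return -self.prestim_ms

    def time_axis_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class EpochSet:
    """Sensor-space trials with condition labels and a stimulus-locked clock."""

    data: np.ndarray  # (n_epochs, n_sensors, n_samples)
    condition: np.ndarray  # per-epoch label, 'erp' or 'noise'
    fs: float
    t0_ms: float
    montage_id: str = ""
    clean_erp: np.ndarray | None = None  # (n_sensors, n_samples) noiseless component
    meta: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_axis_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def epochs_of(self, condition: str) -> np.ndarray:
        return self.data[self.condition == condition]


def erp_waveform(
    freq_hz: float,
    onset_ms: float,
    duration_ms: float,
    amplitude: float,
    fs: float,
    n_samples: int,
    t0_ms: float,
) -> np.ndarray:
    """Single half-sine lobe: zero outside [onset, onset+duration], peak =
    ``amplitude`` at the lobe center."""
    if onset_ms < t0_ms:
        raise InvalidArgumentError("onset precedes the epoch start")
    half_cycle = 1000.0 / (2.0 * freq_hz)
    if abs(duration_ms - half_cycle) > 1000.0 / fs:
        raise InvalidArgumentError(
            "duration must equal a half cycle of the waveform frequency"
        )
    t = t0_ms + np.arange(n_samples) * 1000.0 / fs
    if onset_ms + duration_ms > t[-1] + 1000.0 / fs:
        raise InvalidArgumentError("waveform must end within the epoch")
    w = np.zeros(n_samples)
    # the lobe is analytically zero at both endpoints; restrict to the open
    # interval so float sin(pi) residue does not leak outside the support
    inside = (t > onset_ms) & (t < onset_ms + duration_ms)
    w[inside] = amplitude * np.sin(np.pi * (t[inside] - onset_ms) / duration_ms)
    return w


def select_roi_dipoles(sources: SourceSpace, roi: ROISpec) -> np.ndarray:
    """Indices of all dipoles within ``roi.radius_mm`` of the ROI center."""
    d = np.linalg.norm(sources.positions - roi.center[None, :], axis=1)
    idx = np.flatnonzero(d <= roi.radius_mm * 1e-3)
    if idx.size == 0:
        raise EmptyROIError(
            f"ROI {roi.name!r} selects no dipoles (center too far from the grid)"
        )
    return idx


def pink_noise(n_channels: int, n_samples: int, fs: float, seed=None) -> np.ndarray:
    """Independent 1/f-power noise per channel, zero mean, unit variance.

    White Gaussian noise is shaped in the frequency domain with an
    amplitude spectrum proportional to 1/sqrt(f) (the DC bin is zeroed).
    """
    if n_samples < 64:
        raise InvalidArgumentError("need at least 64 samples for spectral shaping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = rng.standard_normal((n_channels, n_samples))
    y = np.fft.irfft(np.fft.rfft(x, axis=-1) * shape, n_samples, axis=-1)
    y -= y.mean(axis=-1, keepdims=True)
    y /= y.std(axis=-1, keepdims=True)
    return y


def _prestim_mask(epochs: EpochSet) -> np.ndarray:
    return epochs.time_axis_ms() < 0.0


def measure_snr(epochs: EpochSet) -> float:
    """SNR in dB: peak ERP-component amplitude over mean pre-stimulus
    peak-to-peak amplitude, at the sensor where the component peaks.

    The ERP component is identical across erp-condition epochs, so its
    condition average is the stored noiseless component (``clean_erp``).
    When it is unavailable the component is estimated as the difference of
    the two condition averages, an estimate whose peak is noise-floor
    limited at low SNR.
    """
    mask = _prestim_mask(epochs)
    if not mask.any():
        raise InvalidArgumentError("epochs contain no pre-stimulus samples")
    erp_epochs = epochs.epochs_of("erp")
    if erp_epochs.shape[0] == 0 or (epochs.condition == "noise").sum() == 0:
        raise InvalidArgumentError("both conditions must be present")
    if epochs.clean_erp is not None:
        component = epochs.clean_erp
    else:
        component = erp_epochs.mean(axis=0) - epochs.epochs_of("noise").mean(axis=0)
    sensor = int(np.argmax(np.abs(component).max(axis=1)))
    a_peak = float(np.abs(component[sensor]).max())
    pre = erp_epochs[:, sensor, :][:, mask]
    a_pp = float((pre.max(axis=1) - pre.min(axis=1)).mean())
    if a_pp == 0.0:
        return np.inf
    if a_peak == 0.0:
        return -np.inf
    return 20.0 * np.log10(a_peak / a_pp)


def calibrate_noise_scale(
    clean_sensor_erp: np.ndarray,
    noise_prototype: np.ndarray,
    target_snr_db: float,
    prestim_mask: np.ndarray,
    tol_db: float = 0.05,
    max_iter: int = 40,
) -> float:
    """Noise scale factor that makes the measured SNR hit the target.

    ``noise_prototype`` holds the unscaled noise of the erp-condition
    epochs, shape (n_epochs_erp, n_sensors, n_samples). Bisection on the
    scale (the measured SNR is strictly decreasing in it).
    """
    if not np.isfinite(target_snr_db):
        raise InvalidArgumentError("target SNR must be finite")
    if not np.any(noise_prototype):
        raise InvalidArgumentError("noise prototype is identically zero")
    sensor = int(np.argmax(np.abs(clean_sensor_erp).max(axis=1)))
    a_peak = float(np.abs(clean_sensor_erp[sensor]).max())
    if a_peak == 0.0:
        raise InvalidArgumentError("clean ERP is identically zero")
    pre = noise_prototype[:, sensor, :][:, prestim_mask]
    pp_unit = float((pre.max(axis=1) - pre.min(axis=1)).mean())

    def snr_of(scale: float) -> float:
        return 20.0 * np.log10(a_peak / (scale * pp_unit))

    lo, hi = 1e-12, 1e12
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: SNR is linear in log(scale)
        if snr_of(mid) > target_snr_db:
            lo = mid
        else:
            hi = mid
        if abs(snr_of(mid) - target_snr_db) < tol_db:
            return float(mid)
    raise NumericalError(
        f"noise calibration did not converge: last SNR {snr_of(mid):.2f} dB, "
        f"target {target_snr_db:.2f} dB"
    )


def simulate_epochs(
    network: NetworkSpec,
    subject_leadfield: Leadfield,
    sources: SourceSpace,
    config: SimulationConfig,
) -> EpochSet:
    """Generate the two-condition sensor-space dataset for one subject.

    Every dipole of ROI k carries the ROI-k half-sine waveform with radial
    orientation, scaled by the ROI's amplitude factor; the summed source
    activity is projected through the subject's own (generating) leadfield,
    and calibrated pink noise is added to all epochs at the sensor level.
    """
    if subject_leadfield.source_space_id and sources.source_space_id:
        if subject_leadfield.source_space_id != sources.source_space_id:
            raise ProvenanceError(
                "leadfield and source space come from different grids"
            )
    n_samples = config.n_samples
    t0 = config.t0_ms
    radial = sources.radial_units

    clean = np.zeros((subject_leadfield.n_sensors, n_samples))
    gain3 = subject_leadfield.gain.reshape(subject_leadfield.n_sensors, -1, 3)
    for roi in network.rois:
        idx = select_roi_dipoles(sources, roi)
        wave = erp_waveform(
            config.erp_freq_hz,
            roi.onset_ms,
            config.erp_duration_ms,
            roi.amplitude_scale,
            config.fs,
            n_samples,
            t0,
        )
        # topography of unit radial moments at the ROI dipoles
        topo = np.einsum("mnd,nd->m", gain3[:, idx, :], radial[idx])
        clean += np.outer(topo, wave)

    rng = np.random.default_rng(config.seed)
    n_ep = config.n_epochs
    if config.noise_in_source_space:
        # optional variant: independent pink noise on every dipole (radial
        # orientation), seen at the sensors through the same forward model
        proj = np.einsum("mnd,nd->mn", gain3, radial)  # (M, N)
        noise = np.stack(
            [
                proj @ pink_noise(sources.n_dipoles, n_samples, config.fs, rng)
                for _ in range(n_ep)
            ]
        )
    else:
        noise = np.stack(
            [
                pink_noise(subject_leadfield.n_sensors, n_samples, config.fs, rng)
                for _ in range(n_ep)
            ]
        )
    condition = np.array(["erp"] * (n_ep // 2) + ["noise"] * (n_ep // 2))
    t_axis = t0 + np.arange(n_samples) * 1000.0 / config.fs
    prestim = t_axis < 0.0
    scale = calibrate_noise_scale(
        clean, noise[: n_ep // 2], config.snr_db, prestim
    )
    data = noise * scale
    data[: n_ep // 2] += clean[None, :, :]
    return EpochSet(
        data=data,
        condition=condition,
        fs=config.fs,
        t0_ms=t0,
        montage_id=subject_leadfield.montage_id,
        clean_erp=clean,
        meta={
            "network": network.name,
            "snr_db": config.snr_db,
            "noise_scale": scale,
            "seed": config.seed,
        },
    )
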