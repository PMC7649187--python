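"""Synthetic multi-source nonlinearly coupled signals, linearly mixed to sensors.

A narrowband noise carrier and its quadratic and cubic powers are assigned to
one, two or three spatially distinct sources and mapped to sensors through an
instantaneous mixing matrix.  With all three harmonics in a single source (or
split over two), the totally antisymmetric cross-bispectrum cancels
algebraically; only the genuinely three-source configuration produces
significant coupling.  This makes the simulator the universal end-to-end
fixture for the analysis pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FrequencyError, ValidationError
from .spectral import EpochedRecording

__all__ = [
    "SourceSignals",
    "MixingModel",
    "ASSIGNMENTS",
    "generate_sources",
    "assign_and_mix",
    "default_mixing",
    "simulate_recording",
]

logger = logging.getLogger(__name__)

ASSIGNMENTS = ("one_source", "two_sources", "three_sources")


@dataclass
class SourceSignals:
    """Unit-L2 narrowband carrier and its squared and cubed harmonics.

    ``x2`` and ``x3`` are derived from the same realization of ``x1`` before
    normalization, so their phases are deterministically coupled.
    """

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    carrier: float
    bandwidth: float
    fs: float
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.x1.size


@dataclass
class MixingModel:
    """Assignment of the harmonic signals to sources, plus the sensor mixing.

    ``assignment`` selects how many spatially distinct sources carry the three
    harmonics; ``mixing_matrix`` is ``(n_sensors, n_sources)`` with full
    column rank over the active sources.  ``sensor_noise_level`` is the noise
    RMS relative to the mixed-signal RMS (0 = noiseless).
    """

    assignment: str
    mixing_matrix: np.ndarray
    sensor_noise_level: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.assignment not in ASSIGNMENTS:
            raise ConfigurationError(
                f"assignment must be one of {ASSIGNMENTS}, got {self.assignment!r}"
            )
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.ndim != 2:
            raise ConfigurationError("mixing_matrix must be 2-D (sensors x sources)")

    @property
    def n_active_sources(self) -> int:
        return {"one_source": 1, "two_sources": 2, "three_sources": 3}[self.assignment]


def generate_sources(
    carrier: float = 10.0,
    bandwidth: float = 1.0,
    fs: float = 256.0,
    n_samples: int = 61440,
    seed: int | np.random.Generator | None = None,
) -> SourceSignals:
    """White noise band-limited to ``carrier +- bandwidth/2``, plus its powers.

    Band-limiting uses a hard frequency-domain mask (exactly controlled
    bandwidth, fully deterministic given the seed).  All three signals are
    normalized to unit L2 norm.

    Raises
    ------
    FrequencyError
        If the cubic harmonic band ``3 * (carrier + bandwidth/2)`` would
        exceed the Nyquist frequency.
    """
    nyquist = fs / 2.0
    if 3.0 * (carrier + bandwidth / 2.0) > nyquist:
        raise FrequencyError(
            f"cubic harmonic of {carrier} Hz (bandwidth {bandwidth}) exceeds "
            f"Nyquist {nyquist} Hz"
        )
    if bandwidth <= 0 or carrier - bandwidth / 2.0 <= 0:
        raise ConfigurationError("need 0 < bandwidth < 2 * carrier")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= carrier - bandwidth / 2.0) & (freqs <= carrier + bandwidth / 2.0)
    x1 = np.fft.irfft(spectrum * mask, n=n_samples)
    x2 = x1**2
    x3 = x1**3
    x1 = x1 / np.linalg.norm(x1)
    x2 = x2 / np.linalg.norm(x2)
    x3 = x3 / np.linalg.norm(x3)
    return SourceSignals(
        x1=x1,
        x2=x2,
        x3=x3,
        carrier=carrier,
        bandwidth=bandwidth,
        fs=fs,
        seed=seed if isinstance(seed, int) else None,
    )


def _source_activities(src: SourceSignals, assignment: str) -> np.ndarray:
    if assignment == "one_source":
        return np.stack([src.x1 + src.x2 + src.x3])
    if assignment == "two_sources":
        return np.stack([src.x1 + src.x2, src.x3])
    return np.stack([src.x1, src.x2, src.x3])


def assign_and_mix(
    src: SourceSignals,
    model: MixingModel,
    epoch_len: int = 512,
) -> EpochedRecording:
    """Map source activities through the mixing matrix and cut into epochs.

    Trailing samples not filling a complete epoch are dropped.
    """
    s = _source_activities(src, model.assignment)
    k = s.shape[0]
    a = model.mixing_matrix
    if a.shape[1] < k:
        raise ConfigurationError(
            f"mixing matrix has {a.shape[1]} columns, assignment needs {k}"
        )
    if a.shape[0] < 3:
        raise ConfigurationError(
            "need at least 3 sensors for triple-wise coupling analysis"
        )
    a = a[:, :k]
    if np.linalg.matrix_rank(a) < k:
        raise ConfigurationError("mixing matrix is rank deficient over active sources")
    sensors = a @ s
    if model.sensor_noise_level > 0:
        rng = np.random.default_rng(model.noise_seed)
        rms = np.sqrt(np.mean(sensors**2, axis=1, keepdims=True))
        sensors = sensors + model.sensor_noise_level * rms * rng.standard_normal(
            sensors.shape
        )
    n_epochs = sensors.shape[1] // epoch_len
    if n_epochs < 1:
        raise ValidationError(
            f"signal of {sensors.shape[1]} samples shorter than one epoch ({epoch_len})"
        )
    data = sensors[:, : n_epochs * epoch_len].reshape(a.shape[0], n_epochs, epoch_len)
    return EpochedRecording(data=data, fs=src.fs)


def default_mixing(
    n_sensors: int,
    n_sources: int,
    seed: int | np.random.Generator | None = None,
    identity: bool = False,
) -> np.ndarray:
    """Seeded full-column-rank mixing matrix with smooth sensor patterns.

    Each source projects a Gaussian spatial profile (random center and width
    along a normalized sensor axis) plus a small random component; the draw is
    repeated if it comes out rank deficient.  With ``identity=True`` (requires
    ``n_sensors == n_sources``) the identity matrix is returned.
    """
    if n_sensors < n_sources:
        raise ConfigurationError("need at least as many sensors as sources")
    if identity:
        if n_sensors != n_sources:
            raise ConfigurationError("identity mixing requires n_sensors == n_sources")
        return np.eye(n_sensors)
    rng = np.random.default_rng(seed)
    positions = np.linspace(0.0, 1.0, n_sensors)
    for attempt in range(10):
        centers = rng.uniform(0.1, 0.9, size=n_sources)
        widths = rng.uniform(0.08, 0.25, size=n_sources)
        a = np.exp(
            -((positions[:, None] - centers[None, :]) ** 2)
            / (2.0 * widths[None, :] ** 2)
        )
        a += 0.05 * rng.standard_normal(a.shape)
        if np.linalg.matrix_rank(a) == n_sources:
            return a
        logger.info("mixing draw %d rank deficient, redrawing", attempt)
    raise ConfigurationError("could not draw a full-rank mixing matrix")


def simulate_recording(
    assignment: str,
    n_sensors: int = 64,
    fs: float = 256.0,
    epoch_seconds: float = 2.0,
    n_epochs: int = 120,
    carrier: float = 10.0,
    bandwidth: float = 1.0,
    sensor_noise_level: float = 0.0,
    seed: int | None = None,
) -> EpochedRecording:
    """One-call simulation: sources, default mixing, sensor mapping, epoching."""
    epoch_len = int(round(epoch_seconds * fs))
    n_samples = n_epochs * epoch_len
    src = generate_sources(
        carrier=carrier, bandwidth=bandwidth, fs=fs, n_samples=n_samples, seed=seed
    )
    rng = np.random.default_rng(None if seed is None else seed + 1)
    model = MixingModel(
        assignment=assignment,
        mixing_matrix=default_mixing(n_sensors, 3, seed=rng),
        sensor_noise_level=sensor_noise_level,
        noise_seed=None if seed is None else seed + 2,
    )
    return assign_and_mix(src, model, epoch_len=epoch_len)
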