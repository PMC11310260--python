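"""Forward-simulated EEG studies with known ground truth.

Oscillatory sources (band-limited Gaussian noise) are placed on a
hemispherical source mesh, projected to sensors through an analytic
spherical lead field, and mixed with 1/f background plus white sensor
noise.  Condition-dependent amplitude gains give every simulated study a
recoverable true suppression index: a gain of ``a`` relative to a gain-1
baseline condition corresponds to a true log10 band-power ratio of
``2*log10(a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.spatial import Delaunay

from .core import (
    ConfigurationError,
    InvalidGeometryError,
    Recording,
    SourceModel,
)

#: default condition labels; entries starting with "rest" are resting blocks
DEFAULT_CONDITIONS = ("balls", "simple", "complex", "social")
DEFAULT_REST_CONDITIONS = ("rest_open", "rest_closed")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SourceSpec:
    """One oscillatory source: mesh location, band, and per-condition gain.

    condition_gains keys are condition labels; a key of the form
    ``"session/condition"`` (e.g. ``"post/complex"``) overrides the plain
    condition gain for that session only.
    """

    vertex_index: int
    band_lo: float
    band_hi: float
    base_amplitude: float
    condition_gains: dict[str, float]

    def __post_init__(self) -> None:
        if not self.band_lo < self.band_hi:
            raise ConfigurationError("band_lo must be < band_hi")
        if self.base_amplitude <= 0:
            raise ConfigurationError("base_amplitude must be > 0")
        if any(g < 0 for g in self.condition_gains.values()):
            raise ConfigurationError("condition gains must be >= 0")

    def has_condition(self, condition: str) -> bool:
        return condition in self.condition_gains or any(
            k.endswith(f"/{condition}") for k in self.condition_gains
        )

    def gain(self, condition: str, session: str = "") -> float:
        key = f"{session}/{condition}"
        if session and key in self.condition_gains:
            return self.condition_gains[key]
        try:
            return self.condition_gains[condition]
        except KeyError:
            raise ConfigurationError(
                f"source has no gain for condition {condition!r}"
            ) from None


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults mirror the target study)."""

    n_subjects: int = 16
    n_sessions: int = 2
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    rest_conditions: tuple[str, ...] = ()
    clip_seconds: float = 24.0
    clips_per_condition: int = 5
    rest_seconds: float = 120.0
    fs: float = 512.0
    noise_sd: float = 0.1
    pink_sd: float = 0.1
    pink_exponent: float = 1.0
    subject_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_sessions, self.clips_per_condition) < 1:
            raise ConfigurationError("counts must be positive")
        if self.fs <= 0 or self.clip_seconds <= 0 or self.rest_seconds <= 0:
            raise ConfigurationError("fs and durations must be positive")

    @property
    def session_labels(self) -> list[str]:
        return ["pre", "post"][: self.n_sessions] if self.n_sessions <= 2 else [
            f"s{i}" for i in range(self.n_sessions)
        ]


@dataclass
class GroundTruth:
    """Per subject/session/condition/source amplitude gains and true MSI."""

    gains: dict[tuple[str, str, str, int], float] = field(default_factory=dict)

    def true_msi(
        self, subject: str, session: str, condition: str,
        baseline: str = "balls", source: int = 0,
    ) -> float:
        g = self.gains[(subject, session, condition, source)]
        g0 = self.gains[(subject, session, baseline, source)]
        return 2.0 * np.log10(g / g0)


def _fibonacci_hemisphere(n: int, radius: float, rng: np.random.Generator,
                          jitter: float = 0.0) -> np.ndarray:
    """Quasi-uniform points on the upper (z > 0) hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n                       # strictly in (0, 1)
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(1.0 - z**2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if jitter > 0:
        pts = pts + jitter * rng.standard_normal(pts.shape)
        pts[:, 2] = np.abs(pts[:, 2])       # stay on the upper half
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return radius * pts


def _triangulate(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay mesh of hemisphere points via their (x, y) projection."""
    n = vertices.shape[0]
    adjacency = np.zeros((n, n))
    if n < 3:
        return np.zeros((0, 3), dtype=int), adjacency
    try:
        tri = Delaunay(vertices[:, :2])
    except Exception as exc:  # pragma: no cover - degenerate geometry
        raise InvalidGeometryError(f"cannot triangulate source mesh: {exc}")
    triangles = tri.simplices.astype(int)
    for a, b, c in triangles:
        for u, v in ((a, b), (b, c), (a, c)):
            adjacency[u, v] = adjacency[v, u] = 1.0
    return triangles, adjacency


def make_head_model(
    n_vertices: int,
    n_channels: int,
    seed: int = 0,
    r_src: float = 0.8,
    r_chan: float = 1.0,
    jitter: float = 0.02,
) -> SourceModel:
    """Build a hemispherical source mesh, a sensor shell, and a lead field.

    The lead-field entry for channel c and vertex v is the inverse-square
    kernel ``g(c, v) = r_src**2 / |x_c - x_v|**2``: a smooth function of
    the channel-vertex angle that decays monotonically as the angle grows,
    standing in for a dipole-in-conducting-sphere forward solution while
    preserving its spatial-mixing structure.
    """
    if n_vertices < 1:
        raise InvalidGeometryError("need at least one source vertex")
    if n_channels < 4:
        raise InvalidGeometryError("need at least four channels")
    if r_chan <= r_src:
        raise InvalidGeometryError("sensor shell must enclose the source shell")
    rng = np.random.default_rng(seed)
    vertices = _fibonacci_hemisphere(n_vertices, r_src, rng, jitter)
    channels = _fibonacci_hemisphere(n_channels, r_chan, rng, jitter)
    triangles, adjacency = _triangulate(vertices)
    diff = channels[:, None, :] - vertices[None, :, :]
    dist2 = np.sum(diff**2, axis=2)
    leadfield = r_src**2 / dist2
    ch_names = [f"E{i:02d}" for i in range(n_channels)]
    return SourceModel(vertices, channels, ch_names, triangles, adjacency, leadfield)


def pink_noise(
    shape: tuple[int, ...], fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f**exponent (power) Gaussian noise, unit RMS per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


@lru_cache(maxsize=64)
def _bandpass_sos(fs: float, lo: float, hi: float) -> np.ndarray:
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _band_limited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-pass filtered Gaussian noise normalized to unit RMS."""
    x = sps.sosfiltfilt(_bandpass_sos(fs, lo, hi), rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_condition(
    model: SourceModel,
    sources: list[SourceSpec],
    condition: str,
    duration: float,
    cfg: SimConfig,
    seed: int,
    amplitude_scale: float = 1.0,
    session: str = "",
) -> Recording:
    """Simulate one condition block: lead field x sources + pink + white noise.

    Deterministic given seed.  amplitude_scale carries subject-level jitter.
    """
    n = int(round(duration * cfg.fs))
    if n < 1:
        raise ConfigurationError("duration too short for one sample")
    for src in sources:
        if not src.has_condition(condition):
            raise ConfigurationError(
                f"condition {condition!r} missing from source gains"
            )
        if cfg.fs <= 2 * src.band_hi:
            raise ConfigurationError("fs must exceed twice every band_hi")
    rng = np.random.default_rng(seed)
    sensor = np.zeros((model.n_channels, n))
    for src in sources:
        wave = _band_limited_noise(n, cfg.fs, src.band_lo, src.band_hi, rng)
        amp = src.base_amplitude * src.gain(condition, session) * amplitude_scale
        sensor += np.outer(model.leadfield[:, src.vertex_index], amp * wave)
    if cfg.pink_sd > 0:
        sensor += cfg.pink_sd * pink_noise(
            (model.n_channels, n), cfg.fs, cfg.pink_exponent, rng
        )
    if cfg.noise_sd > 0:
        sensor += cfg.noise_sd * rng.standard_normal((model.n_channels, n))
    return Recording(sensor, cfg.fs, list(model.ch_names), condition=condition)


def simulate_study(
    cfg: SimConfig,
    sources: list[SourceSpec],
    model: SourceModel,
) -> tuple[list[Recording], GroundTruth]:
    """Simulate a full study: subjects x sessions x conditions.

    Action conditions get one recording of clips_per_condition * clip_seconds
    (clips are contiguous sub-blocks); rest conditions get rest_seconds.
    Subject-level log-normal amplitude jitter is drawn once per subject.
    A seed-sequence split keys every block on (seed, subject, session,
    condition) so any block is reproducible in isolation.
    """
    truth = GroundTruth()
    recordings: list[Recording] = []
    jit_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11CE]))
    jitters = np.exp(cfg.subject_jitter_sd * jit_rng.standard_normal(cfg.n_subjects))
    all_conditions = list(cfg.conditions) + list(cfg.rest_conditions)
    for si in range(cfg.n_subjects):
        subject = f"sub{si:02d}"
        for gi, session in enumerate(cfg.session_labels):
            for ci, condition in enumerate(all_conditions):
                if condition in cfg.rest_conditions:
                    duration = cfg.rest_seconds
                else:
                    duration = cfg.clip_seconds * cfg.clips_per_condition
                block_seed = np.random.SeedSequence([cfg.seed, 1 + si, gi, ci])
                rec = simulate_condition(
                    model, sources, condition, duration, cfg,
                    seed=block_seed, amplitude_scale=jitters[si], session=session,
                )
                rec.subject, rec.session = subject, session
                recordings.append(rec)
                for k, src in enumerate(sources):
                    truth.gains[(subject, session, condition, k)] = src.gain(
                        condition, session
                    )
    return recordings, truth


def default_sources(
    model: SourceModel,
    mu_gains: dict[str, float] | None = None,
    with_alpha_confound: bool = True,
    base_amplitude: float = 1.0,
) -> list[SourceSpec]:
    """A central mu source plus (optionally) an occipital alpha confound.

    The mu source sits at the vertex closest to the vertex (apex) of the
    hemisphere; the alpha confound at the most posterior (lowest-z, most
    negative-x) vertex, emulating the concern that posterior alpha leaks
    into central sensors.
    """
    conditions = set(DEFAULT_CONDITIONS) | set(DEFAULT_REST_CONDITIONS)
    apex = int(np.argmax(model.vertices[:, 2]))
    gains = {c: 1.0 for c in conditions}
    if mu_gains:
        gains.update(mu_gains)
    sources = [SourceSpec(apex, 8.0, 13.0, base_amplitude, gains)]
    if with_alpha_confound:
        score = model.vertices[:, 2] - model.vertices[:, 0]
        posterior = int(np.argmin(score))
        sources.append(
            SourceSpec(posterior, 8.0, 13.0, 0.5 * base_amplitude,
                       {c: 1.0 for c in conditions})
        )
    return sources
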