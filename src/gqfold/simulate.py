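"""Synthetic two-channel smFRET datasets and synthetic ligand spectra.

The generator emulates prism-TIRF smFRET recordings of surface-immobilized
DNA carrying a donor (Cy3-like) / acceptor (Cy5-like) pair across a duplex
with a potential GQ-forming insert: a folded GQ brings the dyes close (high
apparent FRET, ~0.8) while the plain duplex keeps them apart (low FRET,
~0.3).  Each molecule is donor-only, statically folded, statically duplexed,
or dynamic (a two-state Markov chain hopping between folded and duplex).
Frames are 100 ms; a brief direct-acceptor-excitation ("red") pulse at the
start marks molecules with an active acceptor; dyes photobleach with
exponential lifetimes; channel noise is additive Gaussian.

Molecules are grouped into fields of view of 400-500 molecules, mirroring
typical surface densities, and everything is bit-reproducible from one seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .spectra import (
    CV_EXCITATION_NM,
    CV_PEAK_NM,
    EmissionSpectrum,
    NMM_EXCITATION_NM,
    NMM_PEAKS_NM,
)

__all__ = [
    "TraceSimConfig",
    "TraceTruth",
    "Trace",
    "TraceDataset",
    "rng_stream",
    "simulate_trace",
    "simulate_dataset",
    "simulate_spectrum",
    "construct_config",
    "CONSTRUCT_FOLDED_PERCENT",
]

STATE_DUPLEX = 0
STATE_FOLDED = 1

#: Measured dsDNA folded percentages used as generative ground truth for the
#: packaged construct fixtures (loop-profile names; CMYC is the 1-2-1 profile).
CONSTRUCT_FOLDED_PERCENT: dict[str, float] = {
    "CMYC": 92.0,
    "1-3-3": 86.0,
    "1-4-4": 66.0,
    "1-5-5": 58.0,
    "TTA3": 0.0,
}

#: Constructs whose single-molecule traces show reversible folding dynamics.
_DYNAMIC_CONSTRUCTS = frozenset({"1-4-4", "1-5-5"})


def rng_stream(seed: int, *keys: object) -> np.random.Generator:
    """Named, collision-resistant substream of a single master seed."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class TraceSimConfig:
    """Generative parameters for one smFRET dataset.

    Intensity units are camera counts per frame; times are seconds.  The
    defaults describe a 1-minute recording at 100 ms frames with total
    emission 500 ± 50 counts/frame per molecule and 30 counts of per-channel
    Gaussian noise.
    """

    n_molecules: int = 500
    frame_interval: float = 0.1
    n_frames: int = 600
    folded_fraction: float = 0.5
    e_folded: float = 0.8
    e_duplex: float = 0.3
    total_intensity_mean: float = 500.0
    total_intensity_sd: float = 50.0
    channel_noise_sd: float = 30.0
    background_mean: float = 0.0
    donor_only_fraction: float = 0.2
    dynamic_fraction: float = 0.0
    k_unfold: float = 0.5  # folded -> duplex, 1/s
    k_fold: float = 0.5  # duplex -> folded, 1/s
    donor_bleach_mean_s: float = 60.0
    acceptor_bleach_mean_s: float = 60.0
    red_pulse_frames: int = 5
    molecules_per_field: tuple[int, int] = (400, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("folded_fraction", "donor_only_fraction", "dynamic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k_unfold < 0 or self.k_fold < 0:
            raise ValueError("rates must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1 or self.n_molecules < 1:
            raise ValueError("n_frames and n_molecules must be >= 1")
        if not self.e_folded > self.e_duplex:
            raise ValueError("e_folded must exceed e_duplex")
        lo, hi = self.molecules_per_field
        if not (1 <= lo <= hi):
            raise ValueError("molecules_per_field must be a valid (lo, hi) range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["molecules_per_field"] = list(self.molecules_per_field)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "TraceSimConfig":
        data = dict(data)
        if "molecules_per_field" in data:
            data["molecules_per_field"] = tuple(data["molecules_per_field"])
        return cls(**data)


@dataclass(frozen=True)
class TraceTruth:
    class_: str  # donor_only | static_folded | static_duplex | dynamic
    state_path: np.ndarray  # per-frame STATE_DUPLEX/STATE_FOLDED
    donor_bleach_frame: Optional[int]  # None = never within the recording
    acceptor_bleach_frame: Optional[int]


@dataclass(frozen=True)
class Trace:
    molecule_id: int
    time: np.ndarray  # s
    donor: np.ndarray
    acceptor: np.ndarray
    red_pulse_acceptor: np.ndarray  # initial direct-excitation marker frames
    truth: Optional[TraceTruth] = None

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("trace series lengths must match")
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class TraceDataset:
    traces: list[Trace]
    field_of_molecule: np.ndarray  # field index per molecule
    config: TraceSimConfig

    @property
    def n_fields(self) -> int:
        return int(self.field_of_molecule.max()) + 1 if len(self.traces) else 0

    def field_traces(self, field_index: int) -> list[Trace]:
        return [
            t
            for t, f in zip(self.traces, self.field_of_molecule)
            if f == field_index
        ]


def _markov_state_path(
    n_frames: int, dt: float, k_unfold: float, k_fold: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact per-frame discretization of the two-state folding chain.

    Transition probabilities over one frame come from the closed-form matrix
    exponential of the 2-state rate matrix; the initial state is drawn from
    the stationary distribution.
    """
    ktot = k_unfold + k_fold
    if ktot == 0:
        state0 = STATE_FOLDED if rng.random() < 0.5 else STATE_DUPLEX
        return np.full(n_frames, state0, dtype=np.int8)
    p_stat_folded = k_fold / ktot
    decay = 1.0 - math.exp(-ktot * dt)
    p_fold_to_duplex = (k_unfold / ktot) * decay
    p_duplex_to_fold = (k_fold / ktot) * decay
    u = rng.random(n_frames)
    path = np.empty(n_frames, dtype=np.int8)
    state = STATE_FOLDED if u[0] < p_stat_folded else STATE_DUPLEX
    path[0] = state
    for t in range(1, n_frames):
        p_switch = p_fold_to_duplex if state == STATE_FOLDED else p_duplex_to_fold
        if u[t] < p_switch:
            state = 1 - state
        path[t] = state
    return path


def _draw_class(config: TraceSimConfig, rng: np.random.Generator) -> str:
    if rng.random() < config.donor_only_fraction:
        return "donor_only"
    if rng.random() < config.dynamic_fraction:
        return "dynamic"
    return "static_folded" if rng.random() < config.folded_fraction else "static_duplex"


def _bleach_frame(
    mean_s: float, dt: float, n_frames: int, rng: np.random.Generator
) -> Optional[int]:
    if mean_s <= 0 or not np.isfinite(mean_s):
        return None
    frame = int(rng.exponential(mean_s) / dt)
    return frame if frame < n_frames else None


def simulate_trace(
    config: TraceSimConfig, molecule_index: int, rng: np.random.Generator
) -> Trace:
    """Simulate one molecule's donor/acceptor trace with truth labels."""
    n, dt = config.n_frames, config.frame_interval
    cls = _draw_class(config, rng)

    if cls == "dynamic":
        path = _markov_state_path(n, dt, config.k_unfold, config.k_fold, rng)
    elif cls == "static_folded":
        path = np.full(n, STATE_FOLDED, dtype=np.int8)
    else:  # static_duplex and donor_only share the duplex geometry
        path = np.full(n, STATE_DUPLEX, dtype=np.int8)

    intensity = max(rng.normal(config.total_intensity_mean, config.total_intensity_sd), 1.0)
    has_acceptor = cls != "donor_only"
    donor_bleach = _bleach_frame(config.donor_bleach_mean_s, dt, n, rng)
    acceptor_bleach = (
        _bleach_frame(config.acceptor_bleach_mean_s, dt, n, rng) if has_acceptor else None
    )

    e_state = np.where(path == STATE_FOLDED, config.e_folded, config.e_duplex)
    if has_acceptor:
        donor_signal = intensity * (1.0 - e_state)
        acceptor_signal = intensity * e_state
    else:
        donor_signal = np.full(n, intensity)
        acceptor_signal = np.zeros(n)

    frames = np.arange(n)
    if acceptor_bleach is not None:
        after = frames >= acceptor_bleach
        acceptor_signal = np.where(after, 0.0, acceptor_signal)
        donor_signal = np.where(after, intensity, donor_signal)
    if donor_bleach is not None:
        after = frames >= donor_bleach
        donor_signal = np.where(after, 0.0, donor_signal)
        acceptor_signal = np.where(after, 0.0, acceptor_signal)

    noise_sd = config.channel_noise_sd
    bg = config.background_mean
    donor = donor_signal + bg + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else donor_signal + bg
    acceptor = (
        acceptor_signal + bg + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else acceptor_signal + bg
    )

    red_alive = has_acceptor and (acceptor_bleach is None or acceptor_bleach >= 1)
    red_signal = intensity if red_alive else 0.0
    red = np.full(config.red_pulse_frames, red_signal) + bg
    if noise_sd > 0:
        red = red + rng.normal(0.0, noise_sd, config.red_pulse_frames)

    return Trace(
        molecule_id=molecule_index,
        time=frames * dt,
        donor=np.maximum(donor, 0.0),
        acceptor=np.maximum(acceptor, 0.0),
        red_pulse_acceptor=np.maximum(red, 0.0),
        truth=TraceTruth(
            class_=cls,
            state_path=path,
            donor_bleach_frame=donor_bleach,
            acceptor_bleach_frame=acceptor_bleach,
        ),
    )


def _field_assignment(
    n_molecules: int, per_field: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = per_field
    out = np.empty(n_molecules, dtype=np.int64)
    pos = 0
    fov = 0
    while pos < n_molecules:
        size = int(rng.integers(lo, hi + 1))
        out[pos : pos + size] = fov
        pos += size
        fov += 1
    return out


def simulate_dataset(config: TraceSimConfig) -> TraceDataset:
    """Simulate a full dataset, partitioned into fields of view.

    Every random draw flows from ``config.seed`` through named substreams, so
    the same config reproduces a bit-identical dataset.
    """
    field_rng = rng_stream(config.seed, "fields")
    fields = _field_assignment(config.n_molecules, config.molecules_per_field, field_rng)
    master = np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, zlib.crc32(b"traces")]
    )
    traces = [
        simulate_trace(config, i, np.random.default_rng(child))
        for i, child in enumerate(master.spawn(config.n_molecules))
    ]
    return TraceDataset(traces=traces, field_of_molecule=fields, config=config)


def construct_config(
    name: str, seed: int = 7, n_molecules: int = 5000, **overrides
) -> TraceSimConfig:
    """Fixture config for one of the packaged dsDNA constructs.

    ``folded_fraction`` is the measured folded percentage of the construct;
    1-4-4 and 1-5-5 additionally carry a 4% dynamic subpopulation whose
    Markov rates are balanced so its stationary folded occupancy equals the
    construct's folded fraction (total rate 1 /s).
    """
    if name not in CONSTRUCT_FOLDED_PERCENT:
        raise ValueError(
            f"unknown construct {name!r}; choose from {sorted(CONSTRUCT_FOLDED_PERCENT)}"
        )
    f = CONSTRUCT_FOLDED_PERCENT[name] / 100.0
    dynamic = 0.04 if name in _DYNAMIC_CONSTRUCTS else 0.0
    params = dict(
        n_molecules=n_molecules,
        folded_fraction=f,
        dynamic_fraction=dynamic,
        k_fold=f if dynamic else 0.5,
        k_unfold=1.0 - f if dynamic else 0.5,
        seed=seed,
    )
    params.update(overrides)
    return TraceSimConfig(**params)


_SPECTRUM_GRID = np.arange(550.0, 750.0 + 1.0, 1.0)
_NMM_AMPLITUDES = (1000.0, 600.0)  # 610 and 670 nm bands
_NMM_WIDTHS = (12.0, 18.0)
_CV_AMPLITUDE = 1000.0
_CV_WIDTH = 20.0


def simulate_spectrum(
    ligand: str,
    response_level: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 2.0,
    sample_id: str = "",
) -> EmissionSpectrum:
    """Synthetic ligand emission spectrum on a 550-750 nm, 1 nm grid.

    NMM is modeled as two Gaussian bands at 610 and 670 nm, CV as a single
    band at 640 nm; amplitudes scale linearly with ``response_level`` in
    [0, 1] (the GQ-bound fraction the ligand reports), plus additive noise.
    """
    if not 0.0 <= response_level <= 1.0:
        raise ValueError("response_level must be in [0, 1]")
    rng = rng or np.random.default_rng()
    w = _SPECTRUM_GRID.copy()
    y = np.zeros_like(w)
    if ligand == "NMM":
        for amp, center, width in zip(_NMM_AMPLITUDES, NMM_PEAKS_NM, _NMM_WIDTHS):
            y += response_level * amp * np.exp(-0.5 * ((w - center) / width) ** 2)
        excitation = NMM_EXCITATION_NM
    elif ligand == "CV":
        y += response_level * _CV_AMPLITUDE * np.exp(
            -0.5 * ((w - CV_PEAK_NM) / _CV_WIDTH) ** 2
        )
        excitation = CV_EXCITATION_NM
    else:
        raise ValueError("ligand must be 'NMM' or 'CV'")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, w.size)
    return EmissionSpectrum(
        wavelengths=w,
        intensities=np.maximum(y, 0.0),
        excitation_nm=excitation,
        ligand=ligand,
        sample_id=sample_id,
    )
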