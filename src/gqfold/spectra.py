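"""Ligand emission spectra and CD spectra processing.

Two conformation-selective ligands report GQ topology: NMM (N-methyl
mesoporphyrin IX) fluoresces when bound to parallel GQs, with emission peaks
at 610 and 670 nm under 393 nm excitation; Crystal Violet (CV) fluoresces
when bound to antiparallel GQs, read at 640 nm under 540 nm excitation.
Normalized (nmm_percent, cv_percent) readouts place samples in a 2-D plane
where parallel, antiparallel and unfolded species form separated clusters; a
nearest-centroid model fitted on labeled calibration samples assigns classes.

Circular dichroism offers an orthogonal check in ssDNA: a parallel GQ shows a
positive peak near 260 nm with a valley near 240 nm, an antiparallel GQ a
major positive peak near 290 nm.  CD cannot resolve a GQ embedded in duplex
DNA (the duplex contributes a broad ~275 nm band), so such spectra are
reported as indeterminate rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "EmissionSpectrum",
    "LigandReadout",
    "ClusterModel",
    "CDSpectrum",
    "peak_intensity",
    "subtract_background",
    "normalize_to_reference",
    "fit_centroids",
    "classify_point",
    "pearson_correlation",
    "classify_cd_spectrum",
]

CLASS_ORDER = ("parallel", "antiparallel", "unfolded")

NMM_PEAKS_NM = (610.0, 670.0)
CV_PEAK_NM = 640.0
NMM_EXCITATION_NM = 393.0
CV_EXCITATION_NM = 540.0


@dataclass(frozen=True)
class EmissionSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # arbitrary fluorescence units
    excitation_nm: float
    ligand: str  # NMM | CV | none
    sample_id: str = ""
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or w.shape != i.shape:
            raise ValueError("wavelengths and intensities must be equal-length 1-D")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.ligand not in ("NMM", "CV", "none"):
            raise ValueError(f"unknown ligand {self.ligand!r}")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class LigandReadout:
    sample_id: str
    nmm_610: float
    nmm_670: float
    cv_640: float
    nmm_percent: float | None = None
    cv_percent: float | None = None


@dataclass(frozen=True)
class CDSpectrum:
    wavelengths: np.ndarray  # nm, nominally 200-320
    ellipticity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        e = np.asarray(self.ellipticity, dtype=float)
        if w.shape != e.shape or w.ndim != 1:
            raise ValueError("wavelengths and ellipticity must be equal-length 1-D")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "ellipticity", e)

    def covers(self, *nm: float) -> bool:
        return all(self.wavelengths[0] <= x <= self.wavelengths[-1] for x in nm)


def peak_intensity(
    spectrum: EmissionSpectrum, wavelength: float, half_window: float = 2.0
) -> float:
    """Mean intensity over ``wavelength ± half_window``.

    The spectrum is treated as piecewise linear; the window mean is the exact
    integral of the interpolant over the window divided by its width, so
    window edges falling between sample points are handled by interpolation.
    ``half_window = 0`` reads the interpolated point value.
    """
    w, inten = spectrum.wavelengths, spectrum.intensities
    lo, hi = wavelength - half_window, wavelength + half_window
    if lo < w[0] or hi > w[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] nm outside spectrum coverage [{w[0]}, {w[-1]}] nm"
        )
    if half_window == 0:
        return float(np.interp(wavelength, w, inten))
    inside = (w > lo) & (w < hi)
    xs = np.concatenate(([lo], w[inside], [hi]))
    ys = np.interp(xs, w, inten)
    return float(np.trapezoid(ys, xs) / (hi - lo))


def subtract_background(
    spectrum: EmissionSpectrum, control: EmissionSpectrum
) -> EmissionSpectrum:
    """Subtract a no-GQ control spectrum pointwise, floored at zero.

    The control is linearly interpolated onto the sample grid; ligand and
    excitation wavelength must match.
    """
    if spectrum.ligand != control.ligand:
        raise ValueError(
            f"ligand mismatch: {spectrum.ligand} vs control {control.ligand}"
        )
    if spectrum.excitation_nm != control.excitation_nm:
        raise ValueError("excitation wavelength mismatch")
    ctrl = np.interp(spectrum.wavelengths, control.wavelengths, control.intensities)
    return replace(spectrum, intensities=np.maximum(spectrum.intensities - ctrl, 0.0))


def readout_from_spectra(
    sample_id: str,
    nmm_spectrum: EmissionSpectrum | None,
    cv_spectrum: EmissionSpectrum | None,
    half_window: float = 2.0,
) -> LigandReadout:
    """Extract the 610/670 (NMM) and 640 nm (CV) peak intensities."""
    nmm_610 = nmm_670 = cv_640 = 0.0
    if nmm_spectrum is not None:
        nmm_610 = peak_intensity(nmm_spectrum, NMM_PEAKS_NM[0], half_window)
        nmm_670 = peak_intensity(nmm_spectrum, NMM_PEAKS_NM[1], half_window)
    if cv_spectrum is not None:
        cv_640 = peak_intensity(cv_spectrum, CV_PEAK_NM, half_window)
    return LigandReadout(sample_id, nmm_610, nmm_670, cv_640)


def normalize_to_reference(
    readouts: Sequence[LigandReadout], reference_sample_id: str
) -> list[LigandReadout]:
    """Express each channel as percent of a reference sample (which maps to 100)."""
    try:
        ref = next(r for r in readouts if r.sample_id == reference_sample_id)
    except StopIteration:
        raise ValueError(f"reference sample {reference_sample_id!r} not found")
    if ref.nmm_610 <= 0 or ref.cv_640 <= 0:
        raise ValueError("reference peak intensities must be positive to normalize")
    return [
        replace(
            r,
            nmm_percent=100.0 * r.nmm_610 / ref.nmm_610,
            cv_percent=100.0 * r.cv_640 / ref.cv_640,
        )
        for r in readouts
    ]


@dataclass(frozen=True)
class ClusterModel:
    """Nearest-centroid model over the (nmm_percent, cv_percent) plane."""

    centroids: Mapping[str, tuple[float, float]]
    metric: str = "standardized_euclidean"
    channel_scale: tuple[float, float] = (1.0, 1.0)  # per-channel sd of training set

    def __post_init__(self) -> None:
        if set(self.centroids) != set(CLASS_ORDER):
            raise ValueError(f"centroids must cover exactly {CLASS_ORDER}")
        pts = list(self.centroids.values())
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("centroids must be pairwise distinct")
        if self.metric not in ("euclidean", "standardized_euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


def fit_centroids(
    labeled_points: Sequence[tuple[float, float, str]],
    metric: str = "standardized_euclidean",
) -> ClusterModel:
    """Per-class mean of labeled (nmm_percent, cv_percent) calibration points.

    With the standardized metric, distances are computed in per-channel
    z-units using the calibration set's channel standard deviations, so the
    typically larger NMM range does not dominate.
    """
    by_class: dict[str, list[tuple[float, float]]] = {c: [] for c in CLASS_ORDER}
    for x, y, label in labeled_points:
        if label not in by_class:
            raise ValueError(f"unknown class label {label!r}")
        by_class[label].append((x, y))
    missing = [c for c, pts in by_class.items() if not pts]
    if missing:
        raise ValueError(f"no calibration points for class(es) {missing}")
    centroids = {
        c: tuple(np.mean(np.asarray(pts), axis=0)) for c, pts in by_class.items()
    }
    all_pts = np.asarray([(x, y) for x, y, _ in labeled_points])
    scale = np.std(all_pts, axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return ClusterModel(centroids=centroids, metric=metric, channel_scale=tuple(scale))


def classify_point(
    point: tuple[float, float], model: ClusterModel
) -> tuple[str, dict[str, float]]:
    """Assign the nearest centroid; ties break by parallel > antiparallel > unfolded.

    Returns the class and the distance to every centroid under the model
    metric.
    """
    p = np.asarray(point, dtype=float)
    scale = (
        np.asarray(model.channel_scale)
        if model.metric == "standardized_euclidean"
        else np.ones(2)
    )
    distances = {
        c: float(np.linalg.norm((p - np.asarray(model.centroids[c])) / scale))
        for c in CLASS_ORDER
    }
    best = min(CLASS_ORDER, key=lambda c: (distances[c], CLASS_ORDER.index(c)))
    return best, distances


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit precondition checks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _smooth3(values: np.ndarray) -> np.ndarray:
    if values.size < 3:
        return values
    kernel = np.ones(3) / 3.0
    out = np.convolve(values, kernel, mode="same")
    out[0], out[-1] = values[0], values[-1]
    return out


def classify_cd_spectrum(
    spectrum: CDSpectrum, window_nm: float = 5.0
) -> str:
    """Rule-based CD topology call for ssDNA GQ spectra.

    parallel: a local maximum within 260 ± window and a local minimum within
    240 ± window.  antiparallel: the global positive maximum lies within
    290 ± window.  Anything else (including the broad duplex ~275 nm band) is
    indeterminate.  Spectra are smoothed with a 3-point moving average first.
    """
    required = (240.0, 260.0, 275.0, 290.0)
    if not spectrum.covers(*required):
        raise ValueError(f"CD spectrum must cover {required} nm")
    w = spectrum.wavelengths
    y = _smooth3(spectrum.ellipticity)

    max_idx, _ = signal.find_peaks(y)
    min_idx, _ = signal.find_peaks(-y)
    has_peak_260 = any(abs(w[i] - 260.0) <= window_nm and y[i] > 0 for i in max_idx)
    has_valley_240 = any(abs(w[i] - 240.0) <= window_nm and y[i] < 0 for i in min_idx)
    if has_peak_260 and has_valley_240:
        return "parallel"

    if np.any(y > 0):
        gmax = int(np.argmax(y))
        if abs(w[gmax] - 290.0) <= window_nm:
            return "antiparallel"
    return "indeterminate"
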