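"""Quantitative analysis of spatial simulations.

Provides tissue areas, basement-membrane (BM) contour extraction, power
spectra of the BM height profile (periodograms and kymographs), spectral
summaries, and per-finger length/width measurements.  Spatial frequencies
are reported in cycles per domain width; power in dB
(``10 log10`` of the linear spectral power, floored at -160 dB).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .fields import FieldState

__all__ = [
    "BMContour",
    "ContourSpectrum",
    "tissue_areas",
    "extract_bm_contour",
    "periodogram",
    "spectral_summaries",
    "finger_metrics",
    "DB_FLOOR",
]

DB_FLOOR = -160.0


@dataclass(frozen=True)
class BMContour:
    """BM height profile sampled uniformly by relative arc length.

    ``xi`` holds the relative arc-length positions in ``[0, 1)``;
    ``height`` the BM y-coordinates relative to ``baseline``.
    """

    xi: np.ndarray
    height: np.ndarray
    baseline: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("arc-length samples must be strictly increasing")
        if not np.all(np.isfinite(self.height)):
            raise ValueError("contour heights must be finite")


@dataclass(frozen=True)
class ContourSpectrum:
    """One-sided periodogram of a BM height profile."""

    frequencies: np.ndarray   # cycles per domain width, starting at 0
    power_db: np.ndarray
    power_linear: np.ndarray
    time: float = 0.0


def tissue_areas(state: FieldState) -> tuple[float, float, float]:
    """(total epithelium, CP, TD) areas as domain integrals of fractions."""
    g = state.grid
    cp = g.integrate(state.chi1)
    td = g.integrate(state.chi2)
    total = g.integrate(state.chiT)
    return total, cp, td


def _trace_bm_curve(state: FieldState) -> np.ndarray:
    """Trace the epithelium-stroma interface as the 0 level set of
    ``chiS - (chiT + chiL/2)``-like indicator; returns (k, 2) points in
    physical (x, y) coordinates ordered along the curve."""
    g = state.grid
    # stroma-vs-rest indicator: 0.5 level of chiS separates stroma from
    # tissue and fluid alike; the relevant (longest) contour is the BM.
    fld = state.chiS
    contours = measure.find_contours(fld, 0.5)
    if not contours:
        raise RuntimeError("no basement-membrane contour found")
    best = max(contours, key=lambda c: len(c))
    ys = g.y0 + (best[:, 0] + 0.5) * g.dy
    xs = g.x0 + (best[:, 1] + 0.5) * g.dx
    return np.column_stack([xs, ys])


def extract_bm_contour(state: FieldState, n: int = 256,
                       baseline: float = 0.0) -> BMContour:
    """Sample the BM height at ``n`` uniform relative arc-length positions.

    The interface is traced as a curve (so overhanging fingers remain
    measurable) and heights are taken relative to ``baseline``.  Raises
    ``RuntimeError`` when the epithelium has vanished.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    bulk_area = state.grid.integrate(state.chi1 + state.chi2)
    if bulk_area < 1e-6:
        raise RuntimeError("epithelium extinct: no BM to extract")
    pts = _trace_bm_curve(state)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise RuntimeError("degenerate BM contour")
    xi = np.arange(n) / n
    height = np.interp(xi * total, arc, pts[:, 1]) - baseline
    return BMContour(xi=xi, height=height, baseline=baseline,
                     time=state.time)


def periodogram(contour: BMContour) -> ContourSpectrum:
    """One-sided power spectrum of the mean-removed height profile.

    Normalized so the linear powers over all nonzero frequencies sum to
    the variance of the profile (Parseval).  Frequencies are in cycles
    per unit relative arc length, i.e. cycles per domain width for a
    gently perturbed strip.
    """
    h = contour.height
    n = len(h)
    if n < 16:
        raise ValueError("need at least 16 contour samples")
    H = np.fft.rfft(h - h.mean())
    p = (np.abs(H) ** 2) / n ** 2
    # one-sided: double all bins except DC and (for even n) Nyquist
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    freqs = np.arange(len(p), dtype=float)
    power_db = 10.0 * np.log10(np.clip(p, 10 ** (DB_FLOOR / 10.0), None))
    return ContourSpectrum(frequencies=freqs, power_db=power_db,
                           power_linear=p, time=contour.time)


def spectral_summaries(spectra: list[ContourSpectrum]):
    """Aggregate statistics over a time-ordered list of spectra.

    Returns a dict with ``kymograph`` (times x frequencies dB matrix),
    ``times``, ``frequencies``, ``spectral_moment(t)`` (power-weighted
    centroid frequency over f > 0), ``average_power(t)`` (mean linear
    power over f > 0) and ``dominant_frequency(t)`` (argmax over f > 0).
    The moment is NaN where the spectrum carries no power.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    freqs = spectra[0].frequencies
    kymo = np.vstack([s.power_db for s in spectra])
    times = np.array([s.time for s in spectra])
    moments = np.empty(len(spectra))
    avg_power = np.empty(len(spectra))
    dominant = np.empty(len(spectra))
    for i, s in enumerate(spectra):
        p = s.power_linear[1:]
        f = s.frequencies[1:]
        tot = p.sum()
        if tot <= 0:
            moments[i] = np.nan
            dominant[i] = np.nan
        else:
            moments[i] = float((f * p).sum() / tot)
            dominant[i] = float(f[np.argmax(p)])
        avg_power[i] = float(p.mean())
    return {
        "kymograph": kymo,
        "times": times,
        "frequencies": freqs,
        "spectral_moment": moments,
        "average_power": avg_power,
        "dominant_frequency": dominant,
    }


def finger_metrics(contour: BMContour, *, decay_length: float = 1.0,
                   domain_width: float | None = None,
                   rel_threshold: float = 0.2,
                   periodic: bool = True,
                   grow_down: bool = False) -> list[tuple[float, float]]:
    """Per-finger (length, width) in multiples of the factor decay length.

    A finger is a connected excursion of the BM height above
    ``rel_threshold`` times the maximum excursion.  Its length is the
    maximum height above the contour baseline; its width is the
    arc-length extent of the excursion measured at half the finger's
    length.  Returns an empty list when the contour carries no excursion
    (flat BM).  Periodic wraparound is honored, so the measurement is
    invariant to horizontal translation.  ``grow_down`` analyzes downward
    excursions (epithelial downgrowths into the stroma, the crypt-like
    fingering geometry) by negating the height profile.
    """
    h = contour.height.astype(float)
    if grow_down:
        h = -h
    n = len(h)
    if domain_width is None:
        domain_width = 1.0
    hmax = float(h.max())
    if hmax <= 1e-9:
        return []
    thresh = rel_threshold * hmax
    mask = h > thresh
    if mask.all():
        return [(hmax / decay_length, domain_width * 1.0 / decay_length)]
    if periodic:
        shift = int(np.argmin(mask))  # rotate so a gap starts at index 0
        h = np.roll(h, -shift)
        mask = np.roll(mask, -shift)
    fingers: list[tuple[float, float]] = []
    i = 0
    dxi = 1.0 / n
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        seg = h[i:j]
        length = float(seg.max())
        half = 0.5 * length
        width = float(np.count_nonzero(seg > half)) * dxi * domain_width
        fingers.append((length / decay_length, width / decay_length))
        i = j
    return fingers
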