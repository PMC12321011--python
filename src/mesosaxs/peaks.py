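"""Bragg-peak detection and Gaussian fitting on 1D SAXS curves.

Step 1 of the two-step analysis: each candidate peak is fitted locally as a
Gaussian on a linear background over a window of about +/-5 sigma;
candidates whose windows overlap are fitted jointly so doublets share one
background. Step 2 (regressing assigned positions against reflection
ratios) lives in :mod:`mesosaxs.phases`.

Detection is intentionally simple and deterministic: a 5-point moving
average, local maxima via :func:`scipy.signal.find_peaks`, and a prominence
threshold expressed as a multiple of the robust noise level (1.4826 x MAD
of the detrended curve).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel, PolynomialModel
from scipy import signal, ndimage

from .io import SAXSPattern

__all__ = [
    "PeakObservation",
    "noise_level",
    "detect_peaks",
    "fit_peaks",
    "peaks_to_frame",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when no candidate peak could be fitted."""


@dataclass
class PeakObservation:
    """One fitted Bragg peak."""

    q0: float
    q0_err: float
    amplitude: float  # apex height, counts
    amplitude_err: float
    sigma: float  # Gaussian width, nm^-1
    sigma_err: float
    area: float
    background: tuple[float, ...] = (0.0, 0.0, 0.0)  # local poly coeffs, high->low
    redchi: float = float("nan")
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("peak width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def significant(self) -> bool:
        return "non-significant" not in self.flags and "non-converged" not in self.flags


def peaks_to_frame(peaks: Sequence[PeakObservation]) -> pd.DataFrame:
    """Peak table as a DataFrame (CSV-exportable)."""
    return pd.DataFrame([{
        "q0": p.q0, "sigma_q0": p.q0_err,
        "amplitude": p.amplitude, "sigma_amplitude": p.amplitude_err,
        "width": p.sigma, "sigma_width": p.sigma_err,
        "area": p.area, "redchi": p.redchi,
        "flags": ";".join(p.flags),
    } for p in peaks])


def _smooth(I: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return ndimage.convolve1d(I, kernel, mode="nearest")


def noise_level(pattern: SAXSPattern, detrend_window: int = 31) -> float:
    """Robust noise estimate: scaled MAD of the median-detrended curve.

    The running median removes both the diffuse background and the (sparse)
    peaks' slow structure, so the MAD of the residual reflects the
    point-to-point scatter in peak-free regions.
    """
    trend = ndimage.median_filter(pattern.I, size=detrend_window, mode="nearest")
    resid = pattern.I - trend
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def detect_peaks(
    pattern: SAXSPattern,
    min_prominence_snr: float = 3.0,
    min_separation: float = 0.06,
) -> np.ndarray:
    """Candidate peak positions (nm^-1), sorted by q.

    A candidate is a local maximum of the lightly smoothed curve whose
    prominence exceeds ``min_prominence_snr`` times the robust noise level.
    Maxima closer than ``min_separation`` (default 3x the typical peak
    width of 0.02 nm^-1) merge; the higher apex survives. Deterministic for
    a fixed input; an empty array is a valid result.
    """
    smoothed = _smooth(pattern.I)
    noise = noise_level(pattern)
    dq = float(np.median(np.diff(pattern.q)))
    distance = max(1, int(round(min_separation / dq)))
    prominence = max(min_prominence_snr * noise, 1e-12 * max(np.ptp(pattern.I), 1.0))
    idx, _ = signal.find_peaks(smoothed, prominence=prominence, distance=distance)
    return pattern.q[idx]


def _initial_width(pattern: SAXSPattern, q0: float, default: float = 0.02) -> float:
    """Half-width at half prominence around q0, as a width initial guess."""
    i0 = int(np.argmin(np.abs(pattern.q - q0)))
    apex = pattern.I[i0]
    base = np.min(pattern.I[max(0, i0 - 20): i0 + 21])
    half = base + 0.5 * (apex - base)
    j = i0
    while j + 1 < pattern.q.size and pattern.I[j] > half:
        j += 1
    hwhm = pattern.q[j] - q0
    sigma = hwhm / math.sqrt(2.0 * math.log(2.0))
    if not np.isfinite(sigma) or sigma <= 0:
        return default
    return float(np.clip(sigma, 0.25 * default, 10 * default))


def _group_windows(pattern, candidates, widths, window_sigmas=5.0):
    """Group candidates whose fit windows overlap; return [(indices, lo, hi)]."""
    spans = [(q0 - window_sigmas * w, q0 + window_sigmas * w)
             for q0, w in zip(candidates, widths)]
    groups = []
    cur = [0]
    lo, hi = spans[0]
    for i in range(1, len(candidates)):
        s_lo, s_hi = spans[i]
        if s_lo <= hi:
            cur.append(i)
            hi = max(hi, s_hi)
        else:
            groups.append((cur, lo, hi))
            cur, (lo, hi) = [i], spans[i]
    groups.append((cur, lo, hi))
    return groups


def _fit_group(x, y, weights, centers, widths, noise, warm=None):
    """Joint fit of len(centers) Gaussians + one linear background.

    Centers are confined near their seeds (a blend can shift an apex by a
    width or two, no more) so components cannot migrate across the group;
    ``warm`` re-uses a previous fit's parameters for all but the newest
    component.
    """
    model = PolynomialModel(degree=2, prefix="bg_")
    params = model.make_params(c0=float(np.min(y)), c1=0.0, c2=0.0)
    for j, (q0, w0) in enumerate(zip(centers, widths)):
        g = GaussianModel(prefix=f"g{j}_")
        model = model + g
        apex = float(y[np.argmin(np.abs(x - q0))]) - float(np.min(y))
        params.update(g.make_params(
            center=dict(value=q0, min=max(x[0], q0 - 2 * w0),
                        max=min(x[-1], q0 + 2 * w0)),
            sigma=dict(value=w0, min=w0 / 20, max=5 * w0),
            amplitude=dict(value=max(apex, noise) * w0 * math.sqrt(2 * math.pi),
                           min=0.0),
        ))
    if warm is not None:
        for name, par in warm.items():
            if name in params and params[name].vary:
                params[name].value = float(
                    np.clip(par.value, params[name].min, params[name].max))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # trust-region reflective: handles the box bounds natively (the
        # MINPACK parameter transform can freeze a parameter whose start
        # value sits exactly mid-bounds, which ours always do)
        return model.fit(y, params, x=x, weights=weights, method="least_squares")


def fit_peaks(
    pattern: SAXSPattern,
    candidates: Sequence[float],
    window_sigmas: float = 5.0,
    snr_floor: float = 3.0,
    residual_snr: float = 5.0,
    max_extra: int = 8,
) -> list[PeakObservation]:
    """Fit each candidate as Gaussian + local linear background.

    Overlapping windows are fitted jointly. Closely blended reflections
    that the detector merged into one candidate are recovered by residual
    augmentation: after each group fit, a further Gaussian is seeded at the
    largest residual and the group refitted, as long as that residual
    exceeds both ``residual_snr`` x noise and a few percent of the group's
    apex (at most ``max_extra`` additions per group; such peaks carry a
    ``residual-added`` flag).

    Parameter uncertainties come from the fit covariance (weighted by
    ``pattern.sigma`` when present). Peaks whose fitted apex falls below
    ``snr_floor`` times the noise level are flagged non-significant;
    non-converged fits are flagged. :class:`FitError` is raised only when
    every candidate fails outright.
    """
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ValueError("need at least one candidate position")
    noise = noise_level(pattern)
    widths = [_initial_width(pattern, q0) for q0 in candidates]
    observations: list[PeakObservation] = []
    n_failed = 0
    for idx_group, lo, hi in _group_windows(pattern, candidates, widths, window_sigmas):
        sel = (pattern.q >= lo) & (pattern.q <= hi)
        if sel.sum() < 3 * len(idx_group) + 2:
            # widen to the minimum viable window
            center = 0.5 * (lo + hi)
            order = np.argsort(np.abs(pattern.q - center))
            sel = np.zeros_like(sel)
            sel[order[:3 * len(idx_group) + 5]] = True
        x = pattern.q[sel]
        y = pattern.I[sel]
        weights = None
        if pattern.sigma is not None:
            s = np.clip(pattern.sigma[sel], 1e-12, None)
            weights = 1.0 / s

        centers = [candidates[i] for i in idx_group]
        gwidths = [widths[i] for i in idx_group]
        added: list[int] = []
        try:
            result = _fit_group(x, y, weights, centers, gwidths, noise)
            for _ in range(max_extra):
                resid = y - result.best_fit
                if weights is not None:
                    # per-point sigma known: threshold in sigma units
                    scaled = resid * weights
                    floor = residual_snr
                else:
                    scaled = resid
                    apex_scale = float(np.max(y) - np.min(y))
                    floor = max(residual_snr * noise, 0.01 * apex_scale)
                # ignore residual structure hugging the window edges (that
                # is background mismatch, not an unmodelled reflection) or
                # sitting on top of an already-modelled component
                guard = 2.0 * float(np.median(gwidths))
                sep = 0.75 * float(np.median(gwidths))
                interior = (x >= x[0] + guard) & (x <= x[-1] - guard)
                for c in centers:
                    interior &= np.abs(x - c) >= sep
                if not np.any(interior):
                    break
                r_int = np.where(interior, scaled, -np.inf)
                i_max = int(np.argmax(r_int))
                if r_int[i_max] <= floor:
                    break
                centers.append(float(x[i_max]))
                gwidths.append(float(np.median(gwidths)))
                added.append(len(centers) - 1)
                new_result = _fit_group(x, y, weights, centers, gwidths, noise,
                                        warm=result.params)
                if not np.isfinite(new_result.redchi) or \
                        new_result.redchi > result.redchi:
                    centers.pop(); gwidths.pop(); added.pop()
                    break
                result = new_result
        except Exception:
            n_failed += len(idx_group)
            continue
        for j, q_seed in enumerate(centers):
            p = result.params
            height = p[f"g{j}_height"]
            center = p[f"g{j}_center"]
            sig = p[f"g{j}_sigma"]
            area = p[f"g{j}_amplitude"]
            flags: list[str] = []
            if j in added:
                flags.append("residual-added")
            if not result.success:
                flags.append("non-converged")
            elif center.stderr is None:
                flags.append("no-errorbars")
            if height.value < snr_floor * noise:
                flags.append("non-significant")
            obs = PeakObservation(
                q0=float(center.value),
                q0_err=float(center.stderr or 0.0),
                amplitude=float(max(height.value, 0.0)),
                amplitude_err=float(height.stderr or 0.0),
                sigma=float(sig.value),
                sigma_err=float(sig.stderr or 0.0),
                area=float(area.value),
                background=(float(p["bg_c2"].value), float(p["bg_c1"].value),
                            float(p["bg_c0"].value)),
                redchi=float(result.redchi),
                flags=tuple(flags),
            )
            if "non-converged" in flags:
                warnings.warn(f"peak near q={q_seed:.3f} did not converge; "
                              "flagged and excluded", stacklevel=2)
            observations.append(obs)
    if not observations and n_failed:
        raise FitError(f"all {n_failed} candidate peak fits failed")
    return sorted(observations, key=lambda o: o.q0)


def significant(peaks: Sequence[PeakObservation]) -> list[PeakObservation]:
    """Converged, above-noise peaks only (what indexing should consume)."""
    return [p for p in peaks if p.significant]
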