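"""Time-resolved analysis of light-induced mesophase transitions.

Given a time-ordered series of 1D SAXS frames, this module tracks the
fitted apex intensity of selected reflections (e.g. lamellar 100/200 and
Pn3m 110), normalizes each frame to a spectator reference peak (typically
Im3m 211, whose phase is unaffected by the transition) to cancel per-frame
scale factors, and detects onset and completion times of the transition
with simple thresholded change detectors. It also tracks the lamellar
repeat distance d(t) through the transition.

Apex amplitude, not integrated area, is tracked: area couples position to
width drift, while apex intensity is what intensity-vs-time transition
plots show.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SAXSPattern
from .peaks import PeakObservation, fit_peaks, noise_level
from .phases import (
    MesophaseModel,
    Phase,
    Reflection,
    lattice_from_assignments,
    reflection_positions,
)

__all__ = [
    "KineticsTrace",
    "track_series",
    "detect_onset",
    "detect_completion",
    "track_d_spacing",
]


def _key(phase: Phase | str, refl: Reflection) -> str:
    return f"{Phase.coerce(phase).value}_{refl.label}"


@dataclass
class KineticsTrace:
    """Per-reflection normalized intensity (and optional d) versus time."""

    times: np.ndarray  # s since illumination start, strictly increasing
    intensity: dict[str, np.ndarray]  # key "phase_hkl" -> normalized trace
    intensity_sigma: dict[str, np.ndarray]
    reference: Optional[str] = None
    d_nm: Optional[np.ndarray] = None
    d_sigma: Optional[np.ndarray] = None
    onsets: dict[str, Optional[float]] = field(default_factory=dict)
    completions: dict[str, Optional[float | str]] = field(default_factory=dict)
    illumination_nm: Optional[float] = None
    direction: Optional[str] = None  # "trans->cis" | "cis->trans"

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (time_s, reflection, norm_intensity, sigma)."""
        rows = []
        for key, vals in self.intensity.items():
            sig = self.intensity_sigma[key]
            for t, v, s in zip(self.times, vals, sig):
                rows.append({"time_s": t, "reflection": key,
                             "norm_intensity": v, "sigma": s})
        df = pd.DataFrame(rows)
        if self.d_nm is not None:
            d_rows = pd.DataFrame({"time_s": self.times, "reflection": "lamellar_d",
                                   "norm_intensity": self.d_nm,
                                   "sigma": self.d_sigma})
            df = pd.concat([df, d_rows], ignore_index=True)
        return df

    def summary(self) -> dict:
        return {
            "reference": self.reference,
            "onset_s": {k: v for k, v in self.onsets.items()},
            "completion_s": {k: v for k, v in self.completions.items()},
        }


def _fit_one(frame: SAXSPattern, q_expect: float, width: float = 0.02,
             neighbors: Sequence[float] = (),
             window_sigmas: float = 5.0,
             max_shift: float = 0.02,
             refine_min: float = 0.0,
             refine_gain: Optional[float] = None) -> Optional[PeakObservation]:
    """Fit the peak at ``q_expect`` by a windowed linear amplitude solve.

    In tracking, positions and widths are known from the seed assignment,
    so the per-frame problem is linear: apex amplitudes of the target and
    of any co-modelled neighbouring reflections, plus a quadratic local
    background, are solved by weighted least squares with the Gaussian
    shapes fixed. The target's position is then refined by a bounded 1-D
    search over a relative shift of at most ``max_shift``, with the linear
    solve nested inside. Fixed shapes make the fit immune to component
    wandering between close reflections and orders of magnitude faster
    than a free nonlinear fit.
    """
    if not frame.q[0] < q_expect < frame.q[-1]:
        return None
    lo = max(frame.q[0], q_expect - window_sigmas * width)
    hi = min(frame.q[-1], q_expect + window_sigmas * width)
    # neighbours whose tails reach into the window are co-modelled, but the
    # window itself never widens (that would pull in unmodelled structure)
    others = [q for q in neighbors
              if lo - 4 * width <= q <= hi + 4 * width
              and abs(q - q_expect) > 0.5 * width
              and frame.q[0] < q < frame.q[-1]]
    sel = (frame.q >= lo) & (frame.q <= hi)
    n_par = len(others) + 4
    if sel.sum() < n_par + 2:
        return None
    x, y = frame.q[sel], frame.I[sel]
    w = np.ones_like(y)
    if frame.sigma is not None:
        w = 1.0 / np.clip(frame.sigma[sel], 1e-12, None)

    def solve(shift: float):
        q0 = q_expect * (1.0 + shift)
        cols = [np.exp(-((x - q0) ** 2) / (2 * width**2))]
        cols += [np.exp(-((x - c) ** 2) / (2 * width**2)) for c in others]
        cols += [np.ones_like(x), x, x * x]
        D = np.stack(cols, axis=1)
        Dw = D * w[:, None]
        yw = y * w
        coef, *_ = np.linalg.lstsq(Dw, yw, rcond=None)
        resid = yw - Dw @ coef
        return float(resid @ resid), coef, Dw

    chi0, coef0, _ = solve(0.0)
    best_shift = 0.0
    # refine the position only when the peak is clearly present at the
    # expected place: shifting a near-zero component just lets it turn
    # collinear with a neighbour and soak up that neighbour's intensity.
    # The shift is kept only on a decisive chi^2 improvement, since for
    # blended reflections a shift can trade amplitude between components
    # while barely changing the residual.
    if max_shift > 0 and coef0[0] > refine_min:
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda s: solve(s)[0], bounds=(-max_shift, max_shift),
                              method="bounded", options={"xatol": 1e-5})
        if refine_gain is None:
            refine_gain = 9.0 if frame.sigma is not None else 0.01 * chi0
        if chi0 - res.fun > refine_gain:
            best_shift = float(res.x)
    chi2, coef, Dw = solve(best_shift)
    ndof = max(x.size - n_par - 1, 1)
    scale2 = 1.0 if frame.sigma is not None else chi2 / ndof
    try:
        cov = np.linalg.inv(Dw.T @ Dw) * scale2
        amp_err = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        amp_err = 0.0
    # position uncertainty from the chi^2 curvature along the shift
    h = max(1e-4, abs(best_shift) * 0.1)
    cplus = solve(min(best_shift + h, max_shift))[0]
    cminus = solve(max(best_shift - h, -max_shift))[0]
    curv = (cplus + cminus - 2 * chi2) / h**2
    q0 = q_expect * (1.0 + best_shift)
    q0_err = q0 * math.sqrt(2.0 * scale2 / curv) if curv > 0 else 0.0
    amp = float(max(coef[0], 0.0))
    return PeakObservation(
        q0=q0, q0_err=q0_err,
        amplitude=amp, amplitude_err=amp_err,
        sigma=width, sigma_err=0.0,
        area=amp * width * math.sqrt(2.0 * math.pi),
        redchi=chi2 / ndof,
    )


def track_series(
    frames: Sequence[SAXSPattern],
    tracked: Sequence[tuple[Phase | str, Reflection]],
    reference: Optional[tuple[Phase | str, Reflection]] = None,
    lattices: Optional[dict[str, float]] = None,
    max_drift_per_frame: float = 0.02,
    onset_baseline: int = 3,
    onset_threshold: float = 3.0,
) -> KineticsTrace:
    """Track reflections through a frame series and detect transition times.

    Parameters
    ----------
    frames : time-ordered SAXS patterns (each with ``metadata['time_s']``).
    tracked : (phase, reflection) pairs to follow.
    reference : optional spectator (phase, reflection); each frame's
        intensities are divided by its fitted apex. Without a reference the
        per-frame total integrated intensity is used.
    lattices : phase name -> lattice parameter a (nm) locating the peaks.
        Required unless every tracked phase can be seeded from the first
        frame via :func:`mesosaxs.indexing.index_phases`.
    max_drift_per_frame : allowed relative position drift per frame; the
        expected position follows the last significant fit.
    """
    if len(frames) < 2:
        raise ValueError("kinetics requires >= 2 frames")
    order = np.argsort([f.time_s if f.time_s is not None else i
                        for i, f in enumerate(frames)])
    frames = [frames[i] for i in order]
    times = np.array([f.time_s if f.time_s is not None else float(i)
                      for i, f in enumerate(frames)])
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")

    if lattices is None:
        lattices = _seed_lattices(frames[0], tracked, reference)

    all_tracked = list(tracked)
    ref_key = None
    if reference is not None:
        ref_key = _key(*reference)
        if all(_key(*t) != ref_key for t in all_tracked):
            all_tracked.append(reference)

    keys = [_key(*t) for t in all_tracked]
    expected = {}
    for (ph, refl), key in zip(all_tracked, keys):
        name = Phase.coerce(ph).value
        if name not in lattices:
            raise ValueError(f"no lattice given or seeded for phase {name}")
        expected[key] = 2.0 * math.pi * refl.m / lattices[name]

    # every reflection of every seeded phase, for neighbour co-modelling
    q_range = (float(frames[0].q[0]), float(frames[0].q[-1]))
    all_positions: list[float] = []
    for name, a in lattices.items():
        model = MesophaseModel.create(name)
        all_positions.extend(q for _, q in reflection_positions(model, a, q_range))

    raw = {k: np.zeros(len(frames)) for k in keys}
    raw_sigma = {k: np.zeros(len(frames)) for k in keys}
    for fi, frame in enumerate(frames):
        noise = noise_level(frame)
        for key in keys:
            q_exp = expected[key]
            floor = 3.0 * noise + 1e-9 * float(np.max(frame.I))
            # expected positions stay anchored at the seed assignment; the
            # bounded in-fit refinement absorbs real drift without letting
            # the window walk onto a neighbouring reflection
            obs = _fit_one(frame, q_exp, width=0.02, neighbors=all_positions,
                           max_shift=max_drift_per_frame, refine_min=5 * floor)
            if obs is not None and obs.amplitude > floor:
                raw[key][fi] = obs.amplitude
                raw_sigma[key][fi] = max(obs.amplitude_err, noise)
            else:
                # vanished peak: amplitude 0 with the fit's amplitude
                # uncertainty as an upper-bound-style error; the trace
                # stays defined over the full series
                raw[key][fi] = 0.0
                raw_sigma[key][fi] = max(
                    obs.amplitude_err if obs is not None else 0.0, noise)

    if ref_key is not None:
        ref = raw[ref_key]
        for fi in range(len(frames)):
            if ref[fi] <= 0:
                raise ValueError(
                    f"reference peak {ref_key} absent in frame {fi} "
                    f"(t = {times[fi]} s)")
        norm = {k: raw[k] / ref for k in keys}
        norm_sigma = {k: raw_sigma[k] / ref for k in keys}
    else:
        total = np.array([np.trapezoid(f.I, f.q) for f in frames])
        norm = {k: raw[k] / total for k in keys}
        norm_sigma = {k: raw_sigma[k] / total for k in keys}

    trace = KineticsTrace(
        times=times,
        intensity=norm,
        intensity_sigma=norm_sigma,
        reference=ref_key,
        illumination_nm=frames[0].metadata.get("illumination_nm"),
    )
    for key in keys:
        t_on = detect_onset(times, norm[key], baseline=onset_baseline,
                            threshold=onset_threshold, sigma=norm_sigma[key])
        trace.onsets[key] = t_on
        trace.completions[key] = detect_completion(times, norm[key], t_on,
                                                   sigma=norm_sigma[key])
    return trace


def _seed_lattices(first_frame, tracked, reference) -> dict[str, float]:
    from .indexing import index_phases  # deferred: indexing imports peaks too
    from .peaks import detect_peaks

    cand = detect_peaks(first_frame)
    if cand.size == 0:
        raise ValueError("cannot seed lattices: no peaks detected in first frame")
    obs = fit_peaks(first_frame, cand)
    ranked = index_phases([p for p in obs if p.significant])
    if not ranked:
        raise ValueError("cannot seed lattices: indexing of first frame failed")
    top = ranked[0]
    lat = {name: est.a for name, est in top.phases.items()}
    needed = {Phase.coerce(ph).value for ph, _ in tracked}
    if reference is not None:
        needed.add(Phase.coerce(reference[0]).value)
    missing = needed - set(lat)
    if missing:
        raise ValueError(
            f"phases {sorted(missing)} not present in the first frame's "
            "assignment; pass their lattices explicitly")
    return lat


def detect_onset(
    times: np.ndarray,
    values: np.ndarray,
    baseline: int = 3,
    threshold: float = 3.0,
    debounce: int = 3,
    sigma: Optional[np.ndarray] = None,
) -> Optional[float]:
    """First sustained deviation from the baseline, or None for flat traces.

    The baseline mean and scatter come from the first ``baseline`` frames.
    Onset is the first frame deviating by more than ``threshold`` baseline
    standard deviations with at least ``debounce``-1 subsequent frames also
    deviating (single-frame blips do not trigger). A floating-point floor
    keeps exactly-constant noiseless traces from triggering on rounding.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if values.size < baseline + 2:
        raise ValueError(f"need at least baseline+2 = {baseline + 2} frames")
    base = values[:baseline]
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1)) if baseline > 1 else 0.0
    if sigma is not None:
        # the per-point measurement uncertainty is the noise floor (a
        # clipped-at-zero baseline has zero empirical scatter); conversely
        # a few-dof empirical sd exceeding the known level is almost
        # surely an upward fluke, so it is capped rather than trusted
        sig_med = float(np.median(np.asarray(sigma, float)[:baseline]))
        sd = max(min(sd, 1.5 * sig_med), sig_med)
    elif values.size >= 4:
        # noise level unknown: a handful of baseline frames badly
        # underestimates the scatter, so pool it with a trend-immune
        # estimate from the whole trace — second differences vanish on the
        # linear/flat segments of a genuine transition but have variance
        # 6*sigma^2 under point noise. Pooling over the combined degrees
        # of freedom keeps downward fluctuations of the noise estimate
        # (the cause of false onsets) small.
        d2 = np.diff(values, n=2)
        sd_d2 = 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / math.sqrt(6)
        df_b, df_d2 = baseline - 1, d2.size - 1
        sd = math.sqrt((df_b * sd**2 + df_d2 * sd_d2**2) / (df_b + df_d2))
    scale = max(np.max(np.abs(values)), 1.0)
    # the baseline mean itself carries sd/sqrt(k) of noise
    limit = threshold * sd * math.sqrt(1.0 + 1.0 / baseline) + 1e-9 * scale
    dev = values - mu
    deviating = np.abs(dev) > limit
    for i in range(baseline, values.size):
        window = slice(i, i + debounce)
        if (i + debounce <= values.size and np.all(deviating[window])
                and (np.all(dev[window] > 0) or np.all(dev[window] < 0))):
            return float(times[i])
    return None


def detect_completion(
    times: np.ndarray,
    values: np.ndarray,
    t_onset: Optional[float],
    plateau_tol: float = 0.05,
    run_length: int = 3,
    sigma: Optional[np.ndarray] = None,
) -> Optional[float | str]:
    """First frame after onset from which the trace stays at its plateau.

    The plateau value is the mean of the last ``run_length`` frames;
    completion requires all subsequent frames (at least ``run_length`` of
    them) to stay within ``plateau_tol`` of the total change. When
    per-point uncertainties are given, the tolerance is floored at three
    of them, so measurement noise on an otherwise flat plateau does not
    postpone completion. A trace still moving in its last step returns
    ``"not reached"``; without an onset, None.
    """
    if t_onset is None:
        return None
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    i_on = int(np.searchsorted(times, t_onset))
    base = float(np.mean(values[:max(i_on, 1)]))
    plateau = float(np.mean(values[-run_length:]))
    total = abs(plateau - base)
    if total == 0:
        return None
    tol = plateau_tol * total
    if sigma is not None:
        tol = max(tol, 3.0 * float(np.median(np.asarray(sigma, float))))
    if abs(values[-1] - values[-2]) > max(tol, 2.0 * plateau_tol * total):
        return "not reached"
    within = np.abs(values - plateau) <= tol
    for j in range(i_on, values.size):
        if np.all(within[j:]) and values.size - j >= run_length:
            return float(times[j])
    return "not reached"


def track_d_spacing(
    frames: Sequence[SAXSPattern],
    lamellar_a: float,
    n_orders: int = 2,
    max_drift_per_frame: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lamellar repeat distance d(t) with uncertainties through a series.

    Per frame, the first ``n_orders`` lamellar reflections are fitted in
    fixed windows and regressed through the origin; d carries the
    regression sigma. Frames where no lamellar order survives yield NaN
    (gap recorded), not an interpolated value.

    Returns (times, d_nm, sigma_d_nm).
    """
    model = MesophaseModel.create(Phase.LAMELLAR, n_orders)
    times = np.array([f.time_s if f.time_s is not None else float(i)
                      for i, f in enumerate(frames)])
    expected = {r.label: 2.0 * math.pi * r.m / lamellar_a for r in model.reflections}
    d = np.full(len(frames), np.nan)
    sigma_d = np.full(len(frames), np.nan)
    for fi, frame in enumerate(frames):
        assigned = []
        noise = noise_level(frame)
        for refl in model.reflections:
            q_exp = expected[refl.label]
            if not frame.q[0] < q_exp < frame.q[-1]:
                continue
            others = [q for lbl, q in expected.items() if lbl != refl.label]
            # the position IS the measurand here, so any chi^2 improvement
            # moves it (lamellar orders are well separated; no neighbour
            # collinearity to guard against)
            obs = _fit_one(frame, q_exp, width=0.02, neighbors=others,
                           max_shift=max_drift_per_frame, refine_gain=0.0)
            floor = 3.0 * noise + 1e-9 * float(np.max(frame.I))
            if (obs is not None and obs.amplitude > floor
                    and abs(obs.q0 - q_exp) / q_exp <= max_drift_per_frame):
                assigned.append((obs, refl))
                expected[refl.label] = obs.q0
        if not assigned:
            warnings.warn(f"lamellar phase absent in frame {fi}; gap recorded",
                          stacklevel=2)
            continue
        est = lattice_from_assignments(assigned)
        d[fi] = est.a
        sigma_d[fi] = est.sigma_a
    return times, d, sigma_d
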