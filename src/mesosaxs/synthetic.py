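"""Synthetic 1D SAXS patterns and kinetic frame series with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
smooth diffuse background ``A*q^-p + C``, Gaussian Bragg peaks at
phase-determined positions q_m = 2*pi*m/a over the analysis window, and
either Poisson counting noise or Gaussian fractional noise. Kinetic series
emulate a light-induced lamellar -> Pn3m transition: lamellar peak
amplitudes ramp to zero from a decay onset, the Pn3m peaks grow from a
(possibly delayed) growth onset, and any Im3m phase present in both end
states acts as a constant spectator — the situation exploited by
reference-peak normalization.

Everything is seeded and bit-reproducible; every generated object carries a
``ground_truth`` record in its metadata so downstream recovery can be
scored without bookkeeping on the caller's side.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SAXSPattern, write_dat, write_manifest
from .phases import MesophaseModel, Phase, reflection_positions, DEFAULT_Q_WINDOW

__all__ = [
    "PhaseSpec",
    "NoiseSpec",
    "KineticSpec",
    "default_q_grid",
    "generate_pattern",
    "generate_kinetic_series",
    "write_fixture_set",
]


def default_q_grid(n: int = 512,
                   window: tuple[float, float] = DEFAULT_Q_WINDOW) -> np.ndarray:
    """Uniform q grid over the analysis window (default 512 pts, 0.5-4.5 nm^-1)."""
    return np.linspace(window[0], window[1], n)


@dataclass
class PhaseSpec:
    """Ground-truth description of one phase's Bragg contribution.

    Relative per-reflection intensities default to a geometric decay with
    ratio 0.5 — higher orders are weaker, as in real powder patterns, but
    no structure-factor physics is implied.
    """

    phase: Phase | str
    a: float  # lattice parameter / lamellar repeat, nm
    amplitude: float = 1000.0  # apex counts of the strongest reflection
    sigma_q: float = 0.02  # Gaussian peak width, nm^-1
    rel_intensities: Optional[Sequence[float]] = None
    n_reflections: int = 6

    def __post_init__(self) -> None:
        self.phase = Phase.coerce(self.phase)
        if not self.a > 0:
            raise ValueError("lattice parameter must be positive")
        if not self.sigma_q > 0:
            raise ValueError("peak width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def model(self) -> MesophaseModel:
        return MesophaseModel.create(self.phase, self.n_reflections)

    def peak_table(self, q_window=DEFAULT_Q_WINDOW) -> list[tuple[str, float, float]]:
        """(reflection label, q, apex amplitude) for reflections in window."""
        positions = reflection_positions(self.model(), self.a, q_window)
        rel = self.rel_intensities
        if rel is None:
            rel = [0.5**i for i in range(len(self.model().reflections))]
        out = []
        for refl, q in positions:
            idx = self.model().reflections.index(refl)
            out.append((refl.label, q, self.amplitude * rel[idx]))
        return out

    def truth(self) -> dict:
        return {"phase": self.phase.value, "a": self.a, "amplitude": self.amplitude,
                "sigma_q": self.sigma_q}


@dataclass
class NoiseSpec:
    """Background and noise model for generated patterns."""

    background_A: float = 50.0
    background_p: float = 2.0
    background_C: float = 5.0
    model: str = "none"  # none | gaussian-fractional | poisson
    fractional: float = 0.02
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian-fractional", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")

    def background(self, q: np.ndarray) -> np.ndarray:
        return self.background_A * q ** (-self.background_p) + self.background_C


def _gaussian(q: np.ndarray, q0: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((q - q0) ** 2) / (2.0 * sigma**2))


def generate_pattern(
    phases: Sequence[PhaseSpec],
    noise: NoiseSpec | None = None,
    q_grid: np.ndarray | None = None,
    metadata: dict | None = None,
    rng: np.random.Generator | None = None,
) -> SAXSPattern:
    """Generate one SAXS pattern: background + Gaussian Bragg peaks + noise.

    I(q) = A*q^-p + C + sum over phases/reflections of Gaussians, then the
    chosen noise model. The uncertainty column matches the noise model
    (sqrt(I) for Poisson, fractional*I for Gaussian-fractional, absent for
    noiseless). Ground truth is attached under ``metadata['ground_truth']``.
    """
    noise = noise or NoiseSpec()
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing without duplicates")
    ideal = noise.background(q)
    peak_truth = []
    for spec in phases:
        for label, q0, amp in spec.peak_table((q[0], q[-1])):
            ideal = ideal + _gaussian(q, q0, amp, spec.sigma_q)
            peak_truth.append({"phase": spec.phase.value, "reflection": label,
                               "q": q0, "amplitude": amp, "sigma_q": spec.sigma_q})
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.model == "poisson":
        I = rng.poisson(np.clip(ideal, 0, None)).astype(float)
        sigma = np.sqrt(np.clip(ideal, 1.0, None))
    elif noise.model == "gaussian-fractional":
        sigma = noise.fractional * np.abs(ideal)
        I = ideal + rng.normal(0.0, 1.0, q.size) * sigma
    else:
        I = ideal
        sigma = None
    meta = dict(metadata or {})
    meta["ground_truth"] = {
        "phases": [s.truth() for s in phases],
        "peaks": peak_truth,
        "background": {"A": noise.background_A, "p": noise.background_p,
                       "C": noise.background_C},
        "noise": {"model": noise.model, "fractional": noise.fractional},
    }
    return SAXSPattern(q, I, sigma, meta)


@dataclass
class KineticSpec:
    """Ground truth for a light-driven phase-transition frame series.

    Phases present only initially decay between ``t_on_decay`` and
    ``t_end``; phases present only finally grow between ``t_on_growth`` and
    ``t_end``; phases in both compositions are constant spectators. The
    default timing (decay onset 30 s, delayed growth onset 50 s, completion
    120 s) mirrors a lamellar -> Pn3m photoswitching transition in which a
    threshold fraction of switched molecules must accumulate before the new
    phase nucleates.
    """

    initial: Sequence[PhaseSpec]
    final: Sequence[PhaseSpec]
    t_on_decay: float = 30.0
    t_on_growth: float = 50.0
    t_end: float = 120.0
    frame_times: Sequence[float] = field(default_factory=lambda: tuple(range(0, 190, 10)))
    shape: str = "piecewise-linear"  # or "logistic"
    intensity_transfer: bool = False
    d_drift: Optional[dict] = None  # {"phase": ..., "a_final": nm}

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing, >= 2 frames")
        for t_on in (self.t_on_decay, self.t_on_growth):
            if not 0 <= t_on <= self.t_end:
                raise ValueError("onsets must lie in [0, t_end]")
        if self.shape not in ("piecewise-linear", "logistic"):
            raise ValueError(f"unknown transition shape {self.shape!r}")
        if self.t_on_growth < self.t_on_decay:
            warnings.warn("growth onset precedes decay onset (reverse transition)",
                          stacklevel=2)

    def progress(self, t: float, t_on: float) -> float:
        """Transition progress in [0, 1] between t_on and t_end."""
        if t <= t_on:
            return 0.0
        if t >= self.t_end:
            return 1.0
        if self.shape == "piecewise-linear":
            return (t - t_on) / (self.t_end - t_on)
        # logistic renormalized to hit 0/1 exactly at the endpoints; the
        # inner 25-75% of the sigmoid spans the window, so the rise starts
        # briskly after the onset (a threshold-then-growth shape) rather
        # than creeping out of an undetectable tail
        mid = 0.5 * (t_on + self.t_end)
        k = 2.0 * math.log(3.0) / (self.t_end - t_on)
        raw = 1.0 / (1.0 + math.exp(-k * (t - mid)))
        lo = 1.0 / (1.0 + math.exp(-k * (t_on - mid)))
        hi = 1.0 / (1.0 + math.exp(-k * (self.t_end - mid)))
        return (raw - lo) / (hi - lo)


def _phase_roles(spec: KineticSpec):
    init_names = {Phase.coerce(p.phase) for p in spec.initial}
    final_names = {Phase.coerce(p.phase) for p in spec.final}
    decaying = [p for p in spec.initial if Phase.coerce(p.phase) not in final_names]
    growing = [p for p in spec.final if Phase.coerce(p.phase) not in init_names]
    spectators = [p for p in spec.initial if Phase.coerce(p.phase) in final_names]
    return decaying, growing, spectators


def _bragg_area(specs: Sequence[PhaseSpec]) -> float:
    total = 0.0
    for s in specs:
        for _, _, amp in s.peak_table():
            total += amp * s.sigma_q * math.sqrt(2.0 * math.pi)
    return total


def generate_kinetic_series(
    spec: KineticSpec,
    noise: NoiseSpec | None = None,
    q_grid: np.ndarray | None = None,
) -> list[SAXSPattern]:
    """Generate a time-ordered frame series for a phase transition.

    With ``intensity_transfer`` the growing phase's amplitude ramp is slaved
    to the decaying phase's (growth fraction = 1 - decay survival) and its
    final amplitudes rescaled so total Bragg area is conserved frame by
    frame in the noiseless case.
    """
    noise = noise or NoiseSpec()
    decaying, growing, spectators = _phase_roles(spec)

    transfer_scale = 1.0
    if spec.intensity_transfer and growing:
        area_out = _bragg_area(decaying)
        area_in = _bragg_area(growing)
        if area_in > 0:
            transfer_scale = area_out / area_in

    rng = np.random.default_rng(noise.seed)
    frames: list[SAXSPattern] = []
    for i, t in enumerate(spec.frame_times):
        frame_phases: list[PhaseSpec] = []
        f_decay = spec.progress(t, spec.t_on_decay)
        f_grow = (f_decay if spec.intensity_transfer
                  else spec.progress(t, spec.t_on_growth))
        for p in decaying:
            a_t = p.a
            if spec.d_drift and Phase.coerce(spec.d_drift["phase"]) == p.phase:
                a_t = p.a + (spec.d_drift["a_final"] - p.a) * f_decay
            frame_phases.append(PhaseSpec(p.phase, a_t,
                                          p.amplitude * (1.0 - f_decay),
                                          p.sigma_q, p.rel_intensities,
                                          p.n_reflections))
        for p in growing:
            frame_phases.append(PhaseSpec(p.phase, p.a,
                                          p.amplitude * transfer_scale * f_grow,
                                          p.sigma_q, p.rel_intensities,
                                          p.n_reflections))
        for p in spectators:
            a_t = p.a
            if spec.d_drift and Phase.coerce(spec.d_drift["phase"]) == p.phase:
                frac = spec.progress(t, spec.t_on_decay)
                a_t = p.a + (spec.d_drift["a_final"] - p.a) * frac
            frame_phases.append(PhaseSpec(p.phase, a_t, p.amplitude,
                                          p.sigma_q, p.rel_intensities,
                                          p.n_reflections))
        frame = generate_pattern(
            frame_phases, noise, q_grid,
            metadata={"time_s": float(t), "frame_index": i,
                      "illumination_state": "transitioning"},
            rng=rng)
        frame.metadata["ground_truth"]["kinetics"] = {
            "t_on_decay": spec.t_on_decay,
            "t_on_growth": spec.t_on_growth,
            "t_end": spec.t_end,
            "shape": spec.shape,
            "decay_fraction": f_decay,
            "growth_fraction": f_grow,
        }
        frames.append(frame)
    return frames


def write_fixture_set(outdir, frames: Sequence[SAXSPattern],
                      illumination_nm: float | None = None) -> Path:
    """Write frames as .dat files + manifest CSV + ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = []
    for i, frame in enumerate(frames):
        name = f"frame_{i:04d}.dat"
        write_dat(frame, outdir / name)
        rows.append({
            "filename": name,
            "time_s": frame.metadata.get("time_s", float(i)),
            "illumination_nm": illumination_nm if illumination_nm is not None else "",
            "state": frame.metadata.get("illumination_state", ""),
        })
        truths.append(frame.metadata.get("ground_truth", {}))
    write_manifest(pd.DataFrame(rows), outdir / "manifest.csv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return outdir
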