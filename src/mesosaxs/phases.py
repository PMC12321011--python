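"""Lattice math and allowed-reflection tables for lyotropic mesophases.

A lyotropic lipid/water mesophase diffracts at Bragg positions

    q_hkl = 2*pi*m / a

where ``a`` is the lattice parameter (the lamellar repeat distance *d* for
a 1D bilayer stack) and ``m`` is the dimensionless spacing ratio of the
reflection: ``m = n`` for lamellar order *n*, ``m = sqrt(h^2+k^2+l^2)`` for
cubic *hkl*, and ``m = sqrt(h^2+hk+k^2)`` for 2D hexagonal *hk*.

Which ratios occur is fixed by the space group's reflection conditions:

* lamellar stack:   1, 2, 3, 4, ...
* Pn3m (Q224, double diamond): sqrt2, sqrt3, sqrt4, sqrt6, sqrt8, sqrt9, ...
* Im3m (Q229, primitive/plumber's nightmare): sqrt2, sqrt4, sqrt6, sqrt8, sqrt10, sqrt12, ...
* 2D hexagonal (HII): 1, sqrt3, sqrt4, sqrt7, ...

These sequences are what distinguishes the phases in a powder pattern, so
they are generated here from the extinction rules rather than hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Reflection",
    "MesophaseModel",
    "LatticeEstimate",
    "reflection_positions",
    "lattice_from_assignments",
    "DEFAULT_Q_WINDOW",
]

#: Analysis q window in nm^-1 (typical reduced lipid-mesophase SAXS range).
DEFAULT_Q_WINDOW = (0.5, 4.5)


class Phase(str, Enum):
    """Candidate mesophase identities."""

    LAMELLAR = "lamellar"
    PN3M = "Pn3m"
    IM3M = "Im3m"
    HEXAGONAL = "hexagonal"

    @classmethod
    def coerce(cls, value: "Phase | str") -> "Phase":
        if isinstance(value, Phase):
            return value
        key = str(value).strip().lower().replace("-", "").replace("_", "")
        aliases = {
            "lamellar": cls.LAMELLAR,
            "lam": cls.LAMELLAR,
            "pn3m": cls.PN3M,
            "im3m": cls.IM3M,
            "hexagonal": cls.HEXAGONAL,
            "hex": cls.HEXAGONAL,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown phase {value!r}") from None


@dataclass(frozen=True)
class Reflection:
    """One allowed reflection, with its dimensionless spacing ratio ``m``.

    Lamellar order *n* is encoded as (n, 0, 0); hexagonal *hk* as (h, k, 0)
    with ``m = sqrt(h^2+hk+k^2)`` stored explicitly.
    """

    h: int
    k: int
    l: int
    m: float

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError(f"spacing ratio m must be positive, got {self.m}")

    @classmethod
    def cubic(cls, h: int, k: int, l: int) -> "Reflection":
        return cls(h, k, l, math.sqrt(h * h + k * k + l * l))

    @classmethod
    def lamellar(cls, n: int) -> "Reflection":
        return cls(n, 0, 0, float(n))

    @classmethod
    def hexagonal(cls, h: int, k: int) -> "Reflection":
        return cls(h, k, 0, math.sqrt(h * h + h * k + k * k))

    @property
    def label(self) -> str:
        return f"{self.h}{self.k}{self.l}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# ---------------------------------------------------------------------------
# extinction rules
# ---------------------------------------------------------------------------

def _allowed_im3m(h: int, k: int, l: int) -> bool:
    # body centring: h+k+l even
    return (h + k + l) % 2 == 0


def _allowed_pn3m(h: int, k: int, l: int) -> bool:
    # n glide: reflections in a zone (one index zero) need an even index sum;
    # general hkl with all indices nonzero are unconditionally allowed.
    if h == 0 or k == 0 or l == 0:
        return (h + k + l) % 2 == 0
    return True


def _enumerate_cubic(allowed, n_reflections: int) -> list[Reflection]:
    """Ascending allowed cubic reflections, deduplicated by h^2+k^2+l^2.

    An m^2 class is allowed if *any* representative hkl passes the rule
    (e.g. Pn3m m^2 = 9: 300 is extinct but 221 is allowed).
    """
    out: list[Reflection] = []
    hmax = 8  # covers far more orders than any realistic q window needs
    by_m2: dict[int, Reflection] = {}
    for h in range(hmax, -1, -1):
        for k in range(h, -1, -1):
            for l in range(k, -1, -1):
                if h == 0:
                    continue
                if not allowed(h, k, l):
                    continue
                m2 = h * h + k * k + l * l
                prev = by_m2.get(m2)
                # representative: highest-symmetry allowed combo, stable choice
                if prev is None or (h, k, l) < (prev.h, prev.k, prev.l):
                    by_m2[m2] = Reflection.cubic(h, k, l)
    for m2 in sorted(by_m2):
        out.append(by_m2[m2])
        if len(out) == n_reflections:
            break
    return out


def _build_reflections(name: Phase, n_reflections: int) -> tuple[Reflection, ...]:
    if name is Phase.LAMELLAR:
        refl = [Reflection.lamellar(n) for n in range(1, n_reflections + 1)]
    elif name is Phase.IM3M:
        refl = _enumerate_cubic(_allowed_im3m, n_reflections)
    elif name is Phase.PN3M:
        refl = _enumerate_cubic(_allowed_pn3m, n_reflections)
    elif name is Phase.HEXAGONAL:
        by_m2: dict[int, Reflection] = {}
        for h in range(1, 7):
            for k in range(0, h + 1):
                m2 = h * h + h * k + k * k
                if m2 not in by_m2:
                    by_m2[m2] = Reflection.hexagonal(h, k)
        refl = [by_m2[m2] for m2 in sorted(by_m2)][:n_reflections]
    else:  # pragma: no cover
        raise ValueError(name)
    return tuple(refl)


@dataclass(frozen=True)
class MesophaseModel:
    """A candidate phase with its ordered allowed-reflection list."""

    name: Phase
    reflections: tuple[Reflection, ...]
    dimensionality: int

    @classmethod
    def create(cls, name: Phase | str, n_reflections: int = 6) -> "MesophaseModel":
        """Build the standard model for ``name`` with its first allowed reflections.

        Six reflections cover the usual analysis window (q = 0.5-4.5 nm^-1,
        lattices 6-13 nm) with margin; raise ``n_reflections`` for larger cells.
        """
        name = Phase.coerce(name)
        dim = {Phase.LAMELLAR: 1, Phase.HEXAGONAL: 2, Phase.PN3M: 3, Phase.IM3M: 3}[name]
        refl = _build_reflections(name, n_reflections)
        ms = [r.m for r in refl]
        assert all(b > a for a, b in zip(ms, ms[1:])), "reflection list not ascending"
        return cls(name=name, reflections=refl, dimensionality=dim)

    @property
    def ratios(self) -> np.ndarray:
        """Spacing ratios m of the allowed reflections, ascending."""
        return np.array([r.m for r in self.reflections])


def standard_candidates(include_hexagonal: bool = False,
                        n_reflections: int = 6) -> list[MesophaseModel]:
    """The default indexing candidate set: lamellar, Pn3m, Im3m (+ optional HII)."""
    names = [Phase.LAMELLAR, Phase.PN3M, Phase.IM3M]
    if include_hexagonal:
        names.append(Phase.HEXAGONAL)
    return [MesophaseModel.create(n, n_reflections) for n in names]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reflection_positions(
    model: MesophaseModel,
    lattice: float,
    q_window: tuple[float, float] = DEFAULT_Q_WINDOW,
) -> list[tuple[Reflection, float]]:
    """Predict Bragg positions q = 2*pi*m/a inside ``q_window``, sorted by q.

    Parameters
    ----------
    model : MesophaseModel
    lattice : float
        Lattice parameter a in nm (> 0).
    q_window : (float, float)
        Inclusive q interval in nm^-1.
    """
    if not lattice > 0:
        raise ValueError(f"lattice parameter must be positive, got {lattice}")
    lo, hi = q_window
    if not hi > lo:
        raise ValueError(f"empty q window {q_window}")
    out = []
    for refl in model.reflections:
        q = 2.0 * math.pi * refl.m / lattice
        if lo <= q <= hi:
            out.append((refl, q))
    return out


@dataclass(frozen=True)
class LatticeEstimate:
    """Lattice parameter a (nm) with uncertainty and fit diagnostics."""

    a: float
    sigma_a: float
    residual_rms: float  # relative, dimensionless
    n_peaks: int

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("lattice parameter must be positive")
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be non-negative")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a:.3g} ± {self.sigma_a:.2g} nm (n={self.n_peaks})"


def _as_q_sigma(obs) -> tuple[float, float | None]:
    """Accept a PeakObservation-like object, a (q, sigma) pair, or a bare q."""
    if hasattr(obs, "q0"):
        return float(obs.q0), (float(obs.q0_err) if getattr(obs, "q0_err", None) else None)
    if isinstance(obs, (tuple, list)) and len(obs) == 2:
        q, s = obs
        return float(q), (float(s) if s is not None else None)
    return float(obs), None


def lattice_from_assignments(
    assigned: Sequence[tuple[object, Reflection]],
) -> LatticeEstimate:
    """Fit the lattice parameter from peaks assigned to reflections.

    Weighted least squares of q_i = (2*pi/a) * m_i through the origin, with
    weights 1/sigma_q^2 when every peak carries a position uncertainty and
    uniform weights otherwise. With >= 2 peaks the uncertainty of a comes
    from the residual scatter of the peak positions about the fitted line;
    with a single peak it is propagated from that peak's position
    uncertainty.
    """
    if len(assigned) == 0:
        raise ValueError("need at least one (peak, reflection) assignment")
    qs, sigmas, ms = [], [], []
    for obs, refl in assigned:
        q, s = _as_q_sigma(obs)
        if not q > 0:
            raise ValueError(f"peak position must be positive, got {q}")
        if not refl.m > 0:
            raise ValueError(f"reflection ratio must be positive, got {refl.m}")
        qs.append(q)
        sigmas.append(s)
        ms.append(refl.m)
    q = np.asarray(qs)
    m = np.asarray(ms)
    if all(s is not None and s > 0 for s in sigmas):
        w = 1.0 / np.asarray(sigmas, dtype=float) ** 2
    else:
        w = np.ones_like(q)

    # slope s_hat of q = s*m through the origin
    swm2 = float(np.sum(w * m * m))
    s_hat = float(np.sum(w * m * q)) / swm2
    a = 2.0 * math.pi / s_hat

    resid = q - s_hat * m
    pred = s_hat * m
    residual_rms = float(np.sqrt(np.mean((resid / pred) ** 2)))

    n = len(q)
    if n >= 2:
        # slope variance from weighted residual scatter; with only a few
        # peaks that estimate has ~1 degree of freedom, so when position
        # uncertainties are available it is floored by the propagated WLS
        # slope error (the larger of the two is the honest one)
        var_s = float(np.sum(w * resid**2)) / ((n - 1) * swm2)
        if all(s is not None and s > 0 for s in sigmas):
            var_s = max(var_s, 1.0 / swm2)
        sigma_s = math.sqrt(max(var_s, 0.0))
    else:
        sq = sigmas[0] if sigmas[0] is not None else 0.0
        sigma_s = s_hat * sq / q[0]
    sigma_a = a * sigma_s / s_hat
    return LatticeEstimate(a=a, sigma_a=sigma_a, residual_rms=residual_rms, n_peaks=n)
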