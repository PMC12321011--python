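"""Assign fitted Bragg peaks to coexisting mesophases by combination search.

Lipid mesophase samples frequently show several phases at once (e.g. a
lamellar stack coexisting with Pn3m and Im3m bicontinuous cubics), so a
single-phase indexer is not enough. This module enumerates phase subsets,
anchors each phase's lattice on a low-q peak interpreted as each of its
low-order reflections, greedily claims peaks within a relative tolerance,
refines the lattice by the through-origin regression of
:func:`mesosaxs.phases.lattice_from_assignments`, and iterates
claim/refine to a fixed point. Assignments are ranked lexicographically:
fewest unexplained peaks, then fewest phases (parsimony), then lowest
relative position RMS. Near-ties are reported, not silently resolved —
with few visible peaks several cubic aspects can fit equally well, and the
ranking is designed to surface that ambiguity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .peaks import PeakObservation
from .phases import (
    LatticeEstimate,
    MesophaseModel,
    Phase,
    Reflection,
    lattice_from_assignments,
    standard_candidates,
)

__all__ = ["PhaseAssignment", "index_phases", "compare_states"]

#: plausible lyotropic lattice range (nm) used to prune anchor hypotheses
_A_RANGE = (1.0, 100.0)
_N_ANCHOR_REFLECTIONS = 3
_MAX_REFINE_ITER = 10


@dataclass
class PhaseAssignment:
    """One candidate explanation of a peak list by a set of phases."""

    phases: dict[str, LatticeEstimate]  # phase name -> lattice estimate
    peak_map: list[tuple[int, Optional[str], Optional[Reflection]]]
    n_unexplained: int
    rms: float  # relative position RMS over mapped peaks
    n_missing: int = 0  # predicted reflections inside the observed span with no peak
    missing_weight: float = 0.0  # sum of 1/m^2 over missing reflections
    flags: tuple[str, ...] = ()

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def score(self) -> tuple:
        """Lexicographic rank key (lower is better).

        The first component counts total defects: observed peaks the
        assignment cannot place plus reflections it predicts inside the
        observed span that have no peak. Counting both symmetrically is
        what separates the cubic aspects when their shared-ratio
        reflections alias onto each other, and keeps an extra phase from
        looking "free" just because it absorbs a stray peak. Ties break by
        parsimony (fewer phases), then position RMS, then the 1/m^2-weighted
        missing count (losing a strong low-order prediction is worse than
        losing a weak high order), then phase names.
        """
        return (self.n_unexplained + self.n_missing, self.n_phases, self.rms,
                self.missing_weight, tuple(sorted(self.phases)))

    @property
    def phase_set(self) -> frozenset[str]:
        return frozenset(self.phases)

    def to_report(self) -> dict:
        return {
            "phases": {name: {"a_nm": est.a, "sigma_a_nm": est.sigma_a,
                              "residual_rms": est.residual_rms,
                              "n_peaks": est.n_peaks}
                       for name, est in self.phases.items()},
            "peak_map": [
                {"peak": i, "phase": ph, "reflection": (r.label if r else None)}
                for i, ph, r in self.peak_map],
            "n_unexplained": self.n_unexplained,
            "n_phases": self.n_phases,
            "n_missing": self.n_missing,
            "rms": self.rms,
            "flags": list(self.flags),
        }


def _predicted(model: MesophaseModel, a: float) -> list[tuple[Reflection, float]]:
    return [(r, 2.0 * math.pi * r.m / a) for r in model.reflections]


def _claim_peaks(
    q_obs: np.ndarray,
    models: dict[str, MesophaseModel],
    lattices: dict[str, float],
    tol: float,
) -> list[tuple[int, Optional[str], Optional[Reflection]]]:
    """Map each peak to its best (phase, reflection) within relative tol.

    Each reflection of each phase may claim at most one peak (the closest);
    each peak maps at most once. Matches are committed best-first so the
    outcome is independent of peak order.
    """
    proposals = []  # (rel_dist, peak_idx, phase, reflection)
    for name, model in models.items():
        for refl, q_pred in _predicted(model, lattices[name]):
            rel = np.abs(q_obs - q_pred) / q_pred
            i = int(np.argmin(rel))
            if rel[i] <= tol:
                proposals.append((float(rel[i]), i, name, refl))
    proposals.sort(key=lambda t: (t[0], t[2], t[3].m))
    mapping: dict[int, tuple[str, Reflection]] = {}
    used: set[tuple[str, float]] = set()
    for rel, i, name, refl in proposals:
        if i in mapping or (name, refl.m) in used:
            continue
        mapping[i] = (name, refl)
        used.add((name, refl.m))
    return [(i, *(mapping.get(i, (None, None)))) for i in range(q_obs.size)]


def _evaluate(
    peaks: Sequence[PeakObservation],
    subset: Sequence[MesophaseModel],
    lattices0: dict[str, float],
    tol: float,
    q_range: Optional[tuple[float, float]] = None,
) -> Optional[PhaseAssignment]:
    """Iterate claim/refine from seed lattices to a fixed point."""
    q_obs = np.array([p.q0 for p in peaks])
    models = {m.name.value: m for m in subset}
    lattices = dict(lattices0)
    peak_map = None
    for _ in range(_MAX_REFINE_ITER):
        new_map = _claim_peaks(q_obs, models, lattices, tol)
        if new_map == peak_map:
            break
        peak_map = new_map
        new_lattices = {}
        for name in models:
            assigned = [(peaks[i], refl) for i, ph, refl in peak_map if ph == name]
            if not assigned:
                return None  # a phase in the subset explains nothing
            new_lattices[name] = lattice_from_assignments(assigned).a
        lattices = new_lattices
    # in a coexistence hypothesis a phase resting on a single peak is no
    # evidence at all (any stray peak can anchor some lattice), so such
    # phases are collapsed out and their peak reverts to unexplained; only
    # a lone single-phase assignment may stand on one peak, flagged below
    if len(models) > 1:
        weak = [name for name in models
                if sum(1 for _, ph, _ in peak_map if ph == name) < 2]
        if weak:
            models = {n: m for n, m in models.items() if n not in weak}
            if not models:
                return None
            peak_map = [(i, None, None) if ph in weak else (i, ph, refl)
                        for i, ph, refl in peak_map]
    estimates = {}
    sq_rel = []
    n_missing = 0
    missing_weight = 0.0
    if q_range is not None:
        # the instrument window: predicted reflections anywhere in the
        # measured range with no matching peak count as missing
        span = (float(q_range[0]), float(q_range[1]))
    else:
        span = (float(q_obs[0]) * (1.0 - tol), float(q_obs[-1]) * (1.0 + tol))
    for name, model in models.items():
        assigned = [(peaks[i], refl) for i, ph, refl in peak_map if ph == name]
        est = lattice_from_assignments(assigned)
        estimates[name] = est
        claimed_m = {refl.m for _, ph, refl in peak_map if ph == name}
        for refl, q_pred in _predicted(model, est.a):
            if span[0] <= q_pred <= span[1] and refl.m not in claimed_m:
                n_missing += 1
                missing_weight += 1.0 / refl.m**2
        for i, ph, refl in peak_map:
            if ph == name:
                q_pred = 2.0 * math.pi * refl.m / est.a
                sq_rel.append(((peaks[i].q0 - q_pred) / q_pred) ** 2)
    n_unexplained = sum(1 for _, ph, _ in peak_map if ph is None)
    rms = float(np.sqrt(np.mean(sq_rel))) if sq_rel else float("inf")
    flags = []
    if all(est.n_peaks <= 1 for est in estimates.values()):
        flags.append("underdetermined")
    return PhaseAssignment(estimates, peak_map, n_unexplained, rms, n_missing,
                           missing_weight, tuple(flags))


def index_phases(
    peaks: Sequence[PeakObservation],
    candidates: Sequence[MesophaseModel] | None = None,
    max_phases: int = 3,
    tol: float = 0.01,
    margin: float | None = None,
    q_range: Optional[tuple[float, float]] = None,
) -> list[PhaseAssignment]:
    """Rank explanations of a fitted peak list by coexisting mesophases.

    Parameters
    ----------
    peaks : sequence of PeakObservation
        Fitted peaks (use converged, significant ones).
    candidates : sequence of MesophaseModel, optional
        Candidate phases; defaults to lamellar + Pn3m + Im3m.
    max_phases : int
        Largest coexistence considered (default 3).
    tol : float
        Relative q tolerance for claiming a peak (default 0.01). Relative,
        not absolute, because candidate lattices span a wide range.
    margin : float, optional
        Reporting margin: assignments whose RMS is within ``margin`` of the
        best one with the same unexplained count are all returned, so
        near-degenerate alternatives stay visible. Defaults to ``tol/2``.
    q_range : (float, float), optional
        The measured q window. When given, a candidate phase predicting a
        reflection anywhere in this window with no observed peak is
        penalized; without it only the span between the outermost observed
        peaks is checked.

    Returns
    -------
    list of PhaseAssignment, best first. Empty (after a diagnostic check)
    only when no candidate explains a single peak.
    """
    if len(peaks) == 0:
        raise ValueError("peak list is empty")
    if max_phases < 1:
        raise ValueError("max_phases must be >= 1")
    if candidates is None:
        candidates = standard_candidates()
    if margin is None:
        margin = tol / 2.0
    peaks = sorted(peaks, key=lambda p: p.q0)
    q_obs = np.array([p.q0 for p in peaks])

    results: dict[tuple, PhaseAssignment] = {}

    def search(subset: tuple[MesophaseModel, ...], phase_idx: int,
               claimed: set[int], lattices: dict[str, float]) -> None:
        if phase_idx == len(subset):
            assignment = _evaluate(peaks, subset, lattices, tol, q_range)
            if assignment is None:
                return
            key = (assignment.phase_set,
                   tuple(round(assignment.phases[n].a, 6)
                         for n in sorted(assignment.phases)))
            prev = results.get(key)
            if prev is None or assignment.score < prev.score:
                results[key] = assignment
            return
        model = subset[phase_idx]
        unclaimed = [i for i in range(len(peaks)) if i not in claimed]
        if not unclaimed:
            return
        anchor = unclaimed[0]  # lowest-q unclaimed peak
        for refl in model.reflections[:_N_ANCHOR_REFLECTIONS]:
            a0 = 2.0 * math.pi * refl.m / q_obs[anchor]
            if not (_A_RANGE[0] <= a0 <= _A_RANGE[1]):
                continue
            # greedy provisional claim for this phase only
            provisional = _claim_peaks(
                q_obs, {model.name.value: model}, {model.name.value: a0}, tol)
            mine = {i for i, ph, _ in provisional if ph is not None and i not in claimed}
            if anchor not in mine:
                continue
            assigned = [(peaks[i], r) for i, ph, r in provisional if i in mine]
            a_ref = lattice_from_assignments(assigned).a
            search(subset, phase_idx + 1, claimed | mine,
                   {**lattices, model.name.value: a_ref})

    # permutations, not combinations: the anchoring is sequential (each
    # phase grabs the lowest-q still-unclaimed peak), so which phase goes
    # first matters when phases interleave in q
    for size in range(1, min(max_phases, len(candidates)) + 1):
        for subset in itertools.combinations(candidates, size):
            for perm in itertools.permutations(subset):
                search(perm, 0, set(), {})

    ranked = sorted(results.values(), key=lambda a: a.score)
    if not ranked:
        return []
    best = ranked[0]
    reported = [a for a in ranked
                if a.score[0] == best.score[0]
                and a.rms <= best.rms + margin]
    # keep the remaining tail too, after the in-margin block, so callers can
    # inspect weaker alternatives without re-running the search
    tail = [a for a in ranked if a not in reported]
    return reported + tail


def compare_states(
    assignment_a: PhaseAssignment,
    assignment_b: PhaseAssignment,
    n_sigma: float = 1.5,
) -> dict:
    """Compare indexed structures of two illumination states.

    Reports phases appearing/disappearing/persisting and, per persisting
    phase, the lattice change da +/- sigma. Classified as a mesophase
    transition when the phase sets differ, as a d-spacing shift when a
    persisting lattice moves by more than ``n_sigma`` combined sigma, else
    no change. The default of 1.5 combined sigmas classifies a 0.04 nm
    lamellar shift with per-state errors of 0.01/0.02 nm as real, which is
    how such photoswitching-induced changes are reported in practice.
    """
    set_a, set_b = assignment_a.phase_set, assignment_b.phase_set
    appeared = sorted(set_b - set_a)
    disappeared = sorted(set_a - set_b)
    persisting = {}
    any_shift = False
    for name in sorted(set_a & set_b):
        ea, eb = assignment_a.phases[name], assignment_b.phases[name]
        da = eb.a - ea.a
        sigma = math.sqrt(ea.sigma_a**2 + eb.sigma_a**2)
        significant = abs(da) > n_sigma * sigma
        any_shift = any_shift or significant
        persisting[name] = {"a_before_nm": ea.a, "a_after_nm": eb.a,
                            "delta_a_nm": da, "sigma_delta_nm": sigma,
                            "significant": significant}
    if appeared or disappeared:
        outcome = "mesophase transition"
    elif any_shift:
        outcome = "d-spacing shift"
    else:
        outcome = "no change"
    return {"outcome": outcome, "appeared": appeared,
            "disappeared": disappeared, "persisting": persisting}
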