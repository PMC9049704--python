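"""Thermal circular-dichroism denaturation analysis.

The stability metric is model-free: raw 228 nm CD signal is normalized so
that its 5–8 °C baseline mean reads 100%, and T50 is the temperature at
which half of that signal is lost (first downward crossing, linearly
interpolated).  No two-state or multi-state thermodynamic fit is attempted;
peptides are rank-ordered directly by T50 with replicate-level ties
reported as equivalence groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import medfilt


@dataclass
class MeltCurve:
    """Temperature-indexed CD signal at a single wavelength."""

    temperatures: np.ndarray      # °C, strictly increasing
    signal: np.ndarray            # raw mdeg, or % remaining once normalized
    wavelength: float = 228.0     # nm
    normalized: bool = False
    replicate: str | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperatures) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class EllipticityInput:
    m: float   # raw CD reading, millidegrees
    l: float   # cell path length, millimeters
    n: int     # number of amino acids
    C: float   # concentration, micromolar

    def __post_init__(self):
        if self.l <= 0 or self.n <= 0 or self.C <= 0:
            raise ValueError("path length, residue count and concentration must be positive")


def mean_molar_ellipticity(inp: EllipticityInput) -> float:
    """Mean (residue) molar ellipticity in deg·cm²·dmol⁻¹.

    [θ] = m·10⁶ / (l·n·C) with m in mdeg, l in mm, n residues and C in µM —
    linear in the raw reading and inversely proportional to path length,
    residue count and concentration.
    """
    return inp.m * 1.0e6 / (inp.l * inp.n * inp.C)


def average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Point-wise average of replicate raw curves sharing a temperature grid
    (replicate averaging precedes normalization)."""
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if len(c.temperatures) != len(t0) or not np.allclose(c.temperatures, t0):
            raise ValueError("replicates must share the temperature grid")
    sig = np.mean([c.signal for c in curves], axis=0)
    return MeltCurve(temperatures=t0.copy(), signal=sig,
                     wavelength=curves[0].wavelength)


def percent_remaining(curve: MeltCurve, baseline_window: tuple[float, float] = (5.0, 8.0),
                      epsilon: float = 1e-9) -> MeltCurve:
    """Normalize so the baseline-window mean reads 100%.

    Every point is divided by the mean signal inside the (inclusive) window
    and multiplied by 100.  Idempotent on already-normalized curves.
    """
    lo, hi = baseline_window
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError("baseline window must contain at least two points")
    base = float(curve.signal[mask].mean())
    if abs(base) <= epsilon:
        raise ValueError("baseline mean is (near) zero; unusable baseline")
    return replace(curve, signal=curve.signal / base * 100.0, normalized=True)


def t50(curve: MeltCurve) -> float | None:
    """Temperature of the first downward crossing of 50% remaining signal,
    linearly interpolated; None when the signal never drops through 50%.

    Crossings are located on a 3-point median-filtered copy so single-point
    noise excursions do not register; the raw curve is left untouched.
    """
    if not curve.normalized:
        raise ValueError("t50 requires a normalized curve (percent_remaining)")
    sig = curve.signal
    if len(sig) >= 3:
        sig = medfilt(sig, kernel_size=3)
    temps = curve.temperatures
    above = sig > 50.0
    if len(sig) and not above[0]:
        # half the signal is already gone at the first measured temperature
        return float(temps[0])
    for i in range(len(sig) - 1):
        if above[i] and not above[i + 1]:
            s0, s1 = sig[i], sig[i + 1]
            frac = (s0 - 50.0) / (s0 - s1)
            return float(temps[i] + frac * (temps[i + 1] - temps[i]))
    return None


def rank_stability(t50_by_name: Mapping[str, float | None],
                   tie_tolerance: float = 0.4) -> list[list[str]]:
    """Descending stability order by T50 with tie groups.

    Curves whose consecutive T50s differ by at most ``tie_tolerance`` °C
    (the replicate standard deviation scale) are merged into one equivalence
    group.  Entries with no T50 are reported last as a separate group.
    """
    known = {k: v for k, v in t50_by_name.items() if v is not None}
    unknown = sorted(k for k, v in t50_by_name.items() if v is None)
    ordered = sorted(known.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[list[str]] = []
    last_t = None
    for name, t in ordered:
        if last_t is not None and (last_t - t) <= tie_tolerance:
            groups[-1].append(name)
        else:
            groups.append([name])
        last_t = t
    if unknown:
        groups.append(unknown)
    return groups


def rank_melt_curves(curves: Mapping[str, MeltCurve],
                     tie_tolerance: float = 0.4) -> list[list[str]]:
    """Rank named normalized curves by their extracted T50."""
    return rank_stability({name: t50(c) for name, c in curves.items()},
                          tie_tolerance=tie_tolerance)


def format_ranking(groups: Sequence[Sequence[str]]) -> str:
    """Human-readable ordering, e.g. ``E5L > WT > (W4S ~ W11S)``."""
    parts = []
    for g in groups:
        parts.append(g[0] if len(g) == 1 else "(" + " ~ ".join(g) + ")")
    return " > ".join(parts)
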