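"""Selectivity landscapes, peak finding and candidate screening.

Selectivity is ``S = p_t - p_b``, the gap between target and bystander
editing probabilities.  Scanning S over the mutation energy ``ddEm``
exposes a single interior maximum for destabilized bystander contexts
(``ddE0 > 0``): the scan, its refined peak, the design window around it
and ranked candidate screening live here, together with one-at-a-time
sensitivity scans over ``gamma1``, ``gamma3`` and ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .closed_form import pt_pb_reduced
from .errors import ValidationError
from .params import ReducedParams

__all__ = [
    "DEFAULT_GRID",
    "SelectivityCurve",
    "PeakInfo",
    "CandidateMutation",
    "selectivity_scan",
    "find_peak",
    "screen_candidates",
    "sensitivity_scan",
]

#: Default ddEm grid: [-5, 15] k_B*T in steps of 0.05.
DEFAULT_GRID = np.round(np.arange(-5.0, 15.0 + 1e-9, 0.05), 10)

_REFINE_TOL = 1e-4
_DEGENERATE_S = 1e-12


@dataclass(frozen=True)
class SelectivityCurve:
    """S(ddEm) on a grid, with the generating parameters.

    ``params.ddEm`` is ignored; ``ddEm`` is the swept variable.
    """

    ddEm: np.ndarray
    p_t: np.ndarray
    p_b: np.ndarray
    s: np.ndarray
    params: ReducedParams

    def __post_init__(self) -> None:
        if self.ddEm.size == 0:
            raise ValidationError("grid must be nonempty")
        if np.any(np.diff(self.ddEm) <= 0):
            raise ValidationError("grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ddEm_kBT": self.ddEm, "pt": self.p_t, "pb": self.p_b, "S": self.s}
        )


@dataclass(frozen=True)
class PeakInfo:
    """Location and height of the selectivity maximum and its window."""

    ddEm_peak: float
    s_max: float
    window: tuple[float, float]
    fraction: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not self.degenerate and not lo <= self.ddEm_peak <= hi:
            raise ValidationError("window must contain the peak")


@dataclass(frozen=True)
class CandidateMutation:
    name: str
    ddEm: float
    p_t: float
    p_b: float
    s: float
    in_window: bool
    rank: int
    ddEm_sem: float | None = None


def _pt_pb_on_grid(p: ReducedParams, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pt = np.empty(grid.size)
    pb = np.empty(grid.size)
    for i, x in enumerate(grid):
        pt[i], pb[i] = pt_pb_reduced(p.replace(ddEm=float(x)))
    return pt, pb


def selectivity_scan(
    p: ReducedParams, grid: np.ndarray | Sequence[float] = DEFAULT_GRID
) -> SelectivityCurve:
    """Evaluate (p_t, p_b, S) at every ddEm grid node."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and not np.all(np.isfinite(grid)):
        raise ValidationError("grid must be finite")
    pt, pb = _pt_pb_on_grid(p, grid)
    return SelectivityCurve(ddEm=grid, p_t=pt, p_b=pb, s=pt - pb, params=p)


def _selectivity_at(p: ReducedParams, x: float) -> float:
    pt, pb = pt_pb_reduced(p.replace(ddEm=x))
    return pt - pb


def find_peak(curve: SelectivityCurve, fraction: float = 0.9) -> PeakInfo:
    """Locate the selectivity maximum and its design window.

    The grid argmax is refined between its neighbouring nodes by
    bounded golden-section search (tolerance 1e-4 k_B*T).  The window
    is the contiguous interval around the peak where
    ``S >= fraction * s_max``, with its edges refined by bisection.
    Grid ties break toward the smallest ddEm (least destabilization).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    s = curve.s
    p = curve.params
    i_max = int(np.argmax(s))  # np.argmax takes the first (smallest ddEm) tie
    if s[i_max] <= _DEGENERATE_S:
        # Flat or non-positive curve (e.g. ddE0 == 0): no usable peak.
        return PeakInfo(
            ddEm_peak=float(curve.ddEm[i_max]),
            s_max=float(s[i_max]),
            window=(float(curve.ddEm[0]), float(curve.ddEm[-1])),
            fraction=fraction,
            degenerate=True,
        )

    lo_i = max(i_max - 1, 0)
    hi_i = min(i_max + 1, s.size - 1)
    if hi_i > lo_i:
        res = optimize.minimize_scalar(
            lambda x: -_selectivity_at(p, x),
            bounds=(float(curve.ddEm[lo_i]), float(curve.ddEm[hi_i])),
            method="bounded",
            options={"xatol": _REFINE_TOL},
        )
        x_peak, s_max = float(res.x), float(-res.fun)
        if s_max < s[i_max]:  # refinement can only improve on the node
            x_peak, s_max = float(curve.ddEm[i_max]), float(s[i_max])
    else:
        x_peak, s_max = float(curve.ddEm[i_max]), float(s[i_max])

    threshold = fraction * s_max

    def edge(i_inside: int, i_outside: int, x_inside: float) -> float:
        """Refine the window edge between an in-window and out-window node."""
        x_out = float(curve.ddEm[i_outside])
        if i_inside == i_outside:
            return x_inside
        f = lambda x: _selectivity_at(p, x) - threshold
        a, b = sorted((float(curve.ddEm[i_inside]), x_out))
        if f(a) * f(b) > 0:
            return float(curve.ddEm[i_inside])
        return float(optimize.brentq(f, a, b, xtol=_REFINE_TOL))

    # Contiguous run of grid nodes around the peak with S >= threshold.
    left = i_max
    while left > 0 and s[left - 1] >= threshold:
        left -= 1
    right = i_max
    while right < s.size - 1 and s[right + 1] >= threshold:
        right += 1
    lo = edge(left, max(left - 1, 0), x_peak) if s[left] >= threshold else x_peak
    hi = edge(right, min(right + 1, s.size - 1), x_peak) if s[right] >= threshold else x_peak
    lo = min(lo, x_peak)
    hi = max(hi, x_peak)
    return PeakInfo(
        ddEm_peak=x_peak, s_max=s_max, window=(lo, hi), fraction=fraction
    )


def screen_candidates(
    p: ReducedParams,
    candidates: Sequence[tuple[str, float] | tuple[str, float, float]],
    fraction: float = 0.9,
    grid: np.ndarray | Sequence[float] = DEFAULT_GRID,
) -> list[CandidateMutation]:
    """Rank candidate mutations by predicted selectivity.

    Each candidate is ``(name, ddEm)`` or ``(name, ddEm, ddEm_sem)``.
    Candidates are ranked by S descending with name as the tiebreaker;
    ``in_window`` flags proximity to the selectivity peak as computed
    by :func:`find_peak` on ``grid``.
    """
    if not candidates:
        raise ValidationError("candidate list must be nonempty")
    peak = find_peak(selectivity_scan(p, grid), fraction=fraction)
    lo, hi = peak.window
    rows = []
    for cand in candidates:
        name, ddEm = cand[0], float(cand[1])
        sem = float(cand[2]) if len(cand) > 2 and cand[2] is not None else None
        pt, pb = pt_pb_reduced(p.replace(ddEm=ddEm))
        rows.append(
            {
                "name": str(name),
                "ddEm": ddEm,
                "ddEm_sem": sem,
                "p_t": pt,
                "p_b": pb,
                "s": pt - pb,
                "in_window": (not peak.degenerate) and lo <= ddEm <= hi,
            }
        )
    rows.sort(key=lambda r: (-r["s"], r["name"]))
    return [
        CandidateMutation(rank=i + 1, **row) for i, row in enumerate(rows)
    ]


def sensitivity_scan(
    p: ReducedParams,
    parameter: str,
    factors: Iterable[float],
    grid: np.ndarray | Sequence[float] = DEFAULT_GRID,
) -> dict[float, SelectivityCurve]:
    """One-at-a-time sensitivity of the selectivity curve.

    For ``gamma1`` / ``gamma3`` each factor multiplies the base value;
    for ``m`` the factor is used as the new value directly (m may be 0,
    so a multiplicative scan would be ill-defined).
    """
    if parameter not in ("gamma1", "gamma3", "m"):
        raise ValidationError(
            f"parameter must be one of gamma1, gamma3, m; got {parameter!r}"
        )
    curves: dict[float, SelectivityCurve] = {}
    for factor in factors:
        factor = float(factor)
        if parameter == "m":
            if not 0.0 <= factor <= 1.0:
                raise ValidationError("m values must lie in [0, 1]")
            varied = p.replace(m=factor)
        else:
            if factor <= 0:
                raise ValidationError("factors must be positive")
            varied = p.replace(**{parameter: getattr(p, parameter) * factor})
        curves[factor] = selectivity_scan(varied, grid)
    return curves
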