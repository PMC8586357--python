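"""Least-squares calibration of the free rate ratios.

Given per-variant binding-energy perturbations and observed target /
bystander editing fractions, ``fit_gammas`` estimates ``gamma1`` and
``gamma3`` (optionally ``m``) by minimizing the unweighted sum of
squared residuals of the reduced closed forms.  The optimization runs
in log10 space with a coarse multi-start grid followed by local
refinement, and is fully deterministic for fixed options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .closed_form import pt_pb_reduced
from .errors import UnderdeterminedError, ValidationError
from .params import ReducedParams

__all__ = [
    "VariantObservation",
    "FitOptions",
    "FitResult",
    "fit_gammas",
    "profile_objective",
]


@dataclass(frozen=True)
class VariantObservation:
    """One editor variant's energy perturbation and observed editing.

    ``ddEm`` / ``ddEm_sem`` are in k_B*T; ``pt_obs`` / ``pb_obs`` are
    editing fractions in [0, 1].
    """

    variant_id: str
    ddEm: float
    pt_obs: float
    pb_obs: float
    ddEm_sem: float | None = None
    locus: str = ""
    n_reps: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddEm):
            raise ValidationError(f"{self.variant_id}: ddEm must be finite")
        for name in ("pt_obs", "pb_obs"):
            value = getattr(self, name)
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{self.variant_id}: {name}={value!r} must lie in [0, 1]"
                )
        if self.ddEm_sem is not None and (
            not math.isfinite(self.ddEm_sem) or self.ddEm_sem < 0
        ):
            raise ValidationError(f"{self.variant_id}: ddEm_sem must be >= 0")


@dataclass(frozen=True)
class FitOptions:
    """Deterministic knobs of the fit.

    ``log10_bounds`` bound both log10(gamma1) and log10(gamma3);
    ``coarse_grid`` is the per-axis size of the multi-start grid;
    ``n_starts`` local refinements are launched from the best coarse
    nodes.
    """

    log10_bounds: tuple[float, float] = (-8.0, 3.0)
    coarse_grid: int = 5
    n_starts: int = 25
    fit_m: bool = False
    weight_by_sem: bool = False
    xtol: float = 1e-10
    ftol: float = 1e-14

    def __post_init__(self) -> None:
        if self.log10_bounds[0] >= self.log10_bounds[1]:
            raise ValidationError("log10_bounds must be an increasing pair")
        if self.coarse_grid < 2 or self.n_starts < 1:
            raise ValidationError("coarse_grid >= 2 and n_starts >= 1 required")


@dataclass(frozen=True)
class FitResult:
    gamma1_hat: float
    gamma3_hat: float
    sse: float
    residuals: pd.DataFrame
    converged: bool
    n_restarts_used: int
    m_hat: float | None = None

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            "gamma1_hat": self.gamma1_hat,
            "gamma3_hat": self.gamma3_hat,
            "sse": self.sse,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        if self.m_hat is not None:
            out["m_hat"] = self.m_hat
        return out


def _check_fixed(fixed: Mapping[str, float], fit_m: bool) -> tuple[float, float, float]:
    try:
        gamma2 = float(fixed["gamma2"])
        ddE0 = float(fixed["ddE0"])
    except KeyError as exc:
        raise ValidationError(f"fixed must provide {exc.args[0]!r}") from exc
    m = float(fixed.get("m", 0.0))
    if not fit_m:
        # Validate through the parameter container.
        ReducedParams(gamma1=1.0, gamma2=gamma2, gamma3=1.0, m=m, ddE0=ddE0)
    return gamma2, ddE0, m


def _model_predictions(
    obs: Sequence[VariantObservation],
    gamma1: float,
    gamma3: float,
    gamma2: float,
    m: float,
    ddE0: float,
) -> np.ndarray:
    """(n_obs, 2) array of model (pt, pb) per observation."""
    out = np.empty((len(obs), 2))
    for i, o in enumerate(obs):
        p = ReducedParams(
            gamma1=gamma1, gamma2=gamma2, gamma3=gamma3, m=m, ddE0=ddE0, ddEm=o.ddEm
        )
        out[i] = pt_pb_reduced(p)
    return out


def _objective(
    obs: Sequence[VariantObservation],
    gamma2: float,
    ddE0: float,
    weights: np.ndarray,
) -> "callable":
    def sse(theta: np.ndarray, m_fixed: float | None) -> float:
        g1 = 10.0 ** theta[0]
        g3 = 10.0 ** theta[1]
        m = float(theta[2]) if m_fixed is None else m_fixed
        if not 0.0 <= m <= 1.0:
            return float("inf")
        try:
            pred = _model_predictions(obs, g1, g3, gamma2, m, ddE0)
        except (OverflowError, ArithmeticError):
            return float("inf")
        observed = np.array([[o.pt_obs, o.pb_obs] for o in obs])
        return float((weights * (pred - observed) ** 2).sum())

    return sse


def _weights(obs: Sequence[VariantObservation], weight_by_sem: bool) -> np.ndarray:
    if not weight_by_sem:
        return np.ones((len(obs), 2))
    sems = np.array(
        [o.ddEm_sem if o.ddEm_sem not in (None, 0) else 1.0 for o in obs]
    )
    return np.repeat((1.0 / sems**2)[:, None], 2, axis=1)


def fit_gammas(
    obs: Sequence[VariantObservation],
    fixed: Mapping[str, float],
    options: FitOptions | None = None,
) -> FitResult:
    """Fit (gamma1, gamma3) [and optionally m] to observed editing.

    ``fixed`` must provide ``gamma2`` and ``ddE0`` and may provide
    ``m`` (default 0).  Requires at least two observations spanning two
    distinct ddEm values; otherwise the two rate ratios are not
    identifiable and :class:`UnderdeterminedError` is raised.
    """
    options = options or FitOptions()
    obs = list(obs)
    if len(obs) < 2 or len({o.ddEm for o in obs}) < 2:
        raise UnderdeterminedError(
            "need >= 2 observations spanning >= 2 distinct ddEm values "
            f"(got {len(obs)} observations, {len({o.ddEm for o in obs})} distinct ddEm)"
        )
    gamma2, ddE0, m_fixed = _check_fixed(fixed, options.fit_m)
    weights = _weights(obs, options.weight_by_sem)
    sse = _objective(obs, gamma2, ddE0, weights)
    lo, hi = options.log10_bounds

    # Coarse multi-start grid (sorted scan order: deterministic).
    axis = np.linspace(lo, hi, options.coarse_grid)
    coarse: list[tuple[float, tuple[float, ...]]] = []
    m_grid = [m_fixed] if not options.fit_m else [0.0, 0.5, 1.0]
    for m0 in m_grid:
        for t1 in axis:
            for t3 in axis:
                theta = (t1, t3) if not options.fit_m else (t1, t3, m0)
                coarse.append((sse(np.array(theta), None if options.fit_m else m_fixed), theta))
    coarse.sort(key=lambda item: (item[0], item[1]))

    ndim = 3 if options.fit_m else 2
    bounds = [(lo, hi), (lo, hi)] + ([(0.0, 1.0)] if options.fit_m else [])
    best: optimize.OptimizeResult | None = None
    n_used = 0
    for _, theta0 in coarse[: options.n_starts]:
        n_used += 1
        res = optimize.minimize(
            sse,
            np.array(theta0),
            args=(None if options.fit_m else m_fixed,),
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "xatol": options.xtol,
                "fatol": options.ftol,
                "maxiter": 2000 * ndim,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    assert best is not None
    g1_hat = 10.0 ** best.x[0]
    g3_hat = 10.0 ** best.x[1]
    m_hat = float(best.x[2]) if options.fit_m else None
    pred = _model_predictions(
        obs, g1_hat, g3_hat, gamma2, m_hat if options.fit_m else m_fixed, ddE0
    )
    residuals = pd.DataFrame(
        {
            "variant_id": [o.variant_id for o in obs],
            "ddEm_kBT": [o.ddEm for o in obs],
            "pt_obs": [o.pt_obs for o in obs],
            "pb_obs": [o.pb_obs for o in obs],
            "pt_model": pred[:, 0],
            "pb_model": pred[:, 1],
            "pt_residual": pred[:, 0] - np.array([o.pt_obs for o in obs]),
            "pb_residual": pred[:, 1] - np.array([o.pb_obs for o in obs]),
        }
    )
    return FitResult(
        gamma1_hat=g1_hat,
        gamma3_hat=g3_hat,
        sse=float(best.fun),
        residuals=residuals,
        converged=bool(best.success),
        n_restarts_used=n_used,
        m_hat=m_hat,
    )


def profile_objective(
    obs: Sequence[VariantObservation],
    fixed: Mapping[str, float],
    log10_gamma1_grid: Iterable[float],
    log10_gamma3_grid: Iterable[float],
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """SSE surface over a (log10 gamma1, log10 gamma3) grid.

    Returns a long-format DataFrame with columns ``log10_gamma1``,
    ``log10_gamma3`` and ``sse``; useful for fit diagnostics.
    """
    options = options or FitOptions()
    g1_grid = list(log10_gamma1_grid)
    g3_grid = list(log10_gamma3_grid)
    if not g1_grid or not g3_grid:
        raise ValidationError("grids must be nonempty")
    gamma2, ddE0, m_fixed = _check_fixed(fixed, fit_m=False)
    sse = _objective(list(obs), gamma2, ddE0, _weights(list(obs), options.weight_by_sem))
    rows = [
        {"log10_gamma1": t1, "log10_gamma3": t3, "sse": sse(np.array([t1, t3]), m_fixed)}
        for t1 in g1_grid
        for t3 in g3_grid
    ]
    return pd.DataFrame(rows)
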