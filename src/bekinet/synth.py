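"""Synthetic per-variant editing observations.

Emulates the experimental unit of the calibration workflow: for each
variant (one ddEm value) a cohort of cells is drawn from the model's
four-outcome categorical distribution, and the observed target /
bystander editing fractions are derived from the outcome counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closed_form import outcomes_from_rates
from .errors import ValidationError
from .fitting import VariantObservation
from .params import ReducedParams, rates_from_reduced

__all__ = ["SyntheticDataset", "generate_synthetic"]

_OUTCOMES = ("CTC", "CTT", "TTC", "TTT")


@dataclass(frozen=True)
class SyntheticDataset:
    """Multinomial outcome counts per variant at known true parameters.

    ``pt_obs``/``pb_obs`` are NaN (flagged missing) when ``n_cells`` is
    zero.
    """

    true_params: ReducedParams
    ddEm: tuple[float, ...]
    n_cells: int
    seed: int
    counts: pd.DataFrame  # columns CTC, CTT, TTC, TTT; one row per variant

    def __post_init__(self) -> None:
        totals = self.counts[list(_OUTCOMES)].sum(axis=1)
        if not (totals == self.n_cells).all():
            raise ValidationError("per-variant counts must sum to n_cells")

    @property
    def pt_obs(self) -> np.ndarray:
        if self.n_cells == 0:
            return np.full(len(self.ddEm), np.nan)
        return ((self.counts["CTT"] + self.counts["TTT"]) / self.n_cells).to_numpy()

    @property
    def pb_obs(self) -> np.ndarray:
        if self.n_cells == 0:
            return np.full(len(self.ddEm), np.nan)
        return ((self.counts["TTC"] + self.counts["TTT"]) / self.n_cells).to_numpy()

    def to_observations(self) -> list[VariantObservation]:
        """Convert to fitting inputs; requires n_cells > 0."""
        if self.n_cells == 0:
            raise ValidationError(
                "dataset has n_cells == 0: editing fractions are undefined"
            )
        return [
            VariantObservation(
                variant_id=f"synthetic_{i}",
                ddEm=float(x),
                pt_obs=float(pt),
                pb_obs=float(pb),
            )
            for i, (x, pt, pb) in enumerate(zip(self.ddEm, self.pt_obs, self.pb_obs))
        ]

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.copy()
        frame.insert(0, "variant_id", [f"synthetic_{i}" for i in range(len(self.ddEm))])
        frame.insert(1, "ddEm_kBT", list(self.ddEm))
        frame["pt_obs"] = self.pt_obs
        frame["pb_obs"] = self.pb_obs
        return frame


def generate_synthetic(
    true_params: ReducedParams,
    variants: "list[float]",
    n_cells: int,
    seed: int,
) -> SyntheticDataset:
    """Draw multinomial outcome counts for each variant ddEm.

    Per variant, ``n_cells`` editing outcomes are drawn from the
    four-outcome distribution of the model evaluated at that ddEm.
    Identical seeds give identical datasets.
    """
    if n_cells < 0:
        raise ValidationError(f"n_cells must be >= 0, got {n_cells}")
    variants = [float(v) for v in variants]
    if not variants:
        raise ValidationError("variants must be a nonempty list of ddEm values")
    for v in variants:
        if not math.isfinite(v):
            raise ValidationError(f"ddEm values must be finite, got {v!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for ddEm in variants:
        probs = outcomes_from_rates(
            rates_from_reduced(true_params.replace(ddEm=ddEm))
        )
        pvec = np.array([probs.p_ctc, probs.p_ctt, probs.p_ttc, probs.p_ttt])
        pvec = np.clip(pvec, 0.0, None)
        counts = rng.multinomial(n_cells, pvec / pvec.sum())
        rows.append(dict(zip(_OUTCOMES, (int(c) for c in counts))))
    return SyntheticDataset(
        true_params=true_params,
        ddEm=tuple(variants),
        n_cells=int(n_cells),
        seed=int(seed),
        counts=pd.DataFrame(rows, columns=list(_OUTCOMES)),
    )
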