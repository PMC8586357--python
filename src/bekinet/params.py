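"""Model parameters and the energy->rate mapping.

The editing model is fully specified by six dimensionless quantities
(:class:`ReducedParams`): three rate ratios ``gamma1``, ``gamma2``,
``gamma3``, the rebinding attenuation ``m`` and two binding free-energy
differences ``ddE0`` (bystander vs target context) and ``ddEm``
(mutant vs wild type), both in units of k_B*T.  Absolute rates are not
identifiable from outcome probabilities, so :func:`rates_from_reduced`
carries three free time scales that default to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

from .errors import ConsistencyError, DomainError, ValidationError

__all__ = [
    "EnzymeKinetics",
    "SiteKinetics",
    "ReducedParams",
    "RateSet",
    "infer_site_kinetics",
    "rates_from_reduced",
    "reduced_from_rates",
    "ENERGY_WARN_LIMIT",
]

#: |ddE| above which exponential rate factors become numerically risky.
ENERGY_WARN_LIMIT = 50.0


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")


def _warn_large_energy(name: str, value: float) -> None:
    if abs(value) > ENERGY_WARN_LIMIT:
        warnings.warn(
            f"|{name}| = {abs(value):g} exceeds {ENERGY_WARN_LIMIT:g} k_B*T; "
            "exponential rate factors may overflow downstream",
            RuntimeWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten constants of the deaminase acting on ssDNA.

    Parameters
    ----------
    Kd_uM : float
        Dissociation constant of the enzyme-substrate complex (µM).
    KM_uM : float
        Michaelis constant (µM).  Must exceed ``Kd_uM`` for the inferred
        substrate-engagement rate to be positive.
    kcat_per_s : float
        Catalytic (deamination) rate constant (1/s).
    """

    Kd_uM: float
    KM_uM: float
    kcat_per_s: float

    def __post_init__(self) -> None:
        _require_positive("Kd_uM", self.Kd_uM)
        _require_positive("KM_uM", self.KM_uM)
        _require_positive("kcat_per_s", self.kcat_per_s)
        if self.KM_uM <= self.Kd_uM:
            raise DomainError(
                f"KM must exceed Kd (KM={self.KM_uM} <= Kd={self.Kd_uM}); "
                "otherwise the inferred on-rate kcat/(KM - Kd) is not positive"
            )


@dataclass(frozen=True)
class SiteKinetics:
    """Catalytic-site kinetics derived from :class:`EnzymeKinetics`.

    ``gamma2 = w1_wt / u3`` is the odds of the cytidine leaving the
    catalytic site before being deaminated.
    """

    kon: float  # 1/(µM*s)
    w1_wt: float  # 1/s
    u3: float  # 1/s
    gamma2: float

    def __post_init__(self) -> None:
        for name in ("kon", "w1_wt", "u3", "gamma2"):
            _require_positive(name, getattr(self, name))
        if not math.isclose(self.gamma2, self.w1_wt / self.u3, rel_tol=1e-12):
            raise ValidationError(
                f"gamma2={self.gamma2} must equal w1_wt/u3={self.w1_wt / self.u3}"
            )


def infer_site_kinetics(ek: EnzymeKinetics) -> SiteKinetics:
    """Infer catalytic-site rates from Michaelis-Menten constants.

    Uses ``kon = kcat / (KM - Kd)``, ``w1_wt = Kd * kon`` and
    ``u3 = kcat``, i.e. the standard identification KM = (w1 + kcat)/kon,
    Kd = w1/kon.

    Examples
    --------
    >>> sk = infer_site_kinetics(EnzymeKinetics(57.0, 62.0, 1.1))
    >>> round(sk.w1_wt, 2), round(sk.gamma2, 1)
    (12.54, 11.4)
    """
    kon = ek.kcat_per_s / (ek.KM_uM - ek.Kd_uM)
    w1_wt = ek.Kd_uM * kon
    u3 = ek.kcat_per_s
    return SiteKinetics(kon=kon, w1_wt=w1_wt, u3=u3, gamma2=w1_wt / u3)


@dataclass(frozen=True)
class ReducedParams:
    """The six dimensionless parameters determining editing outcomes.

    ``gamma1 = u4/u0`` (unproductive vs productive initiation),
    ``gamma2 = w1_wt/u3`` (site unbinding vs chemistry),
    ``gamma3 = w0/u1`` (Cas9 dissociation vs site engagement),
    ``m`` in [0, 1] (rebinding attenuation after an edit), and the two
    binding free-energy differences ``ddE0`` and ``ddEm`` in k_B*T.
    """

    gamma1: float
    gamma2: float
    gamma3: float
    m: float = 0.0
    ddE0: float = 0.0
    ddEm: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("gamma1", self.gamma1)
        _require_positive("gamma2", self.gamma2)
        _require_positive("gamma3", self.gamma3)
        if not math.isfinite(self.m) or not 0.0 <= self.m <= 1.0:
            raise ValidationError(f"m must lie in [0, 1], got {self.m!r}")
        for name in ("ddE0", "ddEm"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            _warn_large_energy(name, value)

    def replace(self, **changes: float) -> "ReducedParams":
        """Return a copy with the given fields replaced."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(changes)
        return ReducedParams(**values)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ReducedParams":
        """Build from a config mapping.

        Recognised keys: ``gamma1``, ``gamma2``, ``gamma3``, ``m``,
        ``ddE0_kBT``, ``ddEm_kBT``; ``gamma2`` may instead be derived
        from an ``enzyme_kinetics`` sub-mapping with keys ``Kd_uM``,
        ``KM_uM``, ``kcat_per_s``.
        """
        data = dict(mapping)
        if "gamma2" not in data:
            ek_map = data.get("enzyme_kinetics")
            if ek_map is None:
                raise ValidationError(
                    "config must provide gamma2 or an enzyme_kinetics block"
                )
            ek = EnzymeKinetics(
                Kd_uM=float(ek_map["Kd_uM"]),
                KM_uM=float(ek_map["KM_uM"]),
                kcat_per_s=float(ek_map["kcat_per_s"]),
            )
            data["gamma2"] = infer_site_kinetics(ek).gamma2
        try:
            return cls(
                gamma1=float(data["gamma1"]),
                gamma2=float(data["gamma2"]),
                gamma3=float(data["gamma3"]),
                m=float(data.get("m", 0.0)),
                ddE0=float(data.get("ddE0_kBT", 0.0)),
                ddEm=float(data.get("ddEm_kBT", 0.0)),
            )
        except KeyError as exc:  # pragma: no cover - message plumbing
            raise ValidationError(f"missing config key: {exc.args[0]}") from exc

    def to_mapping(self) -> dict[str, float]:
        return {
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "gamma3": self.gamma3,
            "m": self.m,
            "ddE0_kBT": self.ddE0,
            "ddEm_kBT": self.ddEm,
        }


@dataclass(frozen=True)
class RateSet:
    """Explicit transition rates of the editing network.

    All rates share one arbitrary time unit; only ratios affect outcome
    probabilities.  ``u2 == u1`` and ``w2 == w1*exp(ddE0)`` hold by
    construction when built via :func:`rates_from_reduced`.
    """

    u0: float  # Cas9 -> ssDNA binding
    u1: float  # target-cytidine engagement
    u2: float  # bystander engagement
    u3: float  # deamination (chemistry)
    u4: float  # commitment to the unproductive/repaired state
    w0: float  # Cas9 dissociation
    w1: float  # target unbinding from the catalytic site
    w2: float  # bystander unbinding
    m: float = 0.0  # rebinding attenuation

    def __post_init__(self) -> None:
        for name in ("u0", "u1", "u3"):
            _require_positive(name, getattr(self, name))
        for name in ("u2", "u4", "w0", "w1", "w2"):
            _require_nonnegative(name, getattr(self, name))
        if not math.isfinite(self.m) or not 0.0 <= self.m <= 1.0:
            raise ValidationError(f"m must lie in [0, 1], got {self.m!r}")


def rates_from_reduced(
    p: ReducedParams,
    scales: Sequence[float] = (1.0, 1.0, 1.0),
) -> RateSet:
    """Materialize a :class:`RateSet` from reduced parameters.

    ``scales = (u0, u1, u3)`` are the three free time scales; outcome
    probabilities are invariant to them.  The mutant unbinding rate is
    ``w1 = gamma2 * u3 * exp(ddEm)`` and the bystander rate is
    ``w2 = w1 * exp(ddE0)``.
    """
    if len(scales) != 3:
        raise ValidationError("scales must be a (u0, u1, u3) triple")
    scale_a, scale_b, scale_c = (float(s) for s in scales)
    for name, value in zip(("scale u0", "scale u1", "scale u3"), (scale_a, scale_b, scale_c)):
        _require_positive(name, value)
    w1 = p.gamma2 * scale_c * math.exp(p.ddEm)
    return RateSet(
        u0=scale_a,
        u1=scale_b,
        u2=scale_b,
        u3=scale_c,
        u4=p.gamma1 * scale_a,
        w0=p.gamma3 * scale_b,
        w1=w1,
        w2=w1 * math.exp(p.ddE0),
        m=p.m,
    )


def reduced_from_rates(
    r: RateSet,
    w1_wt: float | None = None,
    rtol: float = 1e-9,
) -> ReducedParams:
    """Invert :func:`rates_from_reduced`.

    By default the rate set is treated as wild type (``ddEm = 0``,
    ``gamma2 = w1/u3``); pass ``w1_wt`` to report ``gamma2`` relative to
    a wild-type unbinding rate, with ``ddEm = ln(w1/w1_wt)``.
    """
    if r.w1 <= 0 or r.w2 <= 0:
        raise ValidationError("w1 and w2 must be > 0 to recover energies")
    if not math.isclose(r.u1, r.u2, rel_tol=rtol):
        raise ConsistencyError(
            f"u1={r.u1} and u2={r.u2} differ beyond rtol={rtol}; the model "
            "assumes equal target/bystander engagement rates"
        )
    if w1_wt is None:
        gamma2 = r.w1 / r.u3
        ddEm = 0.0
    else:
        _require_positive("w1_wt", w1_wt)
        gamma2 = w1_wt / r.u3
        ddEm = math.log(r.w1 / w1_wt)
    return ReducedParams(
        gamma1=r.u4 / r.u0,
        gamma2=gamma2,
        gamma3=r.w0 / r.u1,
        m=r.m,
        ddE0=math.log(r.w2 / r.w1),
        ddEm=ddEm,
    )
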