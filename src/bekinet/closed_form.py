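"""Analytical first-passage outcome probabilities.

Starting from the unedited, unbound state the editing network absorbs
into one of four outcomes: CTC (no edit), CTT (target only), TTC
(bystander only), TTT (both).  This module evaluates the outcome
probabilities in closed form, both from an explicit :class:`RateSet`
and directly from :class:`ReducedParams`, together with the two
diagnostic ratios ``r1`` (target-first vs bystander-first edit) and
``r2`` (stop-at-CTT vs continue-to-TTT after the target edit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import RangeError, SingularModelError
from .params import RateSet, ReducedParams, rates_from_reduced

__all__ = [
    "OutcomeProbs",
    "SelectivityRatios",
    "outcomes_from_rates",
    "pt_pb_reduced",
    "pt_over_pb_reduced",
    "ratio_r1",
    "ratio_r2",
    "selectivity_ratios",
    "ENERGY_HARD_LIMIT",
]

#: Hard bound on |ddE0|, |ddEm| and |ddE0 + ddEm| in the reduced closed
#: forms; beyond this, exp() products can overflow double precision.
ENERGY_HARD_LIMIT = 300.0


@dataclass(frozen=True)
class OutcomeProbs:
    """Absorption probabilities of the four editing outcomes.

    ``p5``/``p6`` are the probabilities of ever reaching the
    target-edited / bystander-edited intermediate states; they satisfy
    ``p5 + p6 == 1 - p_ctc``.
    """

    p_ctc: float
    p_ctt: float
    p_ttc: float
    p_ttt: float
    p_t: float
    p_b: float
    p5: float
    p6: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class SelectivityRatios:
    r1: float
    r2: float


def _check_finite_positive_denominator(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise SingularModelError(
            f"denominator {name} = {value!r}; the rate set is degenerate "
            "(some absorbing outcome is unreachable or an intermediate "
            "state has no exit)"
        )


def outcomes_from_rates(r: RateSet) -> OutcomeProbs:
    """Outcome probabilities for an explicit rate set.

    The closed forms follow from first-step analysis of the editing
    network: ``p5``/``p6`` solve the pre-edit subnetwork, and the
    post-edit subnetworks give the probability of committing to a
    single-edit outcome rather than editing the second base.  The
    formulas are generic in ``u1 != u2``; under the model assumption
    ``u2 == u1`` they reduce to the standard expressions.
    """
    u0, u1, u2, u3, u4 = r.u0, r.u1, r.u2, r.u3, r.u4
    w0, w1, w2, m = r.w0, r.w1, r.w2, r.m

    # Probability of ever reaching the target-edited (5) or
    # bystander-edited (6) intermediate, from first-step analysis of
    # states {0, 2, 3, 4}.  The denominator is evaluated in an expanded
    # form whose terms are all positive (no cancellation); it equals the
    # raw first-step expression algebraically.
    denom = (u0 + u4) * (
        u1 * u3 * (u3 + w2) + u2 * u3 * (u3 + w1)
    ) + u4 * w0 * (u3 + w1) * (u3 + w2)
    _check_finite_positive_denominator("D(p5,p6)", denom)
    p5 = u0 * u1 * u3 * (u3 + w2) / denom
    p6 = u0 * u2 * u3 * (u3 + w1) / denom

    # After the target edit (state 5): commit to CTT vs go on to TTT.
    # Both the commit probability q5 and its complement are evaluated
    # from positive-term expansions (q5 + q5c == 1 algebraically), so
    # neither loses precision when the other approaches 1.
    d5 = u4 * (u2 * u3 + w0 * u3 + w0 * w2) + m * u0 * u2 * u3
    _check_finite_positive_denominator("D(CTT)", d5)
    q5 = min(u4 * w0 * (u3 + w2) / d5, 1.0)
    q5c = u2 * u3 * (u4 + m * u0) / d5

    # After the bystander edit (state 6): commit to TTC vs TTT.
    d6 = u4 * (u1 * u3 + w0 * u3 + w0 * w1) + m * u0 * u1 * u3
    _check_finite_positive_denominator("D(TTC)", d6)
    q6 = min(u4 * w0 * (u3 + w1) / d6, 1.0)
    q6c = u1 * u3 * (u4 + m * u0) / d6

    p_ctt = p5 * q5
    p_ttc = p6 * q6
    p_ttt = p5 * q5c + p6 * q6c
    p_ctc = 1.0 - p_ctt - p_ttc - p_ttt

    probs = OutcomeProbs(
        p_ctc=p_ctc,
        p_ctt=p_ctt,
        p_ttc=p_ttc,
        p_ttt=p_ttt,
        p_t=p_ctt + p_ttt,
        p_b=p_ttc + p_ttt,
        p5=p5,
        p6=p6,
    )
    for name, value in probs.as_dict().items():
        if not math.isfinite(value) or value < -1e-12 or value > 1 + 1e-12:
            raise SingularModelError(
                f"{name} = {value!r} is not a probability; degenerate rates"
            )
    return probs


def _check_energy_range(p: ReducedParams) -> None:
    for name, value in (
        ("ddE0", p.ddE0),
        ("ddEm", p.ddEm),
        ("ddE0+ddEm", p.ddE0 + p.ddEm),
    ):
        if abs(value) > ENERGY_HARD_LIMIT:
            raise RangeError(
                f"|{name}| = {abs(value):g} exceeds the supported range "
                f"({ENERGY_HARD_LIMIT:g} k_B*T)"
            )


def pt_pb_reduced(p: ReducedParams) -> tuple[float, float]:
    """Overall target and bystander editing probabilities (P_t, P_b).

    Evaluates the reduced closed forms with the shared factor
    ``(1+E)(1+F)`` divided out of numerator and denominator, where
    ``E = gamma2*exp(ddEm)`` and ``F = gamma2*exp(ddE0+ddEm)``; this
    keeps the evaluation stable across the supported energy range.
    """
    _check_energy_range(p)
    g1, g2, g3, m = p.gamma1, p.gamma2, p.gamma3, p.m
    e_mid = g2 * math.exp(p.ddEm)  # E
    e_hi = g2 * math.exp(p.ddE0 + p.ddEm)  # F
    b = g1 + m + g1 * g3

    a_t = b + g1 * g3 * e_mid  # leading factor of the P_t denominator
    a_b = b + g1 * g3 * e_hi  # leading factor of the P_b denominator

    # The shared denominator bracket expands to a sum of positive terms,
    #   (2+2*g1+g1*g3) + (1+g1+g1*g3)*(E+F) + g1*g3*E*F,
    # which avoids the catastrophic cancellation of the raw form; it is
    # evaluated here divided by (1+E)(1+F) via the bounded fractions
    # E/(1+E) and F/(1+F).
    f_mid = e_mid / (1.0 + e_mid)
    f_hi = e_hi / (1.0 + e_hi)
    g_mid = 1.0 / (1.0 + e_mid)
    g_hi = 1.0 / (1.0 + e_hi)
    c2 = 2.0 + 2.0 * g1 + g1 * g3
    bracket = (
        c2 * g_mid * g_hi
        + (1.0 + g1 + g1 * g3) * (f_mid * g_hi + f_hi * g_mid)
        + g1 * g3 * f_mid * f_hi
    )

    num_t = b * g_mid + g1 * g3 * f_mid + (g1 + m) * g_hi
    num_b = b * g_hi + g1 * g3 * f_hi + (g1 + m) * g_mid

    den_t = a_t * bracket
    den_b = a_b * bracket
    if not (math.isfinite(den_t) and den_t > 0 and math.isfinite(den_b) and den_b > 0):
        raise SingularModelError(
            "reduced-form denominator is non-positive or non-finite; "
            f"params={p!r}"
        )
    return num_t / den_t, num_b / den_b


def pt_over_pb_reduced(p: ReducedParams) -> float:
    """The ratio P_t/P_b in its fully cancelled closed form.

    The numerators of the two reduced forms are algebraically equal, so
    the ratio collapses to the ratio of the leading denominator
    factors.
    """
    _check_energy_range(p)
    g1, g3, m = p.gamma1, p.gamma3, p.m
    b = g1 + m + g1 * g3
    e_mid = p.gamma2 * math.exp(p.ddEm)
    e_hi = p.gamma2 * math.exp(p.ddE0 + p.ddEm)
    return (b + g1 * g3 * e_hi) / (b + g1 * g3 * e_mid)


def ratio_r1(p: ReducedParams) -> float:
    """Odds of editing the target before the bystander.

    ``r1 = (1 + gamma2*exp(ddE0+ddEm)) / (1 + gamma2*exp(ddEm))``;
    for large ``gamma2*exp(ddEm)`` this tends to ``exp(ddE0)``.
    """
    _check_energy_range(p)
    e_mid = p.gamma2 * math.exp(p.ddEm)
    e_hi = p.gamma2 * math.exp(p.ddE0 + p.ddEm)
    return (1.0 + e_hi) / (1.0 + e_mid)


def ratio_r2(p: ReducedParams) -> float:
    """Odds of stopping at CTT vs continuing to TTT after the target edit.

    ``r2 = gamma3 * (1 + gamma2*exp(ddE0+ddEm))``.
    """
    _check_energy_range(p)
    return p.gamma3 * (1.0 + p.gamma2 * math.exp(p.ddE0 + p.ddEm))


def selectivity_ratios(p: ReducedParams) -> SelectivityRatios:
    return SelectivityRatios(r1=ratio_r1(p), r2=ratio_r2(p))
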