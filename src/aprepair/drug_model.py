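"""Hill-type drug effects on ion currents and multiplicative combination.

A drug ``k`` acting on current ``i`` is characterised by the triple
(EC50, H, E): the half-maximal concentration, the Hill coefficient and the
maximum relative effect.  At dose ``D`` (uM) the current is scaled by

    1 + eta(D),   eta(D) = (D/EC50)^H / ((D/EC50)^H + 1) * E,

so ``E = -1`` is a complete blocker (the familiar IC50 form) and ``E > 0``
an agonist/opener.  Several drugs act multiplicatively: the per-current
scale factor of a dose vector is the product of the individual
``1 + eta_k`` terms.  Multiplicativity corresponds to strictly independent
(non-competitive, non-allosteric) binding of the compounds.

Because the factor multiplies the per-channel flux only, it is the same
number for every cell type (hiPSC-CM, rabbit, adult human): channel-density
scaling and drug action commute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "HillDrugEffect",
    "DrugProfile",
    "DoseVector",
    "eta",
    "saturation_fraction",
    "combined_factor",
    "percent_change_table",
    "most_affected_current",
    "saturating_dose",
    "round_half_away",
]

#: A dose vector is simply a mapping ``drug name -> concentration (uM)``.
DoseVector = Mapping[str, float]


@dataclass(frozen=True)
class HillDrugEffect:
    """Dose-response parameters of one drug on one current.

    Parameters
    ----------
    ec50 : float
        Half-maximal concentration in uM (``1/eps``); must be positive.
    hill : float
        Hill coefficient; must be positive (non-integer values allowed).
    emax : float
        Maximum relative effect ``E``.  Bounded below by -1 (a current
        cannot be reduced by more than 100%); there is no upper bound.
        ``emax = 0`` would be a no-op and is rejected.
    source : str, optional
        Free-text provenance of the parameter values.
    """

    ec50: float
    hill: float
    emax: float
    source: str | None = None

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and math.isfinite(self.ec50)):
            raise ValueError(f"ec50 must be a positive finite number, got {self.ec50}")
        if not (self.hill > 0 and math.isfinite(self.hill)):
            raise ValueError(f"hill must be a positive finite number, got {self.hill}")
        if not math.isfinite(self.emax) or self.emax < -1 or self.emax == 0:
            raise ValueError(
                f"emax must be finite, >= -1 and nonzero, got {self.emax}"
            )


@dataclass(frozen=True)
class DrugProfile:
    """All characterised effects of a single drug.

    ``effects`` maps a current id (e.g. ``"I_Kr"``) to a
    :class:`HillDrugEffect`; currents without an entry are unaffected
    (factor 1).
    """

    name: str
    effects: Mapping[str, HillDrugEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.effects:
            raise ValueError(f"drug {self.name!r} has no effect entries")
        object.__setattr__(self, "effects", dict(self.effects))


def _pow_hill(x: float, hill: float) -> float:
    """(x)^hill with the x == 0 branch returned exactly, for non-integer hill."""
    if x == 0.0:
        return 0.0
    return math.exp(hill * math.log(x))


def saturation_fraction(effect: HillDrugEffect, dose: float) -> float:
    """Fraction of the maximum effect reached at ``dose``: eta(D)/E in [0, 1).

    This is the "(max % of E)" quantity reported alongside optimal doses.
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose}")
    s = _pow_hill(dose / effect.ec50, effect.hill)
    return s / (s + 1.0)


def eta(effect: HillDrugEffect, dose: float) -> float:
    """Relative change of the current at ``dose`` (uM): (I(D) - I(0)) / I(0).

    Monotone in dose, 0 at dose 0 and saturating at ``emax``; equals
    ``emax / 2`` at the EC50.
    """
    return saturation_fraction(effect, dose) * effect.emax


def combined_factor(
    profiles: Mapping[str, DrugProfile] | Iterable[DrugProfile],
    doses: DoseVector,
    current_id: str,
) -> float:
    """Multiplicative scale factor of ``current_id`` under a dose vector.

    Product over dosed drugs of ``1 + eta``; drugs without an effect entry
    for this current contribute a factor of 1.  The result is positive and
    independent of drug ordering.
    """
    by_name = _as_mapping(profiles)
    factor = 1.0
    # canonical (sorted) order makes the product bitwise permutation-invariant
    for name, dose in sorted(doses.items()):
        if name not in by_name:
            raise KeyError(f"dose given for unknown drug {name!r}")
        if dose < 0:
            raise ValueError(f"negative dose {dose} for drug {name!r}")
        effect = by_name[name].effects.get(current_id)
        if effect is not None:
            factor *= 1.0 + eta(effect, dose)
    return factor


def percent_change_table(
    profiles: Mapping[str, DrugProfile] | Iterable[DrugProfile],
    doses: DoseVector,
    currents: Iterable[str],
) -> pd.Series:
    """Percent change ``100 * (F - 1)`` of each current under a dose vector.

    Values are exact; round only when presenting (the conventional report
    shows one decimal).
    """
    currents = list(currents)
    return pd.Series(
        [100.0 * (combined_factor(profiles, doses, c) - 1.0) for c in currents],
        index=currents,
        name="percent_change",
    )


def most_affected_current(profile: DrugProfile, dose: float) -> tuple[str, float]:
    """Current with the largest absolute relative change at ``dose``.

    Returns ``(current_id, saturation_fraction)`` — the saturation fraction
    of that current, i.e. how close the drug is to its maximum effect on it.
    At dose 0 the current with the largest ``|E|`` (ties: smallest EC50)
    is reported with fraction 0.
    """
    if dose == 0.0:
        cid, eff = min(
            profile.effects.items(), key=lambda kv: (-abs(kv[1].emax), kv[1].ec50)
        )
        return cid, 0.0
    cid, eff = max(
        profile.effects.items(), key=lambda kv: abs(eta(kv[1], dose))
    )
    return cid, saturation_fraction(eff, dose)


def saturating_dose(effect: HillDrugEffect, fraction: float = 0.95) -> float:
    """Dose at which the effect reaches ``fraction`` of its maximum.

    Inverts the Hill curve: ``D = EC50 * (fraction / (1 - fraction))^(1/H)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return effect.ec50 * (fraction / (1.0 - fraction)) ** (1.0 / effect.hill)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (presentation convention for
    percent tables; Python's builtin ``round`` uses banker's rounding)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_mapping(
    profiles: Mapping[str, DrugProfile] | Iterable[DrugProfile],
) -> Mapping[str, DrugProfile]:
    if isinstance(profiles, Mapping):
        return profiles
    return {p.name: p for p in profiles}
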