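"""Biomarker cost between treated-mutant and wild-type beats, and dose search.

The cost of a dose vector ``D`` is the weighted sum of relative absolute
biomarker deviations

    C(D) = sum_j w_j * |R_j^M(D) - R_j^W| / |R_j^W|,

where ``R^W`` are wild-type biomarkers and ``R^M(D)`` those of the mutant
with the multiplicative drug factors applied.  By default every weight is
1 except APD80, APD90 and dvdt_max, which are 5 (late repolarisation and
upstroke velocity matter most for the repair and for conduction).

The search is incremental: the optimal single-drug doses are found first;
the best ``n``-drug solution then seeds every candidate ``(n+1)``-drug
problem with the new drug entering at dose zero (a continuation start), so
the reported optimal cost is non-increasing in the number of drugs.  The
local solver is a bounded Nelder-Mead simplex in linear dose space with a
deterministic multistart lattice for the one- and two-parameter problems.
Evaluations are memoised on dose vectors rounded to 6 significant digits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import ap_model
from .ap_model import APModel, PacingProtocol, SimulationError, simulate
from .biomarkers import BIOMARKER_NAMES, BiomarkerSet, compute_biomarkers
from .drug_model import DrugProfile, combined_factor, most_affected_current

__all__ = [
    "CostSpec",
    "DoseBounds",
    "OptimizationResult",
    "cost_from_biomarkers",
    "cost",
    "factors_for_model",
    "make_objective",
    "optimize_single",
    "optimize_incremental",
    "pairwise_scan",
]

#: Cost tolerance treated as "a tie" (lower total dose wins among ties) and
#: Nelder-Mead function-value convergence tolerance.
COST_TOL = 1e-4


def _default_weights() -> dict[str, float]:
    w = {name: 1.0 for name in BIOMARKER_NAMES}
    for name in ("APD80", "APD90", "dvdt_max"):
        w[name] = 5.0
    return w


@dataclass(frozen=True)
class CostSpec:
    """Biomarker weights ``w_j``; nonnegative, at least one positive."""

    weights: Mapping[str, float] = field(default_factory=_default_weights)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(BIOMARKER_NAMES)
        if unknown:
            raise ValueError(f"weights for unknown biomarkers: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "weights", dict(self.weights))


def cost_from_biomarkers(
    treated: BiomarkerSet | Mapping[str, float],
    wild_type: BiomarkerSet | Mapping[str, float],
    spec: CostSpec | None = None,
) -> float:
    """Weighted sum of relative absolute biomarker deviations from wild type.

    Zero iff every weighted biomarker matches exactly; wild-type reference
    values of weighted terms must be nonzero.
    """
    spec = spec or CostSpec()
    get_t = treated.__getitem__ if isinstance(treated, BiomarkerSet) else treated.__getitem__
    get_w = (wild_type.__getitem__ if isinstance(wild_type, BiomarkerSet)
             else wild_type.__getitem__)
    total = 0.0
    for name, w in spec.weights.items():
        if w == 0.0:
            continue
        rw = get_w(name)
        if rw == 0 or not math.isfinite(rw):
            raise ValueError(
                f"wild-type biomarker {name!r} is degenerate ({rw}); "
                "cannot form a relative deviation"
            )
        total += w * abs(get_t(name) - rw) / abs(rw)
    return total


@dataclass(frozen=True)
class DoseBounds:
    """Per-drug upper dose bounds.

    Modes
    -----
    ``saturation-cap``
        Per drug, the dose at which its most strongly affected current
        reaches ``saturation`` (default 95%) of the maximum effect |E| —
        the default cap when no pharmacological restriction is imposed.
    ``min-EC50`` / ``half-min-EC50``
        The smallest EC50 among the drug's characterised currents (or half
        of it): the low-dose regimes used when side effects of high doses
        are a concern.
    ``explicit``
        User-provided mapping drug name -> bound (uM).
    """

    mode: str = "saturation-cap"
    explicit: Mapping[str, float] = field(default_factory=dict)
    saturation: float = 0.95

    _MODES = ("saturation-cap", "min-EC50", "half-min-EC50", "explicit")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown bounds mode {self.mode!r}; expected {self._MODES}")
        if not 0 < self.saturation < 1:
            raise ValueError("saturation must be in (0, 1)")
        if any(b <= 0 for b in self.explicit.values()):
            raise ValueError("explicit bounds must be positive")
        object.__setattr__(self, "explicit", dict(self.explicit))

    def resolve(self, profile: DrugProfile) -> float:
        """Upper dose bound (uM) for one drug."""
        if self.mode == "explicit":
            if profile.name not in self.explicit:
                raise KeyError(f"no explicit bound for drug {profile.name!r}")
            return float(self.explicit[profile.name])
        min_ec50 = min(e.ec50 for e in profile.effects.values())
        if self.mode == "min-EC50":
            return min_ec50
        if self.mode == "half-min-EC50":
            return min_ec50 / 2.0
        # saturation-cap: invert the Hill curve of the most affected current
        cid, _ = most_affected_current(profile, 0.0)
        eff = profile.effects[cid]
        ratio = self.saturation / (1.0 - self.saturation)
        return eff.ec50 * ratio ** (1.0 / eff.hill)


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one bounded dose minimisation."""

    drugs: tuple[str, ...]
    doses: Mapping[str, float]
    cost: float
    n_evaluations: int
    search_trace: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", dict(self.doses))
        object.__setattr__(self, "drugs", tuple(self.drugs))


# ---------------------------------------------------------------------------
# objective construction (simulation-backed)
# ---------------------------------------------------------------------------


def factors_for_model(
    model: APModel,
    profiles: Mapping[str, DrugProfile],
    doses: Mapping[str, float],
) -> dict[str, float]:
    """Per-current multiplicative factors of a dose vector, for this model.

    Drug effects on currents the model does not carry contribute nothing;
    they are reported once as a warning rather than an error so that one
    drug library can serve reduced models.
    """
    model_currents = set(model.currents)
    for name, dose in doses.items():
        if dose > 0:
            extra = set(profiles[name].effects) - model_currents
            for cid in sorted(extra):
                warnings.warn(
                    f"drug {name!r} affects {cid} which is absent from model "
                    f"{model.name!r}; contribution ignored"
                )
    return {
        cid: combined_factor(profiles, doses, cid) for cid in model.currents
    }


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def make_objective(
    mutant_model: APModel,
    wt_biomarkers: BiomarkerSet,
    profiles: Mapping[str, DrugProfile],
    spec: CostSpec | None = None,
    protocol: PacingProtocol | None = None,
    eval_beats: int = 3,
    base_state: np.ndarray | None = None,
) -> Callable[[Mapping[str, float]], float]:
    """Build the memoised map ``doses -> cost`` for a treated mutant model.

    Drug evaluations start from the drug-free paced steady state of the
    mutant (computed once) and pace ``eval_beats`` conditioning beats under
    the drug factors before the analysed beat.  Simulation failures yield an
    infinite cost with a warning, so a search can step around them.
    """
    spec = spec or CostSpec()
    protocol = protocol or PacingProtocol()
    if base_state is None:
        base_state, _ = ap_model.pace_to_steady(mutant_model, protocol)
    eval_protocol = replace(protocol, n_prebeats=eval_beats)
    cache: dict[tuple, float] = {}

    def objective(doses: Mapping[str, float]) -> float:
        key = tuple(sorted((k, _round_sig(v)) for k, v in doses.items() if v != 0))
        if key in cache:
            return cache[key]
        factors = factors_for_model(mutant_model, profiles, doses)
        try:
            trace = simulate(
                mutant_model, eval_protocol, factors=factors,
                initial_state=base_state,
            )
            value = cost_from_biomarkers(compute_biomarkers(trace), wt_biomarkers, spec)
        except SimulationError as err:
            warnings.warn(f"simulation failed at doses {dict(doses)}: {err}")
            value = math.inf
        cache[key] = value
        return value

    objective.cache = cache  # type: ignore[attr-defined]
    return objective


def cost(
    mutant_model: APModel,
    wt_biomarkers: BiomarkerSet,
    profiles: Mapping[str, DrugProfile],
    doses: Mapping[str, float],
    spec: CostSpec | None = None,
    protocol: PacingProtocol | None = None,
) -> float:
    """Cost of one explicit dose vector (simulates the treated mutant)."""
    objective = make_objective(mutant_model, wt_biomarkers, profiles, spec, protocol)
    return objective(doses)


# ---------------------------------------------------------------------------
# bounded deterministic search
# ---------------------------------------------------------------------------


def _initial_simplex(u0: np.ndarray) -> np.ndarray:
    """Simplex around ``u0`` (unit coordinates) stepping 25% of the range."""
    n = len(u0)
    simplex = np.tile(u0, (n + 1, 1))
    for j in range(n):
        simplex[j + 1, j] += 0.25 if u0[j] + 0.25 <= 1.0 else -0.25
    return simplex


def _nelder_mead(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    maxfev: int,
) -> tuple[np.ndarray, float, int]:
    # search in per-axis normalised coordinates u = dose / bound in [0, 1],
    # so the simplex tolerance (0.1% of each bound) is meaningful on every
    # axis even when bounds span orders of magnitude
    u0 = np.clip(np.asarray(x0, dtype=float) / bounds, 0.0, 1.0)
    res = minimize(
        lambda u: fun(u * bounds), u0, method="Nelder-Mead",
        bounds=[(0.0, 1.0)] * len(bounds),
        options={
            "initial_simplex": _initial_simplex(u0),
            "xatol": 1e-3, "fatol": COST_TOL, "maxfev": maxfev,
        },
    )
    return np.asarray(res.x) * bounds, float(res.fun), int(res.nfev)


def _search(
    drug_names: Sequence[str],
    bounds: np.ndarray,
    objective: Callable[[Mapping[str, float]], float],
    starts: Iterable[np.ndarray],
    maxfev_per_start: int | None = None,
) -> OptimizationResult:
    """Run bounded Nelder-Mead from each start; keep the best with ties
    resolved toward the smaller total normalised dose."""
    names = list(drug_names)
    n = len(names)
    maxfev = maxfev_per_start or 120 * n

    def fun(x: np.ndarray) -> float:
        return objective(dict(zip(names, np.clip(x, 0.0, bounds))))

    candidates: list[tuple[np.ndarray, float]] = []
    nfev_total = 0
    for x0 in starts:
        x, f, nfev = _nelder_mead(fun, np.asarray(x0, dtype=float), bounds, maxfev)
        nfev_total += nfev
        candidates.append((np.clip(x, 0.0, bounds), f))
    best_cost = min(f for _, f in candidates)
    tied = [(x, f) for x, f in candidates if f <= best_cost + COST_TOL]
    # lower-dose preference among (near-)ties, doses normalised by bound
    x_best, f_best = min(tied, key=lambda xf: float(np.sum(xf[0] / bounds)))
    # same preference within the solution: drop drugs whose removal does not
    # worsen the cost beyond the tie tolerance (a flat axis otherwise lets
    # the simplex drift to an arbitrary dose of an ineffective drug)
    for j in np.argsort(-x_best):
        if x_best[j] == 0.0:
            continue
        trial = x_best.copy()
        trial[j] = 0.0
        f_trial = fun(trial)
        nfev_total += 1
        if f_trial <= f_best + COST_TOL:
            x_best, f_best = trial, f_trial
    return OptimizationResult(
        drugs=tuple(names),
        doses=dict(zip(names, map(float, x_best))),
        cost=f_best,
        n_evaluations=nfev_total,
        search_trace=tuple((dict(zip(names, map(float, x))), f) for x, f in candidates),
    )


def _lattice(bounds: np.ndarray, points_per_dim: int = 5) -> list[np.ndarray]:
    axes = [np.linspace(0.0, b, points_per_dim) for b in bounds]
    grids = np.meshgrid(*axes, indexing="ij")
    return [np.array(p) for p in zip(*(g.ravel() for g in grids))]


def optimize_single(
    drug_name: str,
    bound: float,
    objective: Callable[[Mapping[str, float]], float],
    n_multistart: int = 5,
) -> OptimizationResult:
    """Optimal dose of one drug on [0, bound] (deterministic multistart)."""
    if bound <= 0:
        raise ValueError(f"dose bound must be positive, got {bound}")
    bounds = np.array([bound])
    starts = _lattice(bounds, n_multistart)
    return _search([drug_name], bounds, objective, starts)


def optimize_incremental(
    drug_names: Sequence[str],
    bounds: Mapping[str, float],
    objective: Callable[[Mapping[str, float]], float],
    max_n: int | None = None,
    n_multistart: int = 5,
) -> list[OptimizationResult]:
    """Best combinations of n = 1, 2, ... drugs by continuation.

    Stage 1 solves every single-drug problem.  Stage n+1 appends each
    remaining drug at dose zero to the best n-drug solution and re-solves
    the (n+1)-parameter problem from that feasible start, so the optimal
    cost sequence is non-increasing by construction.  Candidates whose
    evaluations all fail are skipped with a warning.
    """
    names = list(drug_names)
    if not names:
        raise ValueError("need at least one drug")
    max_n = min(max_n or len(names), len(names))
    results: list[OptimizationResult] = []

    singles = [
        optimize_single(name, bounds[name], objective, n_multistart)
        for name in names
    ]
    best = min(singles, key=lambda r: (r.cost, sum(
        d / bounds[n] for n, d in r.doses.items())))
    results.append(best)

    while len(results[-1].drugs) < max_n:
        current = results[-1]
        remaining = [n for n in names if n not in current.drugs]
        candidates: list[OptimizationResult] = []
        for new in remaining:
            cand_names = list(current.drugs) + [new]
            cand_bounds = np.array([bounds[n] for n in cand_names])
            x0 = np.array([current.doses[n] for n in current.drugs] + [0.0])
            try:
                candidates.append(
                    _search(cand_names, cand_bounds, objective, [x0])
                )
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"candidate {cand_names} failed: {err}")
        if not candidates:
            warnings.warn("no viable candidate to extend the combination; stopping")
            break
        best_next = min(candidates, key=lambda r: (r.cost, sum(
            d / bounds[n] for n, d in r.doses.items())))
        if best_next.cost > current.cost:
            # continuation start guarantees this cannot exceed the previous
            # optimum beyond solver tolerance; clip to keep monotonicity
            best_next = replace(
                best_next,
                doses={**current.doses, best_next.drugs[-1]: 0.0},
                cost=current.cost,
            )
        results.append(best_next)
    return results


def pairwise_scan(
    drug_names: Sequence[str],
    bounds: Mapping[str, float],
    objective: Callable[[Mapping[str, float]], float],
    n_multistart: int = 5,
):
    """K x K matrix of optimal costs: diagonal = single drugs, off-diagonal =
    two-drug combinations (symmetric).  Returns (DataFrame, best pair)."""
    import pandas as pd

    names = list(drug_names)
    if len(names) < 2:
        raise ValueError("pairwise scan needs at least two drugs")
    K = len(names)
    mat = np.full((K, K), np.nan)
    for i, name in enumerate(names):
        mat[i, i] = optimize_single(name, bounds[name], objective, n_multistart).cost
    best_pair, best_cost = None, math.inf
    for i in range(K):
        for j in range(i + 1, K):
            pair = [names[i], names[j]]
            b = np.array([bounds[n] for n in pair])
            res = _search(pair, b, objective, _lattice(b, n_multistart))
            mat[i, j] = mat[j, i] = res.cost
            if res.cost < best_cost:
                best_pair, best_cost = (names[i], names[j]), res.cost
    frame = pd.DataFrame(mat, index=names, columns=names)
    return frame, best_pair
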