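"""MAP estimation of the six IM-model parameters from a set of gene trees.

With a uniform prior over a bounded box the maximum a posteriori estimate is
the maximum-likelihood estimate constrained to the box, so estimation is a
bounded maximization of :class:`~imcoal.likelihood.LociLikelihood`.  The
surface has flat and ``-inf`` regions (e.g. migration rates pinned at zero
make some trees impossible), so a derivative-free simplex search is used,
restarted from multiple seeded points: one at the box center and the rest
from a Latin-hypercube over the box.  The search is staged: every start gets
a short screening budget, then the most promising simplices are polished to
full tolerance.  The best finite optimum wins; ties go to the first found.
Boundary optima (e.g. ``m-hat = 0``) are returned as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .likelihood import LociLikelihood
from .params import IMParams, PARAM_NAMES, PriorBox
from .trees import GeneTree

__all__ = ["MapResult", "map_estimate"]


@dataclass(frozen=True)
class MapResult:
    """Outcome of one multi-start MAP fit."""

    estimate: IMParams
    log_posterior: float
    n_starts: int
    converged: bool
    #: per-start (start point, final objective, scipy success flag, n evals)
    diagnostics: tuple[dict, ...] = field(default=(), repr=False)


def map_estimate(
    trees: Union[Sequence[GeneTree], LociLikelihood],
    box: PriorBox = PriorBox(),
    *,
    seed: int = 0,
    n_starts: int = 10,
    fixed: Optional[dict[str, float]] = None,
    fatol: float = 1e-6,
    xatol: float = 1e-5,
    max_fun_evals: Optional[int] = None,
    screen_evals: int = 300,
    n_polish: int = 2,
) -> MapResult:
    """Maximize the summed gene-tree log-density over the prior box.

    Parameters
    ----------
    trees
        Gene trees of independent loci, or a prebuilt
        :class:`~imcoal.likelihood.LociLikelihood`.
    box
        Uniform prior box; the estimate never leaves it.
    seed
        Seeds the Latin-hypercube start points (deterministic fits).
    fixed
        Optional ``{parameter_name: value}`` constraints; fixed coordinates
        are held at the given value and excluded from the search.
    fatol, xatol
        Simplex convergence tolerances on the objective and the coordinates.
    screen_evals, n_polish
        Function-evaluation budget of the screening stage, and how many of
        the best screened starts are polished to full tolerance.
    """
    engine = trees if isinstance(trees, LociLikelihood) else LociLikelihood(trees)
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    free = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    lower = box.lower
    upper = box.upper
    template = np.array(
        [fixed.get(n, 0.0) for n in PARAM_NAMES], dtype=float
    )

    def objective(x: np.ndarray) -> float:
        full = template.copy()
        full[free] = x
        if (full < lower).any() or (full > upper).any():
            return np.inf
        ll = engine.log_likelihood(IMParams.from_array(full))
        return -ll if np.isfinite(ll) else np.inf

    lo = lower[free]
    hi = upper[free]
    starts = [0.5 * (lo + hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        starts.extend(lo + sampler.random(n_starts - 1) * (hi - lo))

    bounds = list(zip(lo, hi))
    budget = max_fun_evals or 400 * len(free)

    def search(x0, maxfev, stage):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"fatol": fatol, "xatol": xatol, "maxfev": maxfev},
        )
        diagnostics.append(
            {
                "stage": stage,
                "start": tuple(np.asarray(x0, dtype=float)),
                "objective": float(res.fun),
                "success": bool(res.success),
                "n_evaluations": int(res.nfev),
            }
        )
        return res

    diagnostics: list[dict] = []
    screened = [
        search(x0, min(screen_evals, budget), "screen") for x0 in starts
    ]
    finite = [r for r in screened if np.isfinite(r.fun)]
    finite.sort(key=lambda r: r.fun)
    best = None
    for res in finite[: max(1, n_polish)]:
        res = search(res.x, budget, "polish")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "no start produced a finite likelihood; diagnostics: "
            f"{diagnostics}"
        )
    full = template.copy()
    full[free] = np.clip(best.x, lo, hi)
    return MapResult(
        estimate=IMParams.from_array(full),
        log_posterior=-float(best.fun),
        n_starts=len(starts),
        converged=bool(best.success),
        diagnostics=tuple(diagnostics),
    )
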