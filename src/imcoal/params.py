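"""Demographic parameters of the two-population isolation-with-migration model.

All quantities are mutation-scaled (see the glossary in the README): population
sizes ``theta_i = 4 N_i u``, split time ``tau = t u`` and migration rates
``m_i = M_i / u``, where ``u`` is the per-locus mutation rate.  No raw
generation-scale quantity is ever needed at run time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

__all__ = ["IMParams", "PriorBox", "PARAM_NAMES"]

#: Canonical parameter order used everywhere a flat vector is exchanged.
PARAM_NAMES = ("theta1", "theta2", "theta3", "m1", "m2", "tau")


@dataclass(frozen=True)
class IMParams:
    """The six parameters of the 2-population IM model.

    theta1, theta2
        Scaled sizes of the two sampled populations (``4 N u``); must be > 0.
    theta3
        Scaled size of the ancestral population; must be > 0.
    m1, m2
        Scaled migration rates.  ``m1`` is the backward-in-time hazard for a
        lineage currently in population 1 to jump to population 2 (forward in
        time: the fraction of population 1 replaced by migrants from
        population 2); ``m2`` the converse.  Must be >= 0.
    tau
        Scaled split time: looking backwards, at ``tau`` both populations
        merge into the ancestral one.  Must be >= 0.
    """

    theta1: float
    theta2: float
    theta3: float
    m1: float = 0.0
    m2: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        for name in ("theta1", "theta2", "theta3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "IMParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})

    def replace(self, **kw) -> "IMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PriorBox:
    """Uniform prior box over the six parameters.

    Under a uniform prior the MAP estimate equals the maximum-likelihood
    estimate constrained to the box, so the box doubles as the optimizer's
    search domain.  Defaults follow the standard setting for mutation-scaled
    IM analyses: upper bounds of 50 for population sizes, 0.2 for migration
    rates and 20 for the split time, all lower bounds at 0.
    """

    theta_max: float = 50.0
    m_max: float = 0.2
    tau_max: float = 20.0
    #: strictly positive floor for the sizes (the density is undefined at 0)
    theta_min: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 <= self.theta_min < self.theta_max):
            raise ValueError("need 0 <= theta_min < theta_max")
        if self.m_max <= 0 or self.tau_max <= 0:
            raise ValueError("upper bounds must be positive")

    @property
    def lower(self):
        import numpy as np

        return np.array(
            [self.theta_min, self.theta_min, self.theta_min, 0.0, 0.0, 0.0]
        )

    @property
    def upper(self):
        import numpy as np

        return np.array(
            [self.theta_max, self.theta_max, self.theta_max,
             self.m_max, self.m_max, self.tau_max]
        )

    def contains(self, params: IMParams) -> bool:
        x = params.as_array()
        return bool(((x >= self.lower) & (x <= self.upper)).all())

    def clip(self, x):
        import numpy as np

        return np.clip(np.asarray(x, dtype=float), self.lower, self.upper)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.lower, self.upper))
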