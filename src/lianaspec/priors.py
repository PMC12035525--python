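"""Prior specifications for spectral inversions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["Normal", "Uniform", "Fixed", "PriorSet"]


@dataclass(frozen=True)
class Normal:
    """Normal prior, optionally truncated to [lo, hi]."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.lo >= self.hi:
            raise ValueError("lo must be < hi")

    def _dist(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def logpdf(self, x: float) -> float:
        return float(self._dist().logpdf(x))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d = self._dist()
        return d.ppf(rng.uniform(size=n))

    @property
    def bounds(self):
        return (self.lo, self.hi)


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError("lo must be < hi")

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -np.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)

    @property
    def bounds(self):
        return (self.lo, self.hi)


@dataclass(frozen=True)
class Fixed:
    value: float


class PriorSet:
    """Ordered mapping parameter name -> prior (Normal, Uniform or Fixed).

    Free parameters are those with a samplable prior; Fixed entries are
    excluded from the sampled dimensions but available to the forward model.
    """

    def __init__(self, priors: dict):
        self._priors = dict(priors)
        self.free_names = [k for k, p in self._priors.items() if not isinstance(p, Fixed)]
        if not self.free_names:
            raise ValueError("at least one parameter must be free")
        self.fixed = {
            k: p.value for k, p in self._priors.items() if isinstance(p, Fixed)
        }

    def __getitem__(self, name):
        return self._priors[name]

    def __contains__(self, name):
        return name in self._priors

    def items(self):
        return self._priors.items()

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def log_prior(self, theta: np.ndarray) -> float:
        lp = 0.0
        for name, v in zip(self.free_names, theta):
            lp += self._priors[name].logpdf(float(v))
            if not np.isfinite(lp):
                return -np.inf
        return lp

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cols = [self._priors[name].sample(rng, n) for name in self.free_names]
        return np.column_stack(cols)

    def to_dict(self, theta: np.ndarray) -> dict:
        d = dict(self.fixed)
        d.update({name: float(v) for name, v in zip(self.free_names, theta)})
        return d

    def bounds(self):
        return [self._priors[name].bounds for name in self.free_names]
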