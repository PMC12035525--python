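"""Differential-evolution MCMC with a history archive and snooker updates.

The sampler follows the DE-MC(zs) scheme: a small number of parallel chains
propose jumps along difference vectors of states drawn from a growing
archive of past states, occasionally replaced by the snooker move, which
rescales proposals along the line towards a random archive state.  Three
chains suffice because proposals are informed by the archive rather than the
current population alone.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PosteriorSamples", "run_demc", "gelman_rubin", "InitializationError"]


class InitializationError(RuntimeError):
    """Raised when no starting point with finite posterior density is found."""


#: Crossover levels for subspace updates (fraction of coordinates moved).
_CR_LEVELS = (1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws.

    chains : array (n_chains, n_draws, n_params)
    log_posterior : array (n_chains, n_draws)
    """

    names: list
    chains: np.ndarray
    log_posterior: np.ndarray
    seed: int
    acceptance_rate: float
    meta: dict

    @property
    def flat(self) -> np.ndarray:
        """All draws pooled across chains, shape (n_chains * n_draws, n_params)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.flat, qs, axis=0)


def run_demc(
    log_posterior,
    sample_initial,
    n_params: int,
    n_iter: int = 4000,
    n_chains: int = 3,
    seed: int = 0,
    names: list | None = None,
    gamma_unit_every: int = 10,
    snooker_prob: float = 0.1,
    archive_thin: int = 10,
    burn_fraction: float = 0.5,
    max_init_tries: int = 200,
    temper_burnin: bool = False,
    crossover: bool = False,
) -> PosteriorSamples:
    """Sample a log-density with DE-MC(zs).

    Parameters
    ----------
    log_posterior : callable(theta) -> float (may return -inf)
    sample_initial : callable(rng, n) -> (n, n_params) array of starting
        points (typically prior draws); also seeds the archive.
    n_iter : generations; the first ``burn_fraction`` are discarded.
    temper_burnin : anneal the target during the first 70% of burn-in
        (density exponent ramped from 0.05 to 1), which lets prior-initialised
        chains cross between well-separated modes before sampling starts; the
        post-burn-in kernel is the exact untempered posterior.
    """
    if n_chains < 3:
        raise ValueError("n_chains must be >= 3")
    rng = np.random.default_rng(seed)
    d = n_params
    gamma = 2.38 / np.sqrt(2.0 * d)
    eps_scale = 1e-6

    # Archive seeded with initial draws (at least 10 d states).
    n0 = max(10 * d, n_chains * 3)
    archive = list(np.asarray(sample_initial(rng, n0), dtype=float))

    # Chain starting points must have finite density.
    x = np.empty((n_chains, d))
    lp = np.full(n_chains, -np.inf)
    for c in range(n_chains):
        for _ in range(max_init_tries):
            cand = np.asarray(sample_initial(rng, 1), dtype=float)[0]
            val = float(log_posterior(cand))
            if np.isfinite(val):
                x[c], lp[c] = cand, val
                break
        else:
            raise InitializationError(
                f"no finite-density start for chain {c} in {max_init_tries} tries"
            )

    keep = n_iter - int(n_iter * burn_fraction)
    n_burn = n_iter - keep
    out = np.empty((n_chains, keep, d))
    out_lp = np.empty((n_chains, keep))
    n_acc = 0
    n_prop = 0
    # jump-length multiplier, adapted towards ~25% acceptance during burn-in
    # only and frozen afterwards (so the post-burn-in kernel is fixed)
    scale = 1.0
    win_acc = win_prop = 0

    for it in range(n_iter):
        if temper_burnin and n_burn > 0 and it < 0.7 * n_burn:
            beta = 0.05 + 0.95 * it / (0.7 * n_burn)
        else:
            beta = 1.0
        g = 1.0 if (it + 1) % gamma_unit_every == 0 else gamma * scale
        for c in range(n_chains):
            idx = rng.choice(len(archive), size=3, replace=False)
            z1, z2, z = (archive[i] for i in idx)
            if rng.random() < snooker_prob:
                # Snooker: jump along the line from x towards archive state z.
                dvec = x[c] - z
                norm2 = float(dvec @ dvec)
                if norm2 < 1e-300:
                    continue
                dproj = dvec / np.sqrt(norm2)
                zp1 = float(z1 @ dproj)
                zp2 = float(z2 @ dproj)
                gs = 1.7 * rng.random() + 1.2  # U(1.2, 2.9) around 2.38/sqrt(2)
                cand = x[c] + gs * (zp1 - zp2) * dproj
                dcand = cand - z
                norm2c = float(dcand @ dcand)
                if norm2c < 1e-300:
                    continue
                log_metric = 0.5 * (d - 1) * (np.log(norm2c) - np.log(norm2))
            else:
                eps = eps_scale * rng.standard_normal(d)
                if crossover:
                    # DREAM-style subspace move: update a random coordinate
                    # subset, jump length rescaled to the active dimensions
                    cr = _CR_LEVELS[rng.integers(len(_CR_LEVELS))]
                    active = rng.random(d) <= cr
                    if not np.any(active):
                        active[rng.integers(d)] = True
                    g_eff = g if g == 1.0 else scale * 2.38 / np.sqrt(
                        2.0 * int(active.sum())
                    )
                    cand = x[c] + np.where(active, g_eff * (z1 - z2) + eps, 0.0)
                else:
                    cand = x[c] + g * (z1 - z2) + eps
                log_metric = 0.0
            n_prop += 1
            win_prop += 1
            lp_cand = float(log_posterior(cand))
            if np.log(rng.random()) < beta * (lp_cand - lp[c]) + log_metric:
                x[c], lp[c] = cand, lp_cand
                n_acc += 1
                win_acc += 1
        if it < n_burn and win_prop >= 50 * n_chains:
            rate = win_acc / win_prop
            scale = float(np.clip(scale * np.exp(1.2 * (rate - 0.25)), 0.05, 2.0))
            win_acc = win_prop = 0
        if (it + 1) % archive_thin == 0:
            archive.extend(x.copy())
        if it + 1 == n_burn and len(archive) > n0 + 3 * d:
            # drop the prior-seeded archive head: from here on proposals are
            # built from states visited during and after late burn-in
            archive = archive[n0 + len(archive[n0:]) // 2:]
        j = it - (n_iter - keep)
        if j >= 0:
            out[:, j, :] = x
            out_lp[:, j] = lp

    return PosteriorSamples(
        names=list(names) if names is not None else [f"p{i}" for i in range(d)],
        chains=out,
        log_posterior=out_lp,
        seed=seed,
        acceptance_rate=n_acc / max(n_prop, 1),
        meta={"n_iter": n_iter, "n_chains": n_chains,
              "burn_fraction": burn_fraction, "jump_scale": scale},
    )


def gelman_rubin(samples) -> np.ndarray:
    """Per-parameter potential scale reduction factor R-hat.

    R-hat = sqrt(1 + B_mu / W) where B_mu is the variance of the chain means
    and W the mean within-chain variance; exactly 1 for identical chains,
    > 1 when chains disagree.  Accepts a :class:`PosteriorSamples` or a raw
    (n_chains, n_draws, n_params) array.
    """
    chains = samples.chains if hasattr(samples, "chains") else np.asarray(samples)
    if chains.ndim == 2:
        chains = chains[..., None]
    n_chains, n_draws, _ = chains.shape
    if n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    if n_draws < 10:
        warnings.warn("chains are very short; R-hat is unreliable", stacklevel=2)
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B_mu = means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(1.0 + np.where(W > 0, B_mu / np.where(W > 0, W, 1.0), 0.0))
    return rhat
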