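"""Tree-structured Parzen Estimator for hyperparameter search.

Sequential model-based optimization: after a random start-up phase, observed
trials are split by objective value into a "good" top quantile and the rest;
for each parameter, candidates are sampled from a Parzen (kernel) density
fitted to the good trials and ranked by the density ratio l(x)/g(x). The
factorized form (independent densities per parameter) follows the classic
formulation. Fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class IntParam:
    low: int
    high: int  # inclusive


@dataclass(frozen=True)
class CatParam:
    choices: tuple


ParamSpec = IntParam | CatParam


@dataclass
class Trial:
    params: dict
    value: float


def _sample_random(space: dict[str, ParamSpec], rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, IntParam):
            out[name] = int(rng.integers(spec.low, spec.high + 1))
        else:
            out[name] = spec.choices[int(rng.integers(0, len(spec.choices)))]
    return out


def _parzen_logpdf(x: np.ndarray, centers: np.ndarray, sigma: float,
                   low: float, high: float) -> np.ndarray:
    """Log density of a Gaussian mixture over the centers plus a uniform
    prior component over [low, high]."""
    if centers.size == 0:
        return np.full(x.shape, -np.log(high - low + 1.0))
    diff = (x[:, None] - centers[None, :]) / sigma
    log_k = -0.5 * diff**2 - np.log(sigma * np.sqrt(2 * np.pi))
    log_mix = np.logaddexp.reduce(log_k, axis=1) - np.log(centers.size + 1)
    log_uniform = -np.log(high - low + 1.0) - np.log(centers.size + 1)
    return np.logaddexp(log_mix, log_uniform)


def _suggest(space: dict[str, ParamSpec], history: list[Trial],
             rng: np.random.Generator, gamma: float, n_candidates: int) -> dict:
    values = np.array([t.value for t in history])
    order = np.argsort(-values, kind="stable")  # maximization
    n_good = max(1, int(np.ceil(gamma * len(history))))
    good = {i for i in order[:n_good]}
    out = {}
    for name, spec in space.items():
        if isinstance(spec, IntParam):
            lo, hi = float(spec.low), float(spec.high)
            good_v = np.array([history[i].params[name] for i in good], dtype=float)
            bad_v = np.array([history[i].params[name]
                              for i in range(len(history)) if i not in good],
                             dtype=float)
            sigma = max((hi - lo) / 6.0, 0.5)
            picks = good_v[rng.integers(0, good_v.size, size=n_candidates)]
            cand = np.clip(np.round(picks + rng.normal(0, sigma, n_candidates)),
                           lo, hi)
            score = (_parzen_logpdf(cand, good_v, sigma, lo, hi)
                     - _parzen_logpdf(cand, bad_v, sigma, lo, hi))
            out[name] = int(cand[int(np.argmax(score))])
        else:
            choices = spec.choices
            counts_g = np.ones(len(choices))
            counts_b = np.ones(len(choices))
            for i, t in enumerate(history):
                j = choices.index(t.params[name])
                if i in good:
                    counts_g[j] += 1
                else:
                    counts_b[j] += 1
            ratio = (counts_g / counts_g.sum()) / (counts_b / counts_b.sum())
            cand = rng.choice(len(choices), size=n_candidates,
                              p=counts_g / counts_g.sum())
            out[name] = choices[int(cand[int(np.argmax(ratio[cand]))])]
    return out


def tpe_maximize(objective: Callable[[dict], float],
                 space: dict[str, ParamSpec], n_trials: int, seed: int = 0,
                 n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24) -> tuple[dict, list[Trial]]:
    """Maximize the objective over the space; returns (best params, trials).

    The first ``n_startup`` trials are random; ties in the final ranking
    break to the earliest trial, so reruns with the same seed reproduce the
    same winner exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    for t in range(n_trials):
        if t < n_startup or len(history) < 2:
            params = _sample_random(space, rng)
        else:
            params = _suggest(space, history, rng, gamma, n_candidates)
        history.append(Trial(params=params, value=float(objective(params))))
    best = max(range(len(history)), key=lambda i: (history[i].value, -i))
    return dict(history[best].params), history
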