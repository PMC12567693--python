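"""Sequential model-based hyperparameter optimization with an EI+ acquisition.

A Gaussian-process surrogate (Matern 5/2 over the unit-cube encoding of the
search space) models the cross-validation loss; candidates maximize expected
improvement with an exploration offset xi. The "plus" behaviour inflates xi
whenever the incumbent stalls, escaping over-exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel


@dataclass(frozen=True)
class Param:
    """One dimension of a search space."""

    name: str
    kind: str  # "uniform" | "log" | "int" | "choice"
    bounds: tuple = ()
    choices: tuple = ()

    def decode(self, u: float):
        if self.kind == "choice":
            i = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[i]
        lo, hi = self.bounds
        if self.kind == "log":
            return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        val = lo + u * (hi - lo)
        return int(round(val)) if self.kind == "int" else float(val)


def decode_point(space: Sequence[Param], u: np.ndarray) -> dict:
    return {p.name: p.decode(float(u[i])) for i, p in enumerate(space)}


@dataclass
class OptResult:
    best_params: dict
    best_loss: float
    history: list[tuple[dict, float]]


def minimize_ei_plus(
    objective: Callable[[dict], float],
    space: Sequence[Param],
    budget: int = 50,
    n_init: int = 8,
    xi: float = 0.5,
    n_candidates: int = 256,
    seed: int = 0,
) -> OptResult:
    """Minimize ``objective`` over ``space`` within ``budget`` evaluations.

    An empty space returns the single default (empty) configuration. The
    initial design is random; subsequent points maximize EI+ under the GP
    surrogate. Fully deterministic given ``seed``.
    """
    if not space:
        loss = float(objective({}))
        return OptResult({}, loss, [({}, loss)])
    rng = np.random.default_rng(seed)
    d = len(space)
    U: list[np.ndarray] = []
    L: list[float] = []
    history: list[tuple[dict, float]] = []

    def evaluate(u: np.ndarray) -> None:
        params = decode_point(space, u)
        loss = float(objective(params))
        U.append(u)
        L.append(loss)
        history.append((params, loss))

    for _ in range(min(n_init, budget)):
        evaluate(rng.random(d))

    stall = 0
    import warnings as _warnings

    while len(L) < budget:
        best = min(L)
        xi_eff = xi * (2.0**stall)
        kernel = Matern(nu=2.5, length_scale=np.full(d, 0.3)) + WhiteKernel(1e-4)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=int(rng.integers(2**31)))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(U), np.asarray(L))
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        sd = np.maximum(sd, 1e-9)
        imp = best - mu - xi_eff * np.std(L)
        z = imp / sd
        ei = imp * norm.cdf(z) + sd * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
        if L[-1] < best - 1e-12:
            stall = 0
        else:
            stall = min(stall + 1, 4)

    i = int(np.argmin(L))
    return OptResult(decode_point(space, U[i]), L[i], history)
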