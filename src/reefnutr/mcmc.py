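"""Hamiltonian Monte Carlo engine and posterior-draw container.

All models in this package expose an exact gradient of their log posterior
(they are hierarchical GLMs with log/identity links), so sampling uses
plain HMC with jittered trajectory lengths, dual-averaging step-size
adaptation, and a diagonal mass matrix estimated during warmup. Chains are
vectorized: several independent chains advance simultaneously, initialized
in a small cloud around a MAP estimate found by L-BFGS with the same
gradients. Convergence is assessed with rank-normalized split-R-hat and
effective sample size (arviz); proposals whose Hamiltonian error explodes
are counted as divergences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.optimize import minimize


class ConvergenceError(RuntimeError):
    """Raised when R-hat exceeds tolerance; carries ``.diagnostics``."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class ParamLayout:
    """Packing of named parameter blocks into a flat vector."""

    blocks: list = field(default_factory=list)  # (name, size)

    def add(self, name: str, size: int = 1) -> None:
        self.blocks.append((name, size))

    @property
    def ndim(self) -> int:
        return sum(s for _, s in self.blocks)

    def slices(self) -> dict:
        out, i = {}, 0
        for name, size in self.blocks:
            out[name] = slice(i, i + size) if size > 1 else i
            i += size
        return out


class PosteriorDraws:
    """MCMC draws with chain structure and convergence diagnostics."""

    def __init__(self, chains: np.ndarray, names: list[str],
                 divergences: int = 0):
        self.chains = np.asarray(chains)
        self.names = list(names)
        self.divergences = int(divergences)
        self._index = {n: i for i, n in enumerate(self.names)}
        self.diagnostics = self._compute_diagnostics()

    def _compute_diagnostics(self) -> dict:
        data = {n: self.chains[:, :, i] for n, i in self._index.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(data)
            rhat = az.rhat(ds)
            ess = az.ess(ds)
        return {
            "rhat": {n: float(rhat[n].values) for n in self.names},
            "ess": {n: float(ess[n].values) for n in self.names},
            "divergences": self.divergences,
            "n_chains": self.chains.shape[0],
            "n_draws_per_chain": self.chains.shape[1],
        }

    @property
    def n_draws(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Pooled draws for one parameter, shape (n_draws,)."""
        return self.chains[:, :, self._index[name]].reshape(-1)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Pooled draws, shape (n_draws, len(names))."""
        names = names or self.names
        idx = [self._index[n] for n in names]
        return self.chains[:, :, idx].reshape(-1, len(idx))

    def max_rhat(self, names: list[str] | None = None) -> float:
        rh = self.diagnostics["rhat"]
        vals = [rh[n] for n in (names or self.names) if np.isfinite(rh[n])]
        return max(vals) if vals else np.nan

    def check_convergence(self, tol: float = 1.01,
                          names: list[str] | None = None) -> None:
        worst = self.max_rhat(names)
        if not np.isfinite(worst) or worst > tol:
            raise ConvergenceError(
                f"R-hat {worst:.4f} exceeds tolerance {tol}", self.diagnostics
            )


def hdi(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest (highest-density) interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(x).reshape(-1))
    n = len(x)
    m = max(int(np.floor(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def summarize(x: np.ndarray) -> dict:
    """Median plus 50% and 95% HDIs of a draw vector."""
    lo50, hi50 = hdi(x, 0.50)
    lo95, hi95 = hdi(x, 0.95)
    return {
        "median": float(np.median(x)),
        "hdi50_low": lo50,
        "hdi50_high": hi50,
        "hdi95_low": lo95,
        "hdi95_high": hi95,
        "n_draws": int(np.size(x)),
    }


def find_map(logp_grad, ndim: int, rng, maxiter: int = 1000):
    """MAP estimate by L-BFGS with analytic gradients.

    Returns (x_map, var_diag): the optimum and the diagonal of the L-BFGS
    inverse-Hessian approximation there — a cheap Laplace estimate of the
    posterior variances used to precondition the HMC mass matrix.
    """

    def neg(x):
        lp, g = logp_grad(x[None, :])
        if not np.isfinite(lp[0]):
            return 1e12, np.zeros(ndim)
        return -float(lp[0]), -g[0]

    best_x, best_v, best_var = np.zeros(ndim), neg(np.zeros(ndim))[0], None
    for start in (np.zeros(ndim), 0.2 * rng.standard_normal(ndim)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(neg, start, jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < best_v:
            best_x, best_v = res.x, res.fun
            try:
                diag = res.hess_inv.todense().diagonal()
                best_var = np.clip(diag, 1e-8, 1e4)
            except Exception:
                best_var = None
    if best_var is None:
        best_var = np.ones(ndim)
    return best_x, best_var


def run_hmc(
    logp_grad,
    ndim: int,
    seed: int,
    n_chains: int = 3,
    n_draws: int = 1200,
    warmup: int = 600,
    leapfrog_range: tuple[int, int] = (8, 32),
    target_accept: float = 0.8,
    init: np.ndarray | None = None,
    divergence_threshold: float = 1000.0,
):
    """Run vectorized multi-chain HMC.

    Parameters
    ----------
    logp_grad : callable
        Maps an (n_chains, ndim) position array to a tuple
        ``(log-posterior (n_chains,), gradient (n_chains, ndim))``.

    Returns
    -------
    chains : ndarray, shape (n_chains, n_draws, ndim)
    divergences : int
        Number of post-warmup proposals with exploding Hamiltonian error.
    """
    rng = np.random.default_rng(seed)
    C, D = n_chains, ndim
    inv_mass = np.ones(D)
    if init is None:
        x_map, laplace_var = find_map(logp_grad, D, rng)
        init = x_map + 0.05 * np.sqrt(laplace_var) \
            * rng.standard_normal((C, D))
        inv_mass = laplace_var  # refined from warmup draws below
    x = np.array(init, float)
    lp, grad = logp_grad(x)
    if not np.all(np.isfinite(lp)):
        raise RuntimeError("non-finite log posterior at initialization")
    log_eps = np.full(C, np.log(0.25 * D ** -0.25))
    # dual averaging state (per chain)
    mu = log_eps + np.log(10.0)
    h_bar = np.zeros(C)
    log_eps_bar = np.zeros(C)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_t = np.zeros(C)

    mass_lo, mass_hi = warmup // 4, (3 * warmup) // 4
    mass_buf: list[np.ndarray] = []
    divergences = 0
    out = np.empty((C, n_draws, D))
    lmin, lmax = leapfrog_range

    for t in range(warmup + n_draws):
        eps = np.exp(log_eps if t < warmup else log_eps_bar)
        n_leap = int(rng.integers(lmin, lmax + 1))
        p0 = rng.standard_normal((C, D)) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * ((p0**2) * inv_mass).sum(axis=1)

        xq, pq, gq = x.copy(), p0.copy(), grad.copy()
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(n_leap):
                pq = pq + 0.5 * eps[:, None] * gq
                xq = xq + eps[:, None] * inv_mass * pq
                lpq, gq = logp_grad(xq)
                gq = np.where(np.isfinite(gq), gq, 0.0)
                pq = pq + 0.5 * eps[:, None] * gq
            h1 = -lpq + 0.5 * ((pq**2) * inv_mass).sum(axis=1)
        delta_h = h1 - h0
        delta_h = np.where(np.isfinite(delta_h), delta_h, np.inf)
        accept_prob = np.exp(np.minimum(0.0, -delta_h))
        divergent = delta_h > divergence_threshold
        u = rng.random(C)
        accept = (u < accept_prob) & ~divergent
        x[accept] = xq[accept]
        lp = np.where(accept, lpq, lp)
        grad[accept] = gq[accept]

        if t < warmup:
            adapt_t += 1.0
            frac = 1.0 / (adapt_t + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_t) / gamma * h_bar
            eta = adapt_t ** -kappa
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            if mass_lo <= t < mass_hi:
                mass_buf.append(x.copy())
            if t == mass_hi and mass_buf:
                buf = np.concatenate(mass_buf, axis=0)
                inv_mass = buf.var(axis=0) + 1e-8
                # restart step-size adaptation for the new metric
                mu = log_eps_bar + np.log(10.0)
                h_bar[:] = 0.0
                adapt_t[:] = 0.0
        else:
            divergences += int(divergent.sum())
            out[:, t - warmup, :] = x
    return out, divergences
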