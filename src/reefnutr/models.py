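"""Trait-based Bayesian hierarchical models of fish nutrient concentration.

Two model structures are provided as sklearn-style estimators:

* :class:`TraitNutrientModel` — concentration as a function of five
  life-history covariates (K, TL, AM, PEL, LMX) with hierarchical
  intercepts for taxonomic family and sampling site, or alternatively
  species-level intercepts drawn from a phylogenetic Gaussian process with
  an Ornstein-Uhlenbeck kernel.
* :class:`HabitatEffectModel` — the same trait structure on the
  dual-habitat subset, plus an average macroalgal-habitat effect with
  species-varying slopes.

Non-calcium nutrients use a gamma likelihood in mean/shape form
(``E[y] = μ``, ``Var[y] = μ²/k``) with a log link; calcium is modeled as
log-normal. Positive parameters are sampled on the log scale. Hierarchical
effect blocks enter the linear predictor centered (sum-to-zero), which
removes the ridge between the global intercept and the block mean; the
phylogenetic species effects are parameterized directly (centered) with
their multivariate-normal prior evaluated by Cholesky factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_triangular
from scipy.special import digamma, gammaln, logsumexp
from sklearn.base import BaseEstimator

from .config import TRAITS
from .mcmc import ParamLayout, PosteriorDraws, run_hmc, summarize

__all__ = [
    "Prior",
    "PriorTable",
    "ModelSpec",
    "ou_covariance",
    "TraitNutrientModel",
    "HabitatEffectModel",
    "fit_model",
    "compute_waic",
    "waic_difference",
    "select_intercept_structure",
    "predict_species",
    "habitat_effect_summary",
]

_LOG2PI = float(np.log(2.0 * np.pi))
BETA_NAMES = tuple(f"beta_{t}" for t in TRAITS)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------
@dataclass
class Prior:
    """One parameter prior: ``normal(loc, scale)`` or ``exponential(rate)``
    (rate stored in ``scale``)."""

    family: str
    loc: float = 0.0
    scale: float = 1.0
    provenance: str = "weak_default"

    def logpdf(self, x):
        if self.family == "normal":
            return -0.5 * ((x - self.loc) / self.scale) ** 2
        if self.family == "exponential":
            rate = self.scale
            return np.where(x > 0, np.log(rate) - rate * x, -np.inf)
        raise ValueError(f"unknown prior family {self.family!r}")


@dataclass
class PriorTable:
    """Priors per parameter name, with provenance bookkeeping.

    Informative trait-coefficient priors (posterior summaries of a global
    marine-fish model) can be supplied via YAML; the defaults are weak
    Normal(0, 1) priors and carry ``provenance="weak_default"``.
    """

    priors: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PriorTable":
        p = {name: Prior("normal", 0.0, 1.0, "weak_default")
             for name in BETA_NAMES}
        p["alpha"] = Prior("normal", 0.0, 10.0, "weak_default")
        p["beta_HAB"] = Prior("normal", 0.0, 1.0, "stated_in_paper")
        for s in ("sigma_family", "sigma_site", "sigma_species",
                  "sigma_hab_slope", "eta2"):
            p[s] = Prior("exponential", scale=1.0)
        p["rho"] = Prior("exponential", scale=0.5)
        p["shape"] = Prior("exponential", scale=0.05)
        p["sigma_obs"] = Prior("exponential", scale=1.0)
        return cls(p)

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def update_from_yaml(self, path) -> None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for name, spec in raw.items():
            self.priors[name] = Prior(**spec)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: vars(v) for k, v in self.priors.items()}, fh,
                sort_keys=False,
            )


@dataclass
class ModelSpec:
    """Declarative description of one nutrient model fit."""

    nutrient: str
    likelihood: str | None = None  # "gamma" / "lognormal" / None = by nutrient
    intercept_structure: str = "family_site"
    scaling: str = "centered_scaled"
    varying_slope_on: str | None = None  # "HAB" for the habitat model
    prior_table: PriorTable | None = None


# ---------------------------------------------------------------------------
# phylogenetic kernel
# ---------------------------------------------------------------------------
def ou_covariance(distance, eta2: float, rho: float,
                  nugget: float = 1e-6) -> np.ndarray:
    """Ornstein-Uhlenbeck covariance ``S_ij = η² exp(−ρ d_ij) + nugget·I``.

    ``distance`` must be symmetric with a zero diagonal (normalized
    phylogenetic distances). Positive definiteness follows from the
    exponential-decay kernel plus the diagonal jitter.
    """
    d = np.asarray(distance, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return eta2 * np.exp(-rho * d) + nugget * np.eye(d.shape[0])


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------
def compute_waic(loglik: np.ndarray) -> dict:
    """WAIC from a pointwise log-likelihood matrix (draws × observations).

    ``waic = −2(lppd − p_waic)`` with ``lppd_i = log mean_d exp(ll_di)``
    and ``p_waic_i = var_d(ll_di)`` (sample variance over draws); the
    pointwise vector ``−2(lppd_i − p_waic_i)`` is returned alongside.
    """
    ll = np.asarray(loglik, float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, observations) matrix with >= 2 draws")
    n_draws = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    return {
        "waic": float(pointwise.sum()),
        "lppd": float(lppd_i.sum()),
        "p_waic": float(p_i.sum()),
        "pointwise": pointwise,
    }


def waic_difference(pointwise_a, pointwise_b) -> tuple[float, float]:
    """WAIC difference (a − b) and its standard error over pointwise terms."""
    da = np.asarray(pointwise_a) - np.asarray(pointwise_b)
    n = len(da)
    return float(da.sum()), float(np.sqrt(n * da.var(ddof=1)))


def select_intercept_structure(
    waic_family: float, waic_phylo: float, strict: bool = False
) -> dict:
    """Choose the intercept structure used for prediction.

    The default policy keeps the simpler family-intercept model regardless
    of the WAIC winner (guarding against overfitting); ``strict=True``
    picks the lower-WAIC structure. The comparison is always recorded.
    """
    record = {
        "waic_family": float(waic_family),
        "waic_phylo": float(waic_phylo),
        "waic_winner": (
            "phylo_species_site" if waic_phylo < waic_family else "family_site"
        ),
        "tie": bool(waic_phylo == waic_family),
    }
    if strict and waic_phylo < waic_family:
        record["chosen"] = "phylo_species_site"
    else:
        record["chosen"] = "family_site"
    return record


# ---------------------------------------------------------------------------
# design + log posterior with exact gradients
# ---------------------------------------------------------------------------
class _Design:
    """Prepared data, parameter layout, and differentiable log posterior."""

    def __init__(self, y, X, fam_idx, site_idx, sp_idx, hab, likelihood,
                 structure, varying_slope, priors, dist=None, nugget=1e-6):
        self.y = np.asarray(y, float)
        self.logy = np.log(self.y)
        self.X = np.asarray(X, float)
        self.likelihood = likelihood
        self.structure = structure
        self.varying_slope = varying_slope
        self.priors = priors
        self.dist = dist
        self.nugget = nugget
        self.fam_idx, self.site_idx, self.sp_idx, self.hab = (
            fam_idx, site_idx, sp_idx, hab)
        self.n_fam = int(fam_idx.max()) + 1 if fam_idx is not None else 0
        self.n_site = int(site_idx.max()) + 1
        self.n_sp = int(sp_idx.max()) + 1
        self.p = self.X.shape[1]
        n = len(self.y)

        def onehot(idx, m):
            M = np.zeros((n, m))
            M[np.arange(n), idx] = 1.0
            return M

        self.M_site = onehot(site_idx, self.n_site)
        self.M_fam = onehot(fam_idx, self.n_fam) if self.n_fam else None
        self.M_sp = onehot(sp_idx, self.n_sp)
        self.M_sp_hab = self.M_sp * hab[:, None] if varying_slope else None

        lay = ParamLayout()
        lay.add("beta", self.p)
        lay.add("alpha")
        if structure == "family_site":
            lay.add("z_fam", self.n_fam)
            lay.add("log_sigma_family")
        elif structure == "species_site":
            lay.add("z_sp", self.n_sp)
            lay.add("log_sigma_species")
        elif structure == "phylo_species_site":
            lay.add("z_sp", self.n_sp)
            lay.add("log_eta2")
            lay.add("log_rho")
        else:
            raise ValueError(f"unknown intercept structure {structure!r}")
        lay.add("z_site", self.n_site)
        lay.add("log_sigma_site")
        if varying_slope:
            lay.add("b6_mean")
            lay.add("z_b6", self.n_sp)
            lay.add("log_sigma_hab_slope")
        lay.add("log_disp")
        self.layout = lay
        self.sl = lay.slices()

    # -- linear predictor ---------------------------------------------------
    def _eta(self, P):
        sl = self.sl
        eta = P[:, sl["alpha"]][:, None] + P[:, sl["beta"]] @ self.X.T
        if self.structure == "family_site":
            sig = np.exp(P[:, sl["log_sigma_family"]])
            z = P[:, sl["z_fam"]]
            eff = sig[:, None] * (z - z.mean(axis=1, keepdims=True))
            eta = eta + eff[:, self.fam_idx]
        elif self.structure == "species_site":
            sig = np.exp(P[:, sl["log_sigma_species"]])
            z = P[:, sl["z_sp"]]
            eff = sig[:, None] * (z - z.mean(axis=1, keepdims=True))
            eta = eta + eff[:, self.sp_idx]
        else:
            a, bad = self._phylo_a(P)
            eff = a - a.mean(axis=1, keepdims=True)
            eff[bad] = np.nan  # propagates to -inf log posterior
            eta = eta + eff[:, self.sp_idx]
        sig_s = np.exp(P[:, sl["log_sigma_site"]])
        zs = P[:, sl["z_site"]]
        eff_s = sig_s[:, None] * (zs - zs.mean(axis=1, keepdims=True))
        eta = eta + eff_s[:, self.site_idx]
        if self.varying_slope:
            eta = eta + self._hab_slopes(P)[:, self.sp_idx] * self.hab[None, :]
        return eta

    def _phylo_a(self, P):
        """Non-centered species effects a = L(η², ρ) z; returns (a, bad)."""
        sl = self.sl
        eta2 = np.exp(P[:, sl["log_eta2"]])
        rho = np.exp(P[:, sl["log_rho"]])
        z = P[:, sl["z_sp"]]
        C, nsp = z.shape
        I = np.eye(nsp)
        with np.errstate(over="ignore", invalid="ignore"):
            S = eta2[:, None, None] * np.exp(-rho[:, None, None] * self.dist)
        S = S + self.nugget * I
        bad = ~np.isfinite(S).all(axis=(1, 2))
        S[bad] = I
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            L = np.empty_like(S)
            for c in range(C):
                try:
                    L[c] = np.linalg.cholesky(S[c])
                except np.linalg.LinAlgError:
                    L[c] = I
                    bad[c] = True
        return np.einsum("cij,cj->ci", L, z), bad

    def _hab_slopes(self, P):
        sl = self.sl
        sig = np.exp(P[:, sl["log_sigma_hab_slope"]])
        z = P[:, sl["z_b6"]]
        return (P[:, sl["b6_mean"]][:, None]
                + sig[:, None] * (z - z.mean(axis=1, keepdims=True)))

    # -- joint log posterior and gradient -----------------------------------
    def log_prob_and_grad(self, P):
        P = np.atleast_2d(np.asarray(P, float))
        C = P.shape[0]
        sl, pr = self.sl, self.priors
        g = np.zeros_like(P)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            eta = self._eta(P)
            disp = np.exp(P[:, sl["log_disp"]])
            n = len(self.y)
            if self.likelihood == "gamma":
                k = disp
                w = self.y[None, :] * np.exp(-eta)
                ll = (
                    n * (k * np.log(k) - gammaln(k))
                    + (k - 1.0) * self.logy.sum()
                    - k * (eta.sum(axis=1) + w.sum(axis=1))
                )
                g_eta = k[:, None] * (w - 1.0)
                g_logdisp = k * (
                    n * (np.log(k) + 1.0 - digamma(k))
                    + self.logy.sum()
                    - eta.sum(axis=1)
                    - w.sum(axis=1)
                )
                g_logdisp += 1.0 - pr["shape"].scale * k
            else:
                sig = disp
                r = self.logy[None, :] - eta
                ll = (
                    -n * np.log(sig)
                    - 0.5 * (r**2).sum(axis=1) / sig**2
                    - 0.5 * n * _LOG2PI
                    - self.logy.sum()
                )
                g_eta = r / sig[:, None] ** 2
                g_logdisp = -n + (r**2).sum(axis=1) / sig**2
                g_logdisp += 1.0 - pr["sigma_obs"].scale * sig
            lp = ll

            # fixed effects
            beta = P[:, sl["beta"]]
            g[:, sl["beta"]] = g_eta @ self.X
            for j, name in enumerate(BETA_NAMES[: self.p]):
                b = pr[name]
                lp = lp + b.logpdf(beta[:, j])
                g[:, sl["beta"]][:, j] += -(beta[:, j] - b.loc) / b.scale**2
            a0 = P[:, sl["alpha"]]
            pa = pr["alpha"]
            g[:, sl["alpha"]] = g_eta.sum(axis=1) - (a0 - pa.loc) / pa.scale**2
            lp = lp + pa.logpdf(a0)

            # hierarchical blocks
            lp, g = self._grad_group(
                P, lp, g, g_eta, "z_site", "log_sigma_site", self.M_site,
                pr["sigma_site"].scale)
            if self.structure == "family_site":
                lp, g = self._grad_group(
                    P, lp, g, g_eta, "z_fam", "log_sigma_family", self.M_fam,
                    pr["sigma_family"].scale)
            elif self.structure == "species_site":
                lp, g = self._grad_group(
                    P, lp, g, g_eta, "z_sp", "log_sigma_species", self.M_sp,
                    pr["sigma_species"].scale)
            else:
                lp, g = self._grad_phylo(P, lp, g, g_eta)
            if self.varying_slope:
                lp, g = self._grad_slopes(P, lp, g, g_eta)

            g[:, sl["log_disp"]] = g_logdisp
            rate = (pr["shape"] if self.likelihood == "gamma"
                    else pr["sigma_obs"]).scale
            lp = lp + np.log(rate) - rate * disp + P[:, sl["log_disp"]]
        bad = ~np.isfinite(lp)
        if bad.any():
            lp = np.where(bad, -np.inf, lp)
            g[bad] = 0.0
        return lp, g

    def _grad_group(self, P, lp, g, g_eta, z_name, ls_name, M, rate):
        sl = self.sl
        z = P[:, sl[z_name]]
        sig = np.exp(P[:, sl[ls_name]])
        zc = z - z.mean(axis=1, keepdims=True)
        G = g_eta @ M  # (C, m)
        Gc = G - G.mean(axis=1, keepdims=True)
        g[:, sl[z_name]] = sig[:, None] * Gc - z
        g[:, sl[ls_name]] = sig * (G * zc).sum(axis=1) + 1.0 - rate * sig
        lp = lp - 0.5 * (z**2).sum(axis=1)
        lp = lp + np.log(rate) - rate * sig + P[:, sl[ls_name]]
        return lp, g

    def _grad_slopes(self, P, lp, g, g_eta):
        sl, pr = self.sl, self.priors
        b6 = P[:, sl["b6_mean"]]
        z = P[:, sl["z_b6"]]
        sig = np.exp(P[:, sl["log_sigma_hab_slope"]])
        zc = z - z.mean(axis=1, keepdims=True)
        H = g_eta @ self.M_sp_hab
        Hc = H - H.mean(axis=1, keepdims=True)
        pb = pr["beta_HAB"]
        g[:, sl["b6_mean"]] = H.sum(axis=1) - (b6 - pb.loc) / pb.scale**2
        g[:, sl["z_b6"]] = sig[:, None] * Hc - z
        rate = pr["sigma_hab_slope"].scale
        g[:, sl["log_sigma_hab_slope"]] = (
            sig * (H * zc).sum(axis=1) + 1.0 - rate * sig
        )
        lp = lp + pb.logpdf(b6) - 0.5 * (z**2).sum(axis=1)
        lp = lp + np.log(rate) - rate * sig + P[:, sl["log_sigma_hab_slope"]]
        return lp, g

    def _grad_phylo(self, P, lp, g, g_eta):
        """Gradient of the non-centered phylogenetic block.

        With a = L(θ)z, the kernel-parameter gradients use the Cholesky
        forward-mode rule dL = L·Φ(L⁻¹ dS L⁻ᵀ), where Φ takes the lower
        triangle with halved diagonal.
        """
        sl, pr = self.sl, self.priors
        z = P[:, sl["z_sp"]]
        eta2 = np.exp(P[:, sl["log_eta2"]])
        rho = np.exp(P[:, sl["log_rho"]])
        G = g_eta @ self.M_sp
        Gc = G - G.mean(axis=1, keepdims=True)  # gradient w.r.t. a
        I = np.eye(self.n_sp)
        for c in range(P.shape[0]):
            if not (np.isfinite(eta2[c]) and np.isfinite(rho[c])
                    and np.all(np.isfinite(z[c]))):
                lp[c] = -np.inf
                continue
            K = np.exp(-rho[c] * self.dist)
            S = eta2[c] * K + self.nugget * I
            if not np.all(np.isfinite(S)):
                lp[c] = -np.inf
                continue
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                lp[c] = -np.inf
                continue
            g[c, sl["z_sp"]] = L.T @ Gc[c] - z[c]
            for dS, idx, theta, rate in (
                (K, sl["log_eta2"], eta2[c], pr["eta2"].scale),
                (-eta2[c] * self.dist * K, sl["log_rho"], rho[c],
                 pr["rho"].scale),
            ):
                A = solve_triangular(L, dS, lower=True, check_finite=False)
                B = solve_triangular(L, A.T, lower=True, check_finite=False)
                Phi = np.tril(B)
                Phi[np.diag_indices_from(Phi)] *= 0.5
                dL = L @ Phi
                g[c, idx] = theta * (Gc[c] @ (dL @ z[c])) + 1.0 - rate * theta
        lp = lp - 0.5 * (z**2).sum(axis=1)
        lp = lp + np.log(pr["eta2"].scale) - pr["eta2"].scale * eta2 \
            + P[:, sl["log_eta2"]]
        lp = lp + np.log(pr["rho"].scale) - pr["rho"].scale * rho \
            + P[:, sl["log_rho"]]
        return lp, g

    def log_prob(self, P):
        return self.log_prob_and_grad(P)[0]

    # -- pointwise likelihood for WAIC ---------------------------------------
    def pointwise_loglik(self, P, max_draws: int = 4000, seed: int = 0):
        """Pointwise log-likelihood matrix for WAIC, possibly subsampled."""
        P = np.atleast_2d(P)
        if P.shape[0] > max_draws:
            idx = np.random.default_rng(seed).choice(
                P.shape[0], size=max_draws, replace=False
            )
            P = P[idx]
        eta = self._eta(P)
        disp = np.exp(P[:, self.sl["log_disp"]])
        if self.likelihood == "gamma":
            k = disp[:, None]
            return (
                k * np.log(k)
                - gammaln(k)
                - k * eta
                + (k - 1.0) * self.logy[None, :]
                - k * self.y[None, :] * np.exp(-eta)
            )
        sig = disp[:, None]
        return (
            -np.log(sig)
            - 0.5 * ((self.logy[None, :] - eta) / sig) ** 2
            - 0.5 * _LOG2PI
            - self.logy[None, :]
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
class _BaseNutrientModel(BaseEstimator):
    """Shared fitting/prediction machinery; see subclasses for structure."""

    _structure = "family_site"
    _varying_slope = False

    def __init__(self, nutrient="iron", likelihood=None,
                 scaling="centered_scaled", priors=None, phylo_distance=None,
                 n_chains=3, n_draws=1200, warmup=600, leapfrog_range=(8, 32),
                 seed=0, rhat_tol=1.01, enforce_convergence=True,
                 nugget=1e-6):
        self.nutrient = nutrient
        self.likelihood = likelihood
        self.scaling = scaling
        self.priors = priors
        self.phylo_distance = phylo_distance
        self.n_chains = n_chains
        self.n_draws = n_draws
        self.warmup = warmup
        self.leapfrog_range = leapfrog_range
        self.seed = seed
        self.rhat_tol = rhat_tol
        self.enforce_convergence = enforce_convergence
        self.nugget = nugget

    # -- data preparation ---------------------------------------------------
    def _prepare(self, samples: pd.DataFrame, traits: pd.DataFrame):
        s = samples.loc[samples["nutrient"] == self.nutrient]
        if s.empty:
            raise ValueError(f"no samples for nutrient {self.nutrient!r}")
        missing = set(s["species"]) - set(traits["species"])
        if missing:
            raise ValueError(
                f"traits missing for sampled species: {sorted(missing)}"
            )
        t = traits.drop_duplicates("species").set_index("species")
        self.species_ = sorted(s["species"].unique())
        self.families_ = sorted(t.loc[self.species_, "family"].unique())
        self.sites_ = sorted(s["site"].unique())

        sp_trait = t.loc[self.species_, list(TRAITS)].astype(float)
        if self.scaling == "centered_scaled":
            mean = sp_trait.mean(axis=0)
            sd = sp_trait.std(axis=0, ddof=0).replace(0.0, 1.0)
        else:
            mean = sp_trait.mean(axis=0) * 0.0
            sd = mean + 1.0
        self.trait_scaling_ = {c: (float(mean[c]), float(sd[c]))
                               for c in TRAITS}
        Xsp = ((sp_trait - mean) / sd).to_numpy()
        sp_pos = {sp: i for i, sp in enumerate(self.species_)}
        fam_of_sp = t.loc[self.species_, "family"].to_numpy()
        fam_pos = {f: i for i, f in enumerate(self.families_)}
        site_pos = {x: i for i, x in enumerate(self.sites_)}

        sp_idx = s["species"].map(sp_pos).to_numpy()
        X = Xsp[sp_idx]
        fam_idx = np.array([fam_pos[fam_of_sp[i]] for i in sp_idx])
        site_idx = s["site"].map(site_pos).to_numpy()
        hab = (s["habitat"] == "macroalgal").to_numpy(float)
        y = s["concentration"].to_numpy(float)
        if (y <= 0).any():
            raise ValueError("concentrations must be positive")

        dist = None
        if self._structure == "phylo_species_site":
            if self.phylo_distance is None:
                raise ValueError("phylo intercepts require a distance matrix")
            dist = (self.phylo_distance.loc[self.species_, self.species_]
                    .to_numpy(float))
        likelihood = self.likelihood or (
            "lognormal" if self.nutrient == "calcium" else "gamma"
        )
        self.likelihood_ = likelihood
        priors = self.priors or PriorTable.default()
        if all(priors[n].provenance == "weak_default" for n in BETA_NAMES):
            warnings.warn(
                "using weak default Normal(0,1) trait-coefficient priors; "
                "supply informative priors to match a global-model analysis",
                stacklevel=3,
            )
        self.prior_table_ = priors
        return _Design(
            y, X, fam_idx, site_idx, sp_idx, hab, likelihood,
            self._structure, self._varying_slope, priors, dist, self.nugget
        )

    # -- fit ----------------------------------------------------------------
    def fit(self, samples: pd.DataFrame, traits: pd.DataFrame):
        design = self._prepare(samples, traits)
        self._design = design
        raw, divergences = run_hmc(
            design.log_prob_and_grad,
            design.layout.ndim,
            seed=self.seed,
            n_chains=self.n_chains,
            n_draws=self.n_draws,
            warmup=self.warmup,
            leapfrog_range=self.leapfrog_range,
        )
        self.n_samples_ = len(design.y)
        self._raw_chains = raw
        self.draws_ = self._to_posterior(raw, divergences)
        key = [*BETA_NAMES[: design.p], "alpha"]
        if self._varying_slope:
            key.append("beta_HAB")
        self.key_params_ = key
        self.rhat_max_ = self.draws_.max_rhat(key)
        if self.enforce_convergence:
            self.draws_.check_convergence(self.rhat_tol, key)
        flat = raw.reshape(-1, raw.shape[-1])
        self.loglik_ = design.pointwise_loglik(flat, seed=self.seed)
        self.waic_ = compute_waic(self.loglik_)
        return self

    def _to_posterior(self, raw, divergences) -> PosteriorDraws:
        """Transform raw chains to reporting scale with readable names."""
        d, sl = self._design, self._design.sl
        cols, names = [], []

        def add(name, values):
            names.append(name)
            cols.append(values)

        beta = raw[:, :, sl["beta"]]
        for j, nm in enumerate(BETA_NAMES[: d.p]):
            add(nm, beta[:, :, j])
        add("alpha", raw[:, :, sl["alpha"]])
        if d.structure == "family_site":
            sig = np.exp(raw[:, :, sl["log_sigma_family"]])
            add("sigma_family", sig)
            z = raw[:, :, sl["z_fam"]]
            eff = sig[:, :, None] * (z - z.mean(axis=2, keepdims=True))
            for i, fam in enumerate(self.families_):
                add(f"a_family[{fam}]", eff[:, :, i])
        elif d.structure == "species_site":
            sig = np.exp(raw[:, :, sl["log_sigma_species"]])
            add("sigma_species", sig)
            z = raw[:, :, sl["z_sp"]]
            eff = sig[:, :, None] * (z - z.mean(axis=2, keepdims=True))
            for i, sp in enumerate(self.species_):
                add(f"a_species[{sp}]", eff[:, :, i])
        else:
            add("eta2", np.exp(raw[:, :, sl["log_eta2"]]))
            add("rho", np.exp(raw[:, :, sl["log_rho"]]))
            nc, nd = raw.shape[0], raw.shape[1]
            a, _ = d._phylo_a(raw.reshape(-1, raw.shape[-1]))
            eff = (a - a.mean(axis=1, keepdims=True)).reshape(nc, nd, -1)
            for i, sp in enumerate(self.species_):
                add(f"a_species[{sp}]", eff[:, :, i])
        sig_s = np.exp(raw[:, :, sl["log_sigma_site"]])
        add("sigma_site", sig_s)
        zs = raw[:, :, sl["z_site"]]
        eff_s = sig_s[:, :, None] * (zs - zs.mean(axis=2, keepdims=True))
        for i, site in enumerate(self.sites_):
            add(f"a_site[{site}]", eff_s[:, :, i])
        if d.varying_slope:
            add("beta_HAB", raw[:, :, sl["b6_mean"]])
            sig_b = np.exp(raw[:, :, sl["log_sigma_hab_slope"]])
            add("sigma_hab_slope", sig_b)
            nc, nd = raw.shape[0], raw.shape[1]
            flat = raw.reshape(-1, raw.shape[-1])
            slopes = d._hab_slopes(flat).reshape(nc, nd, -1)
            for i, sp in enumerate(self.species_):
                add(f"b6[{sp}]", slopes[:, :, i])
        disp = np.exp(raw[:, :, sl["log_disp"]])
        add("shape" if d.likelihood == "gamma" else "sigma_obs", disp)
        return PosteriorDraws(np.stack(cols, axis=-1), names, divergences)

    # -- prediction ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise RuntimeError("model is not fitted")

    def predict_draws(self, traits: pd.DataFrame, include_family: bool = True,
                      habitat: str | None = None, n_draws: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
        """Posterior draws of expected concentration per species.

        Site effects are always excluded. The family intercept is included
        when ``include_family`` and the family was observed in fitting;
        otherwise prediction falls back to the population level (with a
        warning for unknown families). For the habitat model,
        ``habitat="macroalgal"`` adds the species' habitat slope (the
        average effect for species outside the fitted set).

        Returns a DataFrame (n_draws × species) on the response scale.
        """
        self._check_fitted()
        rng = np.random.default_rng(seed)
        total = self.draws_.n_draws
        idx = (np.arange(total) if n_draws >= total
               else rng.choice(total, size=n_draws, replace=False))
        alpha = self.draws_.get("alpha")[idx]
        betas = np.column_stack(
            [self.draws_.get(nm)[idx] for nm in BETA_NAMES]
        )
        t = traits.drop_duplicates("species").set_index("species")
        out = {}
        for sp in t.index:
            x = np.array(
                [
                    (float(t.loc[sp, c]) - self.trait_scaling_[c][0])
                    / self.trait_scaling_[c][1]
                    for c in TRAITS
                ]
            )
            eta = alpha + betas @ x
            if include_family:
                fam = t.loc[sp, "family"]
                key = f"a_family[{fam}]"
                if key in self.draws_.names:
                    eta = eta + self.draws_.get(key)[idx]
                elif self._structure == "family_site":
                    warnings.warn(
                        f"family {fam!r} not observed in fit; predicting at "
                        "population level",
                        stacklevel=2,
                    )
            if habitat == "macroalgal" and self._varying_slope:
                key = f"b6[{sp}]"
                b6 = (self.draws_.get(key) if key in self.draws_.names
                      else self.draws_.get("beta_HAB"))
                eta = eta + b6[idx]
            out[sp] = np.exp(eta)
        return pd.DataFrame(out)

    def predict(self, traits: pd.DataFrame, include_family: bool = True,
                habitat: str | None = None, n_draws: int = 1000,
                seed: int = 0) -> pd.DataFrame:
        """Posterior summaries (median, 50%/95% HDIs) per species."""
        draws = self.predict_draws(traits, include_family, habitat,
                                   n_draws, seed)
        rows = []
        for sp in draws.columns:
            row = {"species": sp, "nutrient": self.nutrient,
                   "habitat": habitat or "none"}
            row.update(summarize(draws[sp].to_numpy()))
            rows.append(row)
        return pd.DataFrame(rows)


class TraitNutrientModel(_BaseNutrientModel):
    """Trait model with family+site intercepts (default) or alternatives.

    ``intercept_structure`` is one of ``family_site``,
    ``phylo_species_site`` (OU-kernel Gaussian-process species intercepts;
    requires ``phylo_distance``) or ``species_site`` (iid species
    intercepts).
    """

    def __init__(self, nutrient="iron", intercept_structure="family_site",
                 likelihood=None, scaling="centered_scaled", priors=None,
                 phylo_distance=None, n_chains=3, n_draws=1200, warmup=600,
                 leapfrog_range=(8, 32), seed=0, rhat_tol=1.01,
                 enforce_convergence=True, nugget=1e-6):
        super().__init__(
            nutrient=nutrient, likelihood=likelihood, scaling=scaling,
            priors=priors, phylo_distance=phylo_distance, n_chains=n_chains,
            n_draws=n_draws, warmup=warmup, leapfrog_range=leapfrog_range,
            seed=seed, rhat_tol=rhat_tol,
            enforce_convergence=enforce_convergence, nugget=nugget,
        )
        self.intercept_structure = intercept_structure

    @property
    def _structure(self):
        return self.intercept_structure


class HabitatEffectModel(_BaseNutrientModel):
    """Varying-slopes habitat model on the dual-habitat species subset.

    Species and site intercepts; the macroalgal-habitat indicator enters
    with an average link-scale effect (``beta_HAB``, Normal(0,1) prior)
    plus species-level slope deviations.
    """

    _structure = "species_site"
    _varying_slope = True

    def __init__(self, nutrient="iron", likelihood=None,
                 scaling="centered_scaled", priors=None, phylo_distance=None,
                 n_chains=3, n_draws=1200, warmup=600,
                 leapfrog_range=(32, 64), seed=0, rhat_tol=1.01,
                 enforce_convergence=True, nugget=1e-6):
        # longer trajectories: trait covariates are collinear with the
        # species intercepts here, so the posterior is strongly correlated
        super().__init__(
            nutrient=nutrient, likelihood=likelihood, scaling=scaling,
            priors=priors, phylo_distance=phylo_distance, n_chains=n_chains,
            n_draws=n_draws, warmup=warmup, leapfrog_range=leapfrog_range,
            seed=seed, rhat_tol=rhat_tol,
            enforce_convergence=enforce_convergence, nugget=nugget,
        )

    def _prepare(self, samples: pd.DataFrame, traits: pd.DataFrame):
        s = samples.loc[samples["nutrient"] == self.nutrient]
        by_sp = s.groupby("species")["habitat"].agg(
            lambda h: {"coral", "macroalgal"} <= set(h)
        )
        dual = set(by_sp[by_sp].index)
        if len(dual) < 2:
            raise ValueError(
                "habitat model needs >= 2 species sampled in both habitats"
            )
        subset = samples[samples["species"].isin(dual)]
        return super()._prepare(subset, traits)

    def habitat_effect_summary(self) -> dict:
        """Average and per-species habitat-effect posteriors.

        Flags species whose slope-deviation posterior (b6_sp − b6_mean)
        excludes zero at the 95% HDI — those deviate from the average
        macroalgal effect.
        """
        self._check_fitted()
        avg = self.draws_.get("beta_HAB")
        out = {
            "average": summarize(avg),
            "average_multiplicative": summarize(np.exp(avg)),
            "species": {},
        }
        for sp in self.species_:
            dev = self.draws_.get(f"b6[{sp}]") - avg
            s = summarize(dev)
            s["deviates_from_average"] = bool(
                s["hdi95_low"] > 0 or s["hdi95_high"] < 0
            )
            out["species"][sp] = s
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def fit_model(samples, traits, spec: ModelSpec,
              mcmc_config: dict | None = None):
    """Fit the model described by ``spec``; returns the fitted estimator."""
    mcmc_config = mcmc_config or {}
    if spec.varying_slope_on == "HAB":
        est = HabitatEffectModel(
            nutrient=spec.nutrient, likelihood=spec.likelihood,
            scaling=spec.scaling, priors=spec.prior_table, **mcmc_config,
        )
    else:
        est = TraitNutrientModel(
            nutrient=spec.nutrient,
            intercept_structure=spec.intercept_structure,
            likelihood=spec.likelihood, scaling=spec.scaling,
            priors=spec.prior_table, **mcmc_config,
        )
    return est.fit(samples, traits)


def predict_species(model, traits_row: pd.DataFrame, include_family=True,
                    habitat=None, n_draws=1000, seed=0) -> pd.DataFrame:
    return model.predict(traits_row, include_family, habitat, n_draws, seed)


def habitat_effect_summary(model: HabitatEffectModel) -> dict:
    return model.habitat_effect_summary()
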