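"""Two-species occupancy model with a multivariate-Bernoulli latent state.

The latent presence/absence pair Z = (z1, z2) of two interacting species at
a site follows a four-category (multivariate Bernoulli) distribution over
states {11, 10, 01, 00} with cell probabilities (psi11, psi10, psi01,
psi00).  The distribution is parameterised by natural (log-odds) parameters

    f1  = log(psi10 / psi00)            -- species 1 alone vs neither
    f2  = log(psi01 / psi00)            -- species 2 alone vs neither
    f12 = log(psi11 psi00 / psi01 psi10)  -- co-occurrence log odds-ratio

each modelled as a linear function of site covariates (f1 = x'a, f2 = x'b,
f12 = x'g).  f12 = 0 means the species occur independently; fixing it at 0
yields the independence null model.  Observation is imperfect: given z_s = 1
the species is detected in occasion j with probability p_sj (logit-linear in
detection covariates such as survey effort); given z_s = 0 it is never
detected.  The likelihood marginalises the latent state per site.

Models are fitted by maximum likelihood (quasi-Newton, optional random
restarts), compared by AIC with Akaike weights, and summarised through Wald
intervals and marginal/conditional occupancy predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

INTERCEPT = "(Intercept)"
_STATES = ("psi11", "psi10", "psi01", "psi00")


# ---------------------------------------------------------------------------
# covariate handling


@dataclass
class CovariateTable:
    """Site covariates on the z-score scale, with back-transformation info."""

    data: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    standardized: bool = True

    def original(self, column: str, z: np.ndarray) -> np.ndarray:
        """Back-transform a z-scored axis to the original units."""
        return z * self.scale[column] + self.center[column]


def standardize_covariates(table: pd.DataFrame, columns=None) -> CovariateTable:
    """Convert covariate columns to z-scores (sample sd, n-1 denominator).

    Non-numeric columns and columns outside ``columns`` pass through
    unchanged.  A constant column raises, naming the column.
    """
    df = table.copy()
    if columns is None:
        columns = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    center, scale = {}, {}
    for c in columns:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"covariate {c!r} is constant; cannot standardize")
        center[c], scale[c] = x.mean(), sd
        df[c] = (x - center[c]) / sd
    return CovariateTable(df, pd.Series(center), pd.Series(scale))


def screen_collinearity(table, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Spearman rank correlations with a collinearity flag.

    Pairs with \\|rho\\| >= ``threshold`` must not co-occur in one model.
    """
    df = table.data if isinstance(table, CovariateTable) else table
    cols = [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    if len(cols) < 2:
        raise ValueError("need at least two covariates to screen")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        rho = stats.spearmanr(df[a], df[b]).statistic
        rows.append((a, b, rho, bool(abs(rho) >= threshold)))
    return pd.DataFrame(rows, columns=["var1", "var2", "rho", "flagged"])


def barred_pairs(screen: pd.DataFrame) -> set[frozenset]:
    """Covariate pairs barred from co-occurring in a model."""
    return {frozenset((r.var1, r.var2)) for r in screen.itertuples() if r.flagged}


# ---------------------------------------------------------------------------
# natural parameters <-> cell probabilities


def natural_to_psi(f1, f2, f12):
    """Map natural parameters to (psi11, psi10, psi01, psi00).

    psi00 = 1/Z, psi10 = e^f1/Z, psi01 = e^f2/Z, psi11 = e^(f1+f2+f12)/Z,
    Z = 1 + e^f1 + e^f2 + e^(f1+f2+f12); computed in log space.
    """
    f1, f2, f12 = np.broadcast_arrays(*np.atleast_1d(f1, f2, f12))
    if not (np.isfinite(f1).all() and np.isfinite(f2).all() and np.isfinite(f12).all()):
        raise ValueError("natural parameters must be finite")
    eta = np.stack([f1 + f2 + f12, f1, f2, np.zeros_like(f1)], axis=-1)
    logpsi = eta - logsumexp(eta, axis=-1, keepdims=True)
    psi = np.exp(logpsi)
    return psi if psi.shape[:-1] else psi  # (..., 4) in state order 11,10,01,00


def psi_to_natural(psi):
    """Inverse of :func:`natural_to_psi` (psi in state order 11,10,01,00)."""
    psi = np.asarray(psi, dtype=float)
    p11, p10, p01, p00 = np.moveaxis(psi, -1, 0)
    f1 = np.log(p10 / p00)
    f2 = np.log(p01 / p00)
    f12 = np.log(p11 * p00 / (p01 * p10))
    return f1, f2, f12


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model.

    Occupancy formulas hold at most one covariate per natural parameter (an
    anti-overparameterization rule suited to sparse felid data); empty means
    intercept-only.  ``fix_f12_zero`` drops gamma entirely (independence
    null).  Detection formulas may use site covariates or ``"effort"``.
    """

    label: str
    f1: tuple[str, ...] = ()
    f2: tuple[str, ...] = ()
    f12: tuple[str, ...] = ()
    fix_f12_zero: bool = False
    p1: tuple[str, ...] = ()
    p2: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("f1", "f2", "f12"):
            val = tuple(getattr(self, name))
            object.__setattr__(self, name, val)
            if len(val) > 1:
                raise ValueError(f"at most one occupancy covariate allowed on {name}")
        object.__setattr__(self, "p1", tuple(self.p1))
        object.__setattr__(self, "p2", tuple(self.p2))
        if self.fix_f12_zero and self.f12:
            raise ValueError("cannot put covariates on f12 when it is fixed at 0")

    def covariates_used(self) -> set[str]:
        return set(self.f1) | set(self.f2) | set(self.f12) | set(self.p1) | set(self.p2)

    def violates(self, barred: set[frozenset]) -> bool:
        used = self.covariates_used()
        return any(pair <= used for pair in barred)


def default_label(spec_like: "ModelSpec") -> str:
    def fmt(covs):
        return ",".join(covs) if covs else "."

    s = spec_like
    f12 = "=0" if s.fix_f12_zero else f"({fmt(s.f12)})"
    return (
        f"psi1({fmt(s.f1)}) psi2({fmt(s.f2)}) psi12{f12} "
        f"p1({fmt(s.p1)}) p2({fmt(s.p2)})"
    )


# ---------------------------------------------------------------------------
# likelihood


def _site_logdet(y: np.ndarray, logp: np.ndarray, log1mp: np.ndarray, mask: np.ndarray):
    """Per-site log detection likelihood given presence, and all-zero flag."""
    y0 = np.where(mask, y, 0.0)
    # select rather than multiply so p = 0 or 1 stays exact (0 * -inf traps)
    contrib = np.where(mask, np.where(y0 > 0.5, logp, log1mp), 0.0)
    logA = contrib.sum(axis=1)
    none_detected = (y0 == 0).all(axis=1)
    return logA, none_detected


def loglik_sites(y1, y2, p1, p2, psi):
    """Vectorised marginal log-likelihood contributions per site.

    ``y1, y2``: (n, J) histories with NaN at zero-effort occasions;
    ``p1, p2``: (n, J) detection probabilities; ``psi``: (n, 4) cell
    probabilities in state order (11, 10, 01, 00).
    """
    y1 = np.atleast_2d(np.asarray(y1, float))
    y2 = np.atleast_2d(np.asarray(y2, float))
    p1 = np.broadcast_to(np.atleast_2d(p1), y1.shape)
    p2 = np.broadcast_to(np.atleast_2d(p2), y2.shape)
    psi = np.atleast_2d(psi)
    m1, m2 = np.isfinite(y1), np.isfinite(y2)

    with np.errstate(divide="ignore"):
        logpsi = np.log(psi)
        lA1, none1 = _site_logdet(y1, np.log(p1), np.log1p(-p1), m1)
        lA2, none2 = _site_logdet(y2, np.log(p2), np.log1p(-p2), m2)
    neg_inf = -np.inf
    zero_if = lambda flag: np.where(flag, 0.0, neg_inf)  # noqa: E731
    terms = np.stack(
        [
            logpsi[:, 0] + lA1 + lA2,
            logpsi[:, 1] + lA1 + zero_if(none2),
            logpsi[:, 2] + zero_if(none1) + lA2,
            logpsi[:, 3] + zero_if(none1) + zero_if(none2),
        ]
    )
    return logsumexp(terms, axis=0)


def site_loglik(y_site: dict, p_site: dict, psi) -> float:
    """Log-likelihood of one site's two-species history.

    ``y_site``/``p_site`` map species position (1, 2) to occasion vectors;
    NaN entries of y mark zero-effort occasions and are excluded.  A
    detection recorded in an excluded occasion raises.
    """
    y1, y2 = (np.asarray(y_site[k], float) for k in (1, 2))
    for y in (y1, y2):
        pass
    p1, p2 = (np.asarray(p_site[k], float) for k in (1, 2))
    psi = np.asarray(psi, float)
    if psi.min() < 0 or abs(psi.sum() - 1) > 1e-8:
        raise ValueError("psi must be a probability 4-vector")
    return float(loglik_sites(y1, y2, p1, p2, psi[None, :])[0])


# ---------------------------------------------------------------------------
# fitting


@dataclass
class TwoSpeciesModel:
    """A fitted two-species occupancy model."""

    spec: ModelSpec
    param_names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    loglik: float
    k: int
    aic: float
    converged: bool
    n_sites: int
    covariate_names: dict = field(default_factory=dict)
    effort_scale: tuple[float, float] = (0.0, 1.0)

    def coef(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def coef_table(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, est, se in zip(self.param_names, self.estimates, self.se):
            lo, hi = wald_ci(est, se, level) if np.isfinite(se) else (np.nan, np.nan)
            rows.append((name, est, se, lo, hi, bool(np.isfinite(se) and (lo > 0 or hi < 0))))
        return pd.DataFrame(
            rows, columns=["parameter", "estimate", "se", "ci_lower", "ci_upper", "important"]
        )

    def natural_parameters(self, covariates: pd.DataFrame):
        """Evaluate (f1, f2, f12) linear predictors on covariate rows."""

        def linpred(prefix, covs):
            eta = np.full(len(covariates), self.coef(f"{prefix}:{INTERCEPT}"))
            for c in covs:
                eta = eta + self.coef(f"{prefix}:{c}") * covariates[c].to_numpy(float)
            return eta

        f1 = linpred("f1", self.spec.f1)
        f2 = linpred("f2", self.spec.f2)
        if self.spec.fix_f12_zero:
            f12 = np.zeros(len(covariates))
        else:
            f12 = linpred("f12", self.spec.f12)
        return f1, f2, f12


def _detection_design(spec_covs, data, effort_z):
    """(n_sites, J, k) design tensor for one species' detection model."""
    n, J = data.effort.shape
    cols = [np.ones((n, J))]
    for c in spec_covs:
        if c == "effort":
            cols.append(effort_z)
        else:
            x = data.site_covariates[c].to_numpy(float)
            cols.append(np.broadcast_to(x[:, None], (n, J)))
    return np.stack(cols, axis=-1)


def _occupancy_design(spec_covs, data):
    n = data.n_sites
    cols = [np.ones(n)]
    for c in spec_covs:
        cols.append(data.site_covariates[c].to_numpy(float))
    return np.stack(cols, axis=-1)


class _LikelihoodMachine:
    """Packs model parameters and evaluates the negative log-likelihood."""

    def __init__(self, spec: ModelSpec, data):
        needed = spec.covariates_used() - {"effort"}
        if needed:
            if data.site_covariates is None:
                raise ValueError("model uses covariates but data has none")
            missing = needed - set(data.site_covariates.columns)
            if missing:
                raise ValueError(f"covariates not found in data: {sorted(missing)}")
        self.spec = spec
        self.data = data
        sp1, sp2 = data.species_pair
        self.y1, self.y2 = data.y[sp1], data.y[sp2]
        self.mask = data.effort > 0
        obs = data.effort[self.mask]
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        self.effort_scale = (mu, sd if sd > 0 else 1.0)
        effort_z = np.where(self.mask, (data.effort - mu) / self.effort_scale[1], 0.0)
        self.X1 = _occupancy_design(spec.f1, data)
        self.X2 = _occupancy_design(spec.f2, data)
        self.X12 = None if spec.fix_f12_zero else _occupancy_design(spec.f12, data)
        self.D1 = _detection_design(spec.p1, data, effort_z)
        self.D2 = _detection_design(spec.p2, data, effort_z)
        self.names = (
            [f"f1:{c}" for c in (INTERCEPT, *spec.f1)]
            + [f"f2:{c}" for c in (INTERCEPT, *spec.f2)]
            + ([] if spec.fix_f12_zero else [f"f12:{c}" for c in (INTERCEPT, *spec.f12)])
            + [f"p1:{c}" for c in (INTERCEPT, *spec.p1)]
            + [f"p2:{c}" for c in (INTERCEPT, *spec.p2)]
        )
        self.k = len(self.names)
        sizes = [
            self.X1.shape[1],
            self.X2.shape[1],
            0 if spec.fix_f12_zero else self.X12.shape[1],
            self.D1.shape[-1],
            self.D2.shape[-1],
        ]
        self.splits = np.cumsum(sizes)[:-1]

    def unpack(self, theta):
        a, b, g, d1, d2 = np.split(np.asarray(theta, float), self.splits)
        return a, b, g, d1, d2

    def loglik(self, theta) -> float:
        a, b, g, d1, d2 = self.unpack(theta)
        f1 = self.X1 @ a
        f2 = self.X2 @ b
        f12 = np.zeros_like(f1) if self.spec.fix_f12_zero else self.X12 @ g
        psi = natural_to_psi(f1, f2, f12)
        p1 = expit(np.clip(self.D1 @ d1, -35, 35))
        p2 = expit(np.clip(self.D2 @ d2, -35, 35))
        # keep p strictly inside (0,1); detections at p=0 would be -inf
        eps = 1e-12
        p1 = np.clip(p1, eps, 1 - eps)
        p2 = np.clip(p2, eps, 1 - eps)
        return float(loglik_sites(self.y1, self.y2, p1, p2, psi).sum())

    def negloglik(self, theta) -> float:
        ll = self.loglik(theta)
        return np.inf if not np.isfinite(ll) else -ll


def _numeric_hessian(fun, x, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit(
    spec: ModelSpec,
    data,
    n_starts: int = 1,
    seed: int | None = None,
    maxiter: int = 1000,
) -> TwoSpeciesModel:
    """Maximum-likelihood fit of a two-species occupancy model.

    Uses L-BFGS-B from a zero start plus ``n_starts - 1`` seeded random
    restarts, keeping the best optimum.  Standard errors come from the
    inverse of the numerically differentiated observed information; a
    singular information matrix leaves them NaN.  Non-convergence is
    reported through ``converged`` rather than raised, so model-selection
    loops can drop such fits.
    """
    machine = _LikelihoodMachine(spec, data)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(machine.k)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(0.0, 0.75, machine.k))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            machine.negloglik,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll = -best.fun

    se = np.full(machine.k, np.nan)
    try:
        H = _numeric_hessian(machine.negloglik, theta)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.clip(d, 0, None)), np.nan)
    except np.linalg.LinAlgError:
        pass

    return TwoSpeciesModel(
        spec=spec,
        param_names=machine.names,
        estimates=theta,
        se=se,
        loglik=ll,
        k=machine.k,
        aic=-2.0 * ll + 2.0 * machine.k,
        converged=bool(best.success and np.isfinite(ll)),
        n_sites=data.n_sites,
        covariate_names={"f1": spec.f1, "f2": spec.f2, "f12": spec.f12},
        effort_scale=machine.effort_scale,
    )


# ---------------------------------------------------------------------------
# inference and selection


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval; z is taken as exactly 1.96 at the 95% level so that
    printed intervals round the way field reports do."""
    if se < 0:
        raise ValueError("se must be >= 0")
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(1 - (1 - level) / 2))
    return estimate - z * se, estimate + z * se


def model_table(models, support_delta: float = 2.0) -> pd.DataFrame:
    """AIC ranking with Akaike weights over converged candidate models.

    Non-converged fits are excluded.  Ties in AIC are broken by fewer
    parameters, then label.  ``supported`` flags dAIC < ``support_delta``.
    """
    fitted = [m for m in models if m.converged]
    if not fitted:
        raise ValueError("no converged models to rank")
    labels = [m.spec.label for m in fitted]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    df = pd.DataFrame(
        {
            "model": labels,
            "AIC": [m.aic for m in fitted],
            "k": [m.k for m in fitted],
            "logLik": [m.loglik for m in fitted],
        }
    ).sort_values(["AIC", "k", "model"], kind="mergesort").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    rel = np.exp(-df["dAIC"] / 2.0)
    df["weight"] = rel / rel.sum()
    df["supported"] = df["dAIC"] < support_delta
    return df[["model", "AIC", "dAIC", "weight", "k", "logLik", "supported"]]


def predict_occupancy(model: TwoSpeciesModel, grid: pd.DataFrame) -> pd.DataFrame:
    """Cell, marginal and conditional occupancy over a covariate grid.

    Grid covariates must be on the standardized scale used at fitting time.
    Conditionals are NaN where the conditioning probability is zero.
    """
    f1, f2, f12 = model.natural_parameters(grid)
    psi = natural_to_psi(f1, f2, f12)
    out = grid.copy().reset_index(drop=True)
    for i, name in enumerate(_STATES):
        out[name] = psi[:, i]
    out["marginal1"] = out["psi11"] + out["psi10"]
    out["marginal2"] = out["psi11"] + out["psi01"]

    def safe_div(num, den):
        den = np.asarray(den, float)
        return np.where(den > 0, np.asarray(num, float) / np.where(den > 0, den, 1.0), np.nan)

    out["psi1_given_2"] = safe_div(out["psi11"], out["psi11"] + out["psi01"])
    out["psi1_given_not2"] = safe_div(out["psi10"], out["psi10"] + out["psi00"])
    out["psi2_given_1"] = safe_div(out["psi11"], out["psi11"] + out["psi10"])
    out["psi2_given_not1"] = safe_div(out["psi01"], out["psi01"] + out["psi00"])
    return out
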