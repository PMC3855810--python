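"""Hierarchical Bayesian growth model with latent true growth.

Annual dbh growth of tree i of species j is predicted as a power function
of light and initial size,

    pred_ij = exp(a_gj + b_gj * x_i + c_j * log(dbh_i / 50 mm)),

with x_i the centered log light proxy.  The *true* growth of a tree varies
lognormally around the prediction (process error, species log-sd d_j), and
the *observed* growth differs from the true growth by a two-component
normal measurement-error mixture: a routine size-dependent error
SD1(dbh) = s0 + s1*dbh and a large size-independent error SD2 affecting a
fraction f of observations; both standard deviations scale inversely with
the census-interval length because growth is annualized.  Species
parameters follow community regressions on ln(abundance); the process
error d_j varies lognormally across the community (hyperparameters delta1,
delta2).  Latent true growth is sampled explicitly; species and hyper
parameters are updated one at a time (single-site Metropolis-Hastings),
with latent updates performed as an element-wise vectorized block (latents
are conditionally independent given the parameters, so each gets its own
accept/reject decision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from treelight.lightfield import LightField
from treelight.mcmc import (
    ADAPT_WINDOW,
    Trace,
    summarize,
    tune_steps,
)

_LOG_2PI = float(np.log(2 * np.pi))
DBH_CENTER_MM = 50.0


@dataclass(frozen=True)
class ErrorModel:
    """Two-component dbh measurement-error mixture.

    ``SD1(dbh) = s0 + s1 * dbh`` (mm, routine error) applies to a fraction
    1 - f of observations; the large error ``SD2`` (decimal slips, record
    mix-ups) to the remaining fraction f.  Both SDs are divided by the
    interval length when applied to annualized growth.  Defaults follow
    published dbh-remeasurement error estimates for tropical censuses.
    """

    s0: float = 0.927
    s1: float = 0.0038
    sd2: float = 25.6
    f: float = 0.027

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.sd2 <= 0 or self.s1 < 0:
            raise ValueError("error SDs must be positive")
        if not 0 <= self.f < 1:
            raise ValueError("large-error fraction must be in [0, 1)")

    def sd1(self, dbh_mm) -> np.ndarray:
        return self.s0 + self.s1 * np.asarray(dbh_mm, dtype=float)


@dataclass(frozen=True)
class GrowthHypers:
    """Community-level hyperparameters of the growth model.

    The three regressions on ln(abundance) default to posterior point
    estimates from a published canopy-index fit (first census interval);
    the community lognormal for the process error d_j (delta1, delta2) is a
    package default chosen to give a median species process log-sd of 0.6.
    """

    alpha_g1: float = -0.06
    alpha_g2: float = -0.06
    sigma_ga: float = 0.48
    beta_g1: float = 0.86
    beta_g2: float = -0.07
    sigma_gb: float = 0.16
    gamma_1: float = -0.21
    gamma_2: float = 0.04
    sigma_g: float = 0.26
    delta_1: float = float(np.log(0.6))
    delta_2: float = 0.4

    def __post_init__(self) -> None:
        if min(self.sigma_ga, self.sigma_gb, self.sigma_g, self.delta_2) <= 0:
            raise ValueError("hyper spreads must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.alpha_g1, self.alpha_g2, self.sigma_ga,
                self.beta_g1, self.beta_g2, self.sigma_gb,
                self.gamma_1, self.gamma_2, self.sigma_g,
                self.delta_1, self.delta_2,
            ]
        )


HYPER_NAMES = [
    "alpha_g1", "alpha_g2", "sigma_ga",
    "beta_g1", "beta_g2", "sigma_gb",
    "gamma_1", "gamma_2", "sigma_g",
    "delta_1", "delta_2",
]
#: Indices of hyperparameters constrained to be positive.
_POSITIVE_HYPERS = [2, 5, 8, 10]


def predict_growth(a, b, c, centered_log_light, dbh_mm):
    """Predicted annual growth (mm/yr): exp(a + b*x + c*log(dbh/50))."""
    dbh = np.asarray(dbh_mm, dtype=float)
    if (dbh <= 0).any():
        raise ValueError("dbh must be positive")
    return np.exp(
        np.asarray(a, float)
        + np.asarray(b, float) * np.asarray(centered_log_light, float)
        + np.asarray(c, float) * np.log(dbh / DBH_CENTER_MM)
    )


def obs_loglik(obs, true, dbh_mm, interval_years, error: ErrorModel):
    """Log density of observed given true annual growth (mixture of normals).

    Standard deviations are divided by the interval length: the raw dbh
    error is spread over ``interval_years`` of annualized growth.
    """
    obs = np.asarray(obs, float)
    true = np.asarray(true, float)
    years = np.asarray(interval_years, float)
    if (years <= 0).any():
        raise ValueError("interval length must be positive")
    resid = obs - true
    s1 = error.sd1(dbh_mm) / years
    s2 = error.sd2 / years
    d1 = np.exp(-0.5 * (resid / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    d2 = np.exp(-0.5 * (resid / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    dens = (1.0 - error.f) * d1 + error.f * d2
    with np.errstate(divide="ignore"):
        return np.log(dens)


def process_loglik(true, pred, d):
    """Lognormal log density of true growth: log-median log(pred), log-sd d.

    The error scales multiplicatively with predicted growth; the median of
    the implied distribution of true growth equals the prediction.
    """
    true = np.asarray(true, float)
    pred = np.asarray(pred, float)
    d = np.asarray(d, float)
    if (pred <= 0).any() or (d <= 0).any():
        raise ValueError("pred and d must be positive")
    ok = true > 0
    lt = np.log(true, where=ok, out=np.zeros_like(true, dtype=float))
    z = (lt - np.log(pred)) / d
    # -log(true * d * sqrt(2 pi)) - z^2/2
    val = -lt - np.log(d) - 0.5 * _LOG_2PI - 0.5 * z**2
    out = np.where(ok, val, -np.inf)
    if out.ndim == 0:
        return float(out)
    return out


def _norm_sum(x, loc, sd):
    resid = np.asarray(x, float) - loc
    n = resid.size
    return float(-0.5 * n * _LOG_2PI - n * np.log(sd) - 0.5 * np.sum(resid**2) / sd**2)


def log_posterior(
    params: pd.DataFrame,
    hypers: GrowthHypers,
    latent_true: np.ndarray,
    records: pd.DataFrame,
    ln_abundance: pd.Series,
    error: ErrorModel,
    light_center: float = 0.0,
) -> float:
    """Full log posterior at explicit values (reference entry point).

    ``params`` has columns a_g, b_g, c, d indexed by species_id; ``records``
    needs columns species_id, dbh0, obs_growth, interval_years, log_light.
    """
    if (params["d"] <= 0).any():
        return -np.inf
    x = records["log_light"].to_numpy(float) - light_center
    sp = records["species_id"].to_numpy()
    a = params["a_g"].reindex(sp).to_numpy(float)
    b = params["b_g"].reindex(sp).to_numpy(float)
    c = params["c"].reindex(sp).to_numpy(float)
    d = params["d"].reindex(sp).to_numpy(float)
    pred = predict_growth(a, b, c, x, records["dbh0"].to_numpy(float))
    total = float(
        np.sum(
            obs_loglik(
                records["obs_growth"].to_numpy(float),
                latent_true,
                records["dbh0"].to_numpy(float),
                records["interval_years"].to_numpy(float),
                error,
            )
        )
    )
    total += float(np.sum(process_loglik(latent_true, pred, d)))
    la = ln_abundance.reindex(params.index).to_numpy(float)
    total += _norm_sum(params["a_g"], hypers.alpha_g1 + hypers.alpha_g2 * la, hypers.sigma_ga)
    total += _norm_sum(params["b_g"], hypers.beta_g1 + hypers.beta_g2 * la, hypers.sigma_gb)
    total += _norm_sum(params["c"], hypers.gamma_1 + hypers.gamma_2 * la, hypers.sigma_g)
    logd = np.log(params["d"].to_numpy(float))
    total += _norm_sum(logd, hypers.delta_1, hypers.delta_2) - float(np.sum(logd))
    return total


@dataclass
class GrowthMCMCConfig:
    """Run lengths for the growth sampler, in full cycles.

    One cycle updates every species parameter and hyperparameter once
    (single-site, cyclic order) and every latent true growth once.  Desk
    defaults (600 burn-in + 800 sampling cycles) correspond to roughly
    2 x 10^5 single-site updates each for a few-thousand-tree dataset.
    """

    burn_cycles: int = 600
    sample_cycles: int = 800
    seed: int = 0
    n_chains: int = 1


@dataclass
class GrowthFit:
    species: list[str]
    traces: list[Trace]
    summary: pd.DataFrame
    rhat: pd.Series
    acceptance: list[float]
    light_center: float
    latent_true: np.ndarray

    def species_summary(self) -> pd.DataFrame:
        rows = []
        for s in self.species:
            row = {"species_id": s}
            for p in ("a_g", "b_g", "c", "d"):
                stats = self.summary.loc[f"{p}[{s}]"]
                row[f"{p}_mean"] = stats["mean"]
                row[f"{p}_lo"] = stats["ci_low"]
                row[f"{p}_hi"] = stats["ci_high"]
            rows.append(row)
        return pd.DataFrame(rows).set_index("species_id")

    def hyper_summary(self) -> pd.DataFrame:
        return self.summary.loc[HYPER_NAMES]


class _GrowthSampler:
    """Single-site MH over species parameters and hypers, with an
    element-wise latent block; caches per-tree likelihood terms."""

    def __init__(self, records, x, ln_abun, species, error, rng):
        self.error = error
        self.rng = rng
        order = np.argsort(records["species_id"].to_numpy(), kind="stable")
        self.rec = records.iloc[order].reset_index(drop=True)
        self.obs = self.rec["obs_growth"].to_numpy(float)
        self.dbh = self.rec["dbh0"].to_numpy(float)
        self.years = self.rec["interval_years"].to_numpy(float)
        self.x = x[order]
        self.ldbh = np.log(self.dbh / DBH_CENTER_MM)
        sp_sorted = self.rec["species_id"].to_numpy()
        self.species = species
        # centered abundance covariate decorrelates hyper intercepts/slopes;
        # recorded draws are transformed back to the ln(abun) = 0 scale
        self.la_center = float(np.mean(ln_abun))
        self.ln_abun = ln_abun - self.la_center
        starts = np.searchsorted(sp_sorted, species, side="left")
        ends = np.searchsorted(sp_sorted, species, side="right")
        self.slices = [slice(s, e) for s, e in zip(starts, ends)]
        self.n_sp = len(species)
        self.n_trees = len(self.rec)
        # measurement-error SDs per tree (fixed)
        self.s1 = error.sd1(self.dbh) / self.years
        self.s2 = error.sd2 / self.years

        # state
        self.a = np.empty(self.n_sp)
        self.b = np.empty(self.n_sp)
        self.c = np.empty(self.n_sp)
        self.d = np.empty(self.n_sp)
        self.hyp = np.empty(11)
        self.true = np.empty(self.n_trees)

        # caches
        self.lpred = np.empty(self.n_trees)
        self.ltrue = np.empty(self.n_trees)
        self.proc = np.empty(self.n_trees)  # per-tree process log-density
        self.obs_ll = np.empty(self.n_trees)

        # step sizes
        self.steps_sp = np.full((self.n_sp, 4), 0.2)
        self.steps_hyp = np.full(11, 0.1)
        self.steps_lat = np.maximum(self.s1, 0.2)

    # -- likelihood pieces ------------------------------------------------
    def _obs_ll_vec(self, true, idx=slice(None)):
        resid = self.obs[idx] - true
        s1, s2 = self.s1[idx], self.s2[idx]
        f = self.error.f
        d1 = np.exp(-0.5 * (resid / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
        d2 = np.exp(-0.5 * (resid / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
        with np.errstate(divide="ignore"):
            return np.log((1 - f) * d1 + f * d2)

    def _proc_vec(self, ltrue, lpred, d):
        z = (ltrue - lpred) / d
        return -ltrue - np.log(d) - 0.5 * _LOG_2PI - 0.5 * z**2

    def _sp_hyper_ll(self):
        """Species-level log density terms given current hypers (vector, n_sp)."""
        (a1, a2, sa, b1, b2, sb, g1, g2, sg, d1, d2) = self.hyp
        la = self.ln_abun
        out = (
            -np.log(sa) - 0.5 * _LOG_2PI - 0.5 * ((self.a - a1 - a2 * la) / sa) ** 2
            - np.log(sb) - 0.5 * _LOG_2PI - 0.5 * ((self.b - b1 - b2 * la) / sb) ** 2
            - np.log(sg) - 0.5 * _LOG_2PI - 0.5 * ((self.c - g1 - g2 * la) / sg) ** 2
        )
        logd = np.log(self.d)
        out += -logd - np.log(d2) - 0.5 * _LOG_2PI - 0.5 * ((logd - d1) / d2) ** 2
        return out

    def init_state(self, hypers: GrowthHypers, b_init: float):
        for j, sl in enumerate(self.slices):
            pos = self.obs[sl][self.obs[sl] > 0]
            self.a[j] = np.log(np.median(pos)) if pos.size else np.log(0.5)
        self.b[:] = b_init
        self.c[:] = 0.0
        self.d[:] = 0.6
        self.hyp[:] = [
            float(np.mean(self.a)), 0.0, 0.5,
            b_init, 0.0, 0.3,
            0.0, 0.0, 0.3,
            np.log(0.6), 0.4,
        ]
        self.true = np.maximum(self.obs, 0.05)
        self._refresh()

    def _refresh(self):
        for j, sl in enumerate(self.slices):
            self.lpred[sl] = self.a[j] + self.b[j] * self.x[sl] + self.c[j] * self.ldbh[sl]
        self.ltrue = np.log(self.true)
        d_per_tree = np.repeat(self.d, [sl.stop - sl.start for sl in self.slices])
        self._d_tree = d_per_tree
        self.proc = self._proc_vec(self.ltrue, self.lpred, d_per_tree)
        self.obs_ll = self._obs_ll_vec(self.true)

    # -- updates ----------------------------------------------------------
    def update_species(self, j):
        """Cyclic single-site updates of a_g, b_g, c, d of species j."""
        sl = self.slices[j]
        accepts = np.zeros(4, dtype=bool)
        (a1, a2, sa, b1, b2, sb, g1, g2, sg, dd1, dd2) = self.hyp
        la = self.ln_abun[j]
        for p in range(4):
            step = self.steps_sp[j, p]
            z = step * self.rng.standard_normal()
            u = np.log(self.rng.uniform())
            if p < 3:
                cur = (self.a, self.b, self.c)[p][j]
                prop = cur + z
                lpred_new = self.lpred[sl] + (
                    z if p == 0 else z * (self.x[sl] if p == 1 else self.ldbh[sl])
                )
                proc_new = self._proc_vec(self.ltrue[sl], lpred_new, self.d[j])
                mu, sd = ((a1 + a2 * la, sa), (b1 + b2 * la, sb), (g1 + g2 * la, sg))[p]
                dlp = (
                    proc_new.sum() - self.proc[sl].sum()
                    - 0.5 * ((prop - mu) / sd) ** 2
                    + 0.5 * ((cur - mu) / sd) ** 2
                )
                if u < dlp:
                    (self.a, self.b, self.c)[p][j] = prop
                    self.lpred[sl] = lpred_new
                    self.proc[sl] = proc_new
                    accepts[p] = True
            else:
                cur = self.d[j]
                prop = cur + z
                if prop <= 0:
                    continue
                proc_new = self._proc_vec(self.ltrue[sl], self.lpred[sl], prop)
                dlp = (
                    proc_new.sum() - self.proc[sl].sum()
                    - np.log(prop) - 0.5 * ((np.log(prop) - dd1) / dd2) ** 2
                    + np.log(cur) + 0.5 * ((np.log(cur) - dd1) / dd2) ** 2
                )
                if u < dlp:
                    self.d[j] = prop
                    self.proc[sl] = proc_new
                    self._d_tree[sl] = prop
                    accepts[p] = True
        return accepts

    def update_hypers(self):
        accepts = np.zeros(11, dtype=bool)
        cur_ll = self._sp_hyper_ll().sum()
        for h in range(11):
            step = self.steps_hyp[h]
            prop = self.hyp[h] + step * self.rng.standard_normal()
            if h in _POSITIVE_HYPERS and prop <= 0:
                continue
            old = self.hyp[h]
            self.hyp[h] = prop
            new_ll = self._sp_hyper_ll().sum()
            if np.log(self.rng.uniform()) < new_ll - cur_ll:
                cur_ll = new_ll
                accepts[h] = True
            else:
                self.hyp[h] = old
        return accepts

    def update_latents(self):
        """Element-wise MH on latent true growth (conditionally independent)."""
        prop = self.true + self.steps_lat * self.rng.standard_normal(self.n_trees)
        ok = prop > 0
        prop_safe = np.where(ok, prop, 1.0)
        lprop = np.log(prop_safe)
        proc_new = self._proc_vec(lprop, self.lpred, self._d_tree)
        obs_new = self._obs_ll_vec(prop_safe)
        with np.errstate(invalid="ignore"):
            dlp = np.where(ok, proc_new + obs_new - self.proc - self.obs_ll, -np.inf)
        dlp = np.nan_to_num(dlp, nan=-np.inf)  # reject on degenerate comparisons
        accept = np.log(self.rng.uniform(size=self.n_trees)) < dlp
        self.true = np.where(accept, prop, self.true)
        self.ltrue = np.where(accept, lprop, self.ltrue)
        self.proc = np.where(accept, proc_new, self.proc)
        self.obs_ll = np.where(accept, obs_new, self.obs_ll)
        return accept

    def cycle(self):
        acc_sp = np.array([self.update_species(j) for j in range(self.n_sp)])
        acc_h = self.update_hypers()
        acc_l = self.update_latents()
        return acc_sp, acc_h, acc_l

    def state_vector(self):
        hyp = self.hyp.copy()
        for i1, i2 in ((0, 1), (3, 4), (6, 7)):  # intercepts back to ln(abun)=0
            hyp[i1] -= self.la_center * hyp[i2]
        return np.concatenate(
            [np.column_stack([self.a, self.b, self.c, self.d]).ravel(), hyp]
        )


def fit_growth(
    records: pd.DataFrame,
    light: LightField,
    abundance: pd.Series,
    error: ErrorModel = ErrorModel(),
    config: GrowthMCMCConfig = GrowthMCMCConfig(),
) -> GrowthFit:
    """Fit the hierarchical growth model.

    ``records`` needs columns tree_id, species_id, dbh0, obs_growth,
    interval_years; the light field is matched on tree_id, log-transformed
    if it is a CAI field, and centered internally.  Latents are initialized
    at max(observed growth, a small positive floor).  Step sizes adapt
    during burn-in toward 0.25 acceptance and freeze for sampling.
    """
    records = records.reset_index(drop=True)
    if len(records) == 0:
        raise ValueError("no growth records")
    light_s = light.to_series()
    vals = light_s.reindex(records["tree_id"]).to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("light field missing values for some trees")
    log_light = np.log(vals) if light.kind == "cai" else vals
    center = float(np.mean(log_light))
    x = log_light - center
    species = sorted(records["species_id"].unique())
    ln_abun = np.log(abundance.reindex(species).to_numpy(dtype=float))
    if np.isnan(ln_abun).any():
        raise ValueError("species missing from abundance table")

    names = []
    for s in species:
        names += [f"a_g[{s}]", f"b_g[{s}]", f"c[{s}]", f"d[{s}]"]
    names += HYPER_NAMES

    traces, acceptance = [], []
    latent_final = None
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain])
        sampler = _GrowthSampler(records, x, ln_abun, np.array(species), error, rng)
        sampler.init_state(GrowthHypers(), b_init=float(chain % 2))

        acc_sp = np.zeros((sampler.n_sp, 4))
        acc_h = np.zeros(11)
        acc_l = np.zeros(sampler.n_trees)
        for it in range(config.burn_cycles):
            a_sp, a_h, a_l = sampler.cycle()
            acc_sp += a_sp
            acc_h += a_h
            acc_l += a_l
            if (it + 1) % ADAPT_WINDOW == 0:
                sampler.steps_sp = tune_steps(acc_sp / ADAPT_WINDOW, sampler.steps_sp)
                sampler.steps_hyp = tune_steps(acc_h / ADAPT_WINDOW, sampler.steps_hyp)
                sampler.steps_lat = tune_steps(acc_l / ADAPT_WINDOW, sampler.steps_lat)
                acc_sp[:] = acc_h[:] = acc_l[:] = 0.0

        draws = np.empty((config.sample_cycles, len(names)))
        n_acc = 0.0
        n_prop = 0.0
        for it in range(config.sample_cycles):
            a_sp, a_h, a_l = sampler.cycle()
            n_acc += a_sp.sum() + a_h.sum()
            n_prop += a_sp.size + a_h.size
            draws[it] = sampler.state_vector()
        traces.append(Trace(names, draws, chain_id=chain))
        acceptance.append(n_acc / n_prop)
        latent_final = sampler.true.copy()

    if len(traces) >= 2:
        from treelight.mcmc import gelman_rubin

        rhat = gelman_rubin(traces)
    else:
        rhat = pd.Series(dtype=float)
    summary = summarize(traces)
    return GrowthFit(
        species=list(species),
        traces=traces,
        summary=summary,
        rhat=rhat,
        acceptance=acceptance,
        light_center=center,
        latent_true=latent_final,
    )
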