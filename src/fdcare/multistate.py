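"""Continuous-time multi-state Markov model for interval-censored panels.

The six FC states form a progression chain: instantaneous transitions are
permitted only between severity-adjacent living states (4<->5, 5<->2,
2<->3, 3<->1) plus every living state -> death (absorbing state 6).  Over a
finite observation interval any living state can nevertheless be reached,
because P(h) = exp(hQ) accumulates multi-step paths.

Transition intensities are parameterized on the log scale with
proportional-intensity covariate effects,

    q_rs(z) = exp(theta_rs + sum_c beta_rs,c * z_c),

so exp(beta) is a hazard ratio.  The panel likelihood is the product over
consecutive observation pairs of P(dt)[s_prev, s_next]; with exact death
times, a death contributes sum_r P(dt)[s_prev, r] * q_r6 instead.
Maximization is quasi-Newton on the log intensities; standard errors come
from the finite-difference Hessian at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .states import DEATH, LIVING_STATES, N_STATES, SEVERITY_ORDER

log = logging.getLogger(__name__)

#: covariate name -> function of (sex, age_band) giving the 0/1 design value
COVARIATE_DESIGN = {
    "female": lambda sex, band: 1.0 if sex == "female" else 0.0,
    "age70": lambda sex, band: 1.0 if band == "70+" else 0.0,
}


@dataclass(frozen=True)
class TransitionStructure:
    """Boolean mask of allowed instantaneous transitions on states 1..6."""

    allowed: tuple  # tuple of tuples, 6x6

    def __post_init__(self):
        a = np.asarray(self.allowed, dtype=bool)
        if a.shape != (N_STATES, N_STATES):
            raise ValueError("allowed mask must be 6x6")
        if a.diagonal().any():
            raise ValueError("mask must be irreflexive")
        if a[DEATH - 1].any():
            raise ValueError("no transition out of the absorbing death state")
        object.__setattr__(self, "allowed", tuple(map(tuple, a)))

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.allowed, dtype=bool)

    @property
    def transitions(self) -> list:
        """Allowed (from_state, to_state) pairs, 1-based, row-major order."""
        m = self.mask
        return [(r + 1, s + 1) for r in range(N_STATES) for s in range(N_STATES) if m[r, s]]

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


def chain_structure() -> TransitionStructure:
    """Severity-adjacent chain 4-5-2-3-1 (two-way) plus living -> death."""
    m = np.zeros((N_STATES, N_STATES), dtype=bool)
    for a, b in zip(SEVERITY_ORDER[:-1], SEVERITY_ORDER[1:]):
        m[a - 1, b - 1] = m[b - 1, a - 1] = True
    for s in LIVING_STATES:
        m[s - 1, DEATH - 1] = True
    return TransitionStructure(tuple(map(tuple, m)))


def full_structure() -> TransitionStructure:
    """All living <-> living transitions plus living -> death."""
    m = np.zeros((N_STATES, N_STATES), dtype=bool)
    for r in LIVING_STATES:
        for s in LIVING_STATES:
            if r != s:
                m[r - 1, s - 1] = True
        m[r - 1, DEATH - 1] = True
    return TransitionStructure(tuple(map(tuple, m)))


@dataclass
class IntensityModel:
    """Log-linear intensity model over an allowed-transition structure.

    ``theta[i]`` is the log baseline intensity of ``structure.transitions[i]``
    (per year).  ``beta`` maps (covariate, (from, to)) -> log hazard ratio;
    transitions absent from ``beta`` have no covariate effect.
    """

    structure: TransitionStructure
    theta: np.ndarray
    beta: dict = field(default_factory=dict)
    covariates: tuple = ()

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.structure.n_transitions,):
            raise ValueError("theta length must match the number of allowed transitions")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        for (cov, pair), b in self.beta.items():
            if cov not in self.covariates:
                raise ValueError(f"beta references unknown covariate {cov!r}")
            if pair not in self.structure.transitions:
                raise ValueError(f"beta references disallowed transition {pair}")
            if not np.isfinite(b):
                raise ValueError("beta must be finite")


def build_Q(model: IntensityModel, covariates: dict | None = None) -> np.ndarray:
    """Generator matrix at covariate values z (0/1 design)."""
    z = covariates or {}
    for c in z:
        if c not in model.covariates:
            raise ValueError(f"unknown covariate {c!r}")
    Q = np.zeros((N_STATES, N_STATES))
    for i, (r, s) in enumerate(model.structure.transitions):
        lin = model.theta[i]
        for cov in model.covariates:
            b = model.beta.get((cov, (r, s)), 0.0)
            lin += b * float(z.get(cov, 0.0))
        Q[r - 1, s - 1] = np.exp(lin)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, h: float) -> np.ndarray:
    """P(h) = exp(h*Q) via scaling-and-squaring Pade (scipy.linalg.expm)."""
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("Q must be finite")
    if h < 0:
        raise ValueError("horizon must be >= 0")
    P = expm(h * Q)
    # clip tiny numerical excursions only
    P[(P < 0) & (P > -1e-12)] = 0.0
    P[(P > 1) & (P < 1 + 1e-12)] = 1.0
    return P


def _design_values(sex, band, covariates):
    return tuple(COVARIATE_DESIGN[c](sex, band) for c in covariates)


def _pair_counts(dataset, covariates, exact_death):
    """Sufficient statistics: {(z, dt, s_prev, s_next): count} plus, with
    exact death handling, {(z, dt, s_prev): count} for death intervals."""
    df = dataset.data
    trans = {}
    deaths = {}
    for (sex, band), sub in df.groupby(["sex", "age_band"], sort=False):
        z = _design_values(sex, band, covariates)
        sub = sub.sort_values(["id", "time"])
        ids = sub["id"].to_numpy()
        t = sub["time"].to_numpy(dtype=float)
        s = sub["state"].to_numpy(dtype=int)
        same = ids[1:] == ids[:-1]
        dt = np.round(t[1:] - t[:-1], 10)
        if np.any(same & (dt <= 0)):
            raise ValueError("non-positive time increment within an individual")
        for d, sp, sn in zip(dt[same], s[:-1][same], s[1:][same]):
            if sp == DEATH:
                continue  # dead stays dead; no information
            if exact_death and sn == DEATH:
                key = (z, d, sp)
                deaths[key] = deaths.get(key, 0) + 1
            else:
                key = (z, d, sp, sn)
                trans[key] = trans.get(key, 0) + 1
    return trans, deaths


def panel_loglik(
    model: IntensityModel, dataset, exact_death: bool = False
) -> float:
    """Interval-censored panel log-likelihood (0 for single-observation ids)."""
    trans, deaths = _pair_counts(dataset, model.covariates, exact_death)
    return _loglik_from_counts(model, trans, deaths)


def _loglik_from_counts(model, trans, deaths):
    zs = {k[0] for k in trans} | {k[0] for k in deaths}
    Qs = {z: build_Q(model, dict(zip(model.covariates, z))) for z in zs}
    dts = {(k[0], k[1]) for k in trans} | {(k[0], k[1]) for k in deaths}
    Ps = {(z, d): transition_probability(Qs[z], d) for (z, d) in dts}
    ll = 0.0
    for (z, d, sp, sn), c in trans.items():
        p = Ps[(z, d)][sp - 1, sn - 1]
        if p <= 0.0:
            log.error(
                "transition %s -> %s over %.3g years has probability 0 "
                "under the structure", sp, sn, d,
            )
            return -np.inf
        ll += c * np.log(p)
    for (z, d, sp), c in deaths.items():
        q6 = Qs[z][:, DEATH - 1]
        dens = float(Ps[(z, d)][sp - 1, : DEATH - 1] @ q6[: DEATH - 1])
        if dens <= 0.0:
            log.error("death from state %s over %.3g years has density 0", sp, d)
            return -np.inf
        ll += c * np.log(dens)
    return float(ll)


@dataclass
class FittedMSM:
    model: IntensityModel
    loglik: float
    covariance: np.ndarray | None
    param_names: list
    converged: bool
    exact_death: bool = False
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def intensity_table(self) -> pd.DataFrame:
        """Baseline intensities with Wald 95% CIs (intensity scale)."""
        rows = []
        T = self.model.structure.n_transitions
        for i, (r, s) in enumerate(self.model.structure.transitions):
            se = np.sqrt(self.covariance[i, i]) if self.covariance is not None else np.nan
            th = self.model.theta[i]
            rows.append(
                dict(
                    from_state=r,
                    to_state=s,
                    intensity=np.exp(th),
                    lower=np.exp(th - 1.959963984540054 * se),
                    upper=np.exp(th + 1.959963984540054 * se),
                )
            )
        return pd.DataFrame(rows)

    def hazard_ratios(self) -> pd.DataFrame:
        """exp(beta) with Wald 95% CIs for every covariate effect."""
        T = self.model.structure.n_transitions
        rows = []
        for j, (cov, (r, s)) in enumerate(sorted(self.model.beta)):
            i = T + j
            b = self.model.beta[(cov, (r, s))]
            se = np.sqrt(self.covariance[i, i]) if self.covariance is not None else np.nan
            rows.append(
                dict(
                    covariate=cov,
                    from_state=r,
                    to_state=s,
                    hr=np.exp(b),
                    lower=np.exp(b - 1.959963984540054 * se),
                    upper=np.exp(b + 1.959963984540054 * se),
                )
            )
        return pd.DataFrame(rows)


def _pack(model):
    keys = sorted(model.beta)
    x = np.concatenate([model.theta, [model.beta[k] for k in keys]])
    names = [f"theta[{r}->{s}]" for r, s in model.structure.transitions]
    names += [f"beta[{cov},{r}->{s}]" for cov, (r, s) in keys]
    return x, keys, names


def _unpack(model, x, keys):
    T = model.structure.n_transitions
    beta = {k: float(v) for k, v in zip(keys, x[T:])}
    return replace(model, theta=np.array(x[:T]), beta=beta)


def _numeric_hessian(f, x, rel_step=1e-5):
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_msm(
    dataset,
    structure: TransitionStructure | None = None,
    covariates: tuple = (),
    covariate_transitions: dict | None = None,
    init_intensity: float = 0.1,
    init_model: IntensityModel | None = None,
    exact_death: bool = False,
    optimizer_opts: dict | None = None,
    compute_covariance: bool = True,
) -> FittedMSM:
    """Maximum-likelihood fit of the intensity model to a panel dataset.

    ``covariate_transitions`` restricts which transitions carry an effect for
    each covariate (default: every allowed living-state transition).
    Non-convergence is reported in the result, not raised; a singular
    Hessian leaves ``covariance`` as None.
    """
    structure = structure or chain_structure()
    if init_model is not None:
        model0 = init_model
    else:
        beta = {}
        for cov in covariates:
            pairs = (covariate_transitions or {}).get(cov, structure.transitions)
            for pair in pairs:
                beta[(cov, tuple(pair))] = 0.0
        model0 = IntensityModel(
            structure,
            np.full(structure.n_transitions, np.log(init_intensity)),
            beta,
            tuple(covariates),
        )
    trans, deaths = _pair_counts(dataset, model0.covariates, exact_death)

    x0, keys, names = _pack(model0)

    def nll(x):
        m = _unpack(model0, x, keys)
        ll = _loglik_from_counts(m, trans, deaths)
        return 1e12 if not np.isfinite(ll) else -ll

    opts = dict(maxiter=500)
    opts.update(optimizer_opts or {})
    res = minimize(nll, x0, method="L-BFGS-B", options=opts)
    success = bool(res.success)
    # polish with a simplex pass then a quasi-Newton restart (finite-difference
    # gradients can stall L-BFGS-B short of the maximum)
    res2 = minimize(nll, res.x, method="Nelder-Mead",
                    options=dict(maxiter=3000, fatol=1e-9, xatol=1e-6))
    if res2.fun <= res.fun:
        res = res2
        success = success or bool(res2.success)
    res3 = minimize(nll, res.x, method="L-BFGS-B", options=opts)
    if res3.fun <= res.fun:
        res = res3
        success = success or bool(res3.success)

    model = _unpack(model0, res.x, keys)
    covariance = None
    if compute_covariance:
        H = _numeric_hessian(nll, res.x)
        try:
            covariance = np.linalg.inv(H)
            if np.any(np.diag(covariance) <= 0):
                log.warning("Hessian not positive definite; SEs unavailable")
                covariance = None
        except np.linalg.LinAlgError:
            log.warning("singular Hessian; SEs unavailable")
    return FittedMSM(
        model, -res.fun, covariance, names, success,
        exact_death, res.message if isinstance(res.message, str) else "",
    )


def observed_prevalence(dataset, time_grid) -> pd.DataFrame:
    """State counts at each grid time, last observation carried forward.

    Individuals enter the risk set at their first observation; the death
    state, once observed, is carried forward indefinitely.
    """
    df = dataset.data.sort_values(["id", "time"])
    rows = []
    for t in time_grid:
        counts = np.zeros(N_STATES)
        for _, sub in df.groupby("id", sort=False):
            times = sub["time"].to_numpy()
            if times[0] > t:
                continue
            idx = np.searchsorted(times, t, side="right") - 1
            counts[int(sub["state"].iloc[idx]) - 1] += 1
        for s in range(1, N_STATES + 1):
            rows.append(dict(time=t, state=s, observed=counts[s - 1]))
    return pd.DataFrame(rows)


def expected_prevalence(fit: FittedMSM, dataset, time_grid) -> pd.DataFrame:
    """Counts implied by the fitted model: the observed first-wave state
    distribution of each covariate pattern propagated by exp(tQ)."""
    df = dataset.data.sort_values(["id", "time"])
    first = df.groupby("id", sort=False).first()
    rows = []
    for t in time_grid:
        counts = np.zeros(N_STATES)
        for (sex, band), sub in first.groupby(["sex", "age_band"], sort=False):
            z = dict(zip(fit.model.covariates,
                         _design_values(sex, band, fit.model.covariates)))
            Q = build_Q(fit.model, z)
            v0 = np.bincount(sub["state"].to_numpy() - 1, minlength=N_STATES).astype(float)
            t0 = float(sub["time"].min())
            counts += v0 @ transition_probability(Q, max(t - t0, 0.0))
        for s in range(1, N_STATES + 1):
            rows.append(dict(time=t, state=s, expected=counts[s - 1]))
    return pd.DataFrame(rows)


def goodness_of_fit(fit: FittedMSM, dataset, time_grid) -> tuple:
    """Pearson-type comparison of observed vs model-expected prevalence.

    Returns ``(table, T, p)`` where T = sum (obs-exp)^2/exp over state x time
    cells with positive expected count, and p comes from a chi-square
    reference with df = cells - fitted parameters (floored at 1).  For a
    simulation-based alternative see :func:`gof_bootstrap_p`.
    """
    time_grid = list(time_grid)
    if not time_grid:
        raise ValueError("time_grid must be non-empty")
    obs = observed_prevalence(dataset, time_grid)
    exp = expected_prevalence(fit, dataset, time_grid)
    table = obs.merge(exp, on=["time", "state"])
    use = table["expected"] > 0
    skipped = (~use) & (table["observed"] == 0)
    if skipped.any():
        log.info("%d cells with expected 0 and observed 0 skipped", skipped.sum())
    T = float(
        ((table.loc[use, "observed"] - table.loc[use, "expected"]) ** 2
         / table.loc[use, "expected"]).sum()
    )
    df_ = max(int(use.sum()) - fit.n_params, 1)
    return table, T, float(chi2.sf(T, df_))


def gof_bootstrap_p(fit, dataset, time_grid, B=50, seed=None):
    """Parametric-bootstrap reference for the prevalence statistic.

    Panels are re-simulated from the fitted intensities (same individuals,
    initial states and wave times); T is recomputed on each replicate
    without refitting.
    """
    from .synthetic import PanelDataset, simulate_ctmc_path

    rng = np.random.default_rng(seed)
    _, T_obs, _ = goodness_of_fit(fit, dataset, time_grid)
    df = dataset.data.sort_values(["id", "time"])
    exceed = 0
    for _ in range(B):
        rows = []
        for (sex, band), sub in df.groupby(["sex", "age_band"], sort=False):
            z = dict(zip(fit.model.covariates,
                         _design_values(sex, band, fit.model.covariates)))
            Q = build_Q(fit.model, z)
            for iid, ind in sub.groupby("id", sort=False):
                times = ind["time"].to_numpy(dtype=float)
                s0 = int(ind["state"].iloc[0])
                if s0 == DEATH:
                    states = [DEATH] * len(times)
                else:
                    et, es = simulate_ctmc_path(Q, s0, times[-1] - times[0], rng)
                    states = [
                        int(es[np.searchsorted(et, t - times[0], side="right") - 1])
                        for t in times
                    ]
                for t, s in zip(times, states):
                    rows.append((iid, sex, band, t, s))
        boot = PanelDataset(
            pd.DataFrame(rows, columns=["id", "sex", "age_band", "time", "state"])
        )
        _, T_b, _ = goodness_of_fit(fit, boot, time_grid)
        if T_b >= T_obs:
            exceed += 1
    return (1.0 + exceed) / (B + 1.0)


def lrt(null_fit: FittedMSM, alt_fit: FittedMSM) -> tuple:
    """Likelihood ratio test of nested intensity models: (G, df, p)."""
    G = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if G < -1e-6:
        raise ValueError(
            f"alternative log-likelihood below the null (G={G:.3g}); "
            "optimization failed"
        )
    G = max(G, 0.0)
    df_ = alt_fit.n_params - null_fit.n_params
    p = 1.0 if df_ == 0 else float(chi2.sf(G, df_))
    return G, df_, p


def compare_subset_fits(
    fitA: FittedMSM, fitB: FittedMSM, horizons=(5, 10, 15, 20)
) -> tuple:
    """Maximum |P_A - P_B| over horizons and covariate strata.

    Returns ``(max_diff, location)`` with location a dict naming the
    stratum, horizon and matrix cell of the maximum.
    """
    horizons = list(horizons)
    if not horizons:
        raise ValueError("horizons must be non-empty")
    if fitA.model.structure != fitB.model.structure:
        raise ValueError("fits have different transition structures")
    if fitA.model.covariates != fitB.model.covariates:
        raise ValueError("fits have different covariate sets")
    covs = fitA.model.covariates
    patterns = [()]
    for c in covs:
        patterns = [p + ((c, v),) for p in patterns for v in (0.0, 1.0)]
    best = (0.0, None)
    for pat in patterns:
        z = dict(pat)
        QA, QB = build_Q(fitA.model, z), build_Q(fitB.model, z)
        for h in horizons:
            D = np.abs(transition_probability(QA, h) - transition_probability(QB, h))
            i, j = np.unravel_index(np.argmax(D), D.shape)
            if D[i, j] > best[0]:
                best = (float(D[i, j]),
                        dict(covariates=z, horizon=h, from_state=i + 1, to_state=j + 1))
    return best
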