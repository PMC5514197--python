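"""Nonlinear mixed-effects estimation of the pulse-informed population model.

Step 2 of the workflow.  Pulse times per subject are fixed inputs (from the
deconvolution step); the population model carries log-normal
inter-individual random effects (eta) on baseline, initial concentration,
elimination rate, secretion width and pulse amplitude, a per-pulse
(between-occasion) log-normal effect (kappa) on amplitude, and a
proportional residual error.

The marginal likelihood is approximated subject by subject with a Laplace
approximation around the joint conditional mode of that subject's random
effects, with the residual variance evaluated at the conditional
predictions (the "interaction" convention for a proportional error model).
The objective reported is the usual -2 log-likelihood with the additive
``n log 2 pi`` data constant dropped, so differences between nested models
are directly chi-square comparable.

Per-subject conditional modes are found with a damped Gauss-Newton method:
the Jacobian columns of the linearly entering random effects (baseline,
initial concentration, amplitude and every kappa) are analytic, and only
the elimination-rate, width and drug-potency effects use central
differences.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pulse_model import (
    GAUSSIAN,
    PopulationModel,
    PulseShape,
    covariate_factor,
    omega2_to_cv,
    pulse_response_matrix,
    pulse_sensitivity_matrix,
)

__all__ = [
    "ModelDataset",
    "EstimationSpec",
    "FitResult",
    "ModelComparison",
    "CovariateScreen",
    "build_dataset",
    "neg2ll",
    "fit",
    "compare_models",
    "bic",
    "screen_covariates",
    "circadian_term",
]

ETA_ORDER = ("baseline", "a0", "kout", "secretion_sd", "amplitude")

_THETA_FIELDS = ("theta_amplitude", "theta_kout", "theta_secretion_sd",
                 "theta_baseline", "theta_a0", "exp_amplitude",
                 "exp_secretion_sd", "exp_baseline")
_DRUG_FIELDS = ("emax", "ea50", "gamma")
_IDENTITY_FIELDS = ("exp_amplitude", "exp_secretion_sd", "exp_baseline")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class ModelDataset:
    """Observations plus per-subject pulse times, covariates and doses.

    ``observations`` has columns ID, TIME (h), DV (mU/L).  Occasions are
    pre-stratified into unique subject ids.  ``doses`` maps a subject id to
    ``(amount_mg, dose_time_h)`` for dosed subjects.
    """

    observations: pd.DataFrame
    pulse_times: dict
    covariates: dict = field(default_factory=dict)
    doses: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        obs = self.observations
        for col in ("ID", "TIME", "DV"):
            if col not in obs.columns:
                raise ValueError(f"observations are missing column {col!r}")
        if len(obs) and (obs["TIME"] < 0).any():
            raise ValueError("observation times must be non-negative")
        if len(obs) and (obs["DV"] < 0).any():
            raise ValueError("DV must be non-negative")
        for sid in obs["ID"].unique():
            pt = np.asarray(self.pulse_times.get(sid, ()), dtype=float)
            if pt.size < 1:
                raise ValueError(f"subject {sid!r} has no pulse times")

    @property
    def subject_ids(self) -> list:
        return list(self.observations["ID"].unique())

    @property
    def n_obs(self) -> int:
        return int(len(self.observations))


@dataclass(frozen=True)
class EstimationSpec:
    """Which parameters are estimated and which random effects exist."""

    free_fixed: tuple = ()
    free_variances: tuple = ()
    iiv: tuple = ETA_ORDER
    bov_on_amplitude: bool = True
    error_model: str = "proportional"
    shape: PulseShape = GAUSSIAN
    # (parameter, covariate, form) records of included covariate terms;
    # the estimable form is the power model (the exponents are fixed
    # effects and may be freed through ``free_fixed``)
    covariate_terms: tuple = ()

    def __post_init__(self) -> None:
        if self.error_model != "proportional":
            raise ValueError("only the proportional error model is supported")
        allowed = set(ETA_ORDER) | {"bov_amplitude", "ea50", "sigma2"}
        for v in self.free_variances:
            if v not in allowed:
                raise ValueError(f"unknown variance name {v!r}")

    @property
    def free_names(self) -> tuple:
        return tuple(self.free_fixed) + tuple(
            v if v == "sigma2" else f"omega2_{v}" for v in self.free_variances)


@dataclass
class FitResult:
    pop: PopulationModel
    drug: Optional[object]
    ofv: float
    n_obs: int
    free_names: tuple
    se: dict = field(default_factory=dict)
    rse_pct: dict = field(default_factory=dict)
    cv_pct: dict = field(default_factory=dict)
    shrinkage_pct: dict = field(default_factory=dict)
    condition_number: Optional[float] = None
    ebes: dict = field(default_factory=dict)
    converged: bool = True
    inner_flags: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.free_names)

    def all_estimates(self) -> dict:
        return {name: _get_param(self.pop, self.drug, name)
                for name in self.free_names}


@dataclass(frozen=True)
class ModelComparison:
    delta_ofv: float
    extra_df: int
    forward_threshold: float
    backward_threshold: float
    forward_accept: bool
    backward_retain: bool


@dataclass
class CovariateScreen:
    candidates: pd.DataFrame
    notices: list = field(default_factory=list)
    forms: tuple = ("linear", "power", "exponential")


# ---------------------------------------------------------------------------
# parameter access / transforms
# ---------------------------------------------------------------------------

def _get_param(pop: PopulationModel, drug, name: str):
    if name in _THETA_FIELDS:
        return getattr(pop, name)
    if name in _DRUG_FIELDS:
        return getattr(drug, name)
    if name == "sigma2":
        return pop.sigma2_prop
    if name.startswith("omega2_"):
        key = name[len("omega2_"):]
        if key == "bov_amplitude":
            return pop.omega2_bov_amplitude
        return pop.omega2[key]
    raise KeyError(name)


def _set_param(pop: PopulationModel, drug, name: str, value: float):
    if name in _THETA_FIELDS:
        return dataclasses.replace(pop, **{name: value}), drug
    if name in _DRUG_FIELDS:
        return pop, dataclasses.replace(drug, **{name: value})
    if name == "sigma2":
        return dataclasses.replace(pop, sigma2_prop=value), drug
    if name.startswith("omega2_"):
        key = name[len("omega2_"):]
        if key == "bov_amplitude":
            return dataclasses.replace(pop, omega2_bov_amplitude=value), drug
        omega2 = dict(pop.omega2)
        omega2[key] = value
        return dataclasses.replace(pop, omega2=omega2), drug
    raise KeyError(name)


GAMMA_MAX = 12.0  # Hill coefficients beyond ~10 are not biologically
# meaningful for drug effects and are indistinguishable on a 10-min grid;
# the bound also keeps the effect front resolvable by the convolution grid


def _to_internal(name: str, value: float) -> float:
    if name == "emax":
        return math.log1p(value)  # bounded below at -1
    if name == "gamma":  # logit scale on (0, GAMMA_MAX)
        v = min(max(value, 1e-6), GAMMA_MAX - 1e-6)
        return math.log(v / (GAMMA_MAX - v))
    if name in _IDENTITY_FIELDS:
        return value
    return math.log(max(value, 1e-12))


def _from_internal(name: str, u: float) -> float:
    if name == "emax":
        return math.expm1(u)
    if name == "gamma":
        return GAMMA_MAX / (1.0 + math.exp(-u))
    if name in _IDENTITY_FIELDS:
        return u
    return math.exp(u)


def _dnat_du(name: str, value: float) -> float:
    if name == "emax":
        return 1.0 + value
    if name == "gamma":
        return value * (GAMMA_MAX - value) / GAMMA_MAX
    if name in _IDENTITY_FIELDS:
        return 1.0
    return value


# ---------------------------------------------------------------------------
# per-subject machinery
# ---------------------------------------------------------------------------

def _effect_closure(emax, ea50, gamma, drug_half_life, dose, dose_time):
    """Hill effect of a decaying bolus plus its eta-EA50 derivative.

    Returns ``(effect, deffect)`` callables of time; ``deffect`` is the
    derivative of the effect with respect to the log-EA50 random effect,
    ``-gamma * emax * r / (1 + r)^2`` with ``r = (A(t)/ea50)^gamma``.
    """
    kd = math.log(2.0) / drug_half_life

    def _ratio(tau):
        tau = np.asarray(tau, dtype=float)
        amt = np.where(tau >= dose_time,
                       dose * np.exp(-kd * np.maximum(tau - dose_time, 0.0)), 0.0)
        return (amt / ea50) ** gamma

    def eff(tau):
        r = _ratio(tau)
        return emax * np.where(r > 1e100, 1.0, r / (1.0 + r))

    def deff(tau):
        r = _ratio(tau)
        s = np.where(r > 1e100, 1.0 / np.maximum(r, 1.0), r / (1.0 + r) ** 2)
        return -gamma * emax * s

    return eff, deff


class _Subject:
    """Pre-extracted data and the Laplace machinery for one subject."""

    __slots__ = ("sid", "t", "y", "pt", "tbw", "dose", "eta_names", "has_ea50",
                 "n_kappa", "dim", "O_inv", "O_logdet", "fine_m")

    def __init__(self, sid, t, y, pt, tbw, dose):
        self.sid = sid
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pt = np.asarray(pt, dtype=float)
        self.tbw = tbw
        self.dose = dose

    def configure(self, pop: PopulationModel, spec: EstimationSpec, drug):
        self.eta_names = [n for n in spec.iiv if pop.omega2.get(n, 0.0) > 0.0]
        self.has_ea50 = bool(drug is not None and self.dose is not None
                             and pop.omega2.get("ea50", 0.0) > 0.0)
        self.n_kappa = (self.pt.size
                        if spec.bov_on_amplitude and pop.omega2_bov_amplitude > 0.0
                        else 0)
        self.dim = len(self.eta_names) + int(self.has_ea50) + self.n_kappa
        # freeze the convolution refinement at the typical width so the
        # prediction stays smooth in the perturbed random effects
        self.fine_m = None
        if self.dose is not None and self.t.size > 1:
            ref = pop.tbw_reference
            tbw = self.tbw if self.tbw is not None else ref
            sd_typ = covariate_factor(pop.theta_secretion_sd, tbw,
                                      pop.exp_secretion_sd, ref)
            step = float(self.t[1] - self.t[0])
            self.fine_m = min(max(1, int(math.ceil(step / (sd_typ / 20.0)))), 600)
        if self.dim == 0:
            self.O_inv = np.zeros((0, 0))
            self.O_logdet = 0.0
            return
        O = np.zeros((self.dim, self.dim))
        for i, n in enumerate(self.eta_names):
            O[i, i] = pop.omega2[n]
        cov = pop.omega_block_baseline_amplitude_cov
        if (cov is not None and "baseline" in self.eta_names
                and "amplitude" in self.eta_names):
            i = self.eta_names.index("baseline")
            j = self.eta_names.index("amplitude")
            O[i, j] = O[j, i] = cov
        k = len(self.eta_names)
        if self.has_ea50:
            O[k, k] = pop.omega2["ea50"]
            k += 1
        for i in range(self.n_kappa):
            O[k + i, k + i] = pop.omega2_bov_amplitude
        L = np.linalg.cholesky(O)
        self.O_logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        self.O_inv = np.linalg.inv(O)

    # -- prediction ---------------------------------------------------------

    def _realize(self, pop: PopulationModel, drug, b):
        ne = len(self.eta_names)
        eta = dict(zip(self.eta_names, b[:ne]))
        k = ne
        eta_ea50 = 0.0
        if self.has_ea50:
            eta_ea50 = b[k]
            k += 1
        kappas = b[k:] if self.n_kappa else np.zeros(self.pt.size)
        ref = pop.tbw_reference
        tbw = self.tbw if self.tbw is not None else ref
        baseline = covariate_factor(pop.theta_baseline, tbw, pop.exp_baseline,
                                    ref) * math.exp(eta.get("baseline", 0.0))
        a0 = pop.theta_a0 * math.exp(eta.get("a0", 0.0))
        kout = pop.theta_kout * math.exp(eta.get("kout", 0.0))
        sd = covariate_factor(pop.theta_secretion_sd, tbw, pop.exp_secretion_sd,
                              ref) * math.exp(eta.get("secretion_sd", 0.0))
        amp_typ = covariate_factor(pop.theta_amplitude, tbw, pop.exp_amplitude,
                                   ref) * math.exp(eta.get("amplitude", 0.0))
        amps = amp_typ * np.exp(kappas)
        effect = deffect = None
        if drug is not None and self.dose is not None and drug.emax != 0.0:
            amount, dose_time = self.dose
            effect, deffect = _effect_closure(
                drug.emax, drug.ea50 * math.exp(eta_ea50), drug.gamma,
                drug.half_life, amount, dose_time)
        return baseline, a0, kout, sd, amps, effect, deffect

    def predict_parts(self, pop, spec, drug, b):
        (baseline, a0, kout, sd, amps, effect,
         deffect) = self._realize(pop, drug, b)
        t0 = float(self.t[0])
        decay = np.exp(-kout * np.maximum(self.t - t0, 0.0))
        P = pulse_response_matrix(self.t, t0, kout, self.pt, sd, spec.shape,
                                  effect, self.fine_m)
        f = baseline * (1.0 - decay) + a0 * decay + amps @ P
        return f, decay, P, amps, baseline, a0, kout, sd, deffect

    def predict(self, pop, spec, drug, b):
        return self.predict_parts(pop, spec, drug, b)[0]

    def jacobian(self, pop, spec, drug, b, parts):
        """d f / d b.

        Columns for the log-linearly entering effects (baseline, initial
        concentration, amplitude, kappas) are analytic; so is the EA50
        column (a finite difference cannot resolve the shift of a steep
        effect front between grid nodes and would under-measure it,
        deflating the Laplace determinant); elimination rate and width use
        forward differences.
        """
        f, decay, P, amps, baseline, a0, kout, sd, deffect = parts
        ne = len(self.eta_names)
        J = np.empty((self.t.size, self.dim))
        fd_names = []
        for i, n in enumerate(self.eta_names):
            if n == "baseline":
                J[:, i] = baseline * (1.0 - decay)
            elif n == "a0":
                J[:, i] = a0 * decay
            elif n == "amplitude":
                J[:, i] = amps @ P
            else:  # kout, secretion_sd: finite difference
                fd_names.append(i)
        if self.has_ea50:
            if deffect is not None:
                M = pulse_sensitivity_matrix(self.t, float(self.t[0]), kout,
                                             self.pt, sd, deffect, self.fine_m)
                J[:, ne] = amps @ M
            else:
                J[:, ne] = 0.0
        k = ne + int(self.has_ea50)
        for i in range(self.n_kappa):
            J[:, k + i] = amps[i] * P[i]
        h = 1e-5
        for i in fd_names:
            bp = b.copy(); bp[i] += h
            J[:, i] = (self.predict(pop, spec, drug, bp) - f) / h
        return J

    # -- Laplace objective ---------------------------------------------------

    def penalized(self, pop, spec, drug, b, sigma2):
        f = self.predict(pop, spec, drug, b)
        f = np.maximum(f, 1e-10)
        res = self.y - f
        v = sigma2 * f * f
        q = float(np.sum(np.log(v) + res * res / v))
        if self.dim:
            q += float(b @ self.O_inv @ b)
        return q, f

    def laplace_neg2ll(self, pop, spec, drug, sigma2, b0=None,
                       max_iter=300):
        """Conditional-mode search + Laplace -2 log-likelihood contribution.

        Iterates until the penalized objective stops improving (absolute
        progress below 1e-4 per step with a small gradient), which bounds
        the mode error's second-order effect on the contribution well below
        the outer optimizer's tolerance.  Returns
        ``(contribution, b_hat, converged)``.
        """
        if self.dim == 0:
            q, _ = self.penalized(pop, spec, drug, np.zeros(0), sigma2)
            return q, np.zeros(0), True
        b = np.zeros(self.dim) if b0 is None or b0.size != self.dim else b0.copy()
        lam = 1e-6
        converged = False
        q, _ = self.penalized(pop, spec, drug, b, sigma2)
        J = None
        j_current = False  # whether J was evaluated at the final b
        for _ in range(max_iter):
            q_before = q
            parts = self.predict_parts(pop, spec, drug, b)
            f = np.maximum(parts[0], 1e-10)
            res = self.y - f
            v = sigma2 * f * f
            J = self.jacobian(pop, spec, drug, b, parts)
            j_current = True
            last_parts = parts
            dqdf = 2.0 / f - 2.0 * res / v - 2.0 * res * res / (v * f)
            grad = J.T @ dqdf + 2.0 * self.O_inv @ b
            gmax = float(np.max(np.abs(grad)))
            if gmax < 1e-6 * (1.0 + abs(q)):
                converged = True
                break
            # Newton Hessian: exact second derivative of the data terms in f
            # plus the curvature of the multiplicative (log-scale) effects;
            # Levenberg damping guards the regions where it is indefinite
            w2 = (-2.0 / f**2 + 2.0 / v + 8.0 * res / (v * f)
                  + 6.0 * res * res / (v * f * f))
            H = J.T @ (J * w2[:, None]) + 2.0 * self.O_inv
            curv = J.T @ dqdf  # sum_t dq/df * d2f/db2 for log-scale effects
            for i, n in enumerate(self.eta_names):
                if n in ("baseline", "a0", "amplitude"):
                    H[i, i] += curv[i]
            k0 = len(self.eta_names) + int(self.has_ea50)
            if self.n_kappa:
                idx = np.arange(k0, k0 + self.n_kappa)
                H[idx, idx] += curv[idx]
                if "amplitude" in self.eta_names:
                    ia = self.eta_names.index("amplitude")
                    H[ia, idx] += curv[idx]
                    H[idx, ia] += curv[idx]
            step_ok = False
            for _ in range(25):
                try:
                    step = np.linalg.solve(H + lam * np.eye(self.dim), -grad)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                if not np.all(np.isfinite(step)):
                    lam *= 10.0
                    continue
                # trust region: log-scale random effects never need to move
                # more than a few units per iteration
                biggest = float(np.max(np.abs(step)))
                if biggest > 3.0:
                    step *= 3.0 / biggest
                b_new = np.clip(b + step, -15.0, 15.0)
                q_new, _ = self.penalized(pop, spec, drug, b_new, sigma2)
                if q_new < q:
                    b = b_new
                    q = q_new
                    lam = max(lam / 3.0, 1e-10)
                    step_ok = True
                    j_current = False
                    break
                lam *= 10.0
                if lam > 1e10:
                    break
            if not step_ok:
                converged = gmax < 1.0
                break
            if q_before - q < 1e-4 and gmax < 1.0:
                converged = True
                break
        # Laplace: -2 ln integral = q(b^) + ln|Omega| + ln|J'V^-1 J + Omega^-1|
        # (J must be evaluated at the final mode: the loop may exit right
        # after an accepted step, leaving its J one step stale)
        if not j_current or J is None:
            parts = self.predict_parts(pop, spec, drug, b)
            J = self.jacobian(pop, spec, drug, b, parts)
        else:
            parts = last_parts
        f = np.maximum(parts[0], 1e-10)
        v = sigma2 * f * f
        A = J.T @ (J / v[:, None]) + self.O_inv
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:  # pragma: no cover - A is PSD by construction
            logdet = 0.0
            converged = False
        return q + self.O_logdet + logdet, b, converged


def _prepare_subjects(data: ModelDataset) -> list:
    subjects = []
    for sid, g in data.observations.groupby("ID", sort=False):
        tbw = None
        cov = data.covariates.get(sid)
        if cov:
            tbw = cov.get("tbw_pct")
        subjects.append(_Subject(sid, g["TIME"].to_numpy(), g["DV"].to_numpy(),
                                 np.asarray(data.pulse_times[sid], dtype=float),
                                 tbw, data.doses.get(sid)))
    return subjects


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_dataset(profiles, decon_results, covariates=None) -> ModelDataset:
    """Merge observation series with their deconvolution results.

    Each (subject, occasion) pair becomes a unique model subject id
    ``"subject:occasion"`` (occasions stratified).  ``decon_results`` is a
    mapping ``(subject_id, occasion) -> DeconvolutionResult`` or a sequence
    in the same order as ``profiles``.
    """
    covariates = covariates or {}
    if not isinstance(decon_results, Mapping):
        decon_results = {(r.subject_id, r.occasion): r for r in decon_results}
    rows = []
    pulse_times = {}
    covs = {}
    for s in profiles:
        key = (s.subject_id, s.occasion)
        if key not in decon_results:
            raise ValueError(f"no deconvolution result for profile {key}")
        r = decon_results[key]
        uid = f"{s.subject_id}:{s.occasion}"
        for i in np.flatnonzero(s.mask):
            rows.append({"ID": uid, "TIME": s.scheduled_times[i],
                         "DV": s.mean_conc[i]})
        pulse_times[uid] = np.asarray([p.pulse_time for p in r.pulses])
        cv = covariates.get(key, covariates.get(s.subject_id, {}))
        covs[uid] = dict(cv)
    obs = pd.DataFrame(rows, columns=["ID", "TIME", "DV"])
    return ModelDataset(observations=obs, pulse_times=pulse_times,
                        covariates=covs)


def neg2ll(pop: PopulationModel, spec: EstimationSpec, data: ModelDataset,
           drug=None, inner_cache: Optional[dict] = None,
           subjects: Optional[list] = None, multi_start: bool = False):
    """Laplace-with-interaction -2 log-likelihood (OFV) plus EBEs.

    Returns ``(ofv, ebes, flags)``: ``ebes`` maps subject id to a dict with
    the named eta estimates and the kappa vector; ``flags`` maps subject id
    to the inner convergence status.  With ``multi_start`` each subject's
    conditional mode is searched from both the cached warm start and a cold
    start and the deeper (lower penalized objective) mode kept; the
    subject-level problems can be multimodal and a warm start left behind
    by an optimizer excursion may otherwise pin a shallow mode.
    """
    if subjects is None:
        subjects = _prepare_subjects(data)
    sigma2 = pop.sigma2_prop
    if not sigma2 > 0:
        raise ValueError("sigma2_prop must be positive for estimation")
    total = 0.0
    ebes: dict = {}
    flags: dict = {}
    for s in subjects:
        s.configure(pop, spec, drug)
        b0 = inner_cache.get(s.sid) if inner_cache is not None else None
        contrib, b_hat, ok = s.laplace_neg2ll(pop, spec, drug, sigma2, b0)
        if multi_start and s.dim and b0 is not None and np.any(b0 != 0.0):
            c2, b2, ok2 = s.laplace_neg2ll(pop, spec, drug, sigma2, None)
            q1 = s.penalized(pop, spec, drug, b_hat, sigma2)[0]
            q2 = s.penalized(pop, spec, drug, b2, sigma2)[0]
            if q2 < q1:
                contrib, b_hat, ok = c2, b2, ok2
        total += contrib
        flags[s.sid] = ok
        if inner_cache is not None:
            inner_cache[s.sid] = b_hat
        ne = len(s.eta_names)
        entry = {n: float(b_hat[i]) for i, n in enumerate(s.eta_names)}
        if s.has_ea50:
            entry["ea50"] = float(b_hat[ne])
        entry["kappas"] = np.array(b_hat[ne + int(s.has_ea50):])
        ebes[s.sid] = entry
    return total, ebes, flags


def fit(data: ModelDataset, spec: EstimationSpec, start: PopulationModel,
        drug=None, compute_se: bool = True, outer_options: Optional[dict] = None
        ) -> FitResult:
    """Outer maximum-likelihood fit of the free population parameters.

    Free fixed effects and variances are optimized on transformed scales
    (logs for positive quantities, ``log(1 + Emax)`` for the drug maximum
    effect) with a Nelder-Mead simplex on the Laplace OFV.  Standard errors
    come from the finite-difference Hessian of the OFV at the optimum
    (``cov = 2 H^-1``), eta shrinkage from the spread of the empirical
    Bayes estimates, and the condition number from the correlation matrix
    of the fixed-effect estimates.
    """
    names = spec.free_names
    subjects = _prepare_subjects(data)
    cache: dict = {}

    def build(u):
        pop, dr = start, drug
        for name, ui in zip(names, u):
            pop, dr = _set_param(pop, dr, name, _from_internal(name, float(ui)))
        return pop, dr

    def objective(u):
        pop, dr = build(u)
        try:
            return neg2ll(pop, spec, data, dr, cache, subjects)[0]
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    converged = True
    if names:
        x0 = np.array([_to_internal(n, _get_param(start, drug, n)) for n in names])
        options = {"xatol": 1e-3, "fatol": 1e-2, "maxfev": 200 * max(len(names), 1),
                   "adaptive": len(names) > 4}
        if outer_options:
            options.update(outer_options)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options=options)
        if len(names) > 1:
            # restart with a fresh simplex: Nelder-Mead can collapse along
            # a ridge; a restarted simplex either confirms the optimum or
            # escapes the collapsed configuration
            res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                     options=options)
            if res2.fun < res.fun:
                res = res2
        converged = bool(res.success)
        x_opt = res.x
    else:
        x_opt = np.zeros(0)

    pop_f, drug_f = build(x_opt)
    ofv, ebes, flags = neg2ll(pop_f, spec, data, drug_f, cache, subjects,
                              multi_start=True)

    result = FitResult(pop=pop_f, drug=drug_f, ofv=float(ofv),
                       n_obs=data.n_obs, free_names=names, ebes=ebes,
                       converged=converged and all(flags.values()),
                       inner_flags=flags)

    # CV% of the log-normal variance components
    for name in names:
        if name.startswith("omega2_"):
            result.cv_pct[name] = omega2_to_cv(_get_param(pop_f, drug_f, name))

    # eta/kappa shrinkage from the EBE spread
    def _shrink(values, omega2):
        values = np.asarray(values, dtype=float)
        if values.size < 2 or omega2 <= 0:
            return float("nan")
        return 100.0 * (1.0 - values.std(ddof=1) / math.sqrt(omega2))

    for name in ETA_ORDER:
        if pop_f.omega2.get(name, 0.0) > 0:
            vals = [e[name] for e in ebes.values() if name in e]
            result.shrinkage_pct[f"omega2_{name}"] = _shrink(vals, pop_f.omega2[name])
    if pop_f.omega2.get("ea50", 0.0) > 0:
        vals = [e["ea50"] for e in ebes.values() if "ea50" in e]
        result.shrinkage_pct["omega2_ea50"] = _shrink(vals, pop_f.omega2["ea50"])
    if pop_f.omega2_bov_amplitude > 0:
        kaps = np.concatenate([e["kappas"] for e in ebes.values()
                               if e["kappas"].size])
        result.shrinkage_pct["omega2_bov_amplitude"] = _shrink(
            kaps, pop_f.omega2_bov_amplitude)

    if compute_se and names:
        _attach_uncertainty(result, objective, x_opt, names)
    return result


def _attach_uncertainty(result: FitResult, objective, x_opt, names) -> None:
    """Finite-difference Hessian -> SEs, RSEs and the condition number."""
    p = len(names)
    h = 1e-3
    f0 = objective(x_opt)
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp = x_opt.copy(); xp[i] += h
        xm = x_opt.copy(); xm[i] -= h
        fp[i] = objective(xp)
        fm[i] = objective(xm)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x_opt.copy(); xpp[[i, j]] += h
            xpm = x_opt.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x_opt.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x_opt.copy(); xmm[[i, j]] -= h
            H[i, j] = H[j, i] = (objective(xpp) - objective(xpm)
                                 - objective(xmp) + objective(xmm)) / (4 * h * h)
    try:
        cov_u = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        result.converged = result.converged and False
        return
    d = np.diag(cov_u)
    if np.any(d <= 0):
        return  # singular or indefinite Hessian: SEs reported absent
    # delta method back to the natural scales
    nat = np.array([_get_param(result.pop, result.drug, n) for n in names])
    scale = np.array([_dnat_du(n, v) for n, v in zip(names, nat)])
    cov_nat = cov_u * np.outer(scale, scale)
    se = np.sqrt(np.diag(cov_nat))
    for n, s, v in zip(names, se, nat):
        result.se[n] = float(s)
        result.rse_pct[n] = float(100.0 * s / abs(v)) if v != 0 else float("inf")
    fixed_idx = [i for i, n in enumerate(names)
                 if not n.startswith("omega2_") and n != "sigma2"]
    if len(fixed_idx) >= 2:
        sub = cov_nat[np.ix_(fixed_idx, fixed_idx)]
        dd = np.sqrt(np.diag(sub))
        corr = sub / np.outer(dd, dd)
        eig = np.linalg.eigvalsh(corr)
        if eig[0] > 0:
            result.condition_number = float(eig[-1] / eig[0])
    elif len(fixed_idx) == 1:
        result.condition_number = 1.0


def compare_models(fit_small: FitResult, fit_big: FitResult,
                   extra_df: int) -> ModelComparison:
    """Forward/backward likelihood-ratio decisions for nested models.

    Forward inclusion requires the OFV to drop by *more than* the 5%
    chi-square critical value (3.84 at 1 df); backward elimination removes
    a term whose removal raises the OFV by less than the 1% critical value
    (6.6 at 1 df).
    """
    if extra_df <= 0:
        raise ValueError("extra_df must be positive")
    delta = fit_small.ofv - fit_big.ofv
    fwd = float(stats.chi2.ppf(0.95, extra_df))
    bwd = float(stats.chi2.ppf(0.99, extra_df))
    return ModelComparison(delta_ofv=float(delta), extra_df=extra_df,
                           forward_threshold=fwd, backward_threshold=bwd,
                           forward_accept=bool(delta > fwd),
                           backward_retain=bool(delta >= bwd))


def bic(fit_result: FitResult, data: Optional[ModelDataset] = None) -> float:
    """Bayesian information criterion: OFV + k log(n_obs)."""
    n = data.n_obs if data is not None else fit_result.n_obs
    return float(fit_result.ofv + fit_result.n_params * math.log(n))


def screen_covariates(fit_result: FitResult,
                      covariate_table: pd.DataFrame,
                      threshold: float = 0.5) -> CovariateScreen:
    """Pearson screen of covariates against the eta EBEs.

    Candidates with ``|r| >= threshold`` are then to be tested formally as
    linear, power and exponential terms through :func:`compare_models`
    (forward p < 0.05, backward p < 0.01).
    """
    notices: list[str] = []
    rows = []
    ids = [sid for sid in fit_result.ebes]
    table = covariate_table.loc[[i for i in ids if i in covariate_table.index]]
    for name in ETA_ORDER:
        vals = {sid: e[name] for sid, e in fit_result.ebes.items() if name in e}
        if len(vals) < 3:
            continue
        common = [sid for sid in table.index if sid in vals]
        eta_vec = np.array([vals[sid] for sid in common])
        for col in covariate_table.columns:
            x = table.loc[common, col].to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                notices.append(f"covariate {col!r} is constant: skipped")
                continue
            if np.allclose(eta_vec, eta_vec[0]):
                notices.append(f"eta {name!r} has no spread: skipped")
                continue
            r = float(np.corrcoef(x, eta_vec)[0, 1])
            if abs(r) >= threshold:
                rows.append({"parameter": name, "covariate": col, "r": r})
    cand = pd.DataFrame(rows, columns=["parameter", "covariate", "r"])
    if len(cand):
        cand = cand.reindex(cand["r"].abs().sort_values(ascending=False).index)
        cand = cand.reset_index(drop=True)
    return CovariateScreen(candidates=cand, notices=notices)


def circadian_term(t_clock, phase: float, magnitude: float,
                   mode: str = "cosine24", night_window=(23.0, 7.0)):
    """Multiplicative circadian modulation factor for the pulse amplitude.

    ``cosine24``: ``1 + magnitude * cos(2 pi (t - phase) / 24)`` (acrophase
    at ``phase`` hours-of-day).  ``day_night``: ``1 + magnitude`` inside the
    night window (wrapping over midnight), 1 otherwise.
    """
    t = np.asarray(t_clock, dtype=float) % 24.0
    if mode == "cosine24":
        return 1.0 + magnitude * np.cos(2.0 * np.pi * (t - phase) / 24.0)
    if mode == "day_night":
        lo, hi = night_window
        inside = (t >= lo) | (t < hi) if lo > hi else (t >= lo) & (t < hi)
        return 1.0 + magnitude * inside.astype(float)
    raise ValueError(f"unknown circadian mode {mode!r}")
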