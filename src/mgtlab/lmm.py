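"""Mixed-model estimation, contrasts and recovery experiments.

The primary analysis fits a linear mixed model to the type-averaged risk
score with session (1, 2), group (placebo, probiotics), stimulation (sham,
SPL, VMPFC) and all their interactions as fixed factors, and random
intercepts for participant and for trial type nested within participant:

    risk ~ session * group * stimulation
           + (1 | participant) + (1 | trial_code : participant)

estimated by maximum likelihood. Choice optimality and response time reuse
the same structure; heart rate and questionnaire scales use a
participant-only random intercept estimated by REML. Estimation is
delegated to statsmodels ``MixedLM`` (participant as the grouping factor,
the nested trial-type intercept as a variance component).

On top of the fit this module provides estimated marginal means over the
session x group x stimulation grid with pairwise contrasts
(Bonferroni-adjusted within the requested family, asymptotic z inference),
Nakagawa-style marginal/conditional R^2, ICC, response-SD standardized
coefficients, the partial-eta-squared -> Cohen's f conversion used for
power analysis, and a simulate -> fit -> summarize parameter-recovery
harness.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .simulate import CohortDesign, EffectSpec, simulate_lmm_dataset

__all__ = [
    "ModelSpec",
    "FitResult",
    "ContrastResult",
    "RecoveryReport",
    "MODEL_SPECS",
    "fit_lmm",
    "fit_repetition_model",
    "contrast_analysis",
    "table2_family",
    "standardized_coefficients",
    "partial_eta_to_f",
    "cohens_f_to_eta",
    "icc_from_components",
    "recovery_experiment",
]

FACTOR_LEVELS = {
    "session": [1, 2],
    "group": ["placebo", "probiotics"],
    "stimulation": ["sham", "SPL", "VMPFC"],
    "repetition": ["A", "B", "C"],
    "time": ["pre", "post"],
}


@dataclass(frozen=True)
class ModelSpec:
    """A named model: response, fixed formula, random structure, method.

    ``random`` is one of ``"nested"`` (participant intercept plus trial
    type within participant), ``"participant"`` (participant intercept
    only) or ``"none"`` (ordinary least squares; used as a degenerate
    reference and as the closed-form oracle route in tests).
    """

    name: str
    response: str
    fixed: str
    random: str = "nested"
    method: str = "ML"

    def __post_init__(self) -> None:
        if self.random not in ("nested", "participant", "none"):
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.method not in ("ML", "REML"):
            raise ValueError(f"method must be ML or REML, got {self.method!r}")

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


_FACTORIAL = "session * group * stimulation"

MODEL_SPECS: dict[str, ModelSpec] = {
    "risk": ModelSpec("risk", "risk", _FACTORIAL, "nested", "ML"),
    "risk_rep": ModelSpec("risk_rep", "risk",
                          "session * group * stimulation * repetition",
                          "nested", "ML"),
    "co": ModelSpec("co", "co", _FACTORIAL, "nested", "ML"),
    "rt": ModelSpec("rt", "rt", _FACTORIAL, "nested", "ML"),
    "hr": ModelSpec("hr", "hr",
                    "session + group + stimulation + time + session:group",
                    "participant", "REML"),
    "scale": ModelSpec("scale", "value", "session * group",
                       "participant", "REML"),
}


@dataclass
class FitResult:
    """Full report of one mixed-model fit."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # estimate, se, z, p, ci_low, ci_high
    vcov: pd.DataFrame  # fixed-effects covariance, cleaned names
    variance_components: dict[str, float]
    icc: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    factors: dict[str, list] = field(repr=False)
    design_info: object = field(repr=False, default=None)

    @property
    def params(self) -> pd.Series:
        return self.coefficients["estimate"]

    def to_dict(self) -> dict:
        """JSON-serializable report."""
        return {
            "model": self.spec.name,
            "formula": self.spec.formula,
            "random": self.spec.random,
            "method": self.spec.method,
            "coefficients": self.coefficients.reset_index()
                .rename(columns={"index": "term"}).to_dict("records"),
            "variance_components": self.variance_components,
            "icc": self.icc,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "aic": self.aic,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


@dataclass
class ContrastResult:
    """Pairwise estimated-marginal-mean contrasts with Bonferroni p."""

    table: pd.DataFrame
    family_size: int


def _clean_term(name: str) -> str:
    """Map patsy term names to compact labels.

    ``session[T.2]`` -> ``session2``; ``group[T.probiotics]`` ->
    ``probiotics``; ``stimulation[T.SPL]`` -> ``SPL``; interaction parts
    joined with ``:``. The intercept keeps its name.
    """
    def one(part: str) -> str:
        m = re.fullmatch(r"(\w+)\[T\.([^\]]+)\]", part)
        if not m:
            return part
        factor, level = m.groups()
        if factor in ("session", "repetition", "time"):
            return f"{factor}{level}"
        return level

    return ":".join(one(p) for p in name.split(":"))


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = table.copy()
    factors = [f for f in FACTOR_LEVELS if re.search(rf"\b{f}\b", spec.fixed)]
    missing = [f for f in factors if f not in df.columns]
    if missing:
        raise ValueError(f"table lacks factor column(s): {missing}")
    for f in factors:
        levels = [l for l in FACTOR_LEVELS[f] if l in set(df[f])]
        unknown = set(df[f]) - set(FACTOR_LEVELS[f])
        if unknown:
            raise ValueError(f"unknown {f} level(s): {sorted(map(str, unknown))}")
        if len(levels) < 2:
            raise ValueError(
                f"factor {f!r} has fewer than 2 levels in the data")
        df[f] = pd.Categorical(df[f], categories=levels)
    df = df.dropna(subset=[spec.response])
    if spec.random != "none" and "participant" not in df.columns:
        raise ValueError("table lacks a 'participant' column")
    return df


def fit_lmm(table: pd.DataFrame, spec: ModelSpec | str = "risk",
            retain_col: str | None = None) -> FitResult:
    """Fit one of the study's models and assemble the full report.

    ``spec`` is a ModelSpec or the name of a predefined one. For the
    response-time model pass ``retain_col="rt_retained"`` to honor the
    outlier fence. Non-convergence is reported on the result (and raised
    only if the optimizer's retry ladder fails outright).
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    df = table
    if retain_col is not None:
        df = df[df[retain_col]]
    df = _prepare(df, spec)
    factors = {f: list(df[f].cat.categories)
               for f in FACTOR_LEVELS if f in df.columns
               and isinstance(df[f].dtype, pd.CategoricalDtype)}

    if spec.random == "none":
        res = smf.ols(spec.formula, data=df).fit()
        sigma2 = float(res.scale)
        vc: dict[str, float] = {"residual": sigma2}
        converged = True
        llf, k = res.llf, res.df_model + 2
        cov = res.cov_params()
        re_var = 0.0
        design_info = res.model.data.design_info
        fe = res.params
        bse, pvals = res.bse, res.pvalues
        n_groups = {}
    else:
        kwargs: dict = {"groups": "participant", "re_formula": "1"}
        if spec.random == "nested":
            kwargs["vc_formula"] = {"trialtype": "0 + C(trial_code)"}
        md = smf.mixedlm(spec.formula, df, **kwargs)
        reml = spec.method == "REML"
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "cg"):
                try:
                    cand = md.fit(reml=reml, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                res = cand
                if cand.converged:
                    break
        if res is None:
            raise RuntimeError(f"mixed model {spec.name!r} failed to fit")
        converged = bool(res.converged)
        sigma2 = float(res.scale)
        re_var = float(res.cov_re.iloc[0, 0])
        vc = {"residual": sigma2, "participant": re_var}
        if spec.random == "nested":
            vc["trialtype:participant"] = float(res.vcomp[0])
        k = md.k_fe + md.k_re2 + md.k_vc + 1  # + profiled residual variance
        llf = float(res.llf)
        cov = res.cov_params().iloc[: md.k_fe, : md.k_fe]
        design_info = md.data.design_info
        fe = res.fe_params
        bse = res.bse[: md.k_fe]
        pvals = res.pvalues[: md.k_fe]
        n_groups = {"participant": df["participant"].nunique()}
        if spec.random == "nested":
            n_groups["trial_code"] = df["trial_code"].nunique()

    names = [_clean_term(n) for n in fe.index]
    est = np.asarray(fe, dtype=float)
    se = np.asarray(bse, dtype=float)
    zcrit = scipy.stats.norm.ppf(0.975)
    coef = pd.DataFrame({
        "estimate": est, "se": se,
        "z": np.divide(est, se, out=np.zeros_like(est), where=se > 0),
        "p": np.asarray(pvals, dtype=float),
        "ci_low": est - zcrit * se, "ci_high": est + zcrit * se,
    }, index=pd.Index(names, name="term"))
    vcov = pd.DataFrame(np.asarray(cov), index=names, columns=names)

    tau_total = sum(v for k_, v in vc.items() if k_ != "residual")
    icc = tau_total / (tau_total + sigma2) if (tau_total + sigma2) > 0 else 0.0
    X = np.asarray(build_design_matrices([design_info], df)[0])
    var_fixed = float(np.var(X @ est))
    denom = var_fixed + tau_total + sigma2
    r2_marg = var_fixed / denom if denom > 0 else 0.0
    r2_cond = (var_fixed + tau_total) / denom if denom > 0 else 0.0

    return FitResult(
        spec=spec, coefficients=coef, vcov=vcov, variance_components=vc,
        icc=icc, r2_marginal=r2_marg, r2_conditional=r2_cond,
        aic=float(2 * k - 2 * llf), loglik=float(llf), converged=converged,
        n_obs=int(len(df)), n_groups=n_groups, factors=factors,
        design_info=design_info)


def fit_repetition_model(table: pd.DataFrame) -> FitResult:
    """Post hoc model with task repetition (A, B, C) as a fixed factor,
    fully crossed with session, group and stimulation."""
    return fit_lmm(table, MODEL_SPECS["risk_rep"])


# --------------------------------------------------------------------------
# estimated marginal means and contrasts

def _emm_row(fit: FitResult, cell: dict) -> np.ndarray:
    """Fixed-effects weight vector of the EMM of one (partial) cell.

    The estimated marginal mean of a cell averages model predictions over
    the levels of every factor the cell does not pin down (e.g. repetition
    in the post hoc model), with equal weights.
    """
    unknown = set(cell) - set(fit.factors)
    if unknown:
        raise ValueError(f"contrast references absent factor(s): {unknown}")
    free = {f: levels for f, levels in fit.factors.items() if f not in cell}
    for f, level in cell.items():
        if level not in fit.factors[f]:
            raise ValueError(f"level {level!r} absent from factor {f!r}")
    grid = [dict(zip(free, combo))
            for combo in itertools.product(*free.values())] or [{}]
    rows = pd.DataFrame([{**cell, **g} for g in grid])
    for f in fit.factors:
        rows[f] = pd.Categorical(rows[f], categories=fit.factors[f])
    X = np.asarray(build_design_matrices([fit.design_info], rows)[0])
    return X.mean(axis=0)


def contrast_analysis(fit: FitResult, family: list[dict]) -> ContrastResult:
    """Pairwise EMM contrasts with Bonferroni adjustment over the family.

    Each family member is a dict with keys ``label``, ``cell_a``,
    ``cell_b`` (cells are factor->level dicts; factors left out are
    averaged over) and optional display keys (``group``, ``stimulation``,
    ``session``). Inference is asymptotic normal (z), matching the use of
    z ratios in the study's contrast tables; adjusted p = min(1, m * p).
    """
    m = len(family)
    beta = fit.params.to_numpy()
    V = fit.vcov.to_numpy()
    rows = []
    for spec_ in family:
        L = _emm_row(fit, spec_["cell_a"]) - _emm_row(fit, spec_["cell_b"])
        est = float(L @ beta)
        var = float(L @ V @ L)
        se = float(np.sqrt(max(var, 0.0)))
        z = est / se if se > 0 else 0.0
        p = float(2 * scipy.stats.norm.sf(abs(z))) if se > 0 else 1.0
        rows.append({
            "group": spec_.get("group", ""),
            "stimulation": spec_.get("stimulation", ""),
            "session": spec_.get("session", ""),
            "contrast": spec_["label"],
            "estimate": est, "se": se, "z": z,
            "p_raw": p, "p_adj": min(1.0, m * p),
        })
    return ContrastResult(table=pd.DataFrame(rows), family_size=m)


def table2_family() -> list[dict]:
    """The study's 20-contrast family over session x group x stimulation:
    per-cell session differences, per-cell group differences, and the
    SPL-sham / VMPFC-SPL stimulation ladder."""
    fam: list[dict] = []
    for g in FACTOR_LEVELS["group"]:
        for st in FACTOR_LEVELS["stimulation"]:
            fam.append({
                "label": "SESSION2 - SESSION1", "group": g,
                "stimulation": st,
                "cell_a": {"session": 2, "group": g, "stimulation": st},
                "cell_b": {"session": 1, "group": g, "stimulation": st}})
    for st in FACTOR_LEVELS["stimulation"]:
        for s in FACTOR_LEVELS["session"]:
            fam.append({
                "label": "PROBIOTICS - PLACEBO", "stimulation": st,
                "session": s,
                "cell_a": {"session": s, "group": "probiotics",
                           "stimulation": st},
                "cell_b": {"session": s, "group": "placebo",
                           "stimulation": st}})
    for g in FACTOR_LEVELS["group"]:
        for s in FACTOR_LEVELS["session"]:
            for a, b in (("SPL", "sham"), ("VMPFC", "SPL")):
                fam.append({
                    "label": f"{a} - {b}".upper(), "group": g, "session": s,
                    "cell_a": {"session": s, "group": g, "stimulation": a},
                    "cell_b": {"session": s, "group": g, "stimulation": b}})
    return fam


# --------------------------------------------------------------------------
# effect sizes and standardization

def standardized_coefficients(fit: FitResult,
                              table: pd.DataFrame) -> pd.DataFrame:
    """Coefficients on the response-SD scale.

    Divides estimates, SEs and CI bounds by the overall standard deviation
    of the response in ``table`` (factor predictors are left on their
    contrast coding). The scaling method is stamped into ``attrs``.
    """
    y = table[fit.spec.response].dropna().to_numpy(dtype=float)
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("response has zero variance")
    out = fit.coefficients.copy()
    for c in ("estimate", "se", "ci_low", "ci_high"):
        out[c] = out[c] / sd
    out.attrs["method"] = "response-sd-division"
    out.attrs["response_sd"] = sd
    return out


def partial_eta_to_f(eta2: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= eta2 < 1.0:
        raise ValueError(f"eta2 must be in [0, 1), got {eta2}")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def cohens_f_to_eta(f: float) -> float:
    """Inverse conversion: eta2 = f^2 / (1 + f^2)."""
    if f < 0:
        raise ValueError(f"f must be >= 0, got {f}")
    return float(f**2 / (1.0 + f**2))


def icc_from_components(sigma2: float, *taus: float) -> float:
    """Intraclass correlation: sum(tau) / (sum(tau) + sigma2)."""
    tau = float(sum(taus))
    if sigma2 < 0 or any(t < 0 for t in taus):
        raise ValueError("variance components must be nonnegative")
    total = tau + sigma2
    return tau / total if total > 0 else 0.0


# --------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryReport:
    """Per-coefficient summaries over simulate -> fit replicates."""

    summary: pd.DataFrame
    estimates: pd.DataFrame
    n_reps: int
    n_converged: int
    n_failed: int


def recovery_experiment(effects: EffectSpec | None = None,
                        design: CohortDesign | None = None,
                        n_reps: int = 100, seed: int = 0,
                        alpha: float = 0.05,
                        terms: list[str] | None = None) -> RecoveryReport:
    """Repeatedly simulate from the generative model and refit.

    For each tracked fixed-effect term the report gives the generative
    truth, mean estimate, bias (with its Monte-Carlo SE when n_reps > 1),
    RMSE, 95% CI coverage of the truth, and the Wald rejection rate at
    ``alpha``. Replicates that fail to fit are counted, not hidden.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    effects = effects or EffectSpec()
    design = design or CohortDesign()
    truth_map = {"Intercept": effects.intercept, **effects.coefficients}
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 root.spawn(n_reps)]
    records = []
    n_converged = n_failed = 0
    for r, s in enumerate(rep_seeds):
        table, _ = simulate_lmm_dataset(effects, design, seed=s)
        try:
            fit = fit_lmm(table, "risk")
        except RuntimeError:
            n_failed += 1
            continue
        n_converged += int(fit.converged)
        for term, row in fit.coefficients.iterrows():
            records.append({"rep": r, "term": term,
                            "estimate": row["estimate"], "se": row["se"],
                            "p": row["p"], "ci_low": row["ci_low"],
                            "ci_high": row["ci_high"]})
    est = pd.DataFrame(records)
    if est.empty:
        raise RuntimeError("every recovery replicate failed to fit")
    if terms is None:
        terms = list(est["term"].unique())
    rows = []
    for term in terms:
        sub = est[est["term"] == term]
        truth = float(truth_map.get(term, 0.0))
        e = sub["estimate"].to_numpy()
        n = len(e)
        bias = float(e.mean() - truth)
        mc_se = float(e.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({
            "term": term, "truth": truth, "mean_estimate": float(e.mean()),
            "bias": bias, "mc_se": mc_se,
            "rmse": float(np.sqrt(np.mean((e - truth) ** 2))),
            "coverage": float(((sub["ci_low"] <= truth)
                               & (truth <= sub["ci_high"])).mean()),
            "rejection_rate": float((sub["p"] < alpha).mean()),
            "n_reps": n,
        })
    return RecoveryReport(summary=pd.DataFrame(rows).set_index("term"),
                          estimates=est, n_reps=n_reps,
                          n_converged=n_converged, n_failed=n_failed)
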