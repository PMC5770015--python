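"""Mixed-effects model suite with bootstrap CIs and a convergence fallback.

The analysis fits linear (gaussian) and binomial-logit mixed models with
crossed random effects for item and participant, declared per model as a
maximal structure and simplified deterministically on non-convergence:

1. random-effect correlations are never modelled (variance-components
   parameterisation), so the conventional first fallback step is built in;
2. random slopes are dropped one at a time in reverse order of declaration;
3. intercepts only; an intercept-only failure is a hard error.

Gaussian models are fitted by REML with :class:`statsmodels` MixedLM,
binomial ones by the package's Laplace GLMM (:mod:`symsig.mixedglm`).
p-values are Wald approximations and secondary to parametric-bootstrap 95%
confidence intervals (simulate from the fitted model, refit, take the
2.5/97.5 percentiles per fixed effect).

:func:`run_model_suite` reproduces the full analysis plan on a study table:
five whole-game models (complexity, accuracy and insight against turn and
time-seen), four first-exposure models (insight and accuracy against JD_mu,
iconicity and log complexity), and four older-item models (rating sanity
checks plus insight and accuracy against time, iconicity, familiarity and
log complexity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, NumericalError
from .mixedglm import LogisticMixedModel

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# specifications
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class RandomEffects:
    """Random-effect block for one grouping factor: an intercept and/or
    slopes for named fixed-effect terms (uncorrelated components)."""

    group: str
    intercept: bool = True
    slopes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModelSpec:
    """One mixed model: response, fixed effects, family, random structure."""

    analysis_id: str
    response: str
    fixed: tuple[str, ...]
    family: str  # "gaussian" | "binomial"
    random: tuple[RandomEffects, ...] = ()

    def validate(self, data: pd.DataFrame) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        cols = set(data.columns)
        for term in (self.response, *self.fixed):
            if term not in cols:
                raise DataIntegrityError(f"{self.analysis_id}: column {term!r} missing from data")
        for re_ in self.random:
            if re_.group not in cols:
                raise DataIntegrityError(
                    f"{self.analysis_id}: grouping factor {re_.group!r} missing from data"
                )
            for s in re_.slopes:
                if s not in self.fixed:
                    raise ValueError(
                        f"{self.analysis_id}: slope {s!r} is not among the fixed effects"
                    )
        y = data[self.response]
        if self.family == "binomial" and not set(np.unique(y)).issubset({0, 1, 0.0, 1.0}):
            raise ValueError(f"{self.analysis_id}: binomial response must be 0/1")
        if self.family == "gaussian" and set(np.unique(y)).issubset({0, 1, 0.0, 1.0}) and len(np.unique(y)) <= 2:
            raise ValueError(f"{self.analysis_id}: binary response declared gaussian")

    def describe_random(self) -> str:
        if not self.random:
            return "none"
        parts = []
        for re_ in self.random:
            bits = (["1"] if re_.intercept else []) + list(re_.slopes)
            parts.append(f"{re_.group}({'+'.join(bits) or '-'})")
        return ", ".join(parts)


@dataclass
class FitResult:
    """Fixed-effect estimates for one fitted model."""

    analysis_id: str
    family: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray  # t (gaussian, Wald z in practice) or z (binomial)
    p: np.ndarray
    converged: bool
    structure_used: str
    n_obs: int
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    ci_unreliable: bool = False
    ladder_steps: list[str] = field(default_factory=list)
    # retained for parametric-bootstrap simulation / refitting
    spec: ModelSpec | None = None
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _zblocks: list[tuple[str, np.ndarray]] | None = None
    _re_var: np.ndarray | None = None  # variance per block
    _scale: float | None = None  # residual variance (gaussian)
    _start: object | None = None  # optimiser warm start for bootstrap refits

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "analysis": self.analysis_id,
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "stat": self.stat,
                "p": self.p,
            }
        )
        df["ci_lower"] = self.ci_lower if self.ci_lower is not None else np.nan
        df["ci_upper"] = self.ci_upper if self.ci_upper is not None else np.nan
        df["structure"] = self.structure_used
        df["n_obs"] = self.n_obs
        return df


# --------------------------------------------------------------------------- #
# design construction
# --------------------------------------------------------------------------- #


def _design(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, np.ndarray]], list[str]]:
    spec.validate(data)
    rows = data.dropna(subset=[spec.response, *spec.fixed])
    if len(rows) < len(data):
        raise DataIntegrityError(
            f"{spec.analysis_id}: {len(data) - len(rows)} rows with missing values; "
            "subset the analysis rows explicitly before fitting"
        )
    y = rows[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[t].to_numpy(dtype=float) for t in spec.fixed]
    )
    terms = ["(Intercept)", *spec.fixed]
    zblocks: list[tuple[str, np.ndarray]] = []
    for re_ in spec.random:
        dummies = pd.get_dummies(rows[re_.group], dtype=float).to_numpy()
        if re_.intercept:
            zblocks.append((f"{re_.group}:1", dummies))
        for s in re_.slopes:
            zblocks.append((f"{re_.group}:{s}", dummies * rows[s].to_numpy(dtype=float)[:, None]))
    return y, X, zblocks, terms


def scale_covariates(
    data: pd.DataFrame, terms: list[str], suffix: str = "_s"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardise named columns to mean 0, sample SD 1 over the given rows.

    Returns the augmented frame (new columns ``term + suffix``) and the
    (mean, sd) scaling constants per term.  A zero-variance term is an error.
    """
    out = data.copy()
    scalers: dict[str, tuple[float, float]] = {}
    for t in terms:
        x = out[t].to_numpy(dtype=float)
        m = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot scale zero-variance term {t!r}")
        out[t + suffix] = (x - m) / sd
        scalers[t] = (m, sd)
    return out, scalers


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one mixed model; raises NumericalError instead of returning a
    non-converged fit (callers use :func:`fallback_ladder`)."""
    y, X, zblocks, terms = _design(spec, data)
    if spec.family == "gaussian":
        return _fit_gaussian(spec, y, X, zblocks, terms)
    return _fit_binomial(spec, y, X, zblocks, terms)


def _fit_gaussian(spec, y, X, zblocks, terms, start=None) -> FitResult:
    if not zblocks:
        import statsmodels.api as sm

        res = sm.OLS(y, X).fit()
        return FitResult(
            analysis_id=spec.analysis_id,
            family="gaussian",
            terms=terms,
            beta=np.asarray(res.params, dtype=float),
            se=np.asarray(res.bse, dtype=float),
            stat=np.asarray(res.tvalues, dtype=float),
            p=np.asarray(res.pvalues, dtype=float),
            converged=True,
            structure_used="none",
            n_obs=len(y),
            spec=spec,
            _y=y,
            _X=X,
            _zblocks=[],
            _re_var=np.zeros(0),
            _scale=float(res.scale),
        )

    from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

    names = [n for n, _ in zblocks]
    vcs = VCSpec(
        names,
        [[[f"{n}[{j}]" for j in range(Z.shape[1])]] for n, Z in zblocks],
        [[Z] for _, Z in zblocks],
    )
    groups = np.zeros(len(y), dtype=int)
    model = MixedLM(y, X, groups=groups, exog_re=np.empty((len(y), 0)), exog_vc=vcs)
    # deterministic optimiser cascade: fast L-BFGS first, Powell (which copes
    # better with boundary variance components) warm-started from it otherwise
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", start_params=start, maxiter=300, disp=False)
            if not res.converged:
                res = model.fit(
                    reml=True, method="powell", start_params=res.params_object,
                    maxiter=500, disp=False,
                )
            beta = np.asarray(res.fe_params, dtype=float)
            se = np.asarray(res.bse_fe, dtype=float)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as exc:
            raise NumericalError(f"{spec.analysis_id}: gaussian mixed fit failed ({exc})") from exc
    ok = bool(res.converged) and np.isfinite(se).all() and (se > 0).all() and np.isfinite(beta).all()
    if not ok:
        raise NumericalError(f"{spec.analysis_id}: gaussian mixed fit did not converge")
    t = beta / se
    p = 2 * stats.norm.sf(np.abs(t))
    return FitResult(
        analysis_id=spec.analysis_id,
        family="gaussian",
        terms=terms,
        beta=beta,
        se=se,
        stat=t,
        p=p,
        converged=True,
        structure_used=spec.describe_random(),
        n_obs=len(y),
        spec=spec,
        _y=y,
        _X=X,
        _zblocks=zblocks,
        _re_var=np.maximum(np.asarray(res.vcomp, dtype=float), 0.0),
        _scale=float(res.scale),
        _start=res.params_object,
    )


def _fit_binomial(spec, y, X, zblocks, terms, start=None) -> FitResult:
    model = LogisticMixedModel(y, X, zblocks)
    res = model.fit(start_log_tau=start)  # raises NumericalError on singular Hessians
    if not res.converged:
        raise NumericalError(f"{spec.analysis_id}: binomial mixed fit did not converge")
    return FitResult(
        analysis_id=spec.analysis_id,
        family="binomial",
        terms=terms,
        beta=res.beta,
        se=res.se,
        stat=res.zvalues,
        p=res.pvalues,
        converged=True,
        structure_used=spec.describe_random() if zblocks else "none",
        n_obs=len(y),
        spec=spec,
        _y=y,
        _X=X,
        _zblocks=zblocks,
        _re_var=res.tau**2,
        _scale=None,
        _start=np.log(np.maximum(res.tau, 1e-3)) if len(res.tau) else None,
    )


def _ladder_structures(spec: ModelSpec) -> list[tuple[str, ModelSpec]]:
    """Deterministic simplification sequence for the fallback ladder."""
    out: list[tuple[str, ModelSpec]] = [("maximal", spec)]
    current = spec
    # drop slopes one at a time, in reverse order of declaration
    slope_order = [
        (gi, s) for gi, re_ in enumerate(spec.random) for s in re_.slopes
    ]
    for gi, s in reversed(slope_order):
        new_random = []
        for i, re_ in enumerate(current.random):
            if i == gi:
                re_ = replace(re_, slopes=tuple(x for x in re_.slopes if x != s))
            new_random.append(re_)
        current = replace(current, random=tuple(new_random))
        out.append((f"drop slope {spec.random[gi].group}:{s}", current))
    # intercepts only (skip if already there)
    intercepts = replace(
        spec, random=tuple(replace(r, slopes=()) for r in spec.random if r.intercept)
    )
    if out[-1][1].random != intercepts.random:
        out.append(("intercepts only", intercepts))
    return out


def fallback_ladder(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit with the maximal declared structure, simplifying deterministically
    until convergence; an intercept-only failure is a hard error."""
    steps = []
    for label, s in _ladder_structures(spec):
        steps.append(label)
        try:
            res = fit_mixed(s, data)
        except NumericalError as exc:
            logger.info("%s: %s failed (%s)", spec.analysis_id, label, exc)
            continue
        res.ladder_steps = steps
        if label != "maximal":
            logger.info("%s: converged after fallback %r", spec.analysis_id, label)
        return res
    raise NumericalError(
        f"{spec.analysis_id}: no structure converged, including intercepts-only "
        f"(ladder: {steps})"
    )


# --------------------------------------------------------------------------- #
# parametric bootstrap
# --------------------------------------------------------------------------- #


def bootstrap_ci(
    fit: FitResult, n_reps: int = 200, seed: int = 0, max_fail_frac: float = 0.10
) -> FitResult:
    """Attach parametric-bootstrap 95% CIs to a converged fit.

    Responses are simulated from the fitted model (fixed effects, estimated
    variance components, and for gaussian fits the residual variance), refitted
    with the same structure, and the 2.5/97.5 percentiles taken per fixed
    effect.  If more than ``max_fail_frac`` of the replicates fail to
    converge the CI is flagged unreliable.
    """
    if fit.spec is None or fit._X is None:
        raise ValueError("fit does not carry its design; refit with fit_mixed")
    rng = np.random.default_rng(seed)
    X, y0, zb = fit._X, fit._y, fit._zblocks or []
    draws: list[np.ndarray] = []
    failures = 0
    for _ in range(n_reps):
        eta = X @ fit.beta
        for var, (_, Z) in zip(fit._re_var, zb):
            eta = eta + Z @ rng.normal(scale=np.sqrt(max(var, 0.0)), size=Z.shape[1])
        if fit.family == "gaussian":
            y_star = eta + rng.normal(scale=np.sqrt(fit._scale), size=len(eta))
        else:
            y_star = (rng.random(len(eta)) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        try:
            if fit.family == "gaussian":
                rep = _fit_gaussian(fit.spec, y_star, X, zb, fit.terms, start=fit._start)
            else:
                rep = _fit_binomial(fit.spec, y_star, X, zb, fit.terms, start=fit._start)
            draws.append(rep.beta)
        except NumericalError:
            failures += 1
    if not draws:
        raise NumericalError(f"{fit.analysis_id}: every bootstrap replicate failed")
    B = np.vstack(draws)
    # outward-rounded order statistics: a 2-replicate interval is (min, max)
    fit.ci_lower = np.quantile(B, 0.025, axis=0, method="lower")
    fit.ci_upper = np.quantile(B, 0.975, axis=0, method="higher")
    fit.ci_unreliable = failures > max_fail_frac * n_reps
    if fit.ci_unreliable:
        logger.warning(
            "%s: %d/%d bootstrap replicates failed; CI flagged unreliable",
            fit.analysis_id,
            failures,
            n_reps,
        )
    return fit


# --------------------------------------------------------------------------- #
# the analysis suite
# --------------------------------------------------------------------------- #


def suite_specs() -> list[ModelSpec]:
    """The thirteen analyses, with each model's maximal random structure.

    Grouping factors: ``item`` (the cue word), ``signaller_id`` for models of
    drawing properties and crowd ratings, ``receiver_id`` for models of guess
    responses.  The first-exposure models carry no item random effect because
    JD_mu has a single value per item.
    """
    g, b = "gaussian", "binomial"
    R = RandomEffects
    return [
        # whole-game course
        ModelSpec("game_logpc_turn", "log_pc", ("turn",), g,
                  (R("item", slopes=("turn",)), R("signaller_id", slopes=("turn",)))),
        ModelSpec("game_accuracy_turn", "accuracy", ("turn",), b,
                  (R("item"), R("receiver_id", slopes=("turn",)))),
        ModelSpec("game_insight_turn", "insight", ("turn",), g,
                  (R("item"), R("receiver_id", slopes=("turn",)))),
        ModelSpec("game_insight_time_turn", "insight", ("time", "turn"), g,
                  (R("item"), R("receiver_id", slopes=("time", "turn")))),
        ModelSpec("game_insight_time_accuracy_logpc", "insight",
                  ("time", "accuracy", "log_pc"), g,
                  (R("item"), R("receiver_id", slopes=("time", "accuracy", "log_pc")))),
        # first exposures: ground unpredictability
        ModelSpec("new_insight_jd_icon_logpc", "insight",
                  ("jd_mu_s", "iconicity_s", "log_pc_s"), g,
                  (R("receiver_id", slopes=("iconicity_s", "log_pc_s")),)),
        ModelSpec("new_insight_icon", "insight", ("iconicity_s",), g,
                  (R("receiver_id", slopes=("iconicity_s",)),)),
        ModelSpec("new_accuracy_jd_icon_logpc", "accuracy",
                  ("jd_mu_s", "iconicity_s", "log_pc_s"), b,
                  (R("receiver_id"),)),
        ModelSpec("new_accuracy_icon", "accuracy", ("iconicity_s",), b,
                  (R("receiver_id"),)),
        # older items: familiarity
        ModelSpec("old_icon_time", "iconicity", ("time",), g,
                  (R("item", slopes=("time",)), R("signaller_id"))),
        ModelSpec("old_familiarity_time_quad", "familiarity", ("time", "time_sq"), g,
                  (R("item", slopes=("time",)), R("signaller_id"))),
        ModelSpec("old_insight_time_icon_fam_logpc", "insight",
                  ("time", "iconicity_s", "familiarity_s", "log_pc_s"), g,
                  (R("item", slopes=("log_pc_s", "familiarity_s")),
                   R("receiver_id", slopes=("iconicity_s", "familiarity_s")))),
        ModelSpec("old_accuracy_time_icon_fam_logpc", "accuracy",
                  ("time", "iconicity_s", "familiarity_s", "log_pc_s"), b,
                  (R("item"), R("receiver_id"))),
    ]


@dataclass
class SuiteResult:
    fits: list[FitResult]

    def __getitem__(self, analysis_id: str) -> FitResult:
        for f in self.fits:
            if f.analysis_id == analysis_id:
                return f
        raise KeyError(analysis_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([f.to_frame() for f in self.fits], ignore_index=True)

    def to_records(self) -> list[dict]:
        out = []
        for f in self.fits:
            out.append(
                {
                    "analysis_id": f.analysis_id,
                    "family": f.family,
                    "formula": f"{f.spec.response} ~ {' + '.join(f.spec.fixed)}" if f.spec else "",
                    "n_obs": f.n_obs,
                    "converged": f.converged,
                    "structure_used": f.structure_used,
                    "ladder_steps": f.ladder_steps,
                    "ci_unreliable": f.ci_unreliable,
                    "coefficients": [
                        {
                            "term": t,
                            "beta": float(f.beta[i]),
                            "se": float(f.se[i]),
                            "stat": float(f.stat[i]),
                            "p": float(f.p[i]),
                            "ci_lower": float(f.ci_lower[i]) if f.ci_lower is not None else None,
                            "ci_upper": float(f.ci_upper[i]) if f.ci_upper is not None else None,
                        }
                        for i, t in enumerate(f.terms)
                    ],
                }
            )
        return out


def prepare_analysis_tables(
    signals: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a study table into (all, new-items, older-items) analysis frames.

    Scaling of JD_mu, iconicity, familiarity and log complexity is computed
    within each analysis subset; the quadratic time term is computed on
    centred time to limit collinearity.
    """
    df = signals.copy()
    df["time"] = df["time_seen"].astype(float)

    new = df[df.is_first_exposure & df.jd_mu.notna()].copy()
    new, _ = scale_covariates(new, ["jd_mu", "iconicity", "log_pc"])

    old = df[~df.is_first_exposure & df.familiarity.notna()].copy()
    old, _ = scale_covariates(old, ["iconicity", "familiarity", "log_pc"])
    old["time_sq"] = (old["time"] - old["time"].mean()) ** 2
    return df, new, old


def run_model_suite(
    signals: pd.DataFrame, bootstrap_reps: int = 200, seed: int = 0
) -> SuiteResult:
    """Fit all thirteen analyses on a study table.

    ``bootstrap_reps=0`` skips the CIs.  Bootstrap seeds derive from ``seed``
    per analysis, so the suite is reproducible end to end.
    """
    whole, new, old = prepare_analysis_tables(signals)
    frames = {"game": whole, "new": new, "old": old}
    fits: list[FitResult] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(suite_specs()))]
    for spec, boot_seed in zip(suite_specs(), child_seeds):
        frame = frames[spec.analysis_id.split("_")[0]]
        fit = fallback_ladder(spec, frame)
        if bootstrap_reps:
            fit = bootstrap_ci(fit, n_reps=bootstrap_reps, seed=boot_seed)
        fits.append(fit)
    return SuiteResult(fits)
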