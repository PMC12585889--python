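"""Mixed-effects models for bounded discriminability outcomes.

Two analyses are fitted:

* the condition-level model — AUC per (source x spotlight) cell, with spotlight
  size (continuous, scaled to [0, 1]), sampling source and their interaction as
  fixed effects and the embedding backend as a random intercept;
* the trial-level model — similarity-score correctness with source, spotlight
  size and the information proportion as fixed effects and crossed random
  intercepts for backend and trial.

Both outcomes are continuous in [0, 1]; the logit link is realized by fitting
a linear mixed model (statsmodels MixedLM, maximum likelihood) to the
logit-transformed response after the usual boundary shrinkage
y* = (y (n-1) + 0.5)/n. BIC values are comparable across the logit, linear and
quadratic functional forms because the log-Jacobian of the logit transform is
added to the transformed-scale likelihood (a change-of-variables correction,
as in Box-Cox model comparison).

The sampling source is sequence-coded: one column for control vs random and
one for super vs control, so each coefficient is directly one of the reported
contrasts; exp(b) is the multiplicative odds-style effect of a one-unit change
on the coded predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

SOURCE_ORDER = ("random", "control", "super")


def shrink_bounded(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen shrinkage pulling exact 0/1 off the boundary."""
    y = np.asarray(y, dtype=float)
    n = n or y.size
    return (y * (n - 1) + 0.5) / n


def _logit(y):
    return np.log(y / (1.0 - y))


@dataclass
class ModelFit:
    """A fitted mixed model plus what is needed for likelihood-ratio tests."""

    form: str
    link: str
    terms: pd.DataFrame        # estimate, se, ci, exp(b), z, p per fixed effect
    random_effects: dict
    cov_fe: pd.DataFrame       # covariance of the fixed-effect estimates
    llf: float                 # on the (possibly transformed) fitting scale
    llf_original_scale: float  # with the logit Jacobian, for cross-form BIC
    bic: float
    n_params: int
    nobs: int
    converged: bool
    _data: pd.DataFrame = field(repr=False, default=None)
    _response: str = field(repr=False, default="")
    _fixed_cols: tuple = field(repr=False, default=())
    _term_groups: dict = field(repr=False, default=None)
    _fit_kwargs: dict = field(repr=False, default=None)


def _fit_lmm(data: pd.DataFrame, response: str, fixed_cols, *,
             groups: str | None = None, vc_formula: dict | None = None):
    rhs = " + ".join(["1", *fixed_cols])
    if vc_formula is not None:
        data = data.assign(_all=1)
        model = smf.mixedlm(f"{response} ~ {rhs}", data, groups="_all",
                            vc_formula=vc_formula, re_formula="0")
    else:
        model = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data[groups])
    # variance components are often at the zero boundary in small grids;
    # lbfgs gets there reliably but may not flag convergence, and the
    # powell retry can die on a singular Hessian — so try optimizers
    # explicitly and keep the best likelihood
    best = None
    for method in ("lbfgs", "nm"):
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                # zero-variance boundary estimates are legitimate and common
                # in small grids; the optimizer chatter about them is noise
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, method=method, maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if np.isfinite(res.llf) and (best is None or res.llf > best.llf + 1e-9):
            best = res
        if best is not None and best.converged:
            break
    if best is None:
        raise RuntimeError("mixed-model optimization failed with all optimizers")
    return best


def _count_params(res) -> int:
    k_fe = len(res.fe_params)
    k_re = np.asarray(res.cov_re).shape[0] if res.cov_re is not None else 0
    k_re = k_re * (k_re + 1) // 2
    k_vc = len(res.vcomp) if res.vcomp is not None else 0
    return k_fe + k_re + k_vc + 1  # +1 residual variance


def _summarize(res, form, link, jacobian, data, response, fixed_cols,
               term_groups, fit_kwargs, one_tailed=()) -> ModelFit:
    params = res.fe_params
    se = res.bse_fe
    z = params / se
    rows = []
    for name in params.index:
        p_two = 2.0 * sps.norm.sf(abs(z[name]))
        row = {"term": name, "estimate": params[name], "se": se[name],
               "ci_low": params[name] - 1.959964 * se[name],
               "ci_high": params[name] + 1.959964 * se[name],
               "exp_b": float(np.exp(params[name])), "z": float(z[name]),
               "p": float(p_two)}
        if name in one_tailed:
            row["p_one_tailed"] = float(sps.norm.sf(z[name]))
        rows.append(row)
    nobs = res.nobs
    k = _count_params(res)
    llf_orig = res.llf + jacobian
    bic = -2.0 * llf_orig + k * np.log(nobs)
    re = {"groups_var": float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re is not None
          and np.asarray(res.cov_re).size else None,
          "vcomp": {n: float(v) for n, v in zip(res.model.exog_vc.names, res.vcomp)}
          if res.vcomp is not None and len(res.vcomp) else {},
          "residual_var": float(res.scale)}
    k_fe = len(params)
    cov_fe = pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe],
                          index=params.index, columns=params.index)
    return ModelFit(form=form, link=link, terms=pd.DataFrame(rows),
                    cov_fe=cov_fe,
                    random_effects=re, llf=float(res.llf),
                    llf_original_scale=float(llf_orig), bic=float(bic),
                    n_params=k, nobs=int(nobs), converged=bool(res.converged),
                    _data=data, _response=response, _fixed_cols=tuple(fixed_cols),
                    _term_groups=term_groups, _fit_kwargs=fit_kwargs)


def _source_codes(source: pd.Series) -> pd.DataFrame:
    src = source.astype(str)
    bad = set(src.unique()) - set(SOURCE_ORDER)
    if bad:
        raise ValueError(f"unknown source levels: {sorted(bad)}")
    return pd.DataFrame({
        "src_control_vs_random": src.isin(["control", "super"]).astype(float),
        "src_super_vs_control": (src == "super").astype(float),
    })


def fit_condition_model(table: pd.DataFrame, form: str = "logit") -> ModelFit:
    """Fit the condition-level AUC model in one of three functional forms.

    ``table`` needs columns backend, source_label, spotlight_pct, auc. Forms:
    ``logit`` (logit-transformed response, linear size term), ``linear`` and
    ``quadratic`` (identity scale, linear / quadratic size term). All include
    source and size-by-source interaction fixed effects and a backend random
    intercept, and are fitted by maximum likelihood.
    """
    required = {"backend", "source_label", "spotlight_pct", "auc"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["backend"].nunique() < 2:
        raise ValueError("random backend intercept needs >= 2 backends; "
                         "fit a fixed-effects model instead")
    if not np.isfinite(table["auc"]).all():
        raise ValueError("non-finite AUC values")

    df = table.copy().reset_index(drop=True)
    y = shrink_bounded(df["auc"].to_numpy())
    df["size01"] = df["spotlight_pct"].to_numpy(float) / 100.0
    df = pd.concat([df, _source_codes(df["source_label"])], axis=1)
    base = ["size01", "src_control_vs_random", "src_super_vs_control"]
    df["size_x_cvr"] = df["size01"] * df["src_control_vs_random"]
    df["size_x_svc"] = df["size01"] * df["src_super_vs_control"]
    inter = ["size_x_cvr", "size_x_svc"]

    if form == "logit":
        df["resp"] = _logit(y)
        jac = float(-np.log(y * (1.0 - y)).sum())
        cols, link = base + inter, "logit"
        term_groups = {"spotlight_size": ["size01"],
                       "source": ["src_control_vs_random", "src_super_vs_control"],
                       "interaction": inter}
    elif form == "linear":
        df["resp"] = y
        jac, cols, link = 0.0, base + inter, "identity"
        term_groups = {"spotlight_size": ["size01"],
                       "source": ["src_control_vs_random", "src_super_vs_control"],
                       "interaction": inter}
    elif form == "quadratic":
        df["resp"] = y
        df["size01_sq"] = df["size01"] ** 2
        jac, link = 0.0, "identity"
        cols = ["size01", "size01_sq", *base[1:], *inter]
        term_groups = {"spotlight_size": ["size01", "size01_sq"],
                       "source": ["src_control_vs_random", "src_super_vs_control"],
                       "interaction": inter}
    else:
        raise ValueError("form must be one of: logit, linear, quadratic")

    fit_kwargs = {"groups": "backend"}
    res = _fit_lmm(df, "resp", cols, groups="backend")
    return _summarize(res, form, link, jac, df, "resp", cols, term_groups,
                      fit_kwargs,
                      one_tailed=("src_control_vs_random", "src_super_vs_control"))


def compare_condition_forms(table: pd.DataFrame) -> dict[str, ModelFit]:
    """Fit all three functional forms; the best model minimizes BIC."""
    return {form: fit_condition_model(table, form)
            for form in ("logit", "linear", "quadratic")}


def fit_trial_model(table: pd.DataFrame) -> ModelFit:
    """Fit the trial-level correctness model.

    ``table`` needs columns backend, trial_id, source_label, spotlight_pct,
    info_proportion, correctness. Logit-transformed correctness is modelled
    with source, size and information-proportion fixed effects (no
    interaction) and crossed random intercepts for backend and trial.
    """
    required = {"backend", "trial_id", "source_label", "spotlight_pct",
                "info_proportion", "correctness"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = table.copy().reset_index(drop=True)
    if not (np.isfinite(df["info_proportion"]).all()
            and np.isfinite(df["correctness"]).all()):
        raise ValueError("non-finite covariates or response")
    y = shrink_bounded(df["correctness"].to_numpy())
    df["resp"] = _logit(y)
    jac = float(-np.log(y * (1.0 - y)).sum())
    df["size01"] = df["spotlight_pct"].to_numpy(float) / 100.0
    df = pd.concat([df, _source_codes(df["source_label"])], axis=1)
    cols = ["size01", "info_proportion", "src_control_vs_random",
            "src_super_vs_control"]
    term_groups = {"spotlight_size": ["size01"],
                   "info_proportion": ["info_proportion"],
                   "source": ["src_control_vs_random", "src_super_vs_control"]}
    vc = {"backend": "0 + C(backend)", "trial": "0 + C(trial_id)"}
    res = _fit_lmm(df, "resp", cols, vc_formula=vc)
    return _summarize(res, "trial_logit", "logit", jac, df, "resp", cols,
                      term_groups, {"vc_formula": vc},
                      one_tailed=("src_control_vs_random", "src_super_vs_control"))


def term_tests(fit: ModelFit) -> pd.DataFrame:
    """Likelihood-ratio chi-square test for each named fixed-effect term.

    Each term's columns are dropped and the nested model refitted by ML;
    chi2 = 2 (llf_full - llf_reduced), df = number of dropped columns.
    """
    if fit._term_groups is None:
        raise ValueError("fit carries no term structure for nested tests")
    return pd.DataFrame([dict(zip(("term", "chi2", "df", "p"),
                                  (term, *lrt_term(fit, term))))
                         for term in fit._term_groups])


def lrt_term(fit: ModelFit, term: str) -> tuple[float, int, float]:
    """Likelihood-ratio test of one named term; returns (chi2, df, p)."""
    cols = fit._term_groups[term]
    reduced_cols = [c for c in fit._fixed_cols if c not in cols]
    if len(reduced_cols) == len(fit._fixed_cols):
        raise ValueError(f"unknown term {term!r}")
    res = _fit_lmm(fit._data, fit._response, reduced_cols, **fit._fit_kwargs)
    chi2 = max(0.0, 2.0 * (fit.llf - res.llf))
    df_ = len(fit._fixed_cols) - len(reduced_cols)
    return chi2, df_, float(sps.chi2.sf(chi2, df_))


def wald_term_test(fit: ModelFit, term: str) -> tuple[float, int, float]:
    """Wald chi-square test of a named fixed-effect term from a single fit.

    Asymptotically equivalent to the likelihood-ratio test in
    :func:`term_tests` but needs no refit, so it is the workhorse for
    replicate-heavy calibration studies. Returns (chi2, df, p).
    """
    if term not in fit._term_groups:
        raise ValueError(f"unknown term {term!r}")
    present = set(fit.terms["term"])
    names = [c for c in fit._term_groups[term] if c in present]
    b = fit.terms.set_index("term").loc[names, "estimate"].to_numpy()
    v = fit.cov_fe.loc[names, names].to_numpy()
    chi2 = float(b @ np.linalg.solve(v, b))
    return chi2, len(names), float(sps.chi2.sf(chi2, len(names)))


# ---------------------------------------------------------------------------
# generative simulators used to check the models' calibration

def simulate_condition_table(n_backends: int = 5, *, b0: float = -1.5,
                             b_size: float = 3.0, b_cvr: float = 0.0,
                             b_svc: float = 0.0, backend_sd: float = 0.25,
                             resid_sd: float = 0.3, form: str = "logit",
                             seed: int = 0) -> pd.DataFrame:
    """AUC tables from the condition model's own generative form.

    On the logit (or identity) scale: b0 + b_size*size + b_cvr*[control or
    super] + b_svc*[super] + backend intercept + noise, then mapped through the
    inverse link and clipped into (0, 1).
    """
    rng = np.random.default_rng(seed)
    sizes = np.array([12, 24, 36, 48, 60, 100], float)
    rows = []
    for b in range(n_backends):
        u = rng.normal(0.0, backend_sd)
        for src in SOURCE_ORDER:
            cvr = 1.0 if src in ("control", "super") else 0.0
            svc = 1.0 if src == "super" else 0.0
            eta = (b0 + b_size * sizes / 100.0 + b_cvr * cvr + b_svc * svc + u
                   + rng.normal(0.0, resid_sd, size=len(sizes)))
            auc = 1.0 / (1.0 + np.exp(-eta)) if form == "logit" \
                else np.clip(eta, 1e-3, 1 - 1e-3)
            for s, a in zip(sizes, auc):
                rows.append({"backend": f"net{b}", "source_label": src,
                             "spotlight_pct": int(s), "auc": float(a)})
    return pd.DataFrame(rows)


def simulate_trial_table(n_backends: int = 4, n_trials_per_source: int = 20,
                         *, b0: float = 0.2, b_size: float = 1.0,
                         b_info: float = 2.0, b_cvr: float = 0.0,
                         b_svc: float = 0.0, info_via_source: float = 0.0,
                         backend_sd: float = 0.2, trial_sd: float = 0.3,
                         resid_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Trial tables with crossed backend/trial effects and a mediation knob.

    ``info_via_source`` shifts the information proportion itself by source
    rank (random < control < super), emulating a purely quantity-mediated
    advantage; ``b_cvr``/``b_svc`` add direct source effects on correctness
    beyond information quantity.
    """
    rng = np.random.default_rng(seed)
    sizes = np.array([12, 36, 60, 100], float)
    u_backend = rng.normal(0.0, backend_sd, size=n_backends)
    rows = []
    trial = 0
    for src_rank, src in enumerate(SOURCE_ORDER):
        cvr = 1.0 if src in ("control", "super") else 0.0
        svc = 1.0 if src == "super" else 0.0
        for _ in range(n_trials_per_source):
            size = rng.choice(sizes) / 100.0
            base_info = 0.15 + 0.6 * size + info_via_source * src_rank
            info = float(np.clip(base_info + rng.normal(0, 0.05), 0.01, 0.99))
            u_trial = rng.normal(0.0, trial_sd)
            for b in range(n_backends):
                eta = (b0 + b_size * size + b_info * info + b_cvr * cvr
                       + b_svc * svc + u_backend[b] + u_trial
                       + rng.normal(0.0, resid_sd))
                corr = 1.0 / (1.0 + np.exp(-eta))
                rows.append({"backend": f"net{b}", "trial_id": f"tr{trial:04d}",
                             "source_label": src, "spotlight_pct": int(size * 100),
                             "info_proportion": info, "correctness": float(corr)})
            trial += 1
    return pd.DataFrame(rows)
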