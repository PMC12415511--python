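"""Trial-level design matrices, mixed-effects fitting with a deterministic
random-effects backoff, planned contrasts and FDR adjustment.

Coding conventions: categorical predictors are deviation coded against a
declared reference level (indicator minus 1/k, so a two-level factor is
-0.5/+0.5 and a three-level group factor yields two columns whose
coefficients are direct reference-vs-level mean differences, e.g. OCD vs HC
and OCD vs SAD), and continuous predictors are centered (around their mean
or a stated midpoint, e.g. block around 2.5), so the intercept is the grand
mean.  Models attempt the maximal random-effects structure (by-participant
intercept plus slopes for all within-participant terms and their
correlations, plus a by-electrode intercept for ERP models) and back off
deterministically on non-convergence or singular fit: correlations first,
then highest-order interaction slopes, then lower-order slopes — never the
participant intercept.

The numerical solvers are statsmodels' MixedLM (gaussian) and variational
BinomialBayesMixedGLM (binomial); this module owns the coding rules, the
backoff policy, the contrast algebra and the FDR families.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Term",
    "DesignSpec",
    "DesignMatrices",
    "MixedFit",
    "build_design",
    "fit_mixed",
    "planned_contrasts",
    "simple_effect_weights",
    "fdr_adjust",
]

SINGULAR_REL_TOL = 1e-4
MAX_ABS_CORR = 0.999


@dataclass(frozen=True)
class Term:
    """One fixed-effect predictor and its coding rule.

    kind 'categorical': deviation coded against ``reference``; 'continuous':
    centered at ``center`` (a number, or None for the sample mean); 'map':
    values replaced via ``mapping`` (e.g. contingency A/B, C/D, E/F ->
    -1, 0, 1) and used as-is.
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None
    levels: tuple[str, ...] | None = None
    center: float | None = None
    mapping: dict | None = None
    within: bool = True  # varies within participant (eligible for a random slope)


@dataclass(frozen=True)
class DesignSpec:
    outcome: str
    terms: tuple[Term, ...]
    family: str = "gaussian"
    electrode_intercept: bool = False
    max_order: int | None = None  # cap on interaction order; None = full crossing


@dataclass
class DesignMatrices:
    """Coded data plus bookkeeping for formulas, slopes and contrasts."""

    data: pd.DataFrame
    outcome: str
    fixed_cols: list[str]
    slope_cols: list[str]
    col_order: dict[str, int]  # interaction order of every fixed column
    codes: dict[str, dict[str, float]]  # categorical column -> level -> code
    family: str
    electrode_intercept: bool

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.fixed_cols)


def _code_categorical(values: pd.Series, term: Term) -> dict[str, pd.Series]:
    levels = list(term.levels) if term.levels else sorted(values.dropna().unique())
    ref = term.reference if term.reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among levels of {term.name}: {levels}")
    unknown = set(values.dropna().unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(unknown)} in {term.name}")
    k = len(levels)
    cols = {}
    for lev in levels:
        if lev == ref:
            continue
        cols[f"{term.name}_{lev}"] = (values == lev).astype(float) - 1.0 / k
    return cols


def build_design(df: pd.DataFrame, spec: DesignSpec) -> DesignMatrices:
    """Code predictors and expand the full factorial crossing.

    Interaction columns are elementwise products named ``a_x_b``; the
    random-slope template comprises the coded columns of all
    within-participant terms and their mutual interactions.
    """
    data = df.copy()
    term_cols: dict[str, list[str]] = {}
    codes: dict[str, dict[str, float]] = {}
    within_terms: list[str] = []
    for term in spec.terms:
        if term.name not in data.columns:
            raise ValueError(f"column {term.name!r} missing from data")
        if term.kind == "categorical":
            new = _code_categorical(data[term.name], term)
            for col, series in new.items():
                data[col] = series
                lev = col[len(term.name) + 1 :]
                k = (len(term.levels) if term.levels
                     else data[term.name].dropna().nunique())
                codes[col] = {
                    l: (1.0 if l == lev else 0.0) - 1.0 / k
                    for l in (term.levels or sorted(data[term.name].dropna().unique()))
                }
            term_cols[term.name] = list(new)
        elif term.kind == "continuous":
            center = data[term.name].mean() if term.center is None else term.center
            col = f"{term.name}_c"
            data[col] = data[term.name].astype(float) - center
            term_cols[term.name] = [col]
        elif term.kind == "map":
            col = f"{term.name}_code"
            mapped = data[term.name].map(term.mapping)
            if mapped.isna().any() and not data[term.name].isna().all():
                bad = sorted(data.loc[mapped.isna(), term.name].dropna().unique())
                raise ValueError(f"no mapping for level(s) {bad} of {term.name}")
            data[col] = mapped.astype(float)
            term_cols[term.name] = [col]
        else:
            raise ValueError(f"unknown term kind {term.kind!r}")
        if term.within:
            within_terms.append(term.name)

    fixed_cols: list[str] = []
    col_order: dict[str, int] = {}
    names = [t.name for t in spec.terms]
    max_order = spec.max_order or len(names)
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(names, order):
            for cols in itertools.product(*(term_cols[n] for n in combo)):
                name = "_x_".join(cols) if order > 1 else cols[0]
                if order > 1:
                    data[name] = np.prod([data[c].to_numpy() for c in cols], axis=0)
                fixed_cols.append(name)
                col_order[name] = order

    slope_cols = [
        c for c in fixed_cols
        if all(any(part in term_cols[w] for w in within_terms) for part in c.split("_x_"))
    ]
    return DesignMatrices(
        data=data,
        outcome=spec.outcome,
        fixed_cols=fixed_cols,
        slope_cols=slope_cols,
        col_order=col_order,
        codes=codes,
        family=spec.family,
        electrode_intercept=spec.electrode_intercept,
    )


@dataclass
class MixedFit:
    """A converged mixed model plus the backoff path that produced it."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    family: str
    backoff_log: list[str]
    structure: str
    result: object = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = self.coef / se
        return pd.DataFrame(
            {"term": self.names, "estimate": self.coef, "se": se, "z": z,
             "p": 2 * sps.norm.sf(np.abs(z))}
        )


def _is_singular(res, scale: float) -> bool:
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    diag = np.diag(cov_re) if cov_re.size else np.array([])
    vcs = np.asarray(res.vcomp) if res.vcomp.size else np.array([])
    tol = SINGULAR_REL_TOL * scale
    if (diag < tol).any() or (vcs < tol).any():
        return True
    if cov_re.size > 1:
        d = np.sqrt(np.clip(diag, 1e-300, None))
        corr = cov_re / np.outer(d, d)
        off = corr[~np.eye(len(d), dtype=bool)]
        if (np.abs(off) > MAX_ABS_CORR).any():
            return True
    return False


def _gaussian_stages(dm: DesignMatrices) -> list[tuple[str, str, dict[str, str]]]:
    """Backoff ladder: (label, re_formula, vc_formula) per stage."""
    el_vc = {"electrode": "0 + C(electrode)"} if dm.electrode_intercept else {}
    stages = []
    slopes = list(dm.slope_cols)
    if slopes:
        stages.append(
            ("maximal_correlated", "1 + " + " + ".join(slopes), dict(el_vc))
        )
        # drop correlations: slopes become independent variance components
        remaining = sorted(slopes, key=lambda c: (-dm.col_order[c], -slopes.index(c)))
        while remaining:
            vc = dict(el_vc)
            vc.update({f"s_{c}": f"0 + {c}" for c in remaining})
            label = "uncorrelated[" + ",".join(remaining) + "]"
            stages.append((label, "1", vc))
            remaining = remaining[1:]  # drop highest-order slope first
    stages.append(("intercept_only", "1", dict(el_vc)))
    if el_vc:
        stages.append(("participant_intercept_only", "1", {}))
    return stages


def fit_mixed(dm: DesignMatrices, groups: str = "participant_id") -> MixedFit:
    """Fit the model with the maximal random-effects structure that converges.

    Gaussian outcomes use REML MixedLM; a stage is rejected on
    non-convergence, a fitting error, or a singular fit (a variance
    component within ``1e-4 * var(y)`` of zero, or a random-effect
    correlation at the boundary).  Binomial outcomes use the variational
    Bayes binomial GLMM with a participant intercept (random slopes are not
    attempted; the backoff log records this).  Inference on fixed effects
    uses the normal approximation in both families.
    """
    data = dm.data.dropna(subset=[dm.outcome] + dm.fixed_cols).copy()
    log: list[str] = []
    if dm.family == "gaussian":
        scale = float(data[dm.outcome].var())
        last_err = None
        for label, re_formula, vc_formula in _gaussian_stages(dm):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM.from_formula(
                        dm.formula, data, groups=data[groups],
                        re_formula=re_formula, vc_formula=vc_formula or None,
                    )
                    res = model.fit(reml=True)
                if not res.converged:
                    log.append(f"{label}: not converged")
                    continue
                if _is_singular(res, scale):
                    log.append(f"{label}: singular fit")
                    continue
            except (np.linalg.LinAlgError, ValueError) as err:
                log.append(f"{label}: {err}")
                last_err = err
                continue
            log.append(f"{label}: accepted")
            k = len(dm.fixed_cols) + 1
            return MixedFit(
                names=["Intercept"] + dm.fixed_cols,
                coef=np.asarray(res.fe_params),
                cov=np.asarray(res.cov_params())[:k, :k],
                family="gaussian",
                backoff_log=log,
                structure=label,
                result=res,
            )
        raise RuntimeError(f"no random-effects structure converged: {log}") from last_err
    if dm.family == "binomial":
        log.append("binomial: participant random intercept (variational); slopes not attempted")
        vcf = {"participant": f"0 + C({groups})"}
        if dm.electrode_intercept:
            vcf["electrode"] = "0 + C(electrode)"
        model = BinomialBayesMixedGLM.from_formula(dm.formula, vcf, data)
        res = model.fit_vb()
        k = len(dm.fixed_cols) + 1
        return MixedFit(
            names=["Intercept"] + dm.fixed_cols,
            coef=np.asarray(res.fe_mean),
            cov=np.diag(np.asarray(res.fe_sd[:k]) ** 2),
            family="binomial",
            backoff_log=log,
            structure="vb_intercepts",
            result=res,
        )
    raise ValueError(f"unknown family {dm.family!r}")


def planned_contrasts(
    fit: MixedFit,
    contrasts: dict[str, dict[str, float]],
    alpha: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Estimate linear combinations of fixed effects with CIs and BH-adjusted p.

    Each contrast is a dict of fixed-effect-name -> weight; a bare
    coefficient contrast is ``{name: 1.0}``.  The supplied set forms one FDR
    family.
    """
    index = {n: i for i, n in enumerate(fit.names)}
    rows = []
    for label, weights in contrasts.items():
        c = np.zeros(len(fit.names))
        for name, w in weights.items():
            if name not in index:
                raise ValueError(f"contrast {label!r}: unknown term {name!r}")
            c[index[name]] = w
        est = float(c @ fit.coef)
        se = float(np.sqrt(c @ fit.cov @ c))
        z = est / se
        half = sps.norm.ppf(1 - alpha / 2) * se
        rows.append(
            {"label": label, "estimate": est, "se": se, "stat": z,
             "ci_low": est - half, "ci_high": est + half,
             "p": 2 * sps.norm.sf(abs(z))}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_adjust(out["p"].to_numpy()) if adjust else out["p"]
    return out


def simple_effect_weights(
    dm: DesignMatrices, effect_col: str, within: dict[str, str]
) -> dict[str, float]:
    """Contrast weights for the simple effect of one coded column at fixed
    levels of other (deviation-coded categorical) factors.

    Under deviation coding the effect of A at level l of B is
    ``b_A + code_B(l) * b_AxB`` (extended multiplicatively over several
    conditioning factors); these are the follow-ups run when an interaction
    is flagged.
    """
    weights = {effect_col: 1.0}
    for col in dm.fixed_cols:
        parts = col.split("_x_")
        if effect_col not in parts or len(parts) == 1:
            continue
        others = [p for p in parts if p != effect_col]
        w = 1.0
        ok = True
        for p in others:
            if p in dm.codes and p in within:
                w *= dm.codes[p][within[p]]
            else:
                ok = False
                break
        if ok:
            weights[col] = w
    return weights


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
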