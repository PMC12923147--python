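"""Mixed-model comparison of movement outcomes across conditions.

Given a long-format outcome table (per-trial entropy or pair-distance CV
with columns ``condition, session, trial, <unit>, <outcome>`` where the unit
is the offensive role or the player pair), this module

1. fits the four-model ladder
   * ``rand_role``  — outcome ~ condition + (1 | unit)
   * ``rand_sess``  — outcome ~ condition + (1 | session) + (1 | session:trial)
   * ``basic``      — outcome ~ condition + (1 | unit) + (1 | session) + (1 | session:trial)
   * ``interactive``— outcome ~ condition * unit + (1 | session) + (1 | session:trial)
   compares them by sequential likelihood-ratio tests on ML fits and by AIC,
   and selects the model with the smallest AIC (the first ladder pair is not
   nested; its chi-square is reported clamped at zero and flagged);
2. refits the selected model by REML with treatment coding and stated
   baseline categories, reporting Satterthwaite t tests per coefficient;
3. runs a Type III ANOVA (sum-to-zero contrasts) with partial eta-squared
   effect sizes; and
4. produces Bonferroni-adjusted pairwise condition contrasts within each
   unit level (family = number of condition pairs), plus a distribution-free
   permutation fallback for any single comparison.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError
from .lmm import LMMResult, contrast_test, fit_lmm, lr_test, wald_F
from .tracking import CONDITION_ORDER

LADDER = ("rand_role", "rand_sess", "basic", "interactive")

_UNIT_PREFERRED = ("O1", "O2", "O3", "D1", "D2", "D3",
                   "O3-O1", "O3-O2", "O3-D1", "O3-D2", "O3-D3")


def _ordered_levels(values, preferred) -> list[str]:
    present = list(pd.unique(np.asarray(values)))
    ordered = [l for l in preferred if l in present]
    ordered += sorted(set(present) - set(ordered))
    return ordered


def _factor_columns(series, levels, base, coding: str):
    """Columns encoding a factor. Treatment: dummies vs base; sum: sum-to-zero."""
    vals = np.asarray(series)
    if coding == "treatment":
        lv = [l for l in levels if l != base]
        cols = [(vals == l).astype(float) for l in lv]
        names = [str(l) for l in lv]
    else:  # sum coding; last level carries -1
        lv = levels[:-1]
        cols, names = [], []
        for l in lv:
            col = (vals == l).astype(float) - (vals == levels[-1]).astype(float)
            cols.append(col)
            names.append(str(l))
    return cols, names


def build_design(
    table: pd.DataFrame,
    outcome: str,
    unit_col: str,
    cond_base: str | None = None,
    unit_base: str | None = None,
    interactive: bool = True,
    coding: str = "treatment",
):
    """Build y and the fixed-effect design matrix for a ladder model.

    Returns ``(y, X, names, info)`` where ``info`` carries the level orders
    and term column spans needed for cell predictions and Type III blocks.
    """
    cond_levels = _ordered_levels(table["condition"], CONDITION_ORDER)
    unit_levels = _ordered_levels(table[unit_col], _UNIT_PREFERRED)
    if len(cond_levels) < 2:
        raise ContractError("need at least two condition levels")
    cond_base = cond_base or cond_levels[0]
    unit_base = unit_base or unit_levels[0]
    if cond_base not in cond_levels or unit_base not in unit_levels:
        raise ContractError("baseline category not present in the data")
    if coding == "treatment":  # baseline first so treatment dummies are vs base
        cond_levels = [cond_base] + [l for l in cond_levels if l != cond_base]
        unit_levels = [unit_base] + [l for l in unit_levels if l != unit_base]

    n = len(table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    c_cols, c_names = _factor_columns(table["condition"], cond_levels, cond_base, coding)
    cols += c_cols
    names += [f"condition[{nm}]" for nm in c_names]
    spans = {"condition": (1, 1 + len(c_cols))}
    u_cols: list[np.ndarray] = []
    if interactive:
        u_cols, u_names = _factor_columns(table[unit_col], unit_levels, unit_base, coding)
        cols += u_cols
        names += [f"{unit_col}[{nm}]" for nm in u_names]
        spans[unit_col] = (spans["condition"][1], spans["condition"][1] + len(u_cols))
        start = spans[unit_col][1]
        for cc, cn in zip(c_cols, c_names):
            for uc, un in zip(u_cols, u_names):
                cols.append(cc * uc)
                names.append(f"condition[{cn}]:{unit_col}[{un}]")
        spans["interaction"] = (start, start + len(c_cols) * len(u_cols))
    X = np.column_stack(cols)
    y = table[outcome].to_numpy(dtype=float)
    info = {
        "cond_levels": cond_levels, "unit_levels": unit_levels,
        "cond_base": cond_base, "unit_base": unit_base,
        "coding": coding, "interactive": interactive, "spans": spans,
        "unit_col": unit_col, "names": names,
    }
    return y, X, names, info


def cell_row(info: dict, cond: str, unit: str) -> np.ndarray:
    """Design row predicting the (condition, unit) cell mean."""
    names = info["names"]
    x = np.zeros(len(names))
    x[0] = 1.0

    def factor_vals(levels, base, level):
        if info["coding"] == "treatment":
            return {l: float(l == level) for l in levels if l != base}
        vals = {}
        for l in levels[:-1]:
            vals[l] = 1.0 if level == l else (-1.0 if level == levels[-1] else 0.0)
        return vals

    cv = factor_vals(info["cond_levels"], info["cond_base"], cond)
    for i, nm in enumerate(names):
        if nm.startswith("condition[") and ":" not in nm:
            x[i] = cv[nm[len("condition["):-1]]
    if info["interactive"]:
        uv = factor_vals(info["unit_levels"], info["unit_base"], unit)
        ucol = info["unit_col"]
        for i, nm in enumerate(names):
            if nm.startswith(f"{ucol}[") and ":" not in nm:
                x[i] = uv[nm[len(ucol) + 1:-1]]
            elif ":" in nm:
                cpart, upart = nm.split(":")
                x[i] = cv[cpart[len("condition["):-1]] * uv[upart[len(ucol) + 1:-1]]
    return x


def _vc_spec(table: pd.DataFrame, model: str, unit_col: str) -> dict[str, np.ndarray]:
    sess = table["session"].to_numpy()
    st = (table["session"].astype(str) + ":" + table["trial"].astype(str)).to_numpy()
    unit = table[unit_col].to_numpy()
    if model == "rand_role":
        return {unit_col: unit}
    if model == "rand_sess":
        return {"session": sess, "session_trial": st}
    if model == "basic":
        return {unit_col: unit, "session": sess, "session_trial": st}
    if model == "interactive":
        return {"session": sess, "session_trial": st}
    raise ValueError(f"unknown model: {model}")


def _fit_model(table, outcome, unit_col, model, method, cond_base=None, unit_base=None,
               coding="treatment") -> tuple[LMMResult, dict]:
    y, X, names, info = build_design(
        table, outcome, unit_col, cond_base, unit_base,
        interactive=(model == "interactive"), coding=coding,
    )
    res = fit_lmm(y, X, _vc_spec(table, model, unit_col), method=method, exog_names=names)
    return res, info


@dataclass
class ModelComparison:
    """Ladder comparison: ML fits, sequential LRTs, AIC, selection."""

    table: pd.DataFrame          # model, k, loglik, AIC, chi2, df, p, non_nested
    fits: dict[str, LMMResult]   # ML fits by model name
    selected: str                # smallest-AIC model


def fit_ladder(table: pd.DataFrame, outcome: str, unit_col: str = "role") -> ModelComparison:
    """Fit the four-model ladder with ML and compare by LRT + AIC."""
    if not table["condition"].nunique() >= 2:
        raise ContractError("ladder needs at least two conditions")
    fits = {}
    for model in LADDER:
        fits[model], _ = _fit_model(table, outcome, unit_col, model, method="ml")
    rows = []
    prev = None
    for model in LADDER:
        f = fits[model]
        row = {"model": model, "k": f.k_params, "loglik": f.loglik, "AIC": f.aic,
               "chi2": np.nan, "df": np.nan, "p": np.nan, "non_nested": False}
        if prev is not None:
            chi2, df, p = lr_test(fits[prev], f)
            row.update(chi2=chi2, df=df, p=p, non_nested=(prev, model) == ("rand_role", "rand_sess"))
        rows.append(row)
        prev = model
    comp = pd.DataFrame(rows)
    selected = comp.loc[comp["AIC"].idxmin(), "model"]
    comp["selected"] = comp["model"] == selected
    return ModelComparison(table=comp, fits=fits, selected=str(selected))


@dataclass
class OptimalFit:
    """REML fit of the selected model plus the design metadata for contrasts."""

    result: LMMResult
    info: dict
    model: str
    outcome: str

    def fixed_effects(self) -> pd.DataFrame:
        return self.result.fixef_table()

    def random_effects(self) -> dict[str, float]:
        out = dict(self.result.vcomp)
        out["residual"] = self.result.sigma2_resid
        return out


def fit_optimal(
    table: pd.DataFrame,
    outcome: str,
    unit_col: str = "role",
    model: str = "interactive",
    cond_base: str = "low_before_tips",
    unit_base: str | None = None,
) -> OptimalFit:
    """REML fit of a ladder model with treatment coding and stated baselines."""
    unit_base = unit_base or _ordered_levels(table[unit_col], _UNIT_PREFERRED)[0]
    res, info = _fit_model(
        table, outcome, unit_col, model, method="reml",
        cond_base=cond_base, unit_base=unit_base,
    )
    return OptimalFit(result=res, info=info, model=model, outcome=outcome)


def anova_type3(table: pd.DataFrame, outcome: str, unit_col: str = "role") -> pd.DataFrame:
    """Type III ANOVA of ``outcome ~ condition * unit`` with sum contrasts.

    Fits the interactive model by REML under sum-to-zero coding and Wald-F
    tests each term block (condition, unit, interaction) with
    Satterthwaite-pooled denominator df.  Returns one row per effect with F,
    the df pair, p, and partial eta-squared F*df1 / (F*df1 + df2).
    """
    if table["condition"].nunique() < 2:
        raise ContractError("Type III ANOVA needs at least two conditions")
    res, info = _fit_model(table, outcome, unit_col, "interactive", method="reml",
                           coding="sum")
    rows = []
    labels = {"condition": "condition", unit_col: unit_col, "interaction": "interaction"}
    for term in ("condition", unit_col, "interaction"):
        lo, hi = info["spans"][term]
        L = np.zeros((hi - lo, res.p))
        L[:, lo:hi] = np.eye(hi - lo)
        F, ndf, ddf, p = wald_F(res, L)
        rows.append(
            {"effect": labels[term], "F": F, "df_num": ndf, "df_den": ddf, "p": p,
             "partial_eta2": partial_eta_squared(F, ndf, ddf)}
        )
    return pd.DataFrame(rows)


def partial_eta_squared(F: float, df_num: float, df_den: float) -> float:
    """partial eta^2 = F*df_num / (F*df_num + df_den)."""
    return float(F * df_num / (F * df_num + df_den))


def bonferroni(p, family: int):
    """Bonferroni adjustment, capped at 1."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * family)


def pairwise_contrasts(fit: OptimalFit, adjust: str = "bonferroni") -> pd.DataFrame:
    """All pairwise condition contrasts within each unit level.

    Contrast ``A vs B`` estimates cell-mean(A) - cell-mean(B).  p-values are
    Bonferroni-adjusted within each unit's family of condition pairs.  If the
    fitted model has no condition x unit interaction the contrasts do not
    depend on the unit: a warning is issued and one marginal family returned.
    """
    info = fit.info
    conds = info["cond_levels"]
    if info["coding"] == "treatment":
        ordered = [l for l in CONDITION_ORDER if l in conds]
        ordered += [l for l in conds if l not in ordered]
        conds = ordered
    pairs = list(itertools.combinations(conds, 2))
    family = len(pairs)
    if not info["interactive"]:
        warnings.warn("model has no condition x unit interaction; returning marginal contrasts")
        units = [None]
    else:
        units = info["unit_levels"]
    rows = []
    for unit in units:
        for a, b in pairs:
            u = unit if unit is not None else info["unit_levels"][0]
            c = cell_row(info, a, u) - cell_row(info, b, u)
            est, se, df, t, p = contrast_test(fit.result, c)
            rows.append(
                {
                    info["unit_col"]: unit if unit is not None else "(marginal)",
                    "comparison": f"{a} vs {b}",
                    "estimate": est, "se": se, "df": df, "t": t,
                    "p_raw": p,
                    "p_adj": float(bonferroni(p, family)) if adjust == "bonferroni" else p,
                }
            )
    return pd.DataFrame(rows)


def permutation_contrast(
    table: pd.DataFrame,
    outcome: str,
    cond_a: str,
    cond_b: str,
    unit_col: str = "role",
    unit_level: str | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive_limit: int = 20000,
) -> dict:
    """Two-sided permutation p for the mean difference between two conditions.

    Condition labels are permuted within session strata.  When the number of
    distinct label arrangements is small the null distribution is enumerated
    exhaustively; otherwise ``n_perm`` Monte-Carlo permutations are drawn.
    """
    sub = table[table["condition"].isin([cond_a, cond_b])]
    if unit_level is not None:
        sub = sub[sub[unit_col] == unit_level]
    if (sub["condition"] == cond_a).sum() < 2 or (sub["condition"] == cond_b).sum() < 2:
        raise ContractError("permutation test needs >=2 trials per condition")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")

    strata = []
    for _, g in sub.groupby("session", sort=True):
        vals = g[outcome].to_numpy(dtype=float)
        n_a = int((g["condition"] == cond_a).sum())
        strata.append((vals, n_a))
    na_tot = sum(na for _, na in strata)
    nb_tot = len(sub) - na_tot
    tot_sum = sub[outcome].sum()

    def stat_from_asums(asum: float) -> float:
        return asum / na_tot - (tot_sum - asum) / nb_tot

    obs = stat_from_asums(sub.loc[sub["condition"] == cond_a, outcome].sum())

    n_arr = math.prod(math.comb(len(v), na) for v, na in strata)
    eps = 1e-12 + 1e-9 * abs(obs)
    if n_arr <= exhaustive_limit:
        per_stratum = [
            [sum(v[list(ix)]) for ix in itertools.combinations(range(len(v)), na)]
            for v, na in strata
        ]
        count = 0
        for combo in itertools.product(*per_stratum):
            if abs(stat_from_asums(sum(combo))) >= abs(obs) - eps:
                count += 1
        p = count / n_arr
        method = "exhaustive"
        n_used = n_arr
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBEEF]))
        count = 0
        for _ in range(n_perm):
            asum = 0.0
            for v, na in strata:
                asum += rng.permutation(v)[:na].sum()
            if abs(stat_from_asums(asum)) >= abs(obs) - eps:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "monte_carlo"
        n_used = n_perm
    return {"estimate": float(obs), "p": float(p), "method": method, "n_perm": n_used}
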