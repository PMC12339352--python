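"""Three-factor ANOVA and broad-sense heritability from REML components.

The trial design is genotype (G) x year (Y) x treatment (L) with a single
observation per cell.  Two complementary analyses are provided:

* a fixed-effects ANOVA (Type III sums of squares, sum-to-zero contrasts)
  testing G, Y, L and the G x Y / G x L interactions against the residual;
* a REML mixed model with random genotype, genotype-by-year and
  genotype-by-treatment effects (year and treatment fixed), whose variance
  components feed the multi-environment broad-sense heritability

      R = VA / (VA + VAL/L + VAY/Y + Ve/(L*Y))

  with L treatments and Y years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .phenotype import trait_columns

_TERMS = {
    "C(accession, Sum)": "G",
    "C(year, Sum)": "Y",
    "C(treatment, Sum)": "L",
    "C(accession, Sum):C(year, Sum)": "GxY",
    "C(accession, Sum):C(treatment, Sum)": "GxL",
}


def _long(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    df = table[["accession", "year", "treatment", trait]].rename(columns={trait: "value"})
    return df.dropna(subset=["value"])


def three_way_anova(table: pd.DataFrame, trait: str) -> pd.Series:
    """Type III F tests for G, Y, L, GxY and GxL on one trait.

    Returns a Series with F_* and p_* per term plus residual df and MS.
    Raises if the design is singular (aliased terms).
    """
    df = _long(table, trait)
    formula = (
        "value ~ C(accession, Sum) + C(year, Sum) + C(treatment, Sum)"
        " + C(accession, Sum):C(year, Sum) + C(accession, Sum):C(treatment, Sum)"
    )
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom; design saturated")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(fit, typ=3)
    out = {"trait": trait}
    for term, short in _TERMS.items():
        if term not in tab.index or not np.isfinite(tab.loc[term, "F"]):
            raise ValueError(f"aliased/singular term in design: {short}")
        out[f"F_{short}"] = float(tab.loc[term, "F"])
        out[f"p_{short}"] = float(tab.loc[term, "PR(>F)"])
    out["df_resid"] = float(fit.df_resid)
    out["ms_resid"] = float(fit.ssr / fit.df_resid)
    return pd.Series(out)


def anova_table(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """ANOVA rows for every trait, in the layout of the trial summary table."""
    traits = traits if traits is not None else trait_columns(table)
    return pd.DataFrame([three_way_anova(table, t) for t in traits]).set_index("trait")


def heritability(va: float, val: float, vay: float, ve: float,
                 n_treatments: int, n_years: int) -> float:
    """Broad-sense heritability R = VA/(VA + VAL/L + VAY/Y + Ve/(L*Y))."""
    if n_treatments < 1 or n_years < 1:
        raise ValueError("need at least one treatment and one year")
    comps = np.array([va, val, vay, ve], dtype=float)
    if np.any(comps < 0):
        raise ValueError("variance components must be >= 0")
    denom = va + val / n_treatments + vay / n_years + ve / (n_treatments * n_years)
    if denom == 0:
        warnings.warn("all variance components zero; heritability undefined")
        return np.nan
    return float(va / denom)


@dataclass
class VarianceComponentsResults:
    """REML variance components and the heritability they imply."""

    trait: str
    va: float
    val: float
    vay: float
    ve: float
    n_treatments: int
    n_years: int
    converged: bool
    truncated: list
    model_result: object = None

    @property
    def heritability(self) -> float:
        return heritability(self.va, self.val, self.vay, self.ve,
                            self.n_treatments, self.n_years)

    def components(self) -> dict:
        return {"VA": self.va, "VAL": self.val, "VAY": self.vay, "Ve": self.ve}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.va, self.val, self.vay, self.ve, self.heritability],
            },
            index=["VA", "VAL (GxL)", "VAY (GxY)", "Ve", "R (broad-sense)"],
        )


class VarianceComponentsModel:
    """REML mixed model for one trait of the G x Y x L trial.

    Fixed effects: intercept, year, treatment.  Random effects: genotype
    intercept plus iid genotype-by-year and genotype-by-treatment
    deviations (variance-component formulation grouped by accession).
    Negative point estimates cannot occur under the profiled REML
    parameterization; estimates at the zero boundary are flagged.
    """

    def __init__(self, table: pd.DataFrame, trait: str):
        self.trait = trait
        self.data = _long(table, trait)
        for col, need in (("year", 2), ("treatment", 2), ("accession", 2)):
            if self.data[col].nunique() < need:
                raise ValueError(f"need >= {need} levels of {col}")
        self.n_treatments = int(self.data["treatment"].nunique())
        self.n_years = int(self.data["year"].nunique())

    def fit(self, **kwargs) -> VarianceComponentsResults:
        vcf = {"gxy": "0 + C(year)", "gxl": "0 + C(treatment)"}
        model = smf.mixedlm(
            "value ~ C(year) + C(treatment)", data=self.data,
            groups=self.data["accession"], re_formula="1", vc_formula=vcf,
        )
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "lbfgs", "powell"):
                try:
                    fit_kw = dict(kwargs)
                    if method is not None:
                        fit_kw.setdefault("method", method)
                    res = model.fit(reml=True, **fit_kw)
                except Exception:
                    continue
                if res.converged:
                    break
        if res is None or not np.all(np.isfinite(res.params)):
            trace = None if res is None else res.params.to_dict()
            raise RuntimeError(
                f"REML did not converge for {self.trait}; last parameters: {trace}")
        if not res.converged:
            # variance component on the zero boundary: estimates remain valid
            warnings.warn(
                f"REML for {self.trait} stopped at a boundary solution; "
                "component estimates retained")
        va = float(res.cov_re.iloc[0, 0])
        vay = float(res.vcomp[list(model.exog_vc.names).index("gxy")])
        val = float(res.vcomp[list(model.exog_vc.names).index("gxl")])
        ve = float(res.scale)
        truncated = [n for n, v in (("VA", va), ("VAY", vay), ("VAL", val))
                     if v < 1e-8]
        if truncated:
            warnings.warn(f"variance component(s) at zero boundary: {truncated}")
        return VarianceComponentsResults(
            trait=self.trait,
            va=max(va, 0.0), val=max(val, 0.0), vay=max(vay, 0.0), ve=max(ve, 0.0),
            n_treatments=self.n_treatments, n_years=self.n_years,
            converged=bool(res.converged), truncated=truncated, model_result=res,
        )


def estimate_variance_components(table: pd.DataFrame, trait: str,
                                 **kwargs) -> VarianceComponentsResults:
    """Functional wrapper around :class:`VarianceComponentsModel`."""
    return VarianceComponentsModel(table, trait).fit(**kwargs)


def heritability_table(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """ANOVA F tests plus REML heritability per trait (summary-table layout)."""
    traits = traits if traits is not None else trait_columns(table)
    anova = anova_table(table, traits)
    rs = {}
    for t in traits:
        rs[t] = estimate_variance_components(table, t).heritability
    anova["R"] = pd.Series(rs)
    return anova
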