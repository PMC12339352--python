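"""Descriptive statistics for the phenotype table.

The canonical in-memory form is the wide table written by the simulator /
expected from field records: columns ``accession, year, treatment`` plus
one column per trait (DW, PH, TN, GN, TGW, SR, PL, PW, DH).  All functions
exclude missing values trait-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TRAITS

_ID_COLS = ("accession", "year", "treatment")


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in _ID_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    bad = set(df["treatment"].unique()) - {"CK", "AK"}
    if bad:
        raise ValueError(f"unknown treatment labels: {sorted(bad)}")
    return df


def trait_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in _ID_COLS]


def seed_setting_rate(gn, ug):
    """Seed setting rate SR = GN / (GN + UG).

    Accepts scalars or arrays; GN + UG == 0 yields NaN with a warning
    (the rate is undefined for a plant with no spikelets recorded).
    """
    gn = np.asarray(gn, dtype=float)
    ug = np.asarray(ug, dtype=float)
    if np.any(gn < 0) or np.any(ug < 0):
        raise ValueError("grain counts must be non-negative")
    total = gn + ug
    zero = total == 0
    if np.any(zero):
        warnings.warn("SR undefined where GN + UG == 0; returning missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.where(zero, np.nan, gn / np.where(zero, 1.0, total))
    return float(sr) if sr.ndim == 0 else sr


def shannon_diversity(values, mode: str = "distinct", k: int = 10) -> float:
    """Shannon-Weaver index H' = -sum Pi ln Pi (nats), Pi = Ni / N.

    ``distinct`` treats each distinct observed value as a class.
    ``binned`` uses the germplasm-standard k-class scheme: class 1 holds
    x < mu - 2*sigma, class k holds x >= mu + 2*sigma, and the k-2 interior
    classes have equal width 4*sigma / (k - 2).  Missing values are
    excluded; empty classes contribute nothing.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no non-missing values for diversity index")
    if mode == "distinct":
        _, counts = np.unique(x, return_counts=True)
    elif mode == "binned":
        if k < 3:
            raise ValueError("binned mode needs k >= 3")
        mu, sigma = x.mean(), x.std(ddof=1) if x.size > 1 else 0.0
        if sigma == 0:
            return 0.0
        edges = np.concatenate([
            [-np.inf], mu - 2 * sigma + np.arange(k - 1) * 4 * sigma / (k - 2), [np.inf]
        ])
        counts, _ = np.histogram(x, bins=edges)
        counts = counts[counts > 0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(stats.entropy(counts))  # natural log


def trait_summary(table: pd.DataFrame, group_by=("year", "treatment"),
                  shannon_mode: str = "distinct") -> pd.DataFrame:
    """Per-group, per-trait n, mean, SD, CV (%), min, max and H'.

    CV uses the sample SD (n-1 denominator) as 100*SD/mean; a zero mean
    leaves CV as NaN with a warning flag in the ``cv_defined`` column.
    """
    traits = trait_columns(table)
    rows = []
    for keys, grp in table.groupby(list(group_by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for t in traits:
            x = grp[t].dropna().to_numpy(dtype=float)
            if x.size < 2:
                raise ValueError(f"need >= 2 non-missing values for {t} in group {keys}")
            mean, sd = x.mean(), x.std(ddof=1)
            cv_ok = mean != 0
            if not cv_ok:
                warnings.warn(f"CV undefined for {t} in group {keys} (zero mean)")
            rows.append({
                **dict(zip(group_by, keys)),
                "trait": t, "n": int(x.size), "mean": mean, "sd": sd,
                "cv": 100.0 * sd / mean if cv_ok else np.nan,
                "cv_defined": cv_ok,
                "min": x.min(), "max": x.max(),
                "shannon": shannon_diversity(x, mode=shannon_mode),
            })
    return pd.DataFrame(rows)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    year: object = None
    treatment: object = None

    def to_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t")


def correlation_matrix(table: pd.DataFrame, year=None, treatment=None,
                       traits=None) -> CorrelationMatrix:
    """Trait x trait Pearson r for one (year, treatment) group.

    p-values come from the t statistic r*sqrt((n-2)/(1-r^2)) with n-2 df,
    two-sided; pairs are complete-case per trait pair.  A zero-variance
    trait yields NaN entries for its pairs.
    """
    grp = table
    if year is not None:
        grp = grp[grp["year"] == year]
    if treatment is not None:
        grp = grp[grp["treatment"] == treatment]
    traits = list(traits) if traits is not None else trait_columns(grp)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    data = grp[traits].to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = int(np.sum(~np.isnan(data[:, i])))
        for j in range(i + 1, k):
            mask = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            nij = int(mask.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3:
                raise ValueError(f"fewer than 3 complete pairs for {traits[i]}/{traits[j]}")
            xi, xj = data[mask, i], data[mask, j]
            if xi.std() == 0 or xj.std() == 0:
                warnings.warn(f"zero-variance trait in pair {traits[i]}/{traits[j]}")
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=traits),
        p=pd.DataFrame(p, index=idx, columns=traits),
        n=pd.DataFrame(n, index=idx, columns=traits),
        year=year, treatment=treatment,
    )
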