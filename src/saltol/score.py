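"""Fuzzy-membership comprehensive tolerance score D.

The core bespoke computation: per-accession stress/control trait ratios
(the salt tolerance index Si = 100 * AK/CK), a correlation-matrix PCA of
the standardized index matrix, min-max membership values Ui per retained
component, variance-contribution weights Wi = PVi / sum(PVi), and the
comprehensive score

    D = sum_i Ui * Wi          (in [0, 1], larger = more tolerant)

ranked descending to pick tolerant accessions.  D is the phenotype handed
to the GWAS stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import multivariate
from .phenotype import trait_columns

logger = logging.getLogger(__name__)

#: Ranking-stage default: drop the one trait the trial showed no treatment
#: response for (seed setting rate), keeping the 8 stress-responsive traits.
DEFAULT_DROPPED_TRAIT = "SR"


def tolerance_index(table: pd.DataFrame, year, traits=None,
                    drop_sr: bool = False) -> pd.DataFrame:
    """Accession x trait matrix of Si = 100 * AK / CK for one year.

    Accessions missing either treatment are excluded with a warning;
    zero or missing CK cells leave a NaN (flagged by the caller's
    imputation log).  ``drop_sr`` removes the seed-setting-rate column,
    mirroring an index restricted to stress-responsive traits.
    """
    grp = table[table["year"] == year]
    if grp.empty:
        raise ValueError(f"no records for year {year}")
    traits = list(traits) if traits is not None else trait_columns(grp)
    if drop_sr and DEFAULT_DROPPED_TRAIT in traits:
        traits = [t for t in traits if t != DEFAULT_DROPPED_TRAIT]
    ck = grp[grp["treatment"] == "CK"].set_index("accession")[traits]
    ak = grp[grp["treatment"] == "AK"].set_index("accession")[traits]
    common = ck.index.intersection(ak.index)
    dropped = ck.index.symmetric_difference(ak.index)
    if len(dropped):
        warnings.warn(f"excluding {len(dropped)} accession(s) missing a treatment")
    if len(common) == 0:
        raise ValueError("no accession has both CK and AK records")
    ck, ak = ck.loc[common], ak.loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        si = 100.0 * ak.to_numpy() / ck.to_numpy()
    si[~np.isfinite(si)] = np.nan
    out = pd.DataFrame(si, index=common, columns=traits)
    out.attrs["year"] = year
    return out


def index_pca_scores(index_matrix: pd.DataFrame,
                     retain_rule: str = "cumulative_ge",
                     retain_threshold: float = 0.80) -> multivariate.PcaResult:
    """Correlation PCA of the standardized index matrix, with retention.

    Missing cells are mean-imputed (logged by ``standardize``); components
    are retained until the cumulative variance proportion reaches the
    threshold (default 80%).
    """
    if index_matrix.shape[0] < 2 or index_matrix.shape[1] < 2:
        raise ValueError("need at least 2 accessions and 2 traits")
    std = multivariate.standardize(index_matrix)
    res = multivariate.pca(std)
    res.n_retained = multivariate.retain_components(res, retain_rule, retain_threshold)
    return res


def membership(scores) -> np.ndarray:
    """Min-max membership Ui = (Si - Smin) / (Smax - Smin) for one component.

    Order-preserving and affine-invariant for positive scalings; a
    degenerate component (Smax == Smin) maps every accession to 0.5 with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("membership needs >= 2 accessions")
    smin, smax = np.min(s), np.max(s)
    if smax == smin:
        warnings.warn("degenerate component: Smax == Smin, returning 0.5")
        return np.full(s.shape, 0.5)
    return (s - smin) / (smax - smin)


def component_weights(pv) -> np.ndarray:
    """Wi = PVi / sum(PVi) over the retained components."""
    pv = np.asarray(pv, dtype=float)
    if pv.size == 0:
        raise ValueError("no retained components")
    if np.any(pv <= 0):
        raise ValueError("variance contributions must be positive")
    return pv / pv.sum()


def comprehensive_score(U: pd.DataFrame, W) -> tuple:
    """D = sum_i Ui * Wi per accession, plus the descending dense ranking.

    Ties share a rank; within a tie the accession index order is kept.
    """
    W = np.asarray(W, dtype=float)
    if U.shape[1] != W.size:
        raise ValueError("membership columns and weights length differ")
    d = pd.Series(U.to_numpy() @ W, index=U.index, name="D")
    rank = d.rank(method="dense", ascending=False).astype(int).rename("rank")
    return d, rank


@dataclass
class ScoreResults:
    """Fitted comprehensive-score pipeline for one year."""

    year: object
    index_matrix: pd.DataFrame
    pca: multivariate.PcaResult
    U: pd.DataFrame                  # accession x retained component
    W: pd.Series                     # weight per retained component
    D: pd.Series
    rank: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.U.shape[1]

    def top(self, n: int = 40) -> pd.DataFrame:
        """Top-n accessions by D (the tolerant-variety short list)."""
        df = self.summary()
        return df.head(n)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"D": self.D, "rank": self.rank})
        df = df.join(self.U)
        return df.sort_values(["rank", "D"], ascending=[True, False]).sort_values(
            "rank", kind="stable"
        )

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index_label="accession")


class ToleranceScoreModel:
    """Comprehensive saline-alkali tolerance scoring for one trial year.

    Composes index -> standardize -> PCA -> retain -> membership ->
    weights -> D.  ``fit()`` returns :class:`ScoreResults` carrying the
    full provenance (retained k, eigenvalues, PVi, Wi, sign flips).
    """

    def __init__(self, table: pd.DataFrame, year, traits=None, drop_sr: bool = False,
                 retain_rule: str = "cumulative_ge", retain_threshold: float = 0.80):
        self.table = table
        self.year = year
        self.traits = traits
        self.drop_sr = drop_sr
        self.retain_rule = retain_rule
        self.retain_threshold = retain_threshold

    def fit(self) -> ScoreResults:
        idx = tolerance_index(self.table, self.year, self.traits, self.drop_sr)
        res = index_pca_scores(idx, self.retain_rule, self.retain_threshold)
        k = res.n_retained
        comps = list(res.scores.columns[:k])
        U = pd.DataFrame(
            {c: membership(res.scores[c].to_numpy()) for c in comps},
            index=res.scores.index,
        )
        W = pd.Series(component_weights(res.proportion[:k]), index=comps, name="W")
        D, rank = comprehensive_score(U, W.to_numpy())
        prov = {
            "year": self.year,
            "traits": list(idx.columns),
            "n_retained": k,
            "eigenvalues": res.eigenvalues.tolist(),
            "proportion": res.proportion.tolist(),
            "weights": W.to_dict(),
            "sign_flips": res.sign_flips.tolist(),
            "retain_rule": (self.retain_rule, self.retain_threshold),
            "n_imputed": int(idx.isna().sum().sum()),
        }
        logger.info("score pipeline year=%s retained=%d weights=%s",
                    self.year, k, np.round(W.to_numpy(), 4))
        return ScoreResults(self.year, idx, res, U, W, D, rank, prov)


def score_pipeline(table: pd.DataFrame, year, **kwargs) -> ScoreResults:
    """Functional wrapper around :class:`ToleranceScoreModel`."""
    return ToleranceScoreModel(table, year, **kwargs).fit()
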