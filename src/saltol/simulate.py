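"""Synthetic field-trial generator with known ground truth.

Emulates a two-year, two-treatment (control CK vs saline-alkali stress AK)
trial of a rice resource population: nine yield-related traits per
accession with genotype, year, treatment, genotype-by-year and
genotype-by-treatment components, plus a per-accession stress/control
tolerance ratio that a handful of causal SNPs partially control.  The
generative model is

    y[i,j,l,t] = r[i,l] * (mu_t + g[i,t] + yr[j,t] + gy[i,j,t])
                 + s[l,t] + gl[i,l,t] + e[i,j,l,t]

with r[i,CK] = 1 and r[i,AK] = base + sum_k beta_k (x[i,k] - mean_k) + eps_i.
All random effects are mean-zero Gaussians with trait-indexed variances;
the ratio multiplies the systematic part so both treatments keep the stated
residual variance, and genotype-by-treatment effects are drawn for both
treatments so the variance components the downstream REML model estimates
are exactly the ones written into the ground truth.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .genes import GeneModels

TRAITS = ("DW", "PH", "TN", "GN", "TGW", "SR", "PL", "PW", "DH")

TRAIT_UNITS = {
    "DW": "g", "PH": "cm", "TN": "count", "GN": "count", "TGW": "g",
    "SR": "proportion", "PL": "cm", "PW": "g", "DH": "days",
}

#: Plausible japonica trait means for a high-latitude field trial.
TRAIT_MEANS = {
    "DW": 22.0, "PH": 95.0, "TN": 12.0, "GN": 1400.0, "TGW": 25.0,
    "SR": 0.85, "PL": 18.0, "PW": 3.2, "DH": 100.0,
}

# Default variance components as fractions of the trait mean (squared);
# chosen to put trait CVs in the 8-35% range typical of resource panels.
_DEFAULT_FRACS = {
    "var_genotype": 0.12,
    "var_year": 0.04,
    "var_treatment": 0.0,
    "var_gxy": 0.04,
    "var_gxl": 0.04,
    "var_residual": 0.08,
}

_RATIO_FLOOR = 1e-3
_CAUSAL_MAF_MIN = 0.15


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition bundle for the synthetic trial.

    Variance fields accept a scalar (applied to every trait) or a
    length-``n_traits`` sequence; ``None`` selects trait-scaled defaults.
    """

    n_accessions: int = 300
    n_years: int = 2
    n_treatments: int = 2
    n_traits: int = 9
    traits: tuple = TRAITS
    n_markers: int = 2000
    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    maf_range: tuple = (0.05, 0.5)
    var_genotype: object = None
    var_year: object = None
    var_treatment: object = None
    var_gxy: object = None
    var_gxl: object = None
    var_residual: object = None
    n_causal: int = 1
    causal_effect_sizes: object = 0.15
    tolerance_ratio_base: float = 0.8
    tolerance_ratio_sd: float = 0.05
    ld_block_size: int = 1
    first_year: int = 2016
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_years", "n_treatments", "n_traits",
                     "n_markers", "n_chromosomes", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_treatments != 2:
            raise ConfigurationError("the trial design has exactly 2 treatments (CK, AK)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_markers:
            raise ConfigurationError("n_causal cannot exceed n_markers")
        if self.n_causal < 0:
            raise ConfigurationError("n_causal must be >= 0")
        if not 0.0 < self.tolerance_ratio_base:
            raise ConfigurationError("tolerance_ratio_base must be positive")
        if self.tolerance_ratio_sd < 0:
            raise ConfigurationError("tolerance_ratio_sd must be >= 0")
        self.traits = tuple(self.traits)[: self.n_traits]
        if len(self.traits) != self.n_traits:
            raise ConfigurationError("traits list shorter than n_traits")
        for name in _DEFAULT_FRACS:
            arr = self.variances(name)
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} must be >= 0")

    def variances(self, name: str) -> np.ndarray:
        """Resolve a variance field to a per-trait array."""
        val = getattr(self, name)
        if val is None:
            frac = _DEFAULT_FRACS[name]
            means = np.array([TRAIT_MEANS.get(t, 10.0) for t in self.traits])
            return (frac * means) ** 2
        arr = np.broadcast_to(np.atleast_1d(np.asarray(val, dtype=float)),
                              (self.n_traits,)).copy()
        return arr

    def accession_ids(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_accessions)]

    def seed_streams(self) -> dict:
        """Named child RNGs off the master seed.

        Separate streams per component, so e.g. redrawing phenotype noise
        does not perturb the genotypes.
        """
        names = ("genotypes", "effects", "ratio", "noise", "genes")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def digest(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    causal_marker_ids: list
    causal_effects: list
    tolerance_ratio: pd.Series
    variance_components: dict
    ranking: list = field(default=None)

    def __post_init__(self) -> None:
        if self.ranking is None:
            order = self.tolerance_ratio.sort_values(ascending=False, kind="stable")
            self.ranking = list(order.index)
        if sorted(self.ranking) != sorted(self.tolerance_ratio.index):
            raise ValueError("ranking must be a permutation of accession ids")

    def to_json(self, path) -> None:
        payload = {
            "causal_marker_ids": list(self.causal_marker_ids),
            "causal_effects": [float(b) for b in self.causal_effects],
            "tolerance_ratio": {k: float(v) for k, v in self.tolerance_ratio.items()},
            "variance_components": self.variance_components,
            "ranking": list(self.ranking),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["causal_marker_ids"], d["causal_effects"],
            pd.Series(d["tolerance_ratio"]), d["variance_components"], d["ranking"],
        )


# --------------------------------------------------------------- genotypes

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Unlinked biallelic SNP dosages with uniform MAF spectrum.

    Markers are spread over ``n_chromosomes`` with strictly increasing
    positions; dosages are Binomial(2, p) per accession.  With
    ``ld_block_size > 1`` consecutive markers within a block copy the block
    founder column with a 10% per-call resampling rate, giving local LD.
    """
    rng = config.seed_streams()["genotypes"]
    n, m = config.n_accessions, config.n_markers
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)

    chrom_of = np.concatenate(
        [np.full(len(part), c) for c, part in
         enumerate(np.array_split(np.arange(m), config.n_chromosomes))]
    )
    positions = np.empty(m, dtype=int)
    for c in range(config.n_chromosomes):
        idx = np.where(chrom_of == c)[0]
        if len(idx) > config.chrom_length_bp:
            raise ConfigurationError("chromosome too short for marker count")
        pos = np.sort(rng.choice(config.chrom_length_bp, size=len(idx), replace=False)) + 1
        positions[idx] = pos

    if config.ld_block_size > 1:
        for start in range(0, m, config.ld_block_size):
            block = np.arange(start, min(start + config.ld_block_size, m))
            block = block[chrom_of[block] == chrom_of[block[0]]]
            founder = dosages[:, block[0]]
            for j in block[1:]:
                keep = rng.random(n) >= 0.10
                dosages[:, j] = np.where(keep, founder, dosages[:, j])

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    markers = pd.DataFrame({
        "marker": [f"S{c + 1}_{p}" for c, p in zip(chrom_of, positions)],
        "chrom": [str(c + 1) for c in chrom_of],
        "pos": positions,
        "ref": bases[ref_i],
        "alt": bases[alt_i],
    })
    dosage_df = pd.DataFrame(
        dosages, index=pd.Index(config.accession_ids(), name="accession"),
        columns=markers["marker"],
    )
    return GenotypeMatrix(dosage_df, markers)


# -------------------------------------------------------------- phenotypes

def _draw_ratio(config: SimulationConfig, genotypes: GenotypeMatrix, rng):
    """Per-accession AK/CK tolerance ratio and the causal markers behind it."""
    n = config.n_accessions
    r = np.full(n, config.tolerance_ratio_base)
    causal_ids: list = []
    betas = np.array([])
    if config.n_causal > 0:
        maf = genotypes.maf().to_numpy()
        eligible = np.where(maf >= _CAUSAL_MAF_MIN)[0]
        if len(eligible) < config.n_causal:
            eligible = np.argsort(maf)[::-1][: max(config.n_causal, 1)]
        picks = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
        causal_ids = [genotypes.markers["marker"].iloc[j] for j in picks]
        betas = np.broadcast_to(
            np.atleast_1d(np.asarray(config.causal_effect_sizes, dtype=float)),
            (config.n_causal,),
        ).copy()
        X = genotypes.dosages.iloc[:, picks].to_numpy(dtype=float)
        X = np.nan_to_num(X, nan=np.nanmean(X))
        r = r + (X - X.mean(axis=0)) @ betas
    r = r + rng.normal(0.0, config.tolerance_ratio_sd, size=n)
    return np.clip(r, _RATIO_FLOOR, None), causal_ids, betas


def simulate_phenotypes(config: SimulationConfig, genotypes: GenotypeMatrix):
    """Phenotype table plus ground truth for the trial in ``config``.

    Returns
    -------
    (DataFrame, GroundTruth)
        Wide table with columns accession, year, treatment and one column
        per trait; ground truth records the causal markers, the true
        tolerance ratio per accession, and the per-trait variance
        components that generated the data.
    """
    if genotypes.n_accessions != config.n_accessions:
        raise ValueError("genotype accession set does not match the configuration")
    streams = config.seed_streams()
    eff, noise = streams["effects"], streams["noise"]
    n, Y, L, T = config.n_accessions, config.n_years, config.n_treatments, config.n_traits

    sd = {k: np.sqrt(config.variances(k)) for k in _DEFAULT_FRACS}
    g = eff.normal(size=(n, T)) * sd["var_genotype"]
    yr = eff.normal(size=(Y, T)) * sd["var_year"]
    gy = eff.normal(size=(n, Y, T)) * sd["var_gxy"]
    gl = eff.normal(size=(n, L, T)) * sd["var_gxl"]
    shift = eff.normal(size=(L, T)) * sd["var_treatment"]
    e = noise.normal(size=(n, Y, L, T)) * sd["var_residual"]

    ratio, causal_ids, betas = _draw_ratio(config, genotypes, streams["ratio"])
    r_il = np.ones((n, L))
    r_il[:, 1] = ratio  # column 0 = CK, column 1 = AK

    mu = np.array([TRAIT_MEANS.get(t, 10.0) for t in config.traits])
    systematic = mu[None, None, :] + g[:, None, :] + yr[None, :, :] + gy  # (n, Y, T)
    values = (
        r_il[:, None, :, None] * systematic[:, :, None, :]
        + shift[None, None, :, :] + gl[:, None, :, :] + e
    )  # (n, Y, L, T)

    accs = config.accession_ids()
    frames = []
    for j in range(Y):
        for l, treat in enumerate(("CK", "AK")):
            block = pd.DataFrame(values[:, j, l, :], columns=list(config.traits))
            block.insert(0, "treatment", treat)
            block.insert(0, "year", config.first_year + j)
            block.insert(0, "accession", accs)
            frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    if "SR" in table.columns:
        table["SR"] = table["SR"].clip(0.0, 1.0)
    for t in ("TN", "GN"):
        if t in table.columns:
            table[t] = table[t].clip(lower=0.0)

    vc = {
        trait: {
            "VA": float(config.variances("var_genotype")[k]),
            "VAY": float(config.variances("var_gxy")[k]),
            "VAL": float(config.variances("var_gxl")[k]),
            "Ve": float(config.variances("var_residual")[k]),
        }
        for k, trait in enumerate(config.traits)
    }
    truth = GroundTruth(
        causal_marker_ids=causal_ids,
        causal_effects=list(betas),
        tolerance_ratio=pd.Series(ratio, index=pd.Index(accs, name="accession")),
        variance_components=vc,
    )
    return table, truth


# ------------------------------------------------------------- gene models

def simulate_gene_models(config: SimulationConfig, n_genes: int,
                         length_range=(2_000, 8_000), max_exons: int = 5) -> GeneModels:
    """Non-overlapping genes with 1-5 exons each, spread over chromosomes.

    Genes are placed in disjoint equal-width bins per chromosome, which
    guarantees non-overlap; raises if the requested genes cannot fit.
    """
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    rng = config.seed_streams()["genes"]
    per_chrom = [len(p) for p in np.array_split(np.arange(n_genes), config.n_chromosomes)]
    genes, exons = [], []
    serial = 0
    for c, k in enumerate(per_chrom):
        if k == 0:
            continue
        bin_w = config.chrom_length_bp // k
        if bin_w <= length_range[1] + 2:
            raise ConfigurationError("genes cannot fit chromosome length")
        for b in range(k):
            serial += 1
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            start = b * bin_w + int(rng.integers(1, bin_w - length))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{c + 1:02d}_{serial:04d}"
            genes.append((gid, str(c + 1), start, end, strand))
            n_ex = int(rng.integers(1, max_exons + 1))
            if n_ex == 1:
                bounds = [start, end]
            else:
                cuts = np.sort(rng.choice(
                    np.arange(start + 1, end), size=2 * (n_ex - 1), replace=False))
                bounds = [start, *cuts.tolist(), end]
            for x in range(n_ex):
                exons.append((gid, str(c + 1), int(bounds[2 * x]),
                              int(bounds[2 * x + 1]), x + 1))
    return GeneModels(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end", "exon_number"]),
    )


# ------------------------------------------------------------- fixture set

def write_fixture_set(config: SimulationConfig, out_dir, n_genes: int = 60) -> dict:
    """Write the full fixture bundle and return its manifest.

    Files: phenotypes.csv, genotypes.vcf + genotypes.tsv, genes.gff3,
    ground_truth.json, manifest.json.  Deterministic for a given config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(config)
    table, truth = simulate_phenotypes(config, genotypes)
    models = simulate_gene_models(config, n_genes)

    files = {}
    table.to_csv(out / "phenotypes.csv", index=False, float_format="%.6g")
    files["phenotypes"] = "phenotypes.csv"
    genotypes.to_vcf(out / "genotypes.vcf")
    files["genotypes_vcf"] = "genotypes.vcf"
    genotypes.to_tsv(out / "genotypes.tsv")
    files["genotypes_tsv"] = "genotypes.tsv"
    models.to_gff3(out / "genes.gff3")
    files["gene_models"] = "genes.gff3"
    truth.to_json(out / "ground_truth.json")
    files["ground_truth"] = "ground_truth.json"

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_accessions": config.n_accessions,
        "n_markers": config.n_markers,
        "n_genes": n_genes,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["files"] = dict(files, manifest="manifest.json")
    return manifest
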