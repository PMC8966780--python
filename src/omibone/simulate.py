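"""Synthetic paired microbiome / metabolome / phenotype cohorts.

The generator emulates the structure of a paired shotgun-metagenomic and
untargeted serum-metabolomics study of ~500 peri/post-menopausal women
with a standardized bone-mineral-density phenotype:

* compositions drawn as the softmax of a logistic-normal model with a
  power-law mean profile (heavy-tailed relative abundances, a few
  dominant taxa) and multinomial count sampling at a fixed depth;
* metabolite intensities log-normal with pooled-QC replicate rows, a
  single injection-order drift term and intensity-dependent missingness
  (low intensities are more likely missing, mimicking detection limits);
* six covariates (age, BMI, exercise, years since menopause, FSH,
  estradiol) with the empirical sign pattern of their bivariate
  phenotype associations;
* a phenotype assembled additively from the covariates, a zero-sum
  log-contrast taxon effect on the latent CLR matrix, standardized
  metabolite effects and Gaussian noise — every component is recorded
  so downstream recovery is checkable against ground truth;
* cross-omics correlation blocks implemented as latent Gaussian factors
  shared between member taxa (log abundance) and member metabolites
  (log intensity), planted on phenotype-associated features so that the
  supervised integration methods have a recoverable target.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .metabolome import IntensityTable

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort",
           "generate_reference_pairs", "ReferencePairs"]

# phylum proportions observed in comparable gut metagenome studies
_PHYLA = [
    ("Firmicutes", 0.592),
    ("Bacteroidetes", 0.315),
    ("Proteobacteria", 0.061),
    ("Actinobacteria", 0.022),
    ("Fusobacteria", 0.005),
    ("Verrucomicrobia", 0.005),
]

# standardized covariate effects on the phenotype; signs follow the
# empirical bivariate association pattern (BMI and exercise positive,
# years since menopause and FSH negative, estradiol positive, age ~ 0)
_COVARIATE_EFFECTS = {
    "age": -0.03,
    "bmi": 0.32,
    "exercise": 0.10,
    "years_since_menopause": -0.13,
    "fsh": -0.32,
    "estradiol": 0.24,
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the emulated study scale: ~500 subjects, ~600
    taxa (nearly all above the 0.01% mean-abundance filter), ~400
    annotated serum metabolites with one pooled-QC injection per ten
    samples.
    """

    n_samples: int = 500
    n_taxa: int = 600
    n_metabolites: int = 400
    n_qc: int = 50
    frac_planted_taxa: float = 0.05
    frac_planted_metabolites: float = 0.05
    effect_size: float = 0.8
    n_cross_blocks: int = 2
    block_rho: float = 0.6
    block_n_taxa: int = 8
    block_n_metabolites: int = 6
    missing_rate: float = 0.1
    noise_sd: float = 1.0
    sequencing_depth: int = 100_000
    log_abundance_sd: float = 1.0
    log_intensity_sd: float = 0.5
    batch_drift: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_planted_taxa", "frac_planted_metabolites",
                     "block_rho", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_samples", "n_taxa", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_planted_taxa(self) -> int:
        # rounded to even so the ±effect split sums to zero exactly
        n = round(self.frac_planted_taxa * self.n_taxa)
        return n - (n % 2)

    @property
    def n_planted_metabolites(self) -> int:
        return round(self.frac_planted_metabolites * self.n_metabolites)


@dataclass
class SyntheticCohort:
    """A generated cohort with its planted ground truth.

    ``truth`` records the zero-sum taxon effect vector, the metabolite
    effect vector and the cross-block memberships;
    ``phenotype_components`` the exact additive decomposition of the
    phenotype (covariates / taxa / metabolites / noise).
    """

    config: CohortConfig
    counts: pd.DataFrame
    metabolites: pd.DataFrame
    qc_samples: pd.DataFrame
    covariates: pd.DataFrame
    phenotype: pd.Series
    taxonomy: pd.Series
    truth: dict
    latent_clr: pd.DataFrame
    phenotype_components: dict

    def intensity_table(self) -> IntensityTable:
        """Stack biological and QC rows into one annotated table."""
        values = pd.concat([self.metabolites, self.qc_samples])
        qc = np.r_[np.zeros(len(self.metabolites), dtype=bool),
                   np.ones(len(self.qc_samples), dtype=bool)]
        return IntensityTable(values=values, qc=qc)

    def write(self, outdir) -> None:
        """Dump the cohort as TSV tables plus a JSON truth file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.metabolites.to_csv(outdir / "metabolites.tsv", sep="\t", na_rep="NA")
        self.qc_samples.to_csv(outdir / "qc_samples.tsv", sep="\t", na_rep="NA")
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
        self.phenotype.rename("phenotype").to_csv(outdir / "phenotype.tsv", sep="\t")
        self.taxonomy.rename("phylum").to_csv(outdir / "taxonomy.tsv", sep="\t")
        truth = {
            "beta_taxa": {k: float(v) for k, v in self.truth["beta_taxa"].items()
                          if v != 0},
            "beta_metabolites": {k: float(v) for k, v in
                                 self.truth["beta_metabolites"].items() if v != 0},
            "cross_blocks": self.truth["cross_blocks"],
            "config": asdict(self.config),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def _planted_signs(n: int) -> np.ndarray:
    signs = np.ones(n)
    signs[n // 2:] = -1.0
    return signs


def _loading_signs(beta: np.ndarray) -> np.ndarray:
    """Block factor-loading signs: the planted effect sign where one
    exists, alternating ± for effect-free members."""
    signs = np.sign(beta)
    alt = np.resize([1.0, -1.0], beta.size)
    return np.where(signs != 0, signs, alt)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort under ``config`` (deterministic per seed)."""
    cfg = config
    if cfg.n_planted_taxa > cfg.n_taxa:
        raise ValueError("planted taxa exceed taxon count")
    if cfg.n_planted_metabolites > cfg.n_metabolites:
        raise ValueError("planted metabolites exceed metabolite count")
    needed_taxa = cfg.n_cross_blocks * cfg.block_n_taxa
    if needed_taxa > cfg.n_taxa:
        raise ValueError("cross-block taxa exceed taxon count")
    if cfg.n_cross_blocks * cfg.block_n_metabolites > cfg.n_metabolites:
        raise ValueError("cross-block metabolites exceed metabolite count")
    rng = np.random.default_rng(cfg.seed)
    n, p, m = cfg.n_samples, cfg.n_taxa, cfg.n_metabolites

    sample_ids = [f"S{i:04d}" for i in range(n)]
    taxon_ids = [f"taxon_{j:04d}" for j in range(p)]
    metab_ids = [f"met_{j:04d}" for j in range(m)]

    # --- taxonomy labels -------------------------------------------------
    labels = np.concatenate([
        np.repeat(name, int(round(frac * p))) for name, frac in _PHYLA
    ])
    labels = np.resize(labels, p)
    rng.shuffle(labels)
    taxonomy = pd.Series(labels, index=taxon_ids, name="phylum")

    # --- planted effects and block membership ----------------------------
    # planted taxa drawn from the upper abundance ranks so their signal
    # survives the rare-taxon filter
    upper = np.arange(max(cfg.n_planted_taxa, p // 2))
    planted_taxa = np.sort(rng.choice(upper, size=cfg.n_planted_taxa, replace=False))
    beta_taxa = np.zeros(p)
    beta_taxa[planted_taxa] = cfg.effect_size * _planted_signs(cfg.n_planted_taxa)

    planted_mets = np.sort(rng.choice(m, size=cfg.n_planted_metabolites, replace=False))
    beta_mets = np.zeros(m)
    signs_m = np.resize([1.0, -1.0], cfg.n_planted_metabolites)
    beta_mets[planted_mets] = cfg.effect_size * signs_m

    # cross blocks ride on phenotype-associated features first so that
    # supervised integration has a recoverable target
    blocks = []
    taxa_pool = list(planted_taxa) + [j for j in range(p) if j not in set(planted_taxa)]
    met_pool = list(planted_mets) + [j for j in range(m) if j not in set(planted_mets)]
    for b in range(cfg.n_cross_blocks):
        bt = taxa_pool[b * cfg.block_n_taxa:(b + 1) * cfg.block_n_taxa]
        bm = met_pool[b * cfg.block_n_metabolites:(b + 1) * cfg.block_n_metabolites]
        blocks.append({"taxa": [taxon_ids[j] for j in bt],
                       "metabolites": [metab_ids[j] for j in bm],
                       "taxa_idx": [int(j) for j in bt],
                       "metabolite_idx": [int(j) for j in bm]})

    # --- latent compositions ---------------------------------------------
    mean_log = -1.0 * np.log(np.arange(1, p + 1))          # power-law profile
    n_bg = 5
    f_bg = rng.standard_normal((n, n_bg))
    f_block = rng.standard_normal((n, max(cfg.n_cross_blocks, 1)))
    # sparse background co-occurrence: ~40% of taxa load on one of a few
    # shared factors with varied strength; planted-effect taxa stay out of
    # the background factors so the ground-truth labels remain identifiable
    # by marginal association (correlated-but-non-causal neighbours would
    # otherwise be irreducible false positives of any marginal screen)
    bg_assign = rng.integers(0, n_bg, size=p)
    bg_var = rng.uniform(0.2, 0.6, size=p)
    in_bg = rng.random(p) < 0.4
    in_bg[planted_taxa] = False
    bg_var = np.where(in_bg, bg_var, 0.0)
    z_taxa = np.sqrt(bg_var)[None, :] * f_bg[:, bg_assign]
    resid_var = 1.0 - bg_var
    for b, blk in enumerate(blocks):
        idx = blk["taxa_idx"]
        # factor-loading signs follow the planted effect signs so the
        # shared factor reinforces (rather than cancels out of) the
        # zero-sum phenotype contribution of the block members
        signs = _loading_signs(beta_taxa[idx])
        z_taxa[:, idx] = signs[None, :] * np.sqrt(cfg.block_rho) * f_block[:, [b]]
        resid_var[idx] = 1.0 - cfg.block_rho
    z_taxa = z_taxa + np.sqrt(resid_var)[None, :] * rng.standard_normal((n, p))
    log_abund = mean_log[None, :] + cfg.log_abundance_sd * z_taxa
    log_abund -= log_abund.max(axis=1, keepdims=True)       # softmax stability
    comp = np.exp(log_abund)
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(cfg.sequencing_depth, row) for row in comp
    ])
    latent_clr = np.log(comp) - np.log(comp).mean(axis=1, keepdims=True)

    # --- metabolite intensities ------------------------------------------
    mu_met = rng.normal(12.0, 1.5, size=m)
    z_met = rng.standard_normal((n, m))
    for b, blk in enumerate(blocks):
        idx = blk["metabolite_idx"]
        signs = _loading_signs(beta_mets[idx])
        z_met[:, idx] = (
            signs[None, :] * np.sqrt(cfg.block_rho) * f_block[:, [b]]
            + np.sqrt(1.0 - cfg.block_rho) * rng.standard_normal((n, len(idx)))
        )
    drift = cfg.batch_drift * (np.arange(n) / max(n - 1, 1) - 0.5)
    log_int = mu_met[None, :] + cfg.log_intensity_sd * z_met + drift[:, None]
    intensities = np.exp(log_int)

    # pooled QC replicates: exponential of the mean log intensity plus
    # small technical noise
    qc_ids = [f"QC{i:03d}" for i in range(cfg.n_qc)]
    qc_log = log_int.mean(axis=0)[None, :] + 0.05 * rng.standard_normal((cfg.n_qc, m))
    qc_intensities = np.exp(qc_log)

    # --- covariates -------------------------------------------------------
    cov = pd.DataFrame({
        "age": rng.normal(52.8, 2.9, n),
        "bmi": rng.normal(23.0, 2.9, n),
        "exercise": np.clip(rng.normal(0.81, 0.8, n), 0, None),
        "years_since_menopause": np.clip(rng.normal(2.0, 1.0, n), 0, None),
        "fsh": np.clip(rng.normal(76.2, 32.2, n), 1.0, None),
        "estradiol": (rng.random(n) < 0.383).astype(float),
    }, index=sample_ids)
    cov_std = (cov - cov.mean()) / cov.std(ddof=1)
    gamma = np.array([_COVARIATE_EFFECTS[c] for c in cov.columns])

    # --- phenotype ---------------------------------------------------------
    comp_cov = cov_std.to_numpy() @ gamma
    comp_taxa = latent_clr @ beta_taxa
    comp_mets = z_met @ beta_mets
    comp_noise = cfg.noise_sd * rng.standard_normal(n)
    phenotype = comp_cov + comp_taxa + comp_mets + comp_noise

    # --- intensity-dependent missingness ------------------------------------
    metab = pd.DataFrame(intensities, index=sample_ids, columns=metab_ids)
    if cfg.missing_rate > 0:
        flat = log_int.ravel()
        tau = _calibrate_threshold(flat, cfg.missing_rate)
        scale = 0.5 * flat.std()
        p_miss = _sigmoid(-(log_int - tau) / scale)
        mask = rng.random((n, m)) < p_miss
        # keep every feature observed at least once
        all_missing = mask.all(axis=0)
        mask[0, all_missing] = False
        metab = metab.mask(mask)
        p_miss_qc = _sigmoid(-(qc_log - tau) / scale) * 0.5
        qc_mask = rng.random((cfg.n_qc, m)) < p_miss_qc
        qc_frame = pd.DataFrame(qc_intensities, index=qc_ids, columns=metab_ids)
        qc_frame = qc_frame.mask(qc_mask)
    else:
        qc_frame = pd.DataFrame(qc_intensities, index=qc_ids, columns=metab_ids)

    truth = {
        "beta_taxa": pd.Series(beta_taxa, index=taxon_ids),
        "beta_metabolites": pd.Series(beta_mets, index=metab_ids),
        "cross_blocks": [
            {"taxa": blk["taxa"], "metabolites": blk["metabolites"]}
            for blk in blocks
        ],
        "planted_taxa": [taxon_ids[j] for j in planted_taxa],
        "planted_metabolites": [metab_ids[j] for j in planted_mets],
    }
    return SyntheticCohort(
        config=cfg,
        counts=pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        metabolites=metab,
        qc_samples=qc_frame,
        covariates=cov,
        phenotype=pd.Series(phenotype, index=sample_ids, name="phenotype"),
        taxonomy=taxonomy,
        truth=truth,
        latent_clr=pd.DataFrame(latent_clr, index=sample_ids, columns=taxon_ids),
        phenotype_components={
            "covariates": comp_cov, "taxa": comp_taxa,
            "metabolites": comp_mets, "noise": comp_noise,
        },
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_threshold(values: np.ndarray, rate: float) -> float:
    """Bisect the missingness threshold so the mean masking probability
    equals the requested rate."""
    scale = 0.5 * values.std()
    lo, hi = values.min() - 10 * scale, values.max() + 10 * scale
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if _sigmoid(-(values - mid) / scale).mean() < rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class ReferencePairs(NamedTuple):
    """Paired gene-abundance / fecal-metabolite reference tables with the
    generating linear maps recorded."""

    genes: pd.DataFrame
    metabolites: pd.DataFrame
    true_weights: pd.DataFrame
    linear_mask: pd.Series


def generate_reference_pairs(
    n_ref: int = 155,
    n_genes: int = 200,
    n_fecal_metabolites: int = 80,
    seed: int = 0,
    noise_sd: float = 0.5,
    frac_linear: float = 0.5,
    max_genes_per_metabolite: int = 10,
) -> ReferencePairs:
    """Reference set for imputer training: a stated subset of metabolites
    is a noisy linear function of ≤``max_genes_per_metabolite`` genes
    (unit-variance signal plus ``noise_sd`` Gaussian noise); the rest are
    pure noise."""
    if min(n_ref, n_genes, n_fecal_metabolites) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{j:04d}" for j in range(n_genes)]
    met_ids = [f"fecal_met_{j:03d}" for j in range(n_fecal_metabolites)]
    sample_ids = [f"R{i:03d}" for i in range(n_ref)]
    G = rng.standard_normal((n_ref, n_genes))
    max_genes_per_metabolite = min(max_genes_per_metabolite, n_genes)
    n_linear = int(round(frac_linear * n_fecal_metabolites))
    W = np.zeros((n_genes, n_fecal_metabolites))
    M = np.zeros((n_ref, n_fecal_metabolites))
    for j in range(n_fecal_metabolites):
        if j < n_linear:
            k = int(rng.integers(1, max_genes_per_metabolite + 1))
            idx = rng.choice(n_genes, size=k, replace=False)
            w = rng.standard_normal(k)
            w /= np.linalg.norm(w)          # unit-variance signal
            W[idx, j] = w
            M[:, j] = G[:, idx] @ w + noise_sd * rng.standard_normal(n_ref)
        else:
            M[:, j] = rng.standard_normal(n_ref)
    return ReferencePairs(
        genes=pd.DataFrame(G, index=sample_ids, columns=gene_ids),
        metabolites=pd.DataFrame(M, index=sample_ids, columns=met_ids),
        true_weights=pd.DataFrame(W, index=gene_ids, columns=met_ids),
        linear_mask=pd.Series([j < n_linear for j in range(n_fecal_metabolites)],
                              index=met_ids),
    )
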