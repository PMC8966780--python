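"""End-to-end orchestration of the integration analysis.

Stage order is fixed: preprocessing (microbiome, metabolome) → single
omics screens → SparCC co-occurrence network → coinertia / RV → supervised
sparse CCA → inter-omics GGM → report. Each stage writes its artifact to
the output directory and every randomized step draws its seed from a
single global seed fanned out through a counter, so reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import metabolite_screen, microbiome_screen
from .coinertia import rv_permutation_test
from .ggm import GaussianGraphicalModel
from .io import align_samples, read_table, write_table
from .metabolome import IntensityTable, preprocess
from .microbiome import clr_transform, filter_rare, relative_abundance
from .ordination import bray_curtis, pca, pcoa
from .scca import SupervisedSparseCCA
from .simulate import CohortConfig, generate_cohort
from .sparcc import build_network, sparcc_correlations, sparcc_pvalues

__all__ = ["PipelineConfig", "run_pipeline"]

COVARIATE_NAMES = ["age", "bmi", "exercise", "years_since_menopause",
                   "fsh", "estradiol"]


@dataclass
class PipelineConfig:
    """Analysis thresholds and I/O paths.

    Threshold defaults are the study's stated values: 0.01% rare-taxon
    mean abundance, 50%/80% QC/biological detection, 30% QC RSD,
    VIP ≥ 2.0, SparCC |ρ| > 0.5 with p < 0.001, imputer retention ρ > 0.3.
    """

    # inputs: either a directory of TSV tables or synthetic generation
    input_dir: str | None = None
    synthetic: bool = True
    cohort: dict = field(default_factory=dict)
    # thresholds
    rare_abundance: float = 1e-4
    detection_qc: float = 0.5
    detection_bio: float = 0.8
    rsd_max: float = 0.30
    knn_k: int = 10
    vip_threshold: float = 2.0
    alpha: float = 0.05
    sparcc_rho: float = 0.5
    sparcc_p: float = 0.001
    # the strict p < 0.001 edge criterion needs n_perm > 999 (minimum
    # attainable p is 1/(n_perm + 1)); each permutation run uses a single
    # Dirichlet draw to keep that affordable
    sparcc_n_perm: int = 1999
    sparcc_perm_inner: int = 1
    rv_n_perm: int = 999
    imputer_rho: float = 0.3
    scca_q: int = 50
    scca_folds: int = 10
    ggm_gamma: float = 0.5
    covariates: list = field(default_factory=lambda: list(COVARIATE_NAMES))
    seed: int = 0
    out_dir: str = "omibone_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class _SeedSequence:
    """Fan a global seed out to per-stage seeds via a counter."""

    def __init__(self, base: int):
        self.base = int(base)
        self.counter = 0
        self.log: dict[str, int] = {}

    def next(self, stage: str) -> int:
        self.counter += 1
        seed = (self.base * 1_000 + self.counter) % (2**31)
        self.log[stage] = seed
        return seed


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        cohort = generate_cohort(CohortConfig(**{"seed": config.seed,
                                                 **config.cohort}))
        counts = cohort.counts
        intensity = cohort.intensity_table()
        covariates = cohort.covariates
        phenotype = cohort.phenotype
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when synthetic is false")
        d = Path(config.input_dir)
        counts = read_table(d / "counts.tsv", allow_missing=False)
        metab = read_table(d / "metabolites.tsv")
        qc = read_table(d / "qc_samples.tsv")
        covariates = read_table(d / "covariates.tsv", allow_missing=False)
        phenotype = read_table(d / "phenotype.tsv", allow_missing=False).iloc[:, 0]
        counts, metab, covariates = align_samples(counts, metab, covariates)
        phenotype = phenotype.reindex(counts.index)
        if phenotype.isna().any():
            raise ValueError("phenotype missing for some samples")
        values = pd.concat([metab, qc])
        flags = np.r_[np.zeros(len(metab), dtype=bool),
                      np.ones(len(qc), dtype=bool)]
        intensity = IntensityTable(values=values, qc=flags)
        cohort = None
    return cohort, counts, intensity, covariates, phenotype


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a results bundle (also written to
    ``config.out_dir``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _SeedSequence(config.seed)
    cohort, counts, intensity, covariates, phenotype = _load_inputs(config)
    if cohort is not None:
        cohort.write(out / "cohort")

    y = phenotype.to_numpy(dtype=float)
    y_std = (y - y.mean()) / y.std(ddof=1)
    cov = covariates[config.covariates]
    cov_std = ((cov - cov.mean()) / cov.std(ddof=1)).to_numpy()

    # --- stage 1: microbiome prep ---------------------------------------
    rel = relative_abundance(counts)
    filt = filter_rare(rel, config.rare_abundance)
    clr = clr_transform(filt.table)
    rel_renorm = relative_abundance(filt.table)
    write_table(clr, out / "clr.tsv")

    # --- stage 2: metabolome prep ----------------------------------------
    features = preprocess(
        intensity, qc_min=config.detection_qc, bio_min=config.detection_bio,
        k=config.knn_k, max_rsd=config.rsd_max,
    )
    features = features.reindex(counts.index)
    write_table(features, out / "metabolite_features.tsv")

    # --- stage 3: microbiome screen ---------------------------------------
    mic_screen = microbiome_screen(
        clr, y_std, cov_std, seed=seeds.next("microbiome_screen"),
        alpha=config.alpha,
    )
    mic_screen.to_csv(out / "microbiome_screen.tsv", sep="\t")

    # --- stage 4: metabolite screen ---------------------------------------
    met_screen = metabolite_screen(
        features, y_std, cov_std, vip_threshold=config.vip_threshold,
        alpha=config.alpha, seed=seeds.next("metabolite_screen"),
    )
    met_screen.to_csv(out / "metabolite_screen.tsv", sep="\t")

    # --- stage 5: SparCC network -------------------------------------------
    sparcc_seed = seeds.next("sparcc")
    filt_counts = counts[filt.table.columns]
    rho = sparcc_correlations(filt_counts, seed=sparcc_seed)
    pvals = sparcc_pvalues(filt_counts, n_perm=config.sparcc_n_perm,
                           n_inner_perm=config.sparcc_perm_inner,
                           seed=sparcc_seed)
    network = build_network(rho, pvals, rho_threshold=config.sparcc_rho,
                            p_threshold=config.sparcc_p)
    network.edges.to_csv(out / "sparcc_edges.tsv", sep="\t", index=False)
    taxonomy = cohort.taxonomy if cohort is not None else None
    network.to_graphml(out / "sparcc_network.graphml", phylum=taxonomy)

    # --- stage 6: coinertia / RV ---------------------------------------------
    ord_mic = pcoa(bray_curtis(rel_renorm))
    ord_met = pca(features)
    coin = rv_permutation_test(
        ord_mic.top_axes(), ord_met.top_axes(),
        n_perm=config.rv_n_perm, seed=seeds.next("rv_test"),
    )
    (out / "coinertia.json").write_text(json.dumps({
        "rv": coin.rv, "total_coinertia": coin.total_coinertia,
        "p_value": coin.p_value, "n_permutations": coin.n_permutations,
    }, indent=2))

    # --- stage 7: supervised sparse CCA ---------------------------------------
    clr_std = (clr - clr.mean()) / clr.std(ddof=1)
    scca = SupervisedSparseCCA(clr_std, features, y_std, q=config.scca_q)
    scca_res = scca.fit_cv(folds=config.scca_folds,
                           seed=seeds.next("scca_cv"))
    scca.scores_and_loadings(scca_res, cov_std)
    (out / "scca_model.json").write_text(json.dumps({
        "c1": scca_res.c1, "c2": scca_res.c2,
        "u": {str(k): float(v) for k, v in scca_res.u.items() if v != 0},
        "v": {str(k): float(v) for k, v in scca_res.v.items() if v != 0},
        "q1": [str(clr_std.columns[i]) for i in scca_res.q1],
        "q2": [str(features.columns[i]) for i in scca_res.q2],
        "objective": scca_res.objective,
    }, indent=2))
    scca_res.scores.to_csv(out / "scca_scores.tsv", sep="\t")
    loadings = pd.concat({
        "microbiome": scca_res.loadings["X"],
        "metabolome": scca_res.loadings["Y"],
    }, names=["modality", "feature"]).rename("loading").reset_index()
    loadings.to_csv(out / "scca_loadings.tsv", sep="\t", index=False)

    # --- stage 8: inter-omics GGM ----------------------------------------------
    nodes = pd.concat([
        clr_std[list(scca_res.support_x)],
        features[list(scca_res.support_y)],
        pd.Series(y_std, index=clr_std.index, name="phenotype"),
    ], axis=1)
    ggm_res = GaussianGraphicalModel(nodes).fit(gamma=config.ggm_gamma)
    ggm_stats = ggm_res.stats()
    ggm_res.edge_list().to_csv(out / "ggm_edges.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(ggm_res.to_graph(), out / "ggm_network.graphml")
    (out / "ggm_summary.json").write_text(json.dumps({
        "density": ggm_stats.density,
        "transitivity": ggm_stats.transitivity,
        "ebic": ggm_res.ebic_value, "n_edges": ggm_stats.n_edges,
        "n_nodes": ggm_stats.n_nodes, "gamma": config.ggm_gamma,
    }, indent=2))

    # --- report and manifest -----------------------------------------------------
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds.log,
        "shapes": {
            "samples": int(counts.shape[0]),
            "taxa_total": int(counts.shape[1]),
            "taxa_retained": int(clr.shape[1]),
            "retained_abundance_fraction": filt.retained_fraction,
            "metabolite_features": int(features.shape[1]),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results = {
        "microbiome_screen": mic_screen,
        "metabolite_screen": met_screen,
        "sparcc": network,
        "coinertia": coin,
        "scca": scca_res,
        "ggm": ggm_res,
        "manifest": manifest,
        "clr": clr,
        "features": features,
    }
    _write_report(out, results)
    return results


def _write_report(out: Path, r: dict) -> None:
    mic = r["microbiome_screen"]
    met = r["metabolite_screen"]
    coin = r["coinertia"]
    ggm = r["ggm"]
    stats = ggm.stats()
    mic_hits = mic[mic["selected"]].sort_values("p_value")
    met_hits = met[met["selected"]].sort_values("p_value")
    lines = [
        "# Integration analysis report", "",
        "## Microbiome screen",
        f"- taxa selected in stage 1 (zero-sum elastic net): "
        f"{int(mic['stage1_selected'].sum())}",
        f"- taxa with adjusted partial Spearman p < 0.05: {len(mic_hits)}", "",
        mic_hits[["rho_adj", "p_value", "fdr"]].round(4).to_markdown(), "",
        "## Metabolite screen",
        f"- VIP >= 2.0: {int(met['vip_selected'].sum())}; "
        f"linear-model p < 0.05: {int(met['lm_selected'].sum())}", "",
        met_hits[["vip", "beta_adj", "p_value", "fdr"]].round(4).to_markdown(), "",
        "## Co-occurrence network (SparCC)",
        f"- {r['sparcc'].summary()}".replace("\n", "\n- "), "",
        "## Coinertia",
        f"- RV = {coin.rv:.4f}, permutation p = {coin.p_value:.4g}", "",
        "## Supervised sparse CCA",
        f"- support: {len(r['scca'].support_x)} taxa, "
        f"{len(r['scca'].support_y)} metabolites "
        f"(c1 = {r['scca'].c1:.2f}, c2 = {r['scca'].c2:.2f})", "",
        "## Inter-omics GGM",
        f"- nodes: {stats.n_nodes}, edges: {stats.n_edges}, "
        f"density: {stats.density:.3f}, "
        f"transitivity: {stats.transitivity if stats.transitivity is not None else 'NA'}",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
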