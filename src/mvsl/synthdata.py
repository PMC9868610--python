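"""Synthetic data with the statistical structure the model assumes.

The generator plants a latent-factor model: every gene g gets a factor
u_g ~ N(0, I_d). The lethality propensity of a pair is the scaled factor
inner product plus Gaussian noise, and genetic-interaction (GI) scores are
a decreasing affine map of propensity calibrated so that thresholding at -3
yields the requested positive rate (defaults mirror a CRISPRi double-
knockdown screen of a few hundred genes with ~1.5% SL pairs).

Each of the four cell-independent views draws its edges from a logistic
model in the planted propensity: at informativeness 0 the view is pure
Erdos-Renyi background; larger informativeness makes edges concentrate on
high-propensity pairs. Defaults order the views genetic-PPI >
co-essentiality > physical-PPI > co-expression (the co-expression view is
uninformative by construction). The SL view is the positive labels
themselves and is rebuilt from training positives downstream.

Expression profiles are drawn independently of the SL structure.
Essentiality profiles share latent sample factors with the gene factors, so
a correlation graph built from them recovers latent similarity; the
gene-level essentiality feature is constructed to correlate negatively with
a gene's SL-partner count (default -0.19), the sign real screens show.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneUniverse, GIScoreTable
from .graphs import VIEW_IDS

logger = logging.getLogger("mvsl")

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset",
           "generate_random_view", "write_dataset"]


def _default_informativeness() -> dict[str, float]:
    return {"SL": 1.0, "PPI_PHYS": 0.3, "PPI_GEN": 0.6, "COEXPR": 0.0, "COESS": 0.5}


def _default_missing() -> dict[str, float]:
    # the SL view is rebuilt from training labels, so it gets no dropout
    return {"SL": 0.0, "PPI_PHYS": 0.2, "PPI_GEN": 0.2, "COEXPR": 0.2, "COESS": 0.2}


@dataclass
class SynthConfig:
    """Generator parameters; defaults emulate the K562-like regime at desk
    scale (300 genes, ~1.5% positive pairs, 50 profile samples)."""

    n_genes: int = 300
    n_samples: int = 50
    latent_dim: int = 8
    positive_rate: float = 0.015
    view_informativeness: dict[str, float] = field(default_factory=_default_informativeness)
    missing_gene_fraction: dict[str, float] = field(default_factory=_default_missing)
    ess_sl_correlation: float = -0.19
    seed: int = 0
    # free mechanism knobs (not part of the study-condition contract)
    background_density: float = 0.08   # Erdos-Renyi edge rate at informativeness 0
    edge_logit_gain: float = 6.0       # logistic slope on standardized propensity
    propensity_noise: float = 0.3      # sd of pair-level noise on factor similarity
    gi_scale: float = 2.0              # spread of GI scores around the -3 threshold
    mutation_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.n_samples < 3:
            raise ValueError("need at least 3 profile samples")
        if not 0.0 < self.positive_rate < 0.5:
            raise ValueError("positive_rate must lie in (0, 0.5)")
        for vid, w in self.view_informativeness.items():
            if vid not in VIEW_IDS:
                raise ValueError(f"unknown view {vid!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError("informativeness must lie in [0, 1]")
        if not 0.0 < self.background_density < 1.0:
            raise ValueError("background_density must lie in (0, 1)")


@dataclass
class SynthDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    universe: GeneUniverse
    gi_table: GIScoreTable
    edge_lists: dict[str, list[tuple[str, str]]]
    expression_profiles: np.ndarray      # n_genes x n_samples
    essentiality_profiles: np.ndarray    # n_genes x n_samples
    sample_ids: list[str]
    feature_values: np.ndarray           # n_genes x 4 raw node features
    feature_names: tuple[str, ...]
    latents: np.ndarray                  # n_genes x latent_dim ground truth
    config: SynthConfig


def generate_random_view(n_genes: int, density: float,
                         rng: np.random.Generator) -> list[tuple[int, int]]:
    """Erdos-Renyi G(n, density) as a list of canonical index pairs."""
    if not 0.0 <= density < 1.0:
        raise ValueError("density must lie in [0, 1)")
    iu, ju = np.triu_indices(n_genes, k=1)
    keep = rng.random(iu.size) < density
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def _calibrate_gi(t: np.ndarray, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Map propensities to GI scores so that (gi < -3) hits the target rate."""
    n_pairs = t.size
    k = int(round(cfg.positive_rate * n_pairs))
    if k < 1 or k >= n_pairs:
        raise ValueError(
            f"cannot calibrate {cfg.positive_rate:.3%} positives from {n_pairs} pairs")
    order = np.sort(t)
    cut = 0.5 * (order[n_pairs - k - 1] + order[n_pairs - k])
    gi = -3.0 + cfg.gi_scale * (cut - t)
    positive = gi < -3.0
    achieved = positive.mean()
    if abs(achieved - cfg.positive_rate) > 0.2 * cfg.positive_rate:
        raise ValueError(
            f"GI calibration infeasible: achieved positive rate {achieved:.4f} "
            f"vs target {cfg.positive_rate:.4f} (ties in propensity?)")
    return gi, positive


def generate_dataset(cfg: SynthConfig | None = None) -> SynthDataset:
    """Generate a full synthetic input bundle, reproducible from cfg.seed."""
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0x5D47A,))
    (r_latent, r_noise, r_view, r_drop, r_expr,
     r_ess, r_feat) = (np.random.default_rng(c) for c in ss.spawn(7))

    n = cfg.n_genes
    width = len(str(n))
    genes = [f"G{i:0{width}d}" for i in range(n)]
    universe = GeneUniverse(genes)
    iu, ju = np.triu_indices(n, k=1)

    # planted factors and pair propensity
    U = r_latent.standard_normal((n, cfg.latent_dim))
    sim = (U @ U.T) / np.sqrt(cfg.latent_dim)
    t = sim[iu, ju] + cfg.propensity_noise * r_noise.standard_normal(iu.size)

    gi, positive = _calibrate_gi(t, cfg)
    gi_table = GIScoreTable(
        [(genes[a], genes[b], float(s)) for a, b, s in zip(iu, ju, gi)])

    # views: logistic edge probability in standardized propensity
    z = (t - t.mean()) / t.std()
    base_logit = np.log(cfg.background_density / (1.0 - cfg.background_density))
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    for vid in VIEW_IDS:
        if vid == "SL":
            keep = positive
        else:
            w = cfg.view_informativeness.get(vid, 0.0)
            p_edge = 1.0 / (1.0 + np.exp(-(base_logit + cfg.edge_logit_gain * w * z)))
            keep = r_view.random(iu.size) < p_edge
        a, b = iu[keep], ju[keep]
        frac = cfg.missing_gene_fraction.get(vid, 0.0)
        if frac > 0:
            dropped = r_drop.random(n) < frac
            alive = ~(dropped[a] | dropped[b])
            a, b = a[alive], b[alive]
        edge_lists[vid] = [(genes[x], genes[y]) for x, y in zip(a.tolist(), b.tolist())]
        logger.debug("view %s: %d edges", vid, len(edge_lists[vid]))

    # expression: independent of the SL structure
    expr = r_expr.standard_normal((n, cfg.n_samples))

    # essentiality: gene-level score anti-correlated with SL-partner count,
    # plus shared latent sample factors so co-essentiality reflects similarity
    deg = np.zeros(n)
    np.add.at(deg, iu[positive], 1)
    np.add.at(deg, ju[positive], 1)
    zdeg = (deg - deg.mean()) / deg.std() if deg.std() > 0 else np.zeros(n)
    rho = cfg.ess_sl_correlation
    ess_gene = rho * zdeg + np.sqrt(1.0 - rho * rho) * r_ess.standard_normal(n)
    F = r_ess.standard_normal((cfg.latent_dim, cfg.n_samples))
    ess = (ess_gene[:, None]
           + 0.6 * (U @ F) / np.sqrt(cfg.latent_dim)
           + 0.8 * r_ess.standard_normal((n, cfg.n_samples)))

    features = np.column_stack([
        r_feat.standard_normal(n),                       # expression summary
        r_feat.standard_normal(n),                       # copy number
        (r_feat.random(n) < cfg.mutation_rate).astype(float),  # mutation
        ess_gene,                                        # essentiality
    ])

    return SynthDataset(
        universe=universe,
        gi_table=gi_table,
        edge_lists=edge_lists,
        expression_profiles=expr,
        essentiality_profiles=ess,
        sample_ids=[f"S{j:03d}" for j in range(cfg.n_samples)],
        feature_values=features,
        feature_names=("expression", "copy_number", "mutation", "essentiality"),
        latents=U,
        config=cfg,
    )


def write_dataset(dataset: SynthDataset, out_dir: str | Path) -> dict:
    """Write the input bundle as plain-text files; returns the manifest."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_gi_table(out / "gi_scores.tsv", dataset.gi_table)
    for vid, pairs in dataset.edge_lists.items():
        mio.write_edge_list(out / f"edges_{vid}.tsv", pairs)
    genes = list(dataset.universe.genes)
    mio.write_matrix(out / "expression.csv", genes, dataset.sample_ids,
                     dataset.expression_profiles)
    mio.write_matrix(out / "essentiality.csv", genes, dataset.sample_ids,
                     dataset.essentiality_profiles)
    mio.write_matrix(out / "node_features.csv", genes,
                     list(dataset.feature_names), dataset.feature_values)
    truth = {
        "latents": dataset.latents.tolist(),
        "config": {k: v for k, v in dataclasses.asdict(dataset.config).items()},
    }
    (out / "truth.json").write_text(json.dumps(truth))
    manifest = {
        "n_genes": len(genes),
        "n_pairs": len(dataset.gi_table),
        "positive_rate": float(np.mean(
            [s < -3.0 for _, _, s in dataset.gi_table.records])),
        "edges": {vid: len(p) for vid, p in dataset.edge_lists.items()},
        "seed": dataset.config.seed,
        "files": ["gi_scores.tsv", "expression.csv", "essentiality.csv",
                  "node_features.csv", "truth.json"]
                 + [f"edges_{vid}.tsv" for vid in dataset.edge_lists],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
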