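"""Synthetic CROP-seq generator: single cells with latent cluster states,
low-MOI sgRNA integrations with ambient background, knockdown of target-gene
expression and knockdown-dependent cluster-occupancy shifts.

The generative model, per cell:

* integration count ~ Poisson(moi), integrated sgRNAs uniform over the
  library (distinct guides); cells with zero integrations stay in the pool
  so the assignment stage sees realistic no-signal cells, and cells with two
  or more integrations are retained (truth-labeled) to exercise the singlet
  filter;
* a transcriptional cluster drawn from the base cluster proportions,
  reweighted multiplicatively by the carried gene's occupancy effects (NTC
  and unperturbed cells use base proportions);
* expression UMIs ~ Poisson with cluster-specific means: each cluster has
  one distinctive high-expression marker gene, the per-cell mean profile is
  scaled to the target depth, and every carried target gene's mean is scaled
  by (1 - knockdown_strength);
* sgRNA UMIs = Poisson(signal_umi_mean) on integrated guides plus
  Poisson(ambient_rate) ambient background on every guide.

Everything is driven by one master seed through per-stage substreams, so a
fixed seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .library_io import CellTensorBundle, LibraryManifest, NTC_LABEL

#: Default 9-state marker panel: one distinctive marker per cluster, echoing
#: microglial state markers (disease-associated SPP1, chemokine CCL13, ...).
DEFAULT_CLUSTER_MARKERS = [
    "SPP1", "CCL13", "CD83", "P2RY12", "MKI67", "IL1B", "APOE", "TREM2", "CX3CR1",
]


@dataclass
class CropSimConfig:
    """Parameters of the CROP-seq simulation.

    ``moi`` defaults to 0.10, inside the < 0.15 infection bound the screen
    design imposes so that most transduced cells carry a single sgRNA.
    ``occupancy_effects`` maps target gene -> {cluster label: multiplier}
    applied to the base cluster proportions for cells carrying that gene.
    """

    n_cells: int = 10_000
    n_clusters: int = 9
    cluster_base_proportions: Optional[Sequence[float]] = None  # default uniform
    cluster_markers: Optional[Sequence[str]] = None  # one marker gene per cluster
    marker_fold: float = 8.0           # marker mean fold-up in its own cluster
    n_background_genes: int = 100
    background_mean: float = 1.0       # pre-scaling mean of background genes
    target_gene_mean: float = 5.0      # pre-scaling mean of CRISPRi target genes
    depth: float = 2000.0              # expected UMIs per cell
    moi: float = 0.10                  # expected integrations per cell (< 0.15)
    ambient_rate: float = 0.2          # ambient sgRNA UMIs per cell per guide
    signal_umi_mean: float = 50.0      # sgRNA UMIs from a true integration
    knockdown_strength: float = 0.8    # fractional suppression of target mean
    occupancy_effects: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, manifest: LibraryManifest) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 < self.moi < 0.15:
            raise ValueError("moi must lie in (0, 0.15): low-MOI design contract")
        if not 0 <= self.knockdown_strength <= 1:
            raise ValueError("knockdown_strength must lie in [0, 1]")
        if self.ambient_rate < 0 or self.signal_umi_mean <= 0:
            raise ValueError("ambient_rate >= 0 and signal_umi_mean > 0 required")
        props = self.resolved_proportions()
        if len(props) != self.n_clusters or not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster_base_proportions must have n_clusters entries summing to 1")
        markers = self.resolved_markers()
        if len(markers) != self.n_clusters:
            raise ValueError("need one marker gene per cluster")
        targets = set(manifest.target_genes)
        for gene, effects in self.occupancy_effects.items():
            if gene not in targets:
                raise ValueError(f"occupancy effect for {gene!r}: not a library target gene")
            labels = set(self.cluster_labels())
            for cl in effects:
                if cl not in labels:
                    raise ValueError(f"occupancy effect on unknown cluster {cl!r}")

    def resolved_proportions(self) -> np.ndarray:
        if self.cluster_base_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_base_proportions, dtype=float)

    def resolved_markers(self) -> list[str]:
        if self.cluster_markers is None:
            if self.n_clusters <= len(DEFAULT_CLUSTER_MARKERS):
                return list(DEFAULT_CLUSTER_MARKERS[: self.n_clusters])
            extra = [f"MARKER{i:02d}" for i in range(len(DEFAULT_CLUSTER_MARKERS) + 1,
                                                      self.n_clusters + 1)]
            return list(DEFAULT_CLUSTER_MARKERS) + extra
        return list(self.cluster_markers)

    def cluster_labels(self) -> list[str]:
        return [f"{m}_hi" for m in self.resolved_markers()]


@dataclass
class CropGroundTruth:
    """Generating parameters plus the per-cell truth recorded in the bundle."""

    config: CropSimConfig
    manifest: LibraryManifest
    cluster_labels: list[str]
    occupancy_effects: dict


def simulate_cropseq(
    config: CropSimConfig, manifest: LibraryManifest
) -> tuple[CellTensorBundle, CropGroundTruth]:
    """Generate a CROP-seq cell bundle with ground-truth columns.

    The returned bundle's cell metadata carries the observed ``cluster_label``
    plus truth columns ``true_n_integrations``, ``true_sgrnas`` (semicolon
    joined), ``true_gene`` (gene of the first integrated guide, empty if
    none) — downstream assignment and occupancy stages can be scored against
    them.
    """
    config.validate(manifest)
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_int, rng_clu, rng_expr, rng_umi = (np.random.default_rng(s) for s in ss)

    n_cells = config.n_cells
    sgrna_ids = manifest.sgrna_ids
    n_sgrnas = len(sgrna_ids)
    gene_of = manifest.sgrna_to_gene()
    cluster_labels = config.cluster_labels()
    markers = config.resolved_markers()
    target_genes = manifest.target_genes

    # gene universe: CRISPRi targets + cluster markers + background filler
    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    genes = list(dict.fromkeys(target_genes + markers + background))
    gene_index = {g: j for j, g in enumerate(genes)}

    # --- integrations ---------------------------------------------------
    n_int = rng_int.poisson(config.moi, size=n_cells)
    n_int = np.minimum(n_int, n_sgrnas)
    carried: list[list[int]] = []
    for k in n_int:
        if k == 0:
            carried.append([])
        else:
            carried.append(list(rng_int.choice(n_sgrnas, size=k, replace=False)))
    first_gene = np.array(
        [gene_of[sgrna_ids[c[0]]] if c else "" for c in carried], dtype=object
    )

    # --- cluster identities ----------------------------------------------
    base = config.resolved_proportions()
    cluster_idx = np.empty(n_cells, dtype=np.int64)
    weights_cache: dict[str, np.ndarray] = {}
    u = rng_clu.random(n_cells)
    for i in range(n_cells):
        g = first_gene[i]
        if g in config.occupancy_effects:
            if g not in weights_cache:
                w = base.copy()
                for cl, mult in config.occupancy_effects[g].items():
                    w[cluster_labels.index(cl)] *= mult
                weights_cache[g] = np.cumsum(w / w.sum())
            cdf = weights_cache[g]
        else:
            if "" not in weights_cache:
                weights_cache[""] = np.cumsum(base)
            cdf = weights_cache[""]
        cluster_idx[i] = np.searchsorted(cdf, u[i], side="right")
    cluster_idx = np.minimum(cluster_idx, config.n_clusters - 1)

    # --- expression -------------------------------------------------------
    profile = np.full((config.n_clusters, len(genes)), config.background_mean)
    for g in target_genes:
        profile[:, gene_index[g]] = config.target_gene_mean
    for c, m in enumerate(markers):
        profile[c, gene_index[m]] *= config.marker_fold
    profile *= config.depth / profile.sum(axis=1, keepdims=True)

    mean = profile[cluster_idx]  # (n_cells, n_genes) view-copy
    kd = 1.0 - config.knockdown_strength
    for i, c in enumerate(carried):
        for idx in c:
            g = gene_of[sgrna_ids[idx]]
            if g != NTC_LABEL:
                mean[i, gene_index[g]] *= kd
    expr = rng_expr.poisson(mean).astype(np.int64)

    # --- sgRNA UMIs -------------------------------------------------------
    umi = rng_umi.poisson(config.ambient_rate, size=(n_cells, n_sgrnas)).astype(np.int64)
    for i, c in enumerate(carried):
        for idx in c:
            umi[i, idx] += rng_umi.poisson(config.signal_umi_mean)

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:06d}" for i in range(n_cells)],
            "cluster_label": [cluster_labels[c] for c in cluster_idx],
            "true_n_integrations": n_int,
            "true_sgrnas": [";".join(sgrna_ids[j] for j in c) for c in carried],
            "true_gene": first_gene,
        }
    )
    bundle = CellTensorBundle(
        expr=sp.csr_matrix(expr),
        genes=genes,
        sgrna_umi=sp.csr_matrix(umi),
        sgrna_ids=list(sgrna_ids),
        cells=cells,
    )
    truth = CropGroundTruth(
        config=config,
        manifest=manifest,
        cluster_labels=cluster_labels,
        occupancy_effects=dict(config.occupancy_effects),
    )
    return bundle, truth
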