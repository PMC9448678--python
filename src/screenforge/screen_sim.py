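"""Synthetic pooled-screen generator with known ground truth.

Two screen designs are emulated:

* **survival/proliferation** — a library is seeded at fixed coverage at t0;
  each sgRNA's lineage grows as ``2**(doublings * (1 + efficacy * gamma))``
  where ``gamma`` is its gene's growth phenotype (log2 enrichment per
  population doubling) and ``efficacy`` in [0,1] scales the gene effect per
  guide.  Read counts for t0 and tF are multinomial draws at the configured
  sequencing depth from abundance-proportional frequencies.

* **FACS bin-sorting** — every cell carries one sgRNA and a log-normal
  reporter signal whose location is displaced by ``efficacy * shift`` for
  cells carrying guides against shifted genes.  Cells in the bottom and top
  ``bin_fraction`` tails (default 30%, the standard two-tail sorting gate)
  form the low/high bins; per-bin sgRNA tallies are sequenced multinomially.

Non-targeting controls always have zero effect, making them exchangeable
with null genes — the property the downstream empirical-null statistics rely
on.  A single master seed drives independent substreams per stage (effects,
guide efficacy, growth/reporter noise, sequencing), so each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .library_io import LibraryManifest, NTC_LABEL, CountsTable, SgrnaEntry, synthetic_protospacer


@dataclass
class SimConfig:
    """Parameters of a simulated pooled screen.

    Defaults follow the druggable-genome screen design: 2,325 genes with five
    sgRNAs each plus 500 NTCs, seeded at 1,000 cells per library element,
    sorted (in FACS mode) into bottom/top 30% bins.  Quantities the design
    does not pin down (doublings, hit fraction, effect sizes, reporter scale)
    are simulation choices documented in the methods note.
    """

    n_genes: int = 2325
    sgrnas_per_gene: int = 5
    n_ntc: int = 500
    coverage: int = 1000          # cells per library element at t0
    doublings: float = 5.0        # population doublings between samples (survival)
    fraction_hits: float = 0.1    # fraction of genes with nonzero effect
    effect_size: float = 1.0      # |gamma| of hit genes (survival mode)
    shift_size: float = 2.0       # |reporter shift| of hit genes (FACS mode)
    gamma: Optional[np.ndarray] = None   # explicit per-gene gamma (overrides mixture)
    shift: Optional[np.ndarray] = None   # explicit per-gene reporter shift
    efficacy_alpha: float = 5.0   # per-sgRNA efficacy ~ Beta(alpha, beta)
    efficacy_beta: float = 1.0
    constant_efficacy: Optional[float] = None  # set to 1.0 to disable heterogeneity
    reporter_mu: float = 0.0      # log-scale reporter location
    reporter_sigma: float = 1.0   # log-scale reporter scale
    bin_fraction: float = 0.30    # sorted tail fraction per bin
    depth: Optional[int] = None   # reads per sample; default coverage * n_elements
    overdispersion: Optional[float] = None  # Dirichlet-multinomial concentration scale
    seed: int = 0

    @property
    def n_elements(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_ntc

    def resolved_depth(self) -> int:
        return int(self.depth) if self.depth is not None else self.coverage * self.n_elements

    def validate(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise ValueError("need at least one gene with one sgRNA")
        if self.n_ntc < 2:
            raise ValueError("need at least 2 NTC sgRNAs for downstream statistics")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0 < self.bin_fraction < 0.5:
            raise ValueError("bin_fraction must lie in (0, 0.5)")
        if self.resolved_depth() < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.fraction_hits <= 1:
            raise ValueError("fraction_hits must lie in [0, 1]")
        if self.constant_efficacy is not None and not 0 <= self.constant_efficacy <= 1:
            raise ValueError("efficacy must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-gene effects, per-sgRNA efficacies and the generating manifest."""

    mode: str
    genes: pd.DataFrame    # gene, effect, is_hit
    sgrnas: pd.DataFrame   # sgrna_id, gene, efficacy, (+ per-stage tallies)
    manifest: LibraryManifest
    config: SimConfig


def build_screen_library(config: SimConfig, name: str = "sim_library") -> LibraryManifest:
    """Deterministic synthetic library matching the configured shape."""
    entries = []
    idx = 0
    for g in range(1, config.n_genes + 1):
        gene = f"GENE{g:05d}"
        for j in range(1, config.sgrnas_per_gene + 1):
            entries.append(
                SgrnaEntry(f"{gene}_sg{j}", synthetic_protospacer(idx), gene, False)
            )
            idx += 1
    for j in range(1, config.n_ntc + 1):
        entries.append(
            SgrnaEntry(f"NTC_sg{j:04d}", synthetic_protospacer(idx), NTC_LABEL, True)
        )
        idx += 1
    return LibraryManifest(entries=entries, name=name)


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_effects(
    config: SimConfig, rng: np.random.Generator, explicit: Optional[np.ndarray], size: float
) -> np.ndarray:
    if explicit is not None:
        eff = np.asarray(explicit, dtype=float)
        if eff.shape != (config.n_genes,):
            raise ValueError(f"explicit effects must have shape ({config.n_genes},)")
        return eff
    eff = np.zeros(config.n_genes)
    is_hit = rng.random(config.n_genes) < config.fraction_hits
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    eff[is_hit] = size * signs[is_hit]
    return eff


def _draw_efficacy(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.constant_efficacy is not None:
        return np.full(n, float(config.constant_efficacy))
    return rng.beta(config.efficacy_alpha, config.efficacy_beta, size=n)


def _sequence(
    freqs: np.ndarray, depth: int, rng: np.random.Generator, overdispersion: Optional[float]
) -> np.ndarray:
    """Multinomial read sampling; optional Dirichlet-multinomial overdispersion."""
    freqs = freqs / freqs.sum()
    if overdispersion is not None:
        freqs = rng.dirichlet(freqs * overdispersion)
    return rng.multinomial(depth, freqs)


def _truth_frames(
    manifest: LibraryManifest, effects: np.ndarray, efficacy: np.ndarray, col: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = manifest.target_genes
    gene_df = pd.DataFrame({"gene": genes, col: effects, "is_hit": effects != 0})
    effect_by_gene = dict(zip(genes, effects))
    sg_gene = [e.target_gene for e in manifest.entries]
    sg_df = pd.DataFrame(
        {
            "sgrna_id": manifest.sgrna_ids,
            "gene": sg_gene,
            "efficacy": efficacy,
            col: [0.0 if g == NTC_LABEL else effect_by_gene[g] for g in sg_gene],
        }
    )
    return gene_df, sg_df


def simulate_survival_screen(config: SimConfig) -> tuple[CountsTable, GroundTruth]:
    """Simulate a t0 vs t_final survival/proliferation screen.

    t0 seeds exactly ``coverage`` cells per library element; tF abundance is
    ``coverage * 2**(doublings * (1 + efficacy * gamma))`` with gamma = 0 for
    NTCs.  Both samples are sequenced multinomially at the configured depth.
    """
    config.validate()
    rng_fx, rng_eff, _, rng_seq = _streams(config.seed)
    manifest = build_screen_library(config)
    gamma = _draw_effects(config, rng_fx, config.gamma, config.effect_size)
    efficacy = _draw_efficacy(config, rng_eff, len(manifest))
    # NTCs carry no effect by construction
    is_ntc = np.array([e.is_ntc for e in manifest.entries])
    gene_index = np.repeat(np.arange(config.n_genes), config.sgrnas_per_gene)
    sg_gamma = np.zeros(len(manifest))
    sg_gamma[~is_ntc] = gamma[gene_index] * efficacy[~is_ntc]

    t0_cells = np.full(len(manifest), float(config.coverage))
    tf_cells = t0_cells * 2.0 ** (config.doublings * (1.0 + sg_gamma))
    depth = config.resolved_depth()
    counts = np.column_stack(
        [
            _sequence(t0_cells, depth, rng_seq, config.overdispersion),
            _sequence(tf_cells, depth, rng_seq, config.overdispersion),
        ]
    )
    table = CountsTable(manifest.sgrna_ids, ["t0", "tF"], counts)
    gene_df, sg_df = _truth_frames(manifest, gamma, efficacy, "gamma")
    sg_df["t0_cells"] = t0_cells
    sg_df["tf_cells"] = tf_cells
    return table, GroundTruth("survival", gene_df, sg_df, manifest, config)


def sort_into_bins(values: np.ndarray, bin_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the bottom and top ``bin_fraction`` tails of ``values``.

    Bin size is ``floor(bin_fraction * n)``; ties are broken by cell index
    (stable sort), so the gate is deterministic.
    """
    n = len(values)
    k = int(np.floor(bin_fraction * n))
    order = np.argsort(values, kind="stable")
    return order[:k], order[n - k :]


def simulate_facs_screen(config: SimConfig) -> tuple[CountsTable, GroundTruth]:
    """Simulate a two-tail FACS reporter sorting screen.

    Every cell carries one sgRNA (``coverage`` cells per element); its log
    reporter signal is Normal(reporter_mu + efficacy * shift, reporter_sigma).
    Cells in the bottom/top ``bin_fraction`` tails form the low/high bins and
    each bin's sgRNA tally is sequenced multinomially at the configured depth.
    """
    config.validate()
    rng_fx, rng_eff, rng_rep, rng_seq = _streams(config.seed)
    manifest = build_screen_library(config)
    shift = _draw_effects(config, rng_fx, config.shift, config.shift_size)
    efficacy = _draw_efficacy(config, rng_eff, len(manifest))
    is_ntc = np.array([e.is_ntc for e in manifest.entries])
    gene_index = np.repeat(np.arange(config.n_genes), config.sgrnas_per_gene)
    sg_shift = np.zeros(len(manifest))
    sg_shift[~is_ntc] = shift[gene_index] * efficacy[~is_ntc]

    n_elem = len(manifest)
    cell_sgrna = np.repeat(np.arange(n_elem), config.coverage)
    log_signal = rng_rep.normal(
        config.reporter_mu + sg_shift[cell_sgrna], config.reporter_sigma
    )
    low_idx, high_idx = sort_into_bins(log_signal, config.bin_fraction)
    low_tally = np.bincount(cell_sgrna[low_idx], minlength=n_elem)
    high_tally = np.bincount(cell_sgrna[high_idx], minlength=n_elem)

    depth = config.resolved_depth()
    counts = np.column_stack(
        [
            _sequence(low_tally.astype(float), depth, rng_seq, config.overdispersion),
            _sequence(high_tally.astype(float), depth, rng_seq, config.overdispersion),
        ]
    )
    table = CountsTable(manifest.sgrna_ids, ["low_bin", "high_bin"], counts)
    gene_df, sg_df = _truth_frames(manifest, shift, efficacy, "shift")
    sg_df["low_bin_cells"] = low_tally
    sg_df["high_bin_cells"] = high_tally
    return table, GroundTruth("facs", gene_df, sg_df, manifest, config)
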