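"""Synthetic multi-omics tumor cohorts with planted, recoverable structure.

Every downstream stage of the hot/cold tumor-microenvironment pipeline has a
parameter-recovery test against the ground truth planted here:

* a single-cell count matrix with cell-type labels and planted marker genes,
* bulk per-tumor-type mRNA/miRNA/lncRNA counts generated as mixtures of a
  malignant and an immune expression program, mixed by a trimodal
  infiltration fraction ``f``,
* Beta-distributed promoter methylation with planted group differences,
* exponential survival times whose log hazard is ``-hazard_coeff * f``
  (higher immune infiltration is protective),
* a drug rank-profile database containing one planted "converter" whose
  profile up-ranks hot-specific genes and down-ranks cold-specific genes.

The world is deliberately not a pure null-plus-spikes model: each cell type
carries a broad lognormal background program and many bulk genes are weakly
coupled to infiltration.  Real immune infiltration perturbs thousands of
transcripts; the "top 1%" selection rules of the pipeline are only
meaningful against such a background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger("tmedissect")

PROMOTER_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon")
ALL_REGIONS = PROMOTER_REGIONS + ("Body", "3'UTR")
_REGION_WEIGHTS = (0.15, 0.15, 0.10, 0.10, 0.35, 0.15)

TME_LEVELS = {"cold": 0.0, "median": 0.5, "hot": 1.0}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the synthetic cohort.

    Defaults are the conditions the recovery tests run at: 5 cell types
    (one malignant) x 200 cells, 3 tumor types x 100 samples, trimodal
    infiltration, 4-fold planted differential genes, delta-beta 0.3 planted
    promoter probes, 100 drugs with one converter, hazard coefficient 1
    (hot-vs-cold hazard ratio ~ exp(-0.4) ~ 0.67).
    """

    n_genes: int = 3000
    n_cells_per_type: int = 200
    cell_types: tuple[str, ...] = ("malignant", "T_cell", "B_cell", "NK_cell", "macrophage")
    n_markers_per_type: int = 5
    marker_fold: float = 25.0
    #: breadth of the per-cell-type background expression program (lognormal sigma);
    #: 0 gives a fully exchangeable null when marker_fold == 1
    type_program_sigma: float = 0.7
    n_tumor_types: int = 3
    n_samples_per_type: int = 100
    infiltration_modes: tuple[float, float, float] = (0.05, 0.20, 0.45)
    infiltration_concentration: float = 150.0
    mixture_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_de_genes: int = 40
    de_fold: float = 4.0
    n_mirna: int = 15
    n_lncrna: int = 15
    n_signal_mirna: int = 5
    n_signal_lncrna: int = 5
    n_targets_per_noncoding: int = 5
    n_db_decoys_per_mirna: int = 3
    n_probes: int = 600
    n_dmp: int = 40
    delta_beta: float = 0.3
    beta_precision: float = 50.0
    n_drugs: int = 100
    hazard_coeff: float = 1.0
    baseline_hazard: float = 1 / 1200.0  # events per day at f = 0
    censor_horizon: float = 4800.0  # days; ~30% administrative censoring
    seed: int = 0

    # noise shape knobs (held fixed across the test suite)
    sc_library_sigma: float = 0.35
    sc_abundance_median: float = 0.5
    sc_abundance_sigma: float = 1.5
    marker_base_abundance: float = 0.12
    sc_dispersion_median: float = 0.2
    bulk_dispersion_median: float = 0.1
    bulk_abundance_median: float = 100.0
    background_coupling: tuple[float, float] = (0.8, 1.8)  # |gamma| range of weak f-coupling
    background_coupled_frac: float = 0.5
    lnc_latent_sd: float = 0.07
    lnc_coupling: float = 4.0
    mir_coupling: float = 0.6

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cells_per_type": self.n_cells_per_type,
            "n_markers_per_type": self.n_markers_per_type,
            "n_tumor_types": self.n_tumor_types,
            "n_samples_per_type": self.n_samples_per_type,
            "n_de_genes": self.n_de_genes,
            "n_mirna": self.n_mirna,
            "n_lncrna": self.n_lncrna,
            "n_probes": self.n_probes,
            "n_dmp": self.n_dmp,
            "n_drugs": self.n_drugs,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if "malignant" not in self.cell_types:
            raise ConfigurationError('cell_types must contain "malignant"')
        m = self.infiltration_modes
        if not (0 <= m[0] < m[1] < m[2] <= 1):
            raise ConfigurationError("infiltration_modes must be strictly increasing in [0, 1]")
        if not 0 < self.delta_beta < 1:
            raise ConfigurationError("delta_beta must be in (0, 1)")
        if self.marker_fold < 1 or self.de_fold < 1:
            # the spec-level invariant is > 1; == 1 is admitted as the explicit null world
            raise ConfigurationError("fold parameters must be >= 1")

    @property
    def immune_types(self) -> tuple[str, ...]:
        return tuple(t for t in self.cell_types if t != "malignant")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset; the recovery-test oracle."""

    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    infiltration_fraction: pd.Series | None = None
    tme_label_true: pd.Series | None = None
    #: gene -> signed log2 fold; positive = up in inflamed (hot) samples
    de_genes_true: pd.Series | None = None
    #: probe -> planted beta difference, noninflamed minus inflamed
    dmp_probes_true: pd.Series | None = None
    lnc_target_genes_true: dict[str, list[str]] = field(default_factory=dict)
    mir_target_genes_true: dict[str, list[str]] = field(default_factory=dict)
    converter_drug_id: str | None = None
    #: background genes weakly coupled to infiltration (not null for the hot/cold contrast)
    background_coupled_genes: list[str] = field(default_factory=list)


@dataclass
class BulkCohort:
    """Bulk multi-omics cohort: three RNA count matrices (samples x features),
    a methylation beta matrix (probes x samples) with probe annotation, and a
    survival table."""

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    methylation: pd.DataFrame
    probe_annot: pd.DataFrame  # index probe: columns gene, region
    survival: pd.DataFrame  # index sample: time, event, age, tumor_type
    samples: pd.DataFrame  # index sample: tumor_type
    mirna_target_db: dict[str, set[str]] = field(default_factory=dict)

    @property
    def tumor_type(self) -> pd.Series:
        return self.samples["tumor_type"]


# ---------------------------------------------------------------------------
# planted layout, shared across the three generators so that the drug database
# and the bulk cohort agree about which genes are hot/cold specific
# ---------------------------------------------------------------------------


def _plant_layout(config: SimulationConfig) -> dict:
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    n_marker_total = config.n_markers_per_type * len(config.cell_types)
    needed = (
        n_marker_total
        + config.n_de_genes
        + config.n_signal_lncrna * config.n_targets_per_noncoding
        + config.n_signal_mirna * (config.n_targets_per_noncoding + config.n_db_decoys_per_mirna)
    )
    if needed > config.n_genes:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small for the planted structure ({needed} genes)"
        )

    chosen = rng.choice(config.n_genes, size=needed, replace=False)
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        out = [genes[i] for i in chosen[pos : pos + k]]
        pos += k
        return out

    marker_genes = {t: take(config.n_markers_per_type) for t in config.cell_types}
    n_up = config.n_de_genes // 2
    de_up_hot = take(n_up)
    de_up_cold = take(config.n_de_genes - n_up)
    lnc_names = [f"LNC{i:03d}" for i in range(config.n_lncrna)]
    mir_names = [f"MIR{i:03d}" for i in range(config.n_mirna)]
    signal_lncs = lnc_names[: config.n_signal_lncrna]
    signal_mirs = mir_names[: config.n_signal_mirna]
    lnc_targets = {l: take(config.n_targets_per_noncoding) for l in signal_lncs}
    mir_targets = {m: take(config.n_targets_per_noncoding) for m in signal_mirs}
    mir_decoys = {m: take(config.n_db_decoys_per_mirna) for m in signal_mirs}
    mirna_db = {m: set(mir_targets[m]) | set(mir_decoys[m]) for m in signal_mirs}

    planted = set().union(*marker_genes.values(), de_up_hot, de_up_cold,
                          *lnc_targets.values(), *mir_targets.values(), *mir_decoys.values())
    free = [g for g in genes if g not in planted]
    n_coupled = int(round(config.background_coupled_frac * len(free)))
    coupled_idx = rng.choice(len(free), size=n_coupled, replace=False)
    lo, hi = config.background_coupling
    gamma_vals = rng.uniform(lo, hi, size=n_coupled) * rng.choice([-1.0, 1.0], size=n_coupled)
    background_gamma = pd.Series(gamma_vals, index=[free[i] for i in coupled_idx])

    # methylation probes: one probe <-> one gene <-> one region label
    probes = [f"cg{i:06d}" for i in range(config.n_probes)]
    probe_gene = rng.choice(
        genes, size=config.n_probes, replace=config.n_probes > config.n_genes
    )
    regions = rng.choice(ALL_REGIONS, size=config.n_probes, p=_REGION_WEIGHTS)
    n_dmp = min(config.n_dmp, config.n_probes)
    dmp_idx = rng.choice(config.n_probes, size=n_dmp, replace=False)
    regions[dmp_idx] = rng.choice(PROMOTER_REGIONS, size=n_dmp)
    dmp_dir = rng.choice([1.0, -1.0], size=n_dmp)  # +1: noninflamed hypermethylated
    # baselines chosen so mu +/- delta_beta never clips
    base_inf = np.where(dmp_dir > 0, rng.uniform(0.20, 0.45, n_dmp), rng.uniform(0.55, 0.80, n_dmp))
    null_mu = rng.uniform(0.15, 0.85, size=config.n_probes)

    drug_ids = [f"drug_{i:03d}" for i in range(config.n_drugs)]
    converter = drug_ids[int(rng.integers(config.n_drugs))]

    return {
        "genes": genes,
        "marker_genes": marker_genes,
        "de_up_hot": de_up_hot,
        "de_up_cold": de_up_cold,
        "lnc_names": lnc_names,
        "mir_names": mir_names,
        "signal_lncs": signal_lncs,
        "signal_mirs": signal_mirs,
        "lnc_targets": lnc_targets,
        "mir_targets": mir_targets,
        "mirna_db": mirna_db,
        "background_gamma": background_gamma,
        "probes": probes,
        "probe_gene": probe_gene,
        "probe_region": regions,
        "dmp_idx": dmp_idx,
        "dmp_dir": dmp_dir,
        "dmp_base_inf": base_inf,
        "null_mu": null_mu,
        "drug_ids": drug_ids,
        "converter": converter,
    }


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draws; var = mu + dispersion * mu^2 (gene-wise dispersion)."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / np.broadcast_to(dispersion, mean.shape)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# single-cell generator
# ---------------------------------------------------------------------------


def simulate_scrna(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a labeled single-cell count matrix with planted marker genes.

    Negative binomial counts; each planted marker's expected expression in its
    home type is exactly ``marker_fold`` times its expectation elsewhere;
    per-cell library sizes are lognormal.  Returns an AnnData (cells x genes,
    ``obs["cell_type"]``) plus the ground truth.
    """
    layout = _plant_layout(config)
    rng = np.random.default_rng([config.seed % (2**31), 23])
    genes = layout["genes"]
    gene_index = {g: i for i, g in enumerate(genes)}
    types = list(config.cell_types)
    n_cells = config.n_cells_per_type * len(types)
    cell_type = np.repeat(types, config.n_cells_per_type)

    base = config.sc_abundance_median * np.exp(
        rng.normal(0.0, config.sc_abundance_sigma, size=config.n_genes)
    )
    marker_idx_all = []
    for t in types:
        idx = [gene_index[g] for g in layout["marker_genes"][t]]
        marker_idx_all.extend(idx)
    base[marker_idx_all] = config.marker_base_abundance

    # per-type background program + planted marker folds
    factor = np.exp(
        rng.normal(0.0, config.type_program_sigma, size=(len(types), config.n_genes))
    )
    factor[:, marker_idx_all] = 1.0
    for ti, t in enumerate(types):
        for g in layout["marker_genes"][t]:
            factor[ti, gene_index[g]] = config.marker_fold

    lib = np.exp(rng.normal(0.0, config.sc_library_sigma, size=n_cells))
    type_of_cell = np.repeat(np.arange(len(types)), config.n_cells_per_type)
    mu = lib[:, None] * base[None, :] * factor[type_of_cell, :]
    phi = config.sc_dispersion_median * np.exp(rng.normal(0.0, 0.5, size=config.n_genes))
    counts = _nb_counts(rng, mu, phi[None, :])

    obs = pd.DataFrame(
        {"cell_type": pd.Categorical(cell_type)},
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth = GroundTruth(marker_genes={t: list(v) for t, v in layout["marker_genes"].items()})
    return adata, truth


# ---------------------------------------------------------------------------
# bulk cohort generator
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig, fixed_infiltration: float | None = None
) -> tuple[BulkCohort, GroundTruth]:
    """Simulate the bulk multi-omics cohort.

    Expected mRNA expression of each sample is ``(1 - f) * malignant program
    + f * immune program`` with ``f`` drawn from the three-mode infiltration
    mixture; planted DE genes carry an extra stratum fold; signal lncRNAs
    track a latent ``f + noise``; signal miRNAs suppress their planted
    targets; methylation betas carry the planted promoter delta; survival is
    exponential with log hazard ``-hazard_coeff * f``.

    ``fixed_infiltration`` pins ``f`` for every sample (degenerate world used
    by null tests); all labels are then "cold".
    """
    if config.n_samples_per_type < 6:
        raise ConfigurationError("n_samples_per_type must be >= 6 for usable downstream tests")
    layout = _plant_layout(config)
    rng = np.random.default_rng([config.seed % (2**31), 37])
    genes = layout["genes"]
    gene_index = {g: i for i, g in enumerate(genes)}

    tumor_types = [f"TT{t:02d}" for t in range(config.n_tumor_types)]
    n_s = config.n_tumor_types * config.n_samples_per_type
    sample_ids = [
        f"{tt}_S{i:03d}" for tt in tumor_types for i in range(config.n_samples_per_type)
    ]
    tumor_type = np.repeat(tumor_types, config.n_samples_per_type)

    mode_names = np.array(["cold", "median", "hot"])
    if fixed_infiltration is not None:
        f = np.full(n_s, float(fixed_infiltration))
        labels = np.full(n_s, "cold", dtype=object)
    else:
        comp = rng.choice(3, size=n_s, p=np.asarray(config.mixture_weights))
        conc = config.infiltration_concentration
        means = np.asarray(config.infiltration_modes)[comp]
        f = rng.beta(means * conc, (1.0 - means) * conc)
        labels = mode_names[comp]
    level = np.array([TME_LEVELS[l] for l in labels])

    # ------------------------------------------------------------------ mRNA
    base = config.bulk_abundance_median * np.exp(rng.normal(0.0, 1.5, size=config.n_genes))
    factor = np.ones((n_s, config.n_genes))
    for t, sig in layout["marker_genes"].items():
        idx = [gene_index[g] for g in sig]
        # markers sit at the median baseline: their bulk signal comes from the
        # immune (resp. malignant) compartment, mirroring the single-cell world
        base[idx] = config.bulk_abundance_median
        if t == "malignant":
            factor[:, idx] *= ((1.0 - f) * config.marker_fold + f)[:, None]
        else:
            factor[:, idx] *= ((1.0 - f) + f * config.marker_fold)[:, None]
    up_hot = [gene_index[g] for g in layout["de_up_hot"]]
    up_cold = [gene_index[g] for g in layout["de_up_cold"]]
    factor[:, up_hot] *= config.de_fold ** level[:, None]
    factor[:, up_cold] *= config.de_fold ** (1.0 - level)[:, None]
    gamma = layout["background_gamma"]
    bg_idx = [gene_index[g] for g in gamma.index]
    factor[:, bg_idx] *= np.exp(np.outer(f - 0.25, gamma.to_numpy()))

    # signal lncRNAs share a latent infiltration readout with their partner mRNAs
    lnc_log_signal = {}
    for l in layout["signal_lncs"]:
        latent = f + rng.normal(0.0, config.lnc_latent_sd, size=n_s)
        lnc_log_signal[l] = config.lnc_coupling * (latent - 0.25)
        t_idx = [gene_index[g] for g in layout["lnc_targets"][l]]
        factor[:, t_idx] *= np.exp(lnc_log_signal[l])[:, None]

    # signal miRNAs suppress their targets (negative log-linear coupling)
    mir_log_signal = {}
    for j, m in enumerate(layout["signal_mirs"]):
        direction = 1.0 if j % 2 == 0 else -1.0
        z_raw = direction * math.log(config.de_fold) * level + 0.8 * rng.normal(size=n_s)
        mir_log_signal[m] = z_raw
        z = (z_raw - z_raw.mean()) / max(z_raw.std(), 1e-12)
        t_idx = [gene_index[g] for g in layout["mir_targets"][m]]
        factor[:, t_idx] *= np.exp(-config.mir_coupling * z)[:, None]

    lib = np.exp(rng.normal(0.0, 0.25, size=n_s))
    phi = config.bulk_dispersion_median * np.exp(rng.normal(0.0, 0.3, size=config.n_genes))
    mrna = _nb_counts(rng, lib[:, None] * base[None, :] * factor, phi[None, :])
    mrna = pd.DataFrame(mrna, index=sample_ids, columns=genes)

    # ------------------------------------------------------- noncoding RNAs
    def _nc_counts(names: Sequence[str], log_signal: dict[str, np.ndarray]) -> pd.DataFrame:
        base_nc = 200.0 * np.exp(rng.normal(0.0, 1.0, size=len(names)))
        mu = np.empty((n_s, len(names)))
        for j, name in enumerate(names):
            sig = log_signal.get(name)
            noise = rng.normal(0.0, 0.3, size=n_s) if sig is None else 0.0
            mu[:, j] = lib * base_nc[j] * np.exp(sig if sig is not None else noise)
        phi_nc = 0.1 * np.exp(rng.normal(0.0, 0.3, size=len(names)))
        return pd.DataFrame(
            _nb_counts(rng, mu, phi_nc[None, :]), index=sample_ids, columns=list(names)
        )

    lncrna = _nc_counts(layout["lnc_names"], lnc_log_signal)
    mirna = _nc_counts(layout["mir_names"], mir_log_signal)

    # ---------------------------------------------------------- methylation
    mu_beta = np.tile(layout["null_mu"][:, None], (1, n_s))
    dmp_idx = layout["dmp_idx"]
    for k, pi in enumerate(dmp_idx):
        base_inf = layout["dmp_base_inf"][k]
        delta = layout["dmp_dir"][k] * config.delta_beta
        # level 1 = hot (inflamed); noninflamed mean = inflamed mean + delta
        mu_beta[pi, :] = base_inf + delta * (1.0 - level)
    nu = config.beta_precision
    beta = rng.beta(mu_beta * nu, (1.0 - mu_beta) * nu)
    methylation = pd.DataFrame(beta, index=layout["probes"], columns=sample_ids)
    probe_annot = pd.DataFrame(
        {"gene": layout["probe_gene"], "region": layout["probe_region"]},
        index=pd.Index(layout["probes"], name="probe"),
    )

    # ------------------------------------------------------------- survival
    rate = config.baseline_hazard * np.exp(-config.hazard_coeff * f)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(0.0, config.censor_horizon, size=n_s)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    age = rng.normal(60.0, 10.0, size=n_s)
    survival = pd.DataFrame(
        {"time": time, "event": event, "age": age, "tumor_type": tumor_type},
        index=sample_ids,
    )

    samples = pd.DataFrame({"tumor_type": tumor_type}, index=sample_ids)
    cohort = BulkCohort(
        mrna=mrna,
        mirna=mirna,
        lncrna=lncrna,
        methylation=methylation,
        probe_annot=probe_annot,
        survival=survival,
        samples=samples,
        mirna_target_db={m: set(s) for m, s in layout["mirna_db"].items()},
    )

    de_signed = pd.concat(
        [
            pd.Series(math.log2(config.de_fold), index=layout["de_up_hot"]),
            pd.Series(-math.log2(config.de_fold), index=layout["de_up_cold"]),
        ]
    )
    dmp_true = pd.Series(
        layout["dmp_dir"] * config.delta_beta,
        index=[layout["probes"][i] for i in dmp_idx],
    )
    truth = GroundTruth(
        marker_genes={t: list(v) for t, v in layout["marker_genes"].items()},
        infiltration_fraction=pd.Series(f, index=sample_ids),
        tme_label_true=pd.Series(labels, index=sample_ids),
        de_genes_true=de_signed,
        dmp_probes_true=dmp_true,
        lnc_target_genes_true={l: list(v) for l, v in layout["lnc_targets"].items()},
        mir_target_genes_true={m: list(v) for m, v in layout["mir_targets"].items()},
        converter_drug_id=layout["converter"],
        background_coupled_genes=list(gamma.index),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# drug perturbation database generator
# ---------------------------------------------------------------------------


def simulate_drug_db(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a drug rank-profile database (genes x drugs, rank 1 = most
    up-regulated by the drug).

    All drugs are uniform random permutations of the gene universe except one
    planted "converter" whose profile places the hot-specific planted genes in
    the top 5% of ranks and the cold-specific genes in the bottom 5%.
    """
    if config.n_drugs < 2:
        raise ConfigurationError("n_drugs must be >= 2 (normalization across drugs undefined)")
    layout = _plant_layout(config)
    rng = np.random.default_rng([config.seed % (2**31), 53])
    genes = layout["genes"]
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    ranks = np.empty((n, config.n_drugs), dtype=np.int64)
    for j in range(config.n_drugs):
        ranks[:, j] = rng.permutation(n) + 1

    conv_j = layout["drug_ids"].index(layout["converter"])
    hot_idx = np.array([gene_index[g] for g in layout["de_up_hot"]])
    cold_idx = np.array([gene_index[g] for g in layout["de_up_cold"]])
    block = max(int(math.ceil(0.05 * n)), len(hot_idx), len(cold_idx))
    top = rng.choice(block, size=len(hot_idx), replace=False) + 1
    bottom = n - rng.choice(block, size=len(cold_idx), replace=False)
    rest = np.setdiff1d(np.arange(1, n + 1), np.concatenate([top, bottom]))
    rng.shuffle(rest)
    prof = np.empty(n, dtype=np.int64)
    prof[hot_idx] = top
    prof[cold_idx] = bottom
    other = np.setdiff1d(np.arange(n), np.concatenate([hot_idx, cold_idx]))
    prof[other] = rest
    ranks[:, conv_j] = prof

    db = pd.DataFrame(ranks, index=genes, columns=layout["drug_ids"])
    truth = GroundTruth(
        de_genes_true=pd.concat(
            [
                pd.Series(math.log2(config.de_fold), index=layout["de_up_hot"]),
                pd.Series(-math.log2(config.de_fold), index=layout["de_up_cold"]),
            ]
        ),
        converter_drug_id=layout["converter"],
    )
    return db, truth
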