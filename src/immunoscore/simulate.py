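"""Synthetic cohorts with planted immune-infiltration structure.

The generator emulates the statistical structure a bulk-transcriptome
immune-typing analysis assumes:

* two latent sample groups — a high-infiltration group ``A`` with better
  progression-free survival and a low-infiltration group ``B`` with worse —
  with every immune cell type shifted in the same direction (A above B);
* one disjoint marker-gene signature per cell type, whose genes co-express
  because they share that cell type's latent infiltration;
* designated checkpoint genes (named ``CTLA4`` and ``CD274`` in the output)
  that track the mean infiltration with positive loading;
* exponential progression times with a group-dependent hazard and uniform
  censoring, plus clinical covariates (Gleason grade, nodal status, therapy
  flags, T stage) with group-dependent enrichment where stated.

Expression is simulated directly on the log2 scale (Gaussian around a
per-gene baseline): the downstream pipeline consumes log-transformed
normalized values, so a count layer is unnecessary.

All generators are pure functions of ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    write_clinical,
    write_expression_matrix,
    write_gmt,
)

#: The 28 immune cell subtypes commonly scored by ssGSEA immune profiling.
CELL_TYPES_28 = (
    "Activated_B_cell",
    "Activated_CD4_T_cell",
    "Activated_CD8_T_cell",
    "Activated_dendritic_cell",
    "CD56bright_natural_killer_cell",
    "CD56dim_natural_killer_cell",
    "Central_memory_CD4_T_cell",
    "Central_memory_CD8_T_cell",
    "Effector_memory_CD4_T_cell",
    "Effector_memory_CD8_T_cell",
    "Eosinophil",
    "Gamma_delta_T_cell",
    "Immature_B_cell",
    "Immature_dendritic_cell",
    "Macrophage",
    "Mast_cell",
    "MDSC",
    "Memory_B_cell",
    "Monocyte",
    "Natural_killer_cell",
    "Natural_killer_T_cell",
    "Neutrophil",
    "Plasmacytoid_dendritic_cell",
    "Regulatory_T_cell",
    "T_follicular_helper_cell",
    "Type_1_T_helper_cell",
    "Type_17_T_helper_cell",
    "Type_2_T_helper_cell",
)

CHECKPOINT_GENES = ("CTLA4", "CD274")


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort generator.

    The defaults are the standing benchmark conditions used throughout the
    test suite: n=400 samples, 28 cell types x 30 marker genes, an
    infiltration gap of delta=3 latent units between groups, signature
    loading beta_sig=2, and a log hazard ratio of 1 for the low-infiltration
    group B.
    """

    n_samples: int = 400
    n_cell_types: int = 28
    genes_per_signature: int = 30
    n_background_genes: int = 2000
    group_a_fraction: float = 0.4       # ~193/495 in a typical cohort
    delta: float = 3.0                  # infiltration shift, A minus B, latent units
    sigma_f: float = 1.2                # sd of latent infiltration noise
    beta_sig: float = 2.0               # loading of infiltration on signature genes
    beta_checkpoint: float = 1.5        # loading of mean infiltration on checkpoint genes
    noise_sd: float = 0.5               # residual sd of log2 expression
    baseline_hazard: float = 0.02       # events per month for group A
    log_hr_b: float = 1.0               # log hazard ratio, group B vs A
    censoring_window: float = 120.0     # months; censoring ~ Uniform(0, window]
    p_high_gleason: tuple[float, float] = (0.3, 0.6)   # P(gleason>7) in (A, B)
    p_n_positive: tuple[float, float] = (0.1, 0.3)     # P(N+) in (A, B)
    p_hormone: float = 0.5
    p_radiation: float = 0.3
    hormone_benefit: float = 0.0        # log-hazard reduction for treated group-A samples
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma_f <= 0 or self.noise_sd <= 0:
            raise ValueError("noise scales must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_window <= 0:
            raise ValueError("censoring_window must be > 0")
        if not (0 < self.group_a_fraction < 1):
            raise ValueError("group_a_fraction must be in (0, 1)")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class TruthLabels:
    """Planted ground truth of a synthetic cohort."""

    group: pd.Series            # sample -> 'A' | 'B'
    gene_module: pd.Series      # gene -> cell-type name or 'background'
    latent: pd.DataFrame = field(default=None)  # cell types x samples infiltration

    def __post_init__(self) -> None:
        counts = self.group.value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("each planted group needs >= 2 samples")


def _cell_type_names(n: int) -> list[str]:
    if n <= len(CELL_TYPES_28):
        return list(CELL_TYPES_28[:n])
    extra = [f"Cell_type_{i}" for i in range(len(CELL_TYPES_28), n)]
    return list(CELL_TYPES_28) + extra


def simulate_infiltration(
    params: SimulationParams,
) -> tuple[TruthLabels, pd.DataFrame]:
    """Draw latent per-cell-type infiltration ``f(c, s)``.

    ``f(c, s) = mu_c + delta * I[group(s) == A] + Normal(0, sigma_f^2)``;
    all cell types shift in the same direction, and the shared group effect
    induces positive pairwise cell-type correlation.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_a = max(2, round(n * params.group_a_fraction))
    groups = np.array(["B"] * n, dtype=object)
    groups[rng.permutation(n)[:n_a]] = "A"
    group = pd.Series(groups, index=sample_ids, name="group")

    cell_types = _cell_type_names(params.n_cell_types)
    mu = rng.normal(0.0, 1.0, size=params.n_cell_types)
    shift = params.delta * (groups == "A").astype(float)
    f = (
        mu[:, None]
        + shift[None, :]
        + rng.normal(0.0, params.sigma_f, size=(params.n_cell_types, n))
    )
    latent = pd.DataFrame(f, index=cell_types, columns=sample_ids)

    gene_module = _gene_module_map(params, cell_types)
    truth = TruthLabels(group=group, gene_module=gene_module, latent=latent)
    return truth, latent


def _gene_module_map(params: SimulationParams, cell_types: list[str]) -> pd.Series:
    entries: dict[str, str] = {}
    g = 0
    for ct in cell_types:
        for _ in range(params.genes_per_signature):
            entries[f"G{g:05d}"] = ct
            g += 1
    for _ in range(params.n_background_genes):
        entries[f"B{g:05d}"] = "background"
        g += 1
    for name in CHECKPOINT_GENES:
        entries[name] = "checkpoint"
    return pd.Series(entries, name="module")


def simulate_expression(
    truth: TruthLabels,
    latent: pd.DataFrame,
    params: SimulationParams,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Generate a log2 expression matrix and the true signature GMT.

    Signature gene *g* of cell type *c*:
    ``x(g, s) = b_g + beta_sig * f(c, s) + Normal(0, noise_sd^2)``.
    Background genes are baseline plus noise; checkpoint genes follow the
    mean infiltration with loading ``beta_checkpoint``.
    """
    if list(latent.columns) != list(truth.group.index):
        raise ValueError("latent matrix and truth labels disagree on samples")
    # derive a dedicated stream so expression is reproducible given (params, seed)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    genes = truth.gene_module.index.to_numpy()
    modules = truth.gene_module.to_numpy()
    n_genes, n = len(genes), latent.shape[1]

    baseline = rng.normal(6.0, 1.0, size=n_genes)
    x = np.empty((n_genes, n))
    mean_f = latent.to_numpy().mean(axis=0)
    for i, (gene, mod) in enumerate(zip(genes, modules)):
        if mod == "background":
            signal = 0.0
        elif mod == "checkpoint":
            signal = params.beta_checkpoint * mean_f
        else:
            signal = params.beta_sig * latent.loc[mod].to_numpy()
        x[i] = baseline[i] + signal + rng.normal(0.0, params.noise_sd, size=n)
    expr = pd.DataFrame(x, index=genes, columns=latent.columns)

    sets = {
        ct: truth.gene_module.index[truth.gene_module == ct].tolist()
        for ct in latent.index
    }
    gmt = GeneSetCollection(
        sets=sets,
        descriptions={ct: "synthetic signature" for ct in latent.index},
    )
    return expr, gmt


def simulate_survival(truth: TruthLabels, params: SimulationParams) -> pd.DataFrame:
    """Draw the clinical table: group-dependent PFS plus covariates.

    Event times are exponential with hazard
    ``lambda * exp(log_hr_b * I[B] - hormone_benefit * hormone * I[A])``;
    censoring is uniform on ``(0, window]``.  Gleason > 7 and N+ are enriched
    in group B; therapy flags are assigned independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    groups = truth.group.to_numpy()
    n = len(groups)
    is_b = (groups == "B").astype(float)

    hormone = (rng.random(n) < params.p_hormone).astype(int)
    radiation = (rng.random(n) < params.p_radiation).astype(int)

    log_hazard = (
        np.log(params.baseline_hazard)
        + params.log_hr_b * is_b
        - params.hormone_benefit * hormone * (1.0 - is_b)
    )
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    censor_time = rng.uniform(0.0, params.censoring_window, size=n)
    censor_time = np.maximum(censor_time, 1e-9)  # window is half-open at 0
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    p_gl = np.where(is_b == 1, params.p_high_gleason[1], params.p_high_gleason[0])
    gleason = np.where(rng.random(n) < p_gl, rng.integers(8, 11, size=n), rng.integers(6, 8, size=n))
    p_np = np.where(is_b == 1, params.p_n_positive[1], params.p_n_positive[0])
    n_status = np.where(rng.random(n) < p_np, "N+", "N-")
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.15, 0.35, 0.4, 0.1])

    return pd.DataFrame(
        {
            "sample_id": truth.group.index,
            "pfs_time": observed,
            "pfs_event": event,
            "gleason": gleason,
            "n_status": n_status,
            "hormone_therapy": hormone,
            "radiation_therapy": radiation,
            "t_stage": t_stage,
        }
    ).reset_index(drop=True)


def generate_cohort(
    params: SimulationParams,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, GeneSetCollection, pd.DataFrame, TruthLabels]:
    """Compose the three generators into a full cohort.

    Returns ``(expression, signatures, clinical, truth)``; when ``out_dir``
    is given, also writes ``expression.tsv``, ``signatures.gmt``,
    ``clinical.tsv`` and ``truth.tsv``.
    """
    truth, latent = simulate_infiltration(params)
    expr, gmt = simulate_expression(truth, latent, params)
    clinical = simulate_survival(truth, params)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = [f"seed={params.seed}"]
        write_expression_matrix(expr, out_dir / "expression.tsv", header)
        write_gmt(gmt, out_dir / "signatures.gmt")
        write_clinical(clinical, out_dir / "clinical.tsv", header)
        truth_df = pd.DataFrame(
            {"sample_id": truth.group.index, "group": truth.group.to_numpy()}
        )
        truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        truth.gene_module.rename_axis("gene_id").to_frame().to_csv(
            out_dir / "gene_modules.tsv", sep="\t"
        )
    return expr, gmt, clinical, truth
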