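"""Synthetic single-cell expression data with known ground truth.

Every downstream stage of the pipeline (pathway activity, permutation
significance, PCA heterogeneity, hypoxia correlation, IHC association) is
exercised on data from this module, so each generator plants a known
effect that the corresponding stage must recover:

* cell-type-specific pathway programs of configurable fold change,
* expression-dependent dropout zeros (recorded, so imputation is testable),
* a latent per-cell hypoxia factor loaded onto both the hypoxia signature
  genes and a glycolysis-like pathway, giving a tunable score correlation,
* clinical IHC cohorts whose 2x2 contingency tables match requested margins
  exactly.

The expression model is a log-normal per-gene baseline with per-gene
dispersion, multiplicative cell-type effects, TPM renormalization, then
Bernoulli dropout whose probability falls logistically with a gene's
log-mean. This is a stand-in family chosen for heavy-tailed TPM marginals
and closed-form constructions, not a fit to any real dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import TPM_SCALE, CellAnnotation, ExpressionMatrix, GeneSetCollection, IhcCohort
from .errors import ConfigError, ValidationError

HYPOXIA_SET_NAME = "HALLMARK_HYPOXIA"
GLYCOLYSIS_SET_NAME = "GLYCOLYSIS_GLUCONEOGENESIS"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic expression generator.

    Defaults emulate a scaled-down multi-sample single-cell study: a few
    hundred cells per type across several types, ~1000 genes of which a
    third sit in overlapping metabolic pathways, 30% technical zeros, and
    a hypoxia-glycolysis coupling of rho = 0.8.
    """

    n_genes: int = 1000
    n_cells_per_type: Sequence[int] = (200, 200, 200, 200)
    cell_type_names: Sequence[str] | None = None
    n_samples: int = 3
    n_pathways: int = 30
    genes_per_pathway: int = 10
    pathway_overlap_fraction: float = 0.2
    #: (pathway name, cell type name, fold change > 0) triples.
    planted_effects: Sequence[tuple[str, str, float]] = ()
    dropout_rate: float = 0.3
    hypoxia_rho: float = 0.8
    #: Std-dev of the latent log hypoxia factor; larger = stronger program.
    hypoxia_strength: float = 1.25
    hypoxia_set_size: int = 40
    baseline_mean_tpm: float = 100.0
    #: Mean of the gamma-distributed per-gene log-normal sigma.
    dispersion: float = 0.5
    renormalize_after_dropout: bool = False
    tissue_group: str = "tumor"
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.cell_type_names is None:
            self.cell_type_names = [f"type_{chr(ord('A') + i)}" for i in range(len(self.n_cells_per_type))]
        self.cell_type_names = list(self.cell_type_names)
        self.n_cells_per_type = list(self.n_cells_per_type)
        self.planted_effects = list(self.planted_effects)
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if len(self.cell_type_names) != len(self.n_cells_per_type):
            raise ConfigError("cell_type_names and n_cells_per_type lengths differ")
        if any(n < 1 for n in self.n_cells_per_type):
            raise ConfigError("n_cells_per_type entries must be >= 1")
        if not 0.0 <= self.pathway_overlap_fraction <= 1.0:
            raise ConfigError("pathway_overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1]")
        if not -1.0 <= self.hypoxia_rho <= 1.0:
            raise ConfigError("hypoxia_rho must lie in [-1, 1]")
        if self.baseline_mean_tpm <= 0:
            raise ConfigError("baseline_mean_tpm must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        if self.hypoxia_strength < 0:
            raise ConfigError("hypoxia_strength must be nonnegative")
        for name, ctype, fold in self.planted_effects:
            if fold <= 0:
                raise ConfigError(f"planted fold change for ({name}, {ctype}) must be > 0")
            if ctype not in self.cell_type_names:
                raise ConfigError(f"planted effect references unknown cell type {ctype!r}")
        if self.planted_effects and len(self.cell_type_names) < 2:
            raise ConfigError("planted effects need at least 2 cell types to be detectable")

    @property
    def pathway_names(self) -> list[str]:
        digits = max(2, len(str(self.n_pathways)))
        names = [f"PATHWAY_{i + 1:0{digits}d}" for i in range(self.n_pathways)]
        if self.n_pathways >= 1:
            # the first metabolic pathway plays the role of glycolysis
            names[0] = GLYCOLYSIS_SET_NAME
        return names


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_effects: list[tuple[str, str, float]]
    membership: dict[str, tuple[str, ...]]
    dropout_mask: np.ndarray  # True where a technical zero was introduced
    renormalized_after_dropout: bool
    true_hypoxia: np.ndarray | None = None  # latent per-cell factor
    pre_dropout_tpm: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _build_pathways(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Assign gene indices to pathways; consecutive pathways share
    ``overlap_fraction * genes_per_pathway`` genes."""
    n_shared = int(round(cfg.pathway_overlap_fraction * cfg.genes_per_pathway))
    n_new_total = cfg.genes_per_pathway + (cfg.n_pathways - 1) * (cfg.genes_per_pathway - n_shared)
    if n_new_total + cfg.hypoxia_set_size > cfg.n_genes:
        raise ConfigError(
            f"n_genes={cfg.n_genes} too small for {cfg.n_pathways} pathways of "
            f"{cfg.genes_per_pathway} genes plus a {cfg.hypoxia_set_size}-gene hypoxia set"
        )
    members: dict[str, np.ndarray] = {}
    cursor = 0
    prev: np.ndarray | None = None
    for name in cfg.pathway_names:
        if prev is None or n_shared == 0:
            fresh = np.arange(cursor, cursor + cfg.genes_per_pathway)
            cursor += cfg.genes_per_pathway
            idx = fresh
        else:
            shared = rng.choice(prev, size=n_shared, replace=False)
            n_fresh = cfg.genes_per_pathway - n_shared
            fresh = np.arange(cursor, cursor + n_fresh)
            cursor += n_fresh
            idx = np.concatenate([np.sort(shared), fresh])
        members[name] = idx
        prev = idx
    return members


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, GeneSetCollection, GroundTruth]:
    """Simulate a TPM matrix with planted cell-type pathway programs.

    Returns the matrix (stage ``tpm``, columns summing to 1e6 before any
    dropout renormalization), the cell annotation, the gene-set collection
    (metabolic pathways plus a designated hypoxia signature set), and the
    ground truth (dropout mask, memberships, planted effects).

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells = int(sum(config.n_cells_per_type))
    genes = pd.Index([f"G{i + 1:05d}" for i in range(config.n_genes)])
    cells = pd.Index([f"C{i + 1:06d}" for i in range(n_cells)])

    pathway_idx = _build_pathways(config, rng)
    assigned = np.unique(np.concatenate(list(pathway_idx.values()))) if pathway_idx else np.array([], int)
    free = np.setdiff1d(np.arange(config.n_genes), assigned)
    hypoxia_idx = rng.choice(free, size=config.hypoxia_set_size, replace=False)
    hypoxia_idx.sort()

    # per-gene log-normal baseline and gamma-distributed dispersion
    log_mu = rng.normal(math.log(config.baseline_mean_tpm), 1.0, size=config.n_genes)
    mu = np.exp(log_mu)
    if config.dispersion > 0:
        sigma = rng.gamma(shape=2.0, scale=config.dispersion / 2.0, size=config.n_genes)
    else:
        sigma = np.zeros(config.n_genes)

    # cell-type fold-change matrix (genes x types)
    type_names = list(config.cell_type_names)
    fold = np.ones((config.n_genes, len(type_names)))
    for pname, ctype, f in config.planted_effects:
        if pname not in pathway_idx:
            raise ConfigError(f"planted effect references unknown pathway {pname!r}")
        fold[pathway_idx[pname], type_names.index(ctype)] *= f

    type_codes = np.repeat(np.arange(len(type_names)), config.n_cells_per_type)

    # mean-preserving log-normal noise: E[exp(sigma*z - sigma^2/2)] = 1
    z = rng.standard_normal((config.n_genes, n_cells))
    raw = mu[:, None] * fold[:, type_codes] * np.exp(sigma[:, None] * z - 0.5 * sigma[:, None] ** 2)

    tpm = raw / raw.sum(axis=0, keepdims=True) * TPM_SCALE
    pre_dropout = tpm.copy()

    # expression-dependent dropout: logistic in the gene's log-mean,
    # centred at the median so the average rate ~= dropout_rate
    if config.dropout_rate > 0:
        centred = log_mu - np.median(log_mu)
        p_drop = np.clip(2.0 * config.dropout_rate / (1.0 + np.exp(centred)), 0.0, 1.0)
        drop = rng.random((config.n_genes, n_cells)) < p_drop[:, None]
    else:
        drop = np.zeros((config.n_genes, n_cells), dtype=bool)
    tpm = np.where(drop, 0.0, tpm)
    if config.renormalize_after_dropout:
        totals = tpm.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        tpm = tpm / totals * TPM_SCALE

    matrix = ExpressionMatrix(tpm, genes, cells, stage="tpm")

    sample_ids = [f"S{rng.integers(config.n_samples) + 1}" for _ in range(n_cells)]
    annotation = CellAnnotation(pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue_group": config.tissue_group,
            "cell_type": np.asarray(type_names, dtype=object)[type_codes],
        },
        index=cells,
    ))

    sets = {name: tuple(genes[i] for i in idx) for name, idx in pathway_idx.items()}
    sets[HYPOXIA_SET_NAME] = tuple(genes[i] for i in hypoxia_idx)
    collection = GeneSetCollection(sets, signature_sets=(HYPOXIA_SET_NAME,))

    truth = GroundTruth(
        planted_effects=list(config.planted_effects),
        membership=dict(sets),
        dropout_mask=drop,
        renormalized_after_dropout=config.renormalize_after_dropout,
        pre_dropout_tpm=pre_dropout,
    )
    return matrix, annotation, collection, truth


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0 if sx == sy == 0 else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def generate_hypoxia_program(
    config: SimulationConfig,
    matrix: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    glycolysis_set: str = GLYCOLYSIS_SET_NAME,
    hypoxia_set: str = HYPOXIA_SET_NAME,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Overlay a latent per-cell hypoxia factor on the matrix.

    A latent hypoxia level u_c ~ N(0,1) multiplies the hypoxia genes by
    exp(s*u); the glycolysis genes are multiplied by exp(s*v) with
    v = alpha*u + sqrt(1-alpha^2)*w for independent noise w. Because the
    per-cell set means also carry expression and dropout noise, a fixed
    latent correlation would be attenuated on the observed scale, so
    alpha is calibrated by bisection against the realized Pearson
    correlation of the final (renormalized) per-cell hypoxia-gene and
    glycolysis-gene means — the quantity the configured ``hypoxia_rho``
    refers to. The calibration is deterministic given the seed. If the
    requested rho lies outside the achievable range (lognormal factors
    plus noise bound it), the nearest endpoint is used with a warning.

    At rho = 1 with zero expression noise the construction degenerates to
    v = u and the two set means are exactly proportional (correlation 1).

    Returns the modified matrix and the latent hypoxia factor u (the
    true per-cell hypoxia level).
    """
    if matrix.stage != "tpm":
        raise ConfigError("hypoxia program must be planted at the tpm stage")
    for name in (hypoxia_set, glycolysis_set):
        if name not in gene_sets:
            raise ConfigError(f"gene set {name!r} absent from the collection")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x48595058]))
    s = config.hypoxia_strength
    rho = config.hypoxia_rho

    n = matrix.n_cells
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)

    hyp_idx = matrix.gene_indexer(gene_sets[hypoxia_set])
    gly_idx = matrix.gene_indexer(gene_sets[glycolysis_set])
    if len(hyp_idx) == 0 or len(gly_idx) == 0:
        raise ConfigError("hypoxia/glycolysis genes not present in the matrix")

    base = matrix.values
    hyp_block = base[hyp_idx, :] * np.exp(s * u)[None, :]
    hyp_mean = hyp_block.mean(axis=0)
    hyp_sum = hyp_block.sum(axis=0)
    gly_base = base[gly_idx, :]
    rest_sum = base.sum(axis=0) - base[hyp_idx, :].sum(axis=0) - gly_base.sum(axis=0)

    def realized(alpha: float) -> tuple[float, np.ndarray]:
        """Final-scale correlation of the two set means for a coupling alpha."""
        v = alpha * u + math.sqrt(max(0.0, 1.0 - alpha * alpha)) * w
        factor = np.exp(s * v)
        gly_mean = (gly_base * factor[None, :]).mean(axis=0)
        totals = rest_sum + hyp_sum + gly_mean * len(gly_idx)
        totals = np.where(totals == 0, 1.0, totals)
        return _corr(hyp_mean / totals, gly_mean / totals), v

    lo_corr, _ = realized(-1.0)
    hi_corr, _ = realized(1.0)
    if rho >= hi_corr:
        if rho > hi_corr + 1e-9:
            warnings.warn(
                f"hypoxia_rho={rho} exceeds achievable correlation {hi_corr:.3f}; using the maximum",
                stacklevel=2,
            )
        alpha = 1.0
    elif rho <= lo_corr:
        if rho < lo_corr - 1e-9:
            warnings.warn(
                f"hypoxia_rho={rho} below achievable correlation {lo_corr:.3f}; using the minimum",
                stacklevel=2,
            )
        alpha = -1.0
    else:
        a_lo, a_hi = -1.0, 1.0
        alpha = 0.0
        for _ in range(60):
            alpha = 0.5 * (a_lo + a_hi)
            c, _ = realized(alpha)
            if abs(c - rho) < 1e-6:
                break
            if c < rho:
                a_lo = alpha
            else:
                a_hi = alpha

    _, v = realized(alpha)
    values = base.copy()
    values[hyp_idx, :] = hyp_block
    values[gly_idx, :] = gly_base * np.exp(s * v)[None, :]
    totals = values.sum(axis=0, keepdims=True)
    totals[totals == 0] = 1.0
    values = values / totals * TPM_SCALE

    out = ExpressionMatrix(values, matrix.genes, matrix.cells, stage="tpm")
    return out, u


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, CellAnnotation, GeneSetCollection, GroundTruth]:
    """Full simulation: expression + planted hypoxia program."""
    matrix, annotation, collection, truth = generate_expression(config)
    matrix, u = generate_hypoxia_program(config, matrix, collection)
    truth.true_hypoxia = u
    return matrix, annotation, collection, truth


# intensity x grade combinations by dichotomized class (product >= 4 is high)
_HIGH_COMBOS = [(i, g) for i in (0, 1, 2, 3) for g in (1, 2, 3) if i * g >= 4]
_LOW_COMBOS = [(i, g) for i in (0, 1, 2, 3) for g in (1, 2, 3) if i * g < 4]


def generate_ihc_cohort(
    counts: Mapping[str, Sequence[int]],
    seed: int = 0,
) -> IhcCohort:
    """Build a patient-level cohort matching requested 2x2 margins exactly.

    Parameters
    ----------
    counts
        Mapping ``feature name -> (yes_high, yes_low, no_high, no_low)``.
        All features must describe the same cohort, so the implied
        high-class total (``yes_high + no_high``) and low-class total must
        agree across features.
    seed
        Controls which patients receive which feature value and which
        intensity/grade pair realizes each class.

    Every emitted patient gets staining components consistent with their
    class (product >= 4 for high, < 4 for low), so rebuilding the
    contingency tables from the cohort returns the requested counts.
    """
    rng = np.random.default_rng(seed)
    feats = {k: tuple(int(x) for x in v) for k, v in counts.items()}
    for name, c in feats.items():
        if len(c) != 4:
            raise ValidationError(f"feature {name!r}: expected 4 counts (yh, yl, nh, nl)")
        if any(x < 0 for x in c):
            raise ValidationError(f"feature {name!r}: counts must be nonnegative")
    highs = {name: c[0] + c[2] for name, c in feats.items()}
    lows = {name: c[1] + c[3] for name, c in feats.items()}
    if feats:
        if len(set(highs.values())) > 1 or len(set(lows.values())) > 1:
            raise ValidationError(
                f"inconsistent margins across features: high totals {highs}, low totals {lows}"
            )
        n_high = next(iter(highs.values()))
        n_low = next(iter(lows.values()))
    else:
        n_high = n_low = 0

    n = n_high + n_low
    ids = [f"P{i + 1:03d}" for i in range(n)]
    cls = ["high"] * n_high + ["low"] * n_low

    intensity, grade = [], []
    for c in cls:
        i, g = _HIGH_COMBOS[rng.integers(len(_HIGH_COMBOS))] if c == "high" else \
            _LOW_COMBOS[rng.integers(len(_LOW_COMBOS))]
        intensity.append(i)
        grade.append(g)

    data = {"intensity": intensity, "proportion_grade": grade}
    for name, (yh, yl, _nh, _nl) in feats.items():
        col = np.array(["no"] * n, dtype=object)
        hi_yes = rng.choice(n_high, size=yh, replace=False) if yh else []
        lo_yes = n_high + rng.choice(n_low, size=yl, replace=False) if yl else []
        col[np.asarray(hi_yes, dtype=int)] = "yes"
        col[np.asarray(lo_yes, dtype=int)] = "yes"
        data[name] = col
    table = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"))
    return IhcCohort(table, feature_columns=tuple(feats))
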