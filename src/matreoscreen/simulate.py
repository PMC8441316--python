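"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators are pure functions of (config, seed): age-stratified expression
cohorts with a linear-in-age trend planted on a subset of matrisome genes,
drug z-score libraries with planted signature-concordant compounds and
enriched lifespan flags, abstract tables with planted ECM keyword counts,
and reporter trajectories with a linear decline and a Gaussian-peaked dose
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from matreoscreen.litmine import DEFAULT_ECM_KEYWORDS
from matreoscreen.matrisome import MATRISOME_CATEGORIES, GeneSetCollection
from matreoscreen.scoring import DrugProfileMatrix
from matreoscreen.signature import DOWN, UP, ExpressionCohort, MatreotypeSignature

DEFAULT_BRACKETS = (
    ("20s", 25.0), ("30s", 35.0), ("40s", 45.0),
    ("50s", 55.0), ("60s", 65.0), ("70s", 75.0),
)


@dataclass
class CohortConfig:
    n_genes: int = 200
    n_matrisome: int = 40
    tissues: tuple[str, ...] = ("skin", "thyroid", "aorta")
    donors_per_bracket: int = 20
    age_brackets: tuple[tuple[str, float], ...] = DEFAULT_BRACKETS
    effect_size: float = 1.0  # log-scale young-to-old group mean shift
    frac_planted_up: float = 0.25
    frac_planted_down: float = 0.25
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrisome > self.n_genes:
            raise ValueError("n_matrisome cannot exceed n_genes")
        if self.frac_planted_up + self.frac_planted_down > 1:
            raise ValueError("planted fractions must sum to <= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.age_brackets) < 2:
            raise ValueError("need at least 2 age brackets")


@dataclass
class DrugLibraryConfig:
    n_drugs: int = 500
    n_genes: int = 200
    n_planted_reversed: int = 20
    n_planted_potentiated: int = 20
    delta: float = 1.0  # planted per-gene z offset on signature genes
    lifespan_base_rate: float = 0.05
    lifespan_planted_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.lifespan_base_rate, self.lifespan_planted_rate):
            if not 0 <= r <= 1:
                raise ValueError("lifespan rates must lie in [0, 1]")
        if self.n_planted_reversed + self.n_planted_potentiated > self.n_drugs:
            raise ValueError("planted drugs exceed library size")


@dataclass
class ReporterConfig:
    n_animals: int = 50
    days: tuple[int, ...] = (1, 2, 3, 4, 5)
    intercept: float = 10.0
    slope: float = 1.5  # decline in intensity units/day; must be > 0
    drug_effect_max: float = 3.0
    optimum_dose: float = 2.0
    dose_width: float = 1.0
    doses: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (intensity declines)")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synthetic_gene_names(cfg: CohortConfig) -> tuple[list[str], list[str]]:
    """Deterministic (matrisome, background) gene symbols for a config."""
    mat = [f"MATR{i:04d}" for i in range(cfg.n_matrisome)]
    bg = [f"BG{i:04d}" for i in range(cfg.n_genes - cfg.n_matrisome)]
    return mat, bg


def synthetic_gene_sets(cfg: CohortConfig) -> GeneSetCollection:
    """Gene-set collection matching the simulated universe, matrisome genes
    spread round-robin over the six category sets."""
    mat, bg = synthetic_gene_names(cfg)
    sets: dict[str, list[str]] = {c: [] for c in MATRISOME_CATEGORIES}
    for i, g in enumerate(mat):
        sets[MATRISOME_CATEGORIES[i % len(MATRISOME_CATEGORIES)]].append(g)
    return GeneSetCollection(sets=sets, universe=mat + bg)


def _age_contrast_coeff(cfg: CohortConfig) -> tuple[np.ndarray, float]:
    mids = np.array([m for _, m in cfg.age_brackets], dtype=float)
    x = (mids - mids.min()) / (mids.max() - mids.min())
    young = x[np.argsort(mids)[:2]].mean()
    old = x[np.argsort(mids)[-2:]].mean()
    return x, 1.0 / (old - young)


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[dict[str, ExpressionCohort], pd.DataFrame]:
    """Per-tissue cohorts plus a truth table of planted gene directions.

    Expression is simulated on the natural-log scale — per-gene baseline
    plus, for planted genes, a linear-in-bracket-midpoint trend scaled so
    the two-oldest minus two-youngest group contrast equals
    ``effect_size`` — then exponentiated. Planted genes and directions are
    shared across tissues so a multi-source consensus can recover them.
    """
    rng = np.random.default_rng(cfg.seed)
    mat, bg = synthetic_gene_names(cfg)
    genes = mat + bg

    k_up = round(cfg.frac_planted_up * cfg.n_matrisome)
    k_down = round(cfg.frac_planted_down * cfg.n_matrisome)
    planted = rng.permutation(cfg.n_matrisome)[: k_up + k_down]
    up_genes = [mat[i] for i in planted[:k_up]]
    down_genes = [mat[i] for i in planted[k_up:]]

    baseline = rng.uniform(2.0, 6.0, size=len(genes))
    direction = np.zeros(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in up_genes:
        direction[gene_pos[g]] = 1.0
    for g in down_genes:
        direction[gene_pos[g]] = -1.0

    x, coeff = _age_contrast_coeff(cfg)
    x_centered = x - x.mean()

    cohorts: dict[str, ExpressionCohort] = {}
    truth_rows = []
    for tissue in cfg.tissues:
        cols, bracket_of = [], {}
        log_expr = np.empty((len(genes), cfg.donors_per_bracket * len(cfg.age_brackets)))
        j = 0
        for bi, (label, _mid) in enumerate(cfg.age_brackets):
            shift = direction * cfg.effect_size * coeff * x_centered[bi]
            for d in range(cfg.donors_per_bracket):
                donor = f"{tissue}_{label}_{d:03d}"
                cols.append(donor)
                bracket_of[donor] = label
                log_expr[:, j] = (
                    baseline + shift + rng.normal(0.0, cfg.noise_sd, size=len(genes))
                )
                j += 1
        matrix = pd.DataFrame(np.exp(log_expr), index=genes, columns=cols)
        cohorts[tissue] = ExpressionCohort(
            matrix=matrix,
            tissue=tissue,
            donor_bracket=bracket_of,
            bracket_midpoints=dict(cfg.age_brackets),
        )
        for g in up_genes:
            truth_rows.append({"gene": g, "direction": UP, "tissue": tissue})
        for g in down_genes:
            truth_rows.append({"gene": g, "direction": DOWN, "tissue": tissue})
    truth = pd.DataFrame(truth_rows, columns=["gene", "direction", "tissue"])
    return cohorts, truth


def simulate_drug_library(
    cfg: DrugLibraryConfig, signature: MatreotypeSignature
) -> tuple[DrugProfileMatrix, pd.DataFrame]:
    """Drug x gene z-matrix with planted signature-concordant compounds.

    Background entries are standard normal. Planted *reversed* drugs get
    ``-delta`` added on up-with-age genes and ``+delta`` on down-with-age
    genes (the youthful direction); *potentiated* drugs the opposite.
    Lifespan flags are Bernoulli, at a higher rate for planted drugs.
    """
    if not signature.entries:
        raise ValueError("signature is empty")
    rng = np.random.default_rng(cfg.seed)
    sig_genes = list(signature.entries)
    extra = [f"NSG{i:04d}" for i in range(max(0, cfg.n_genes - len(sig_genes)))]
    genes = sig_genes + extra
    sig_sign = np.zeros(len(genes))
    for i, g in enumerate(sig_genes):
        sig_sign[i] = 1.0 if signature.entries[g] == UP else -1.0

    drugs = [f"DRUG{i:04d}" for i in range(cfg.n_drugs)]
    Z = rng.standard_normal((cfg.n_drugs, len(genes)))
    order = rng.permutation(cfg.n_drugs)
    rev = order[: cfg.n_planted_reversed]
    pot = order[cfg.n_planted_reversed : cfg.n_planted_reversed + cfg.n_planted_potentiated]
    Z[rev] -= cfg.delta * sig_sign  # push signature genes toward youthful
    Z[pot] += cfg.delta * sig_sign

    planted = np.array(["none"] * cfg.n_drugs, dtype=object)
    planted[rev] = "reversed"
    planted[pot] = "potentiated"
    rate = np.where(planted == "none", cfg.lifespan_base_rate, cfg.lifespan_planted_rate)
    flags = rng.random(cfg.n_drugs) < rate

    profiles = DrugProfileMatrix(
        z=pd.DataFrame(Z, index=drugs, columns=genes),
        lifespan_reported={d: bool(f) for d, f in zip(drugs, flags)},
    )
    truth = pd.DataFrame(
        {"compound": drugs, "planted": planted, "lifespan_reported": flags}
    )
    return profiles, truth


# Keyword planting order: prefix-overlapping pairs ("TGF" prefixes
# "TGFbeta") are ordered so the first k tokens hit exactly k keywords.
_PLANT_ORDER = (
    "collagen", "ECM", "extracellular", "matrix", "proteoglycan",
    "hyaluronic", "hyaluronan", "integrin", "TGF", "TGFbeta",
)

_FILLER = (
    "treatment of nematodes with this compound was assayed for survival "
    "benefits and the cohort showed reproducible dose dependent responses "
    "across replicate plates under standard culture conditions"
)


def simulate_abstracts(
    compounds: list[str], planted_keyword_counts: dict[str, int]
) -> pd.DataFrame:
    """Abstract table with exactly the planted number of distinct ECM keywords.

    Raises on unknown compounds or counts outside [0, 10].
    """
    unknown = set(planted_keyword_counts) - set(compounds)
    if unknown:
        raise ValueError(f"unknown compounds: {sorted(unknown)}")
    rows = []
    for comp in compounds:
        k = planted_keyword_counts.get(comp, 0)
        if not 0 <= k <= len(_PLANT_ORDER):
            raise ValueError(f"planted count for {comp!r} must be in [0, {len(_PLANT_ORDER)}]")
        words = list(_PLANT_ORDER[:k])
        text = " ".join([_FILLER] + words) if words else _FILLER
        rows.append({"compound": comp, "abstract_text": text, "planted_keywords": k})
    return pd.DataFrame(rows)


def simulate_reporter(cfg: ReporterConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy reporter trajectories plus per-dose truth.

    Mean intensity is ``max(0, a - b*day + effect(dose) * day/max(day))``
    with Gaussian noise, clipped at zero; the dose effect is a Gaussian
    bump peaking at ``optimum_dose``. The control arm (dose 0) carries no
    drug effect.
    """
    rng = np.random.default_rng(cfg.seed)
    day_max = max(cfg.days)
    rows = []

    def arm(drug: str, dose: float, effect: float) -> None:
        for a in range(cfg.n_animals):
            animal = f"{drug}_{dose:g}_{a:03d}"
            for day in cfg.days:
                mean = max(0.0, cfg.intercept - cfg.slope * day + effect * day / day_max)
                val = mean + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0)
                rows.append(
                    {"animal_id": animal, "day": day, "drug": drug,
                     "dose": dose, "dose_unit": "uM", "intensity": max(0.0, val)}
                )

    arm("control", 0.0, 0.0)
    truth_rows = []
    for dose in cfg.doses:
        effect = cfg.drug_effect_max * np.exp(
            -((dose - cfg.optimum_dose) ** 2) / (2 * cfg.dose_width**2)
        )
        arm("drug", dose, effect)
        truth_rows.append({"dose": dose, "effect": effect})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["optimum_dose"] = cfg.optimum_dose
    return pd.DataFrame(rows), truth
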