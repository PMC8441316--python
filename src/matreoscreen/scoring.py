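"""Drug-profile scoring: matrisome regulation, signature concordance, hit lists.

Each drug profile is a vector of per-gene differential-expression z-scores.
Two scores are computed: (1) a matrisome *regulation* score — the mean z
over matrisome genes standardized against size-matched random gene sets
drawn from the same profile, so a drug-wide expression shift does not
masquerade as matrisome regulation; (2) a signature *concordance* score —
the signed mean z over one directional half of a signature, oriented so
positive means the drug moves the half against (reversed) or with
(potentiated) its age-related direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from matreoscreen.signature import DOWN, UP

DEGENERATE_SD = 1e-12
EXHAUSTIVE_LIMIT = 100_000

INCREASED = "increased"
DECREASED = "decreased"
MINOR = "minor"

REVERSED = "reversed"
POTENTIATED = "potentiated"


@dataclass
class DrugProfileMatrix:
    """Compounds x genes z-score matrix plus per-compound annotations."""

    z: pd.DataFrame  # index = compound names, columns = gene symbols
    lifespan_reported: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise ValueError("non-finite z-scores in drug profile matrix")
        if self.z.index.duplicated().any():
            raise ValueError("duplicate compound names")

    @property
    def compounds(self) -> list[str]:
        return [str(c) for c in self.z.index]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.z.columns]


@dataclass
class RegulationScore:
    compound: str
    score: float
    classification: str = MINOR
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    compound: str
    half: str  # up_with_age | down_with_age
    mode: str  # reversed | potentiated
    score: float
    rank: int = 0


@dataclass
class HitCompendium:
    lists: dict[tuple[str, str], list[str]]  # (half, mode) -> ranked names
    unique: list[str]
    overlap_count: int


def _null_moments_exact(z: np.ndarray, m: int) -> tuple[float, float]:
    # mean and sd of a size-m subset mean under sampling without replacement
    n = z.size
    mu = z.mean()
    var_pop = z.var(ddof=0)
    var = var_pop / m * (n - m) / max(n - 1, 1)
    return float(mu), float(math.sqrt(var))


def matrisome_regulation_score(
    profile: pd.Series,
    matrisome_genes: list[str],
    universe: list[str] | None = None,
    n_null: int = 1000,
    seed: int | None = 0,
    method: str = "auto",
) -> RegulationScore:
    """Standardize the mean z over matrisome genes against size-matched nulls.

    The null is the distribution of mean z over random gene sets of the
    same size drawn from the universe of this profile. With
    ``method="auto"`` the exact null moments (equivalent to enumerating
    every subset) are used when the number of possible subsets is small
    (<= 1e5), else ``n_null`` seeded Monte-Carlo draws; ``"exact"`` and
    ``"sampled"`` force one route. A null sd below 1e-12 yields score 0
    with the ``degenerate`` flag set.
    """
    if method not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    if universe is None:
        universe = [str(g) for g in profile.index]
    mset = [g for g in matrisome_genes if g in set(universe)]
    if len(mset) < 2:
        raise ValueError("need at least 2 matrisome genes in the universe")
    z = profile.loc[universe].to_numpy(dtype=float)
    s = float(profile.loc[mset].mean())
    m, n = len(mset), len(z)
    exact = method == "exact" or (method == "auto" and math.comb(n, m) <= EXHAUSTIVE_LIMIT)
    if exact:
        mean_null, sd_null = _null_moments_exact(z, m)
    else:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_null)
        for i in range(n_null):
            draws[i] = z[rng.choice(n, size=m, replace=False)].mean()
        mean_null, sd_null = float(draws.mean()), float(draws.std(ddof=1))
    name = str(profile.name) if profile.name is not None else ""
    if sd_null < DEGENERATE_SD:
        return RegulationScore(compound=name, score=0.0, degenerate=True)
    return RegulationScore(compound=name, score=(s - mean_null) / sd_null)


def score_library(
    profiles: DrugProfileMatrix,
    matrisome_genes: list[str],
    n_null: int = 1000,
    seed: int | None = 0,
    threshold: float = 1.5,
    method: str = "auto",
) -> list[RegulationScore]:
    """Regulation scores for every compound, sharing one set of null draws.

    Vectorized equivalent of calling :func:`matrisome_regulation_score`
    per row; the same random size-matched gene subsets are reused across
    compounds (the null is within-profile either way). Classifications
    against ``threshold`` are filled in.
    """
    genes = profiles.genes
    mset = [g for g in matrisome_genes if g in set(genes)]
    if len(mset) < 2:
        raise ValueError("need at least 2 matrisome genes in the universe")
    if method not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    Z = profiles.z.to_numpy(dtype=float)
    m, n = len(mset), len(genes)
    s = profiles.z[mset].to_numpy(dtype=float).mean(axis=1)
    if method == "exact" or (method == "auto" and math.comb(n, m) <= EXHAUSTIVE_LIMIT):
        mu = Z.mean(axis=1)
        var = Z.var(axis=1, ddof=0) / m * (n - m) / max(n - 1, 1)
        sd = np.sqrt(var)
    else:
        rng = np.random.default_rng(seed)
        idx = np.empty((n_null, m), dtype=int)
        for i in range(n_null):
            idx[i] = rng.choice(n, size=m, replace=False)
        draws = Z[:, idx].mean(axis=2)  # compounds x n_null
        mu = draws.mean(axis=1)
        sd = draws.std(axis=1, ddof=1)
    out = []
    for i, comp in enumerate(profiles.compounds):
        if sd[i] < DEGENERATE_SD:
            out.append(RegulationScore(comp, 0.0, MINOR, degenerate=True))
            continue
        score = float((s[i] - mu[i]) / sd[i])
        out.append(RegulationScore(comp, score, _classify_one(score, threshold)))
    return out


def _classify_one(score: float, threshold: float) -> str:
    if score >= threshold:
        return INCREASED
    if score <= -threshold:
        return DECREASED
    return MINOR


def classify_matrisome_response(
    scores: list[RegulationScore], threshold: float = 1.5
) -> dict[str, list[RegulationScore]]:
    """Partition compounds into increased / decreased / minor at +-threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    parts: dict[str, list[RegulationScore]] = {INCREASED: [], DECREASED: [], MINOR: []}
    for rs in scores:
        cls = _classify_one(rs.score, threshold)
        rs.classification = cls
        parts[cls].append(rs)
    return parts


def concordance_scores(
    profiles: DrugProfileMatrix, half_genes: list[str], half: str
) -> list[ConcordanceResult]:
    """Score every compound on one signature half, in both modes.

    ``m`` is the compound's mean z over the half's measured genes. For the
    up-with-age half a *reversed* drug pushes those genes down, so its
    reversed score is ``-m`` (potentiated ``+m``); signs swap for the
    down-with-age half. Results carry 1-based ranks by descending score
    (ties by compound name) within each mode.
    """
    if half not in (UP, DOWN):
        raise ValueError(f"half must be {UP!r} or {DOWN!r}")
    measured = [g for g in half_genes if g in set(profiles.genes)]
    if not measured:
        missing = sorted(set(half_genes))[:10]
        raise ValueError(f"no signature genes measured; missing e.g. {missing}")
    m = profiles.z[measured].to_numpy(dtype=float).mean(axis=1)
    sign_reversed = -1.0 if half == UP else 1.0
    results = []
    for mode, sign in ((REVERSED, sign_reversed), (POTENTIATED, -sign_reversed)):
        scored = [
            ConcordanceResult(comp, half, mode, float(sign * mi))
            for comp, mi in zip(profiles.compounds, m)
        ]
        scored.sort(key=lambda r: (-r.score, r.compound))
        for i, r in enumerate(scored, start=1):
            r.rank = i
        results.extend(scored)
    return results


def top_k(results: list[ConcordanceResult], k: int = 50) -> list[ConcordanceResult]:
    """The k best-scoring results; ties broken by ascending compound name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(results, key=lambda r: (-r.score, r.compound))
    return ordered[:k]


def compile_hit_sets(lists: dict[tuple[str, str], list[str]]) -> HitCompendium:
    """Merge the four (half x mode) top-k name lists.

    ``unique`` is the union in first-seen order; ``overlap_count`` counts
    compounds present in both a reversed-mode (youthful-concordant) and a
    potentiated-mode (aged-concordant) list.
    """
    unique: dict[str, None] = {}
    for names in lists.values():
        for name in names:
            unique.setdefault(name)
    rev = set().union(*(set(v) for (h, m), v in lists.items() if m == REVERSED), set())
    pot = set().union(*(set(v) for (h, m), v in lists.items() if m == POTENTIATED), set())
    return HitCompendium(
        lists=dict(lists), unique=list(unique), overlap_count=len(rev & pot)
    )


def enrichment_stats(
    n_hit_flagged: int, n_hits: int, n_bg_flagged: int, n_bg: int
) -> dict[str, float]:
    """Flagged-fraction comparison of a hit set against the full library.

    Returns display percentages (rounded to integer), full-precision
    fractions, the fold ratio of percentages, and an upper-tail
    hypergeometric p for drawing >= ``n_hit_flagged`` flagged compounds in
    ``n_hits`` draws from a library of ``n_bg`` with ``n_bg_flagged``
    flagged.
    """
    if n_hits <= 0 or n_bg <= 0:
        raise ValueError("totals must be positive")
    if not (n_hit_flagged <= n_hits <= n_bg and n_hit_flagged <= n_bg_flagged):
        raise ValueError("inconsistent counts")
    frac_hit = n_hit_flagged / n_hits
    frac_bg = n_bg_flagged / n_bg
    p = float(stats.hypergeom.sf(n_hit_flagged - 1, n_bg, n_bg_flagged, n_hits))
    return {
        "pct_hit": round(100 * frac_hit),
        "pct_bg": round(100 * frac_bg),
        "frac_hit": frac_hit,
        "frac_bg": frac_bg,
        "fold": (frac_hit / frac_bg) if frac_bg > 0 else float("inf"),
        "p_value": p,
    }


def cluster_for_display(matrix: pd.DataFrame):
    """Average-linkage clustering on 1 - Pearson correlation, rows and columns.

    Returns a dict with leaf orderings and linkage matrices for heatmap
    export. Zero-variance rows/columns have undefined correlation; their
    distances are set to the metric maximum (2.0) and they are flagged.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")

    def _axis(df: pd.DataFrame) -> tuple[np.ndarray, list[int], list[str]]:
        X = df.to_numpy(dtype=float)
        sd = X.std(axis=1)
        flat = [str(df.index[i]) for i in np.flatnonzero(sd == 0)]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X)
        dist = 1.0 - corr
        dist[~np.isfinite(dist)] = 2.0
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        np.clip(dist, 0.0, None, out=dist)
        link = hierarchy.average(squareform(dist, checks=False))
        leaves = hierarchy.leaves_list(link)
        return link, [int(i) for i in leaves], flat

    row_link, row_order, row_flat = _axis(matrix)
    col_link, col_order, col_flat = _axis(matrix.T)
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_link,
        "col_linkage": col_link,
        "flat_rows": row_flat,
        "flat_cols": col_flat,
    }
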