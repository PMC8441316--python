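"""Arithmetic consistency checks on the published screen counts.

Each check rebuilds a fixture with the printed input counts and runs the
actual pipeline operation on it, so the reported numbers are recomputed
rather than transcribed: 16 ECM-linked of 567 examined geroprotectors,
41 of 47 library longevity compounds beyond the +-1.5 band, the
19 + 26 + 22 category partition, four top-50 lists with a 15-compound
youthful/aged overlap, and the 24/185 vs 67/1309 lifespan-flag rates.
"""

from __future__ import annotations

import numpy as np

from matreoscreen.litmine import CompoundRecord, flag_ecm
from matreoscreen.scoring import (
    POTENTIATED,
    REVERSED,
    RegulationScore,
    classify_matrisome_response,
    compile_hit_sets,
    enrichment_stats,
)
from matreoscreen.signature import DOWN, UP
from matreoscreen.simulate import simulate_abstracts


def pct_ecm_linked(n_flagged: int = 16, n_total: int = 567, seed: int = 0) -> dict:
    """Flag ECM-linked compounds in a planted abstract table; report percent."""
    rng = np.random.default_rng(seed)
    compounds = [f"cpd{i:04d}" for i in range(n_total)]
    chosen = rng.choice(n_total, size=n_flagged, replace=False)
    counts = {compounds[i]: int(rng.integers(1, 6)) for i in chosen}
    abstracts = simulate_abstracts(compounds, counts)
    records = [
        CompoundRecord(compound=row.compound, mean_lifespan_change_pct=10.0,
                       abstract_text=row.abstract_text)
        for row in abstracts.itertuples()
    ]
    flagged = sum(r.ecm_linked for r in flag_ecm(records))
    return {"value": round(100 * flagged / len(records)), "n": len(records)}


def _scores_with_counts(n_minor: int, n_increased: int, n_decreased: int,
                        threshold: float, seed: int) -> list[RegulationScore]:
    rng = np.random.default_rng(seed)
    scores = (
        list(rng.uniform(-threshold * 0.9, threshold * 0.9, size=n_minor))
        + list(rng.uniform(threshold, threshold * 3, size=n_increased))
        + list(rng.uniform(-threshold * 3, -threshold, size=n_decreased))
    )
    return [RegulationScore(f"c{i:04d}", float(s)) for i, s in enumerate(scores)]


def pct_strong_regulators(n_strong: int = 41, n_total: int = 47, seed: int = 0) -> dict:
    """Classify a 47-compound fixture with 41 beyond the band; report percent."""
    n_inc = n_strong // 2
    scores = _scores_with_counts(n_total - n_strong, n_inc, n_strong - n_inc, 1.5, seed)
    parts = classify_matrisome_response(scores, threshold=1.5)
    strong = len(parts["increased"]) + len(parts["decreased"])
    return {"value": round(100 * strong / n_total), "n": n_total}


def total_lifespan_compounds(n_minor: int = 19, n_increased: int = 26,
                             n_decreased: int = 22, seed: int = 0) -> dict:
    """Partition an engineered 19/26/22 fixture; report the conserved total."""
    scores = _scores_with_counts(n_minor, n_increased, n_decreased, 1.5, seed)
    parts = classify_matrisome_response(scores, threshold=1.5)
    total = sum(len(v) for v in parts.values())
    return {"value": total, "n": total}


def unique_hits(k: int = 50, n_overlap: int = 15, seed: int = 0) -> dict:
    """Compile four top-k lists sharing ``n_overlap`` youthful/aged compounds."""
    rng = np.random.default_rng(seed)
    shared = [f"shared{i:02d}" for i in range(n_overlap)]
    pool = iter(f"only{i:04d}" for i in range(4 * k))
    lists = {}
    for i, (half, mode) in enumerate(
        [(UP, REVERSED), (DOWN, REVERSED), (UP, POTENTIATED), (DOWN, POTENTIATED)]
    ):
        # place the shared names in one reversed and one potentiated list
        names = (shared if i in (0, 2) else []) + [
            next(pool) for _ in range(k - (n_overlap if i in (0, 2) else 0))
        ]
        rng.shuffle(names)
        lists[(half, mode)] = names
    comp = compile_hit_sets(lists)
    assert comp.overlap_count == n_overlap
    return {"value": len(comp.unique), "n": 4 * k}


def enrichment_percentages(
    n_hit_flagged: int = 24, n_hits: int = 185,
    n_bg_flagged: int = 67, n_bg: int = 1309,
) -> dict:
    return enrichment_stats(n_hit_flagged, n_hits, n_bg_flagged, n_bg)


def all_anchors(seed: int = 0) -> dict:
    enrich = enrichment_percentages()
    return {
        "pct_ecm_linked_of_567": pct_ecm_linked(seed=seed)["value"],
        "pct_strong_regulators_of_47": pct_strong_regulators(seed=seed)["value"],
        "total_lifespan_compounds": total_lifespan_compounds(seed=seed)["value"],
        "unique_hits_200_minus_15": unique_hits(seed=seed)["value"],
        "pct_hits_flagged": enrich["pct_hit"],
        "pct_background_flagged": enrich["pct_bg"],
    }
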