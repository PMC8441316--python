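import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from matreoscreen.scoring import (
    DECREASED,
    INCREASED,
    MINOR,
    POTENTIATED,
    REVERSED,
    DrugProfileMatrix,
    RegulationScore,
    classify_matrisome_response,
    cluster_for_display,
    compile_hit_sets,
    concordance_scores,
    enrichment_stats,
    matrisome_regulation_score,
    score_library,
    top_k,
)
from matreoscreen.signature import DOWN, UP


def subset_mean_oracle(z: np.ndarray, m: int) -> tuple[float, float]:
    """Enumerate every size-m subset of the profile and take exact moments."""
    means = [np.mean([z[i] for i in idx]) for idx in itertools.combinations(range(len(z)), m)]
    return float(np.mean(means)), float(np.std(means, ddof=0))


# ------------------------------------------------------- regulation score


def test_all_zero_profile_degenerate():
    profile = pd.Series(np.zeros(10), index=[f"g{i}" for i in range(10)], name="d")
    rs = matrisome_regulation_score(profile, ["g0", "g1"])
    assert rs.score == 0.0 and rs.degenerate


def test_exact_score_matches_enumeration_oracle():
    z = np.array([3.0, 3.0] + [0.0] * 8)
    genes = [f"g{i}" for i in range(10)]
    profile = pd.Series(z, index=genes, name="d")
    rs = matrisome_regulation_score(profile, ["g0", "g1"])  # auto -> exact (45 subsets)
    mu, sd = subset_mean_oracle(z, 2)
    expected = (3.0 - mu) / sd
    assert rs.score == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("m", [2, 3, 4])
def test_exact_moments_match_enumeration_random(m):
    rng = np.random.default_rng(m)
    z = rng.standard_normal(9)
    genes = [f"g{i}" for i in range(9)]
    profile = pd.Series(z, index=genes, name="d")
    rs = matrisome_regulation_score(profile, genes[:m], method="exact")
    mu, sd = subset_mean_oracle(z, m)
    assert rs.score == pytest.approx((z[:m].mean() - mu) / sd, rel=1e-10)


def test_sampled_converges_to_exact_small_universe():
    rng = np.random.default_rng(5)
    z = rng.standard_normal(12)
    genes = [f"g{i}" for i in range(12)]
    profile = pd.Series(z, index=genes, name="d")
    exact = matrisome_regulation_score(profile, genes[:3], method="exact").score
    n_null = 1000
    sampled = matrisome_regulation_score(
        profile, genes[:3], n_null=n_null, seed=11, method="sampled"
    ).score
    assert abs(sampled - exact) <= 3 / math.sqrt(n_null)


def test_score_library_matches_single_profile_exact():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(12)]
    z = pd.DataFrame(rng.standard_normal((4, 12)), index=list("abcd"), columns=genes)
    profiles = DrugProfileMatrix(z=z)
    lib = score_library(profiles, genes[:3], method="exact")
    for rs in lib:
        single = matrisome_regulation_score(z.loc[rs.compound], genes[:3], method="exact")
        assert rs.score == pytest.approx(single.score, rel=1e-12)


def test_empty_matrisome_errors():
    profile = pd.Series(np.ones(5), index=[f"g{i}" for i in range(5)])
    with pytest.raises(ValueError):
        matrisome_regulation_score(profile, [])


def test_threshold_classifies_strong_regulator():
    rs = RegulationScore("d", 1.6)
    parts = classify_matrisome_response([rs], threshold=1.5)
    assert rs in parts[INCREASED]


# ---------------------------------------------------------- classification


def test_classify_boundaries():
    scores = [RegulationScore("a", 0.0), RegulationScore("b", -2.0),
              RegulationScore("c", 1.5), RegulationScore("d", -1.5)]
    parts = classify_matrisome_response(scores)
    assert [r.compound for r in parts[MINOR]] == ["a"]
    assert {r.compound for r in parts[DECREASED]} == {"b", "d"}
    assert [r.compound for r in parts[INCREASED]] == ["c"]


def test_classify_conserves_counts():
    rng = np.random.default_rng(9)
    scores = [RegulationScore(f"c{i}", s) for i, s in enumerate(rng.normal(0, 2, 100))]
    parts = classify_matrisome_response(scores)
    assert sum(len(v) for v in parts.values()) == 100


def test_classify_requires_positive_threshold():
    with pytest.raises(ValueError):
        classify_matrisome_response([], threshold=0)


# ------------------------------------------------------------- concordance


def _profiles(z_rows: dict[str, list[float]], genes: list[str]) -> DrugProfileMatrix:
    return DrugProfileMatrix(z=pd.DataFrame.from_dict(z_rows, orient="index", columns=genes))


def test_reversed_extremal_on_up_half():
    genes = ["u1", "u2", "x"]
    profiles = _profiles(
        {"down_drug": [-1, -1, 0], "up_drug": [1, 1, 0], "flat": [0, 0, 0]}, genes
    )
    results = concordance_scores(profiles, ["u1", "u2"], UP)
    rev = {r.compound: r for r in results if r.mode == REVERSED}
    assert rev["down_drug"].score == pytest.approx(1.0)
    assert rev["down_drug"].rank == 1
    assert rev["flat"].score == 0.0
    pot = {r.compound: r for r in results if r.mode == POTENTIATED}
    assert pot["up_drug"].score == pytest.approx(1.0)


def test_down_half_signs_flip():
    genes = ["d1", "d2"]
    profiles = _profiles({"drug": [2.0, 2.0]}, genes)
    results = {(r.mode): r.score for r in concordance_scores(profiles, genes, DOWN)}
    assert results[REVERSED] == pytest.approx(2.0)
    assert results[POTENTIATED] == pytest.approx(-2.0)


def test_concordance_missing_genes_error(small_profiles):
    with pytest.raises(ValueError, match="missing"):
        concordance_scores(small_profiles, ["NOPE1", "NOPE2"], UP)


def test_concordance_ranks_are_permutation(small_profiles):
    results = concordance_scores(small_profiles, ["A", "B"], UP)
    for mode in (REVERSED, POTENTIATED):
        ranks = sorted(r.rank for r in results if r.mode == mode)
        assert ranks == list(range(1, len(small_profiles.compounds) + 1))


def test_inversion_consistency_exact(small_profiles, toy_signature):
    from matreoscreen.signature import invert_signature, split_signature

    up_aged, down_aged = split_signature(toy_signature)
    inv = invert_signature(toy_signature)
    up_youth, down_youth = split_signature(inv)
    assert set(up_youth) == set(down_aged)

    rev_aged = {
        r.compound: r.score
        for r in concordance_scores(small_profiles, up_aged, UP)
        if r.mode == REVERSED
    }
    # the same genes sit in the youthful down half; potentiating that half
    # is the same contrast
    pot_youth = {
        r.compound: r.score
        for r in concordance_scores(small_profiles, down_youth, DOWN)
        if r.mode == POTENTIATED
    }
    assert rev_aged == pot_youth


# ------------------------------------------------------------------- top-k


def _results(scores: dict[str, float]):
    return [
        ConcordanceResultLike(name, s) for name, s in scores.items()
    ]


class ConcordanceResultLike:
    def __init__(self, compound, score):
        self.compound = compound
        self.score = score
        self.half = UP
        self.mode = REVERSED
        self.rank = 0


def test_top_k_fewer_than_k():
    out = top_k(_results({"a": 1.0, "b": 0.5, "c": 0.1}), k=50)
    assert [r.compound for r in out] == ["a", "b", "c"]


def test_top_k_ties_alphabetical():
    out = top_k(_results({"b": 1.0, "a": 1.0, "c": 2.0}), k=3)
    assert [r.compound for r in out] == ["c", "a", "b"]


def test_top_k_prefix_stable():
    rng = np.random.default_rng(4)
    res = _results({f"c{i}": float(s) for i, s in enumerate(rng.normal(size=60))})
    ten = top_k(res, k=10)
    fifty = top_k(res, k=50)
    assert [r.compound for r in ten] == [r.compound for r in fifty[:10]]


# --------------------------------------------------------------- hit sets


def _four_lists(rev_up, rev_down, pot_up, pot_down):
    return {
        (UP, REVERSED): rev_up,
        (DOWN, REVERSED): rev_down,
        (UP, POTENTIATED): pot_up,
        (DOWN, POTENTIATED): pot_down,
    }


def test_disjoint_lists_unique_is_total():
    names = [f"c{i}" for i in range(200)]
    comp = compile_hit_sets(
        _four_lists(names[:50], names[50:100], names[100:150], names[150:200])
    )
    assert len(comp.unique) == 200
    assert comp.overlap_count == 0


def test_identical_lists_unique_is_k():
    names = [f"c{i}" for i in range(50)]
    comp = compile_hit_sets(_four_lists(names, names, names, names))
    assert len(comp.unique) == 50
    assert comp.overlap_count == 50


def test_fifteen_overlap_gives_185():
    shared = [f"s{i}" for i in range(15)]
    rest = iter(f"r{i}" for i in range(200))
    rev_up = shared + [next(rest) for _ in range(35)]
    rev_down = [next(rest) for _ in range(50)]
    pot_up = shared + [next(rest) for _ in range(35)]
    pot_down = [next(rest) for _ in range(50)]
    comp = compile_hit_sets(_four_lists(rev_up, rev_down, pot_up, pot_down))
    assert len(comp.unique) == 185
    assert comp.overlap_count == 15


# -------------------------------------------------------------- enrichment


def hypergeom_oracle(n_hit_flagged, n_hits, n_bg_flagged, n_bg):
    """Exhaustive tail probability over all C(n_bg, n_hits) draws."""
    flagged = [1] * n_bg_flagged + [0] * (n_bg - n_bg_flagged)
    total = hits = 0
    for combo in itertools.combinations(range(n_bg), n_hits):
        total += 1
        if sum(flagged[i] for i in combo) >= n_hit_flagged:
            hits += 1
    return hits / total


def test_enrichment_published_percentages():
    st = enrichment_stats(24, 185, 67, 1309)
    assert st["pct_hit"] == 13
    assert st["pct_bg"] == 5


def test_enrichment_zero_flagged():
    st = enrichment_stats(0, 10, 5, 100)
    assert st["pct_hit"] == 0
    assert st["fold"] == 0


def test_enrichment_p_matches_enumeration_toy():
    st = enrichment_stats(2, 3, 4, 10)
    assert st["p_value"] == pytest.approx(hypergeom_oracle(2, 3, 4, 10), rel=1e-12)


@pytest.mark.parametrize(
    "counts",
    [(1, 4, 3, 9), (2, 5, 6, 12), (0, 3, 2, 8), (3, 3, 5, 11)],
)
def test_enrichment_p_matches_enumeration_small_tables(counts):
    st = enrichment_stats(*counts)
    assert st["p_value"] == pytest.approx(hypergeom_oracle(*counts), rel=1e-10)


def test_enrichment_zero_denominator_errors():
    with pytest.raises(ValueError):
        enrichment_stats(0, 0, 5, 100)


def test_enrichment_inconsistent_counts_error():
    with pytest.raises(ValueError):
        enrichment_stats(6, 5, 10, 100)


# -------------------------------------------------------------- clustering


def test_identical_rows_merge_first():
    rng = np.random.default_rng(6)
    base = rng.standard_normal(8)
    X = pd.DataFrame(
        [base, base, rng.standard_normal(8), rng.standard_normal(8)],
        index=["a", "a2", "b", "c"],
    )
    out = cluster_for_display(X)
    link = out["row_linkage"]
    assert set(link[0][:2].astype(int)) == {0, 1}
    assert link[0][2] == pytest.approx(0.0, abs=1e-12)


def test_permutation_invariant_topology():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.standard_normal((6, 10)), index=[f"r{i}" for i in range(6)])
    perm = [3, 1, 5, 0, 4, 2]
    out1 = cluster_for_display(X)
    out2 = cluster_for_display(X.iloc[perm])
    d1 = hierarchy.cophenet(out1["row_linkage"])
    d2 = hierarchy.cophenet(out2["row_linkage"])
    # map permuted condensed distances back to original labelling
    from scipy.spatial.distance import squareform

    m2 = squareform(d2)
    inv = np.argsort(perm)
    assert np.allclose(squareform(d1), m2[np.ix_(inv, inv)])


def test_planted_blocks_recovered_at_two_clusters():
    rng = np.random.default_rng(10)
    a = np.tile(np.linspace(-1, 1, 12), (5, 1)) + rng.normal(0, 0.05, (5, 12))
    b = np.tile(np.linspace(1, -1, 12), (5, 1)) + rng.normal(0, 0.05, (5, 12))
    X = pd.DataFrame(np.vstack([a, b]), index=[f"r{i}" for i in range(10)])
    out = cluster_for_display(X)
    labels = hierarchy.fcluster(out["row_linkage"], 2, criterion="maxclust")
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_zero_variance_row_flagged():
    X = pd.DataFrame(
        [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]], index=["flat", "a", "b"]
    )
    out = cluster_for_display(X)
    assert out["flat_rows"] == ["flat"]


def test_cluster_needs_two_rows():
    with pytest.raises(ValueError):
        cluster_for_display(pd.DataFrame([[1.0, 2.0]]))
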