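"""Aged and youthful matrisome expression signatures from age-stratified cohorts.

The analysis contrasts a young donor group against an old donor group per
tissue, reports both the absolute (old minus young) and relative
(fraction-of-young) expression change, controls FDR per tissue with
Benjamini-Hochberg, and combines per-source directional calls into a
multi-source consensus signature that can be inverted into its "youthful"
mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

UP = "up_with_age"
DOWN = "down_with_age"
NONE = "none"

_FLIP = {UP: DOWN, DOWN: UP}


@dataclass
class ExpressionCohort:
    """Genes x donors non-negative expression matrix with donor age brackets.

    ``matrix`` is a DataFrame (index = gene symbols, columns = donor ids).
    ``donor_bracket`` maps each donor column to its ordinal bracket label;
    ``bracket_midpoints`` gives the numeric midpoint of each label.
    """

    matrix: pd.DataFrame
    tissue: str
    donor_bracket: dict[str, str]
    bracket_midpoints: dict[str, float]

    def __post_init__(self) -> None:
        if self.matrix.index.hasnans or any(not g for g in self.matrix.index):
            raise ValueError("missing gene symbols in expression matrix")
        missing = [d for d in self.matrix.columns if d not in self.donor_bracket]
        if missing:
            raise ValueError(f"donors without an age bracket: {missing[:5]}")
        if len(set(self.donor_bracket[d] for d in self.matrix.columns)) < 2:
            raise ValueError("cohort needs at least 2 age brackets")

    def donors_in(self, brackets: set[str]) -> list[str]:
        return [d for d in self.matrix.columns if self.donor_bracket[d] in brackets]


@dataclass
class AgeAssociation:
    """Per-gene age-change statistics within one tissue."""

    gene: str
    tissue: str
    absolute_change: float
    relative_change: float  # NaN when the young mean is zero
    p_value: float
    q_value: float = float("nan")
    direction: str = NONE


@dataclass
class MatreotypeSignature:
    """Consensus gene -> direction signature with per-gene source support."""

    entries: dict[str, str] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    conflicts: frozenset[str] = frozenset()
    kind: str = "aged"

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in (UP, DOWN)}
        if bad:
            raise ValueError(f"invalid directions: {bad}")
        if self.conflicts & set(self.entries):
            raise ValueError("conflict genes may not appear among entries")

    def __len__(self) -> int:
        return len(self.entries)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, reject mask).

    q for the i-th smallest p is ``min_{j>=i} p_(j) * n / j`` clipped at 1;
    rejection is ``q <= alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    # absorb float rounding in p*n/rank at the q == alpha boundary
    return q, q <= alpha * (1 + 1e-9)


def compute_age_change(
    cohort: ExpressionCohort,
    young_brackets: set[str] | None = None,
    old_brackets: set[str] | None = None,
    alpha: float = 0.05,
) -> list[AgeAssociation]:
    """Contrast old vs young donor groups gene-wise.

    Defaults to the two youngest vs the two oldest brackets (by midpoint).
    The location test is Welch's t on log1p-transformed values; absolute
    and relative changes are reported on the original expression scale.
    q-values are filled by BH within this (single-tissue) call.
    """
    if young_brackets is None or old_brackets is None:
        ordered = sorted(cohort.bracket_midpoints, key=cohort.bracket_midpoints.get)
        if young_brackets is None:
            young_brackets = set(ordered[:2])
        if old_brackets is None:
            old_brackets = set(ordered[-2:])
    if not young_brackets or not old_brackets:
        raise ValueError("bracket sets must be non-empty")
    if young_brackets & old_brackets:
        raise ValueError(f"bracket sets overlap: {young_brackets & old_brackets}")

    young = cohort.matrix[cohort.donors_in(young_brackets)].to_numpy(dtype=float)
    old = cohort.matrix[cohort.donors_in(old_brackets)].to_numpy(dtype=float)
    if young.shape[1] < 2 or old.shape[1] < 2:
        raise ValueError("need >=2 donors per group")

    mean_young = young.mean(axis=1)
    mean_old = old.mean(axis=1)
    absolute = mean_old - mean_young
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(mean_young > 0, absolute / mean_young, np.nan)

    t, p = stats.ttest_ind(np.log1p(old), np.log1p(young), axis=1, equal_var=False)
    # zero-variance genes with equal means give nan p; they carry no signal
    p = np.where(np.isnan(p), 1.0, p)
    q, reject = bh_adjust(p, alpha=alpha)

    out = []
    for i, gene in enumerate(cohort.matrix.index):
        if reject[i] and absolute[i] != 0:
            direction = UP if absolute[i] > 0 else DOWN
        else:
            direction = NONE
        out.append(
            AgeAssociation(
                gene=str(gene),
                tissue=cohort.tissue,
                absolute_change=float(absolute[i]),
                relative_change=float(relative[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction=direction,
            )
        )
    return out


def filter_matrisome(assocs: list[AgeAssociation], coll) -> list[AgeAssociation]:
    """Keep only matrisome members, preserving order."""
    members = set(coll.matrisome)
    return [a for a in assocs if a.gene in members]


def build_compendium(
    per_source_signatures: list[tuple[str, dict[str, str]]],
    min_sources: int = 3,
) -> MatreotypeSignature:
    """Combine per-source gene -> direction calls into a consensus signature.

    A gene enters the compendium when >= ``min_sources`` sources report it
    (direction-less reports, encoded as ``"none"``, count toward support
    but not toward the direction vote). Direction is decided by strict
    majority among directional sources; exact ties are excluded and listed
    in ``conflicts``.
    """
    if not per_source_signatures:
        raise ValueError("need at least one source")
    support: dict[str, int] = {}
    votes: dict[str, dict[str, int]] = {}
    for _source, calls in per_source_signatures:
        for gene, direction in calls.items():
            support[gene] = support.get(gene, 0) + 1
            if direction in (UP, DOWN):
                votes.setdefault(gene, {UP: 0, DOWN: 0})[direction] += 1

    entries: dict[str, str] = {}
    kept_support: dict[str, int] = {}
    conflicts: set[str] = set()
    for gene, n in support.items():
        if n < min_sources:
            continue
        v = votes.get(gene, {UP: 0, DOWN: 0})
        if v[UP] > v[DOWN]:
            entries[gene] = UP
        elif v[DOWN] > v[UP]:
            entries[gene] = DOWN
        else:  # tie, incl. no directional source at all
            conflicts.add(gene)
            continue
        kept_support[gene] = n
    return MatreotypeSignature(
        entries=entries, support=kept_support, conflicts=frozenset(conflicts), kind="aged"
    )


def invert_signature(sig: MatreotypeSignature) -> MatreotypeSignature:
    """Flip every direction and toggle kind aged <-> youthful."""
    return replace(
        sig,
        entries={g: _FLIP[d] for g, d in sig.entries.items()},
        kind="youthful" if sig.kind == "aged" else "aged",
    )


def split_signature(sig: MatreotypeSignature) -> tuple[list[str], list[str]]:
    """Return (up_with_age genes, down_with_age genes)."""
    up = [g for g, d in sig.entries.items() if d == UP]
    down = [g for g, d in sig.entries.items() if d == DOWN]
    return up, down


def signature_to_frame(sig: MatreotypeSignature) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": list(sig.entries),
            "direction": [sig.entries[g] for g in sig.entries],
            "support": [sig.support.get(g, 0) for g in sig.entries],
            "kind": sig.kind,
        }
    )


def signature_from_frame(df: pd.DataFrame, kind: str | None = None) -> MatreotypeSignature:
    entries = dict(zip(df["gene"], df["direction"]))
    support = dict(zip(df["gene"], df["support"])) if "support" in df else {g: 1 for g in entries}
    if kind is None:
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else "aged"
    return MatreotypeSignature(entries=entries, support=support, kind=kind)
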