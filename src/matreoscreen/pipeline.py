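"""End-to-end orchestration: simulate -> signature -> score -> rank -> report.

All randomness flows from a single root seed split per stage with
``numpy.random.SeedSequence``; every artifact is written with a checksum
and the effective config, so re-running with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from matreoscreen import gct
from matreoscreen.anchors import all_anchors
from matreoscreen.matrisome import write_gmt
from matreoscreen.litmine import CompoundRecord, filter_lifespan, flag_ecm
from matreoscreen.reporter import (
    category_distribution,
    default_thresholds,
    dose_response,
    fit_decline,
)
from matreoscreen.scoring import (
    POTENTIATED,
    REVERSED,
    classify_matrisome_response,
    compile_hit_sets,
    concordance_scores,
    enrichment_stats,
    score_library,
    top_k,
)
from matreoscreen.signature import (
    DOWN,
    UP,
    build_compendium,
    compute_age_change,
    filter_matrisome,
    invert_signature,
    signature_to_frame,
    split_signature,
)
from matreoscreen.simulate import (
    CohortConfig,
    DrugLibraryConfig,
    ReporterConfig,
    simulate_abstracts,
    simulate_cohort,
    simulate_drug_library,
    simulate_reporter,
    synthetic_gene_sets,
)

log = logging.getLogger("matreoscreen")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    drugs: DrugLibraryConfig = field(default_factory=DrugLibraryConfig)
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    z_threshold: float = 1.5
    alpha: float = 0.05
    min_sources: int = 3
    top_k: int = 50
    min_extension_pct: float = 5.0
    n_null: int = 1000
    seed: int = 0
    out_dir: str = "matreoscreen_run"

    def __post_init__(self) -> None:
        for name in ("z_threshold", "alpha", "min_sources", "top_k", "min_extension_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic inputs; write artifacts and a report.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_seed, drug_seed, reporter_seed, _ = _stage_seeds(config.seed)
    cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
    drug_cfg = dataclasses.replace(config.drugs, seed=drug_seed)
    reporter_cfg = dataclasses.replace(config.reporter, seed=reporter_seed)
    written: dict[str, str] = {}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, sep="\t" if name.endswith(".tsv") else ",")
        written[name] = _checksum(path)

    stage = "simulate-cohort"
    try:
        coll = synthetic_gene_sets(cohort_cfg)
        write_gmt(coll, out / "gene_sets.gmt")
        written["gene_sets.gmt"] = _checksum(out / "gene_sets.gmt")
        cohorts, cohort_truth = simulate_cohort(cohort_cfg)
        save_csv(cohort_truth, "cohort_truth.tsv")
        for tissue, cohort in cohorts.items():
            gct.write_gct(cohort.matrix, out / f"cohort_{tissue}.gct")
            written[f"cohort_{tissue}.gct"] = _checksum(out / f"cohort_{tissue}.gct")
            meta = pd.DataFrame(
                {"donor": list(cohort.matrix.columns),
                 "bracket": [cohort.donor_bracket[d] for d in cohort.matrix.columns]}
            )
            save_csv(meta, f"cohort_{tissue}_donors.tsv")

        stage = "signature"
        sources = []
        assoc_frames = []
        for tissue, cohort in cohorts.items():
            assocs = filter_matrisome(
                compute_age_change(cohort, alpha=config.alpha), coll
            )
            assoc_frames.append(pd.DataFrame([dataclasses.asdict(a) for a in assocs]))
            calls = {a.gene: a.direction for a in assocs if a.direction != "none"}
            sources.append((tissue, calls))
        save_csv(pd.concat(assoc_frames, ignore_index=True), "age_associations.csv")
        aged = build_compendium(sources, min_sources=config.min_sources)
        youthful = invert_signature(aged)
        save_csv(signature_to_frame(aged), "signature_aged.tsv")
        save_csv(signature_to_frame(youthful), "signature_youthful.tsv")
        up_genes, down_genes = split_signature(aged)
        log.info("aged signature: %d up, %d down, %d conflicts",
                 len(up_genes), len(down_genes), len(aged.conflicts))

        stage = "simulate-drugs"
        profiles, drug_truth = simulate_drug_library(drug_cfg, aged)
        gct.write_gct(profiles.z, out / "drug_library.gct")
        written["drug_library.gct"] = _checksum(out / "drug_library.gct")
        save_csv(drug_truth, "drug_truth.tsv")

        stage = "regulation-score"
        reg = score_library(
            profiles, coll.matrisome, n_null=config.n_null,
            seed=drug_seed, threshold=config.z_threshold,
        )
        parts = classify_matrisome_response(reg, threshold=config.z_threshold)
        save_csv(
            pd.DataFrame(
                [{"compound": r.compound, "score": r.score,
                  "classification": r.classification} for r in reg]
            ),
            "regulation_scores.csv",
        )

        stage = "concordance"
        lists: dict[tuple[str, str], list[str]] = {}
        hit_frames = []
        for half, genes in ((UP, up_genes), (DOWN, down_genes)):
            if not genes:
                continue
            results = concordance_scores(profiles, genes, half)
            for mode in (REVERSED, POTENTIATED):
                ranked = top_k([r for r in results if r.mode == mode], k=config.top_k)
                lists[(half, mode)] = [r.compound for r in ranked]
                hit_frames.append(
                    pd.DataFrame(
                        [{"compound": r.compound, "half": half, "mode": mode,
                          "score": r.score, "rank": r.rank} for r in ranked]
                    )
                )
        save_csv(pd.concat(hit_frames, ignore_index=True), "hits.csv")
        compendium = compile_hit_sets(lists)

        stage = "enrichment"
        n_hits = len(compendium.unique)
        n_hit_flagged = sum(
            bool(profiles.lifespan_reported.get(c, False)) for c in compendium.unique
        )
        n_bg = len(profiles.compounds)
        n_bg_flagged = sum(bool(v) for v in profiles.lifespan_reported.values())
        enrich = enrichment_stats(n_hit_flagged, n_hits, n_bg_flagged, n_bg)

        stage = "litmine"
        abstracts = simulate_abstracts(
            profiles.compounds,
            {c: 2 for c in compendium.unique[: max(1, n_hits // 10)]},
        )
        records = [
            CompoundRecord(
                compound=row.compound,
                mean_lifespan_change_pct=10.0
                if profiles.lifespan_reported.get(row.compound) else 0.0,
                abstract_text=row.abstract_text,
            )
            for row in abstracts.itertuples()
        ]
        kept = flag_ecm(filter_lifespan(records, config.min_extension_pct))
        save_csv(
            pd.DataFrame(
                [{"compound": r.compound,
                  "mean_lifespan_change_pct": r.mean_lifespan_change_pct,
                  "keyword_hits": r.keyword_hits, "ecm_linked": r.ecm_linked}
                 for r in kept]
            ),
            "litmine.tsv",
        )

        stage = "reporter"
        traj, reporter_truth = simulate_reporter(reporter_cfg)
        save_csv(traj, "reporter_trajectories.csv")
        ctrl = traj[traj["drug"] == "control"]
        day_means = ctrl.groupby("day")["intensity"].mean()
        slope, intercept, r2 = fit_decline(day_means.to_numpy(), day_means.index.to_numpy())
        thresholds = default_thresholds(
            ctrl.loc[ctrl["day"] == min(reporter_cfg.days), "intensity"]
        )
        save_csv(category_distribution(traj, thresholds), "reporter_categories.csv")
        dr = dose_response(traj, "drug", alpha=config.alpha)
        save_csv(dr.table, "dose_response.csv")
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (artifacts so far: {sorted(written)})"
        ) from exc

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {"cohort": cohort_seed, "drugs": drug_seed, "reporter": reporter_seed},
        "signature": {
            "n_up_with_age": len(up_genes),
            "n_down_with_age": len(down_genes),
            "n_conflicts": len(aged.conflicts),
        },
        "regulation": {k: len(v) for k, v in parts.items()},
        "hits": {
            "lists": {f"{h}|{m}": v for (h, m), v in compendium.lists.items()},
            "n_unique": n_hits,
            "overlap_count": compendium.overlap_count,
        },
        "enrichment": enrich,
        "reporter": {
            "control_slope": slope,
            "control_intercept": intercept,
            "control_r2": r2,
            "selected_dose": dr.selected_dose,
            "planted_optimum": reporter_cfg.optimum_dose,
        },
        "published_anchors": all_anchors(seed=config.seed),
        "artifacts": written,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
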