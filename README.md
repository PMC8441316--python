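# matreoscreen

An in-silico drug-repurposing screen built around extracellular-matrix
(matrisome) gene expression. The toolkit:

1. **builds aged/youthful matreotype signatures** from age-stratified
   expression cohorts — absolute and relative age changes per gene,
   Welch tests on log expression, per-tissue Benjamini–Hochberg FDR, and
   a ≥3-source consensus with strict-majority direction voting
   (`matreoscreen.signature`);
2. **scores drug perturbation profiles** (compound × gene z-score
   matrices) for overall matrisome regulation — the matrisome mean z
   standardized against size-matched random gene sets within the same
   profile, classified at ±1.5 — and for signature concordance
   ("reversed" vs "potentiated" aging signature), compiling the four
   top-50 hit lists, the unique-hit compendium, and hypergeometric
   lifespan-flag enrichment (`matreoscreen.scoring`);
3. **mines compound annotation tables** for >5% lifespan extension and
   ECM keyword mentions in abstracts (`matreoscreen.litmine`);
4. **models the collagen-reporter surrogate assay** — 4-bin intensity
   categorization, linear decline fits over adulthood days 1–5,
   rank-test prolongation effects, and U/J-shaped dose selection
   (`matreoscreen.reporter`);
5. **generates synthetic inputs with planted ground truth** for every
   stage (`matreoscreen.simulate`), so recovery and calibration are
   testable at desk scale.

Gene sets are handled as GMT (`matreoscreen.matrisome`), expression and
drug matrices as GCT 1.2 (`matreoscreen.gct`), and everything is
orchestrated by a deterministic, seed-split pipeline
(`matreoscreen.pipeline`).

## CLI

```sh
# full synthetic run: simulate -> signature -> score -> rank -> report
matreoscreen run-all --seed 1 --out-dir run1

# individual stages on the written artifacts
matreoscreen signature --in-dir run1 --min-sources 3 --alpha 0.05 --out sig.tsv
matreoscreen score     --library run1/drug_library.gct --gmt run1/gene_sets.gmt
matreoscreen rank      --library run1/drug_library.gct --signature sig.tsv --k 50
matreoscreen litmine   --table compounds.tsv --min-extension 5
matreoscreen reporter  --data run1/reporter_trajectories.csv --score-day 4
matreoscreen report    --run-dir run1
```

`run-all` writes every intermediate artifact (GCT/TSV/CSV/JSON) with
checksums plus a `report.json` containing the signature summary, the
regulation-score partition, hit lists, enrichment block, reporter fits,
and a set of arithmetic self-checks on published screen counts.

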