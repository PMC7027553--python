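# coldmeta

Meta-analysis pipeline for warming-experiment effects on belowground
nitrogen pools, fluxes, enzymes, genes, and biota in cold ecosystems.

The pipeline works on study-level summary tables (one CSV row per
warmed-vs-control comparison) and provides:

- **Effect sizes**: standardized mean differences (SMD) with their
  large-sample sampling variances; SE-to-SD normalization; an opt-in
  small-sample (Hedges-type) correction.
- **Shared-control covariance**: comparisons that reuse one control group
  are sampling-correlated; a full variance-covariance matrix is built with
  configurable off-diagonal conventions.
- **Fixed-effect pooling** by GLS under that covariance, with CI selection
  by study count: no CI at k = 1, cluster-aware BCa bootstrap for
  2 &le; k &lt; 15, Wald otherwise; significance = CI excludes zero.
- **Subgroup analysis** across soil-depth bins (5/10/15/below-15 cm),
  latitude bands (&gt;50&deg;N / intermediate / &gt;50&deg;S), and MAT/MAP
  biomes (tundra, boreal, temperate, grassland with a dry-site override),
  gated by a &gt;10-studies rule with a configurable exception list.
- **Meta-regression** on warming magnitude, experiment duration, and
  soil-moisture change, with optional pairwise interactions of the
  centered moderators.
- **Synthetic data**: a generator emitting schema-valid study tables with
  known true effects, moderator-driven heterogeneity, and shared-control
  clusters, so everything is testable without external data.

## CLI

```bash
# synthetic input
coldmeta simulate --seed 42 --out studies.csv            # optional --scenario scenario.yaml

# stage by stage
coldmeta classify --in studies.csv --out labeled.csv     # optional --biome-config biomes.yaml
coldmeta effects  --in studies.csv --out effects.csv --rejects rejects.csv --vcov vcov.csv
coldmeta fit      --effects effects.csv --vcov vcov.csv --by biome --B 10000 --seed 17 --out fits.csv
coldmeta metareg  --effects effects.csv --vcov vcov.csv --interactions --out metareg.csv

# everything at once (effects.csv, vcov.csv, fits.csv, metareg.csv,
# rejects.csv, manifest.json under results/)
coldmeta run --in studies.csv --seed 17 --outdir results/
```

`coldmeta run` is deterministic given (input bytes, config, seed): reruns
are byte-identical, every CSV starts with a `# manifest: <run_id>` line,
and `manifest.json` records input hash, config snapshot, seeds, and
per-stage row counts.

### Study table schema

Required columns: `study_id, dataset_id, response, mean_w, n_w, mean_c,
n_c, latitude_deg, mat_c, map_mm, control_cluster`; exactly one of
`sd_w`/`se_w` and of `sd_c`/`se_c` per row; optional `depth_cm, delta_t,
duration_yr, moisture_effect`. Rows sharing a `control_cluster` must carry
identical control-arm statistics. Empty cell = missing; UTF-8; `.`
decimals.

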