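# rloopkit

Scoring and calibration toolkit for a synthetic study of DNA:RNA hybrid
(R-loop) accumulation and hyper-recombination in yeast, with seeded
generators for every input it consumes.

## Scientific problem

When Okazaki-fragment processing on the lagging strand is impaired, cells
accumulate DNA:RNA hybrids and become hyper-recombinogenic. Measuring this
requires several very different assays, each with its own statistics:

1. **Flow-cytometry recombination screen (screen I).** Each well reports the
   fraction of fluorescent (recombined) cells for one strain. Raw fractions
   drift plate-to-plate, so wells are normalized to their plate median, and
   each mutant is scored against pooled wild-type wells with a percentile
   statistic — the *recombination index* (0–100; 100 means every wild-type
   measurement in the comparison group was lower) — plus a two-sided
   Mann–Whitney test.
2. **Replica-pinning screen (screen II).** Each strain occupies 16 array
   positions pinned onto 3 selective plates, giving 48 binary colony calls;
   a strain's recombinant frequency is compared against pooled wild-type
   calls with a two-sided Fisher exact test, after excluding strains with
   poor pre-selection growth.
3. **Spike-in-calibrated strand-specific DRIP-seq.** Immunoprecipitated
   hybrid coverage is binned at 20 bp per strand. A second ("spike-in")
   genome mixed at a fixed cell proportion anchors the scale: the occupancy
   ratio OR = (spike read fraction in input)/(spike read fraction in IP)
   makes signal comparable across samples and sequencing depths
   (`calibrated = count × 1e6 / ip_total × OR`). From calibrated tracks the
   package computes per-gene template/non-template densities (the template
   strand of a `+` gene is Crick), RNase H sensitivities, condition
   fold-changes, and metagene matrices.
4. **Replication-fork orientation.** OK-seq-style profiles give a local
   slope whose sign encodes fork direction; genes are called co-directional
   (CD) or head-on (HO) with the fork, with a ±2·SE ambiguity band.
5. **Dot-blot hybrid levels and integration.** Log-log standard curves turn
   dot-blot intensities into relative hybrid levels, which are stratified
   into quartiles (Q1 = highest) and correlated (Spearman) with
   recombination metrics.
6. **Repair-foci imaging.** Nuclei are segmented from DAPI (Otsu threshold),
   foci counted as local maxima of a max-projection with a scale-invariant
   prominence criterion, and foci-positive proportions compared with Fisher
   exact tests.

Because the original raw data are not reproducible at desk scale, every
assay has a seeded generator (`rloopkit.simulate`) that emits data *plus a
machine-readable truth table*, so the scoring code is validated by parameter
recovery rather than by frozen fixtures.

## Worked example

Score a small simulated flow screen with one planted 8-fold
hyper-recombination mutant (`mutA`) and one null (`mutB`):

```python
from rloopkit.config import SimConfig
from rloopkit import simulate, flow_screen

cfg = SimConfig(seed=1, n_plates=4, n_wt_wells=24,
                hyper_effects={"mutA": 8.0, "mutB": 1.0}, n_replicates=8)
meas, truth = simulate.gen_flow_screen(cfg)
norm = flow_screen.plate_normalize(meas)
groups = flow_screen.build_comparison_groups(norm[norm["is_wt"]], n_groups=2, seed=0)
res = flow_screen.score_strains(norm, groups)
print(res[["strain_id", "median_index", "p_value", "direction"]].to_string(index=False))
```

prints

```
strain_id  median_index      p_value direction
     mutA         100.0 1.407961e-09     hyper
     mutB          62.5 3.998663e-01      none
```

The planted mutant scores the scale maximum (index 100: all pooled wild-type
wells lower) and is called `hyper`; the null is not significant.

Calibrate a simulated DRIP sample and quantify per-gene strand specificity:

```python
from rloopkit import drip

sim = simulate.gen_drip_experiment(SimConfig(seed=1, n_genes=50, genome_length=50_000))
inp, ip = sim.spike[("control", "mock")]
orv = drip.occupancy_ratio(inp, ip)          # 0.5441
tracks = {s: drip.calibrate(sim.coverage[("control", "mock", "IP", s)], orv, ip.n_total)
          for s in ("W", "C")}
dens = drip.gene_density_table(tracks, sim.genes)
print(dens.head(3).to_string(index=False))
```

prints

```
 gene_id  template_density  nontemplate_density  specificity
gene0000         11.258761             0.885103     0.927115
gene0001          6.450549             0.931353     0.873833
gene0002         69.659219             0.907774     0.987136
```

with mean template-strand specificity 0.905 across the 50 genes (hybrid
signal lands on the template strand; the non-template strand carries only
nonspecific background).

## Command line

```bash
rloopkit simulate --seed 1 --outdir simulated      # all inputs + truth tables
rloopkit score-flow --measurements simulated/flow_measurements.tsv
rloopkit score-pinning --grids grids.tsv --wt-grids wt.tsv
rloopkit drip-calibrate --ip-track s.IP.experimental.W.bedgraph \
    --input-spike 50000 --input-total 1000000 --ip-spike 90000 --ip-total 1000000 \
    --out s.cal.bedgraph
rloopkit drip-density --track-w w.bedgraph --track-c c.bedgraph --genes genes.bed
rloopkit classify-cdho --okseq okseq_profile.tsv --genes genes.bed
rloopkit count-foci --dapi dapi.tiff --signal foci.tiff
rloopkit run-all --seed 1 --outdir run            # end-to-end, deterministic
```

`run-all` writes per-stage TSVs and a `summary.json` that is byte-identical
across runs with the same seed.

## Reproduction

The acceptance quantities (screen recall and false-positive rate, calibrated
DRIP fold/sensitivity/specificity recovery, CD/HO accuracy, qPCR identities,
foci recovery, and the recombination-index scale maximum `t1`) are
recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry is `{"value": ..., "n": ...}`. The full guarantees, with their
tolerances, are encoded in `tests/test_acceptance.py`; modelling choices and
numerical caveats are documented in `docs/methods.md`.
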