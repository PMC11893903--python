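"""End-to-end synthetic run: simulate every assay, score it, and report
recovery of the planted truth.

The run is fully determined by a seed: generators, comparison-group
partitioning, and report serialization are all seeded or order-stable, so
two runs with the same seed produce byte-identical JSON summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drip, flow_screen, foci, hybrid_levels, pinning_screen, simulate
from .config import SimConfig
from .io import write_tsv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# study-scale default configurations
# ---------------------------------------------------------------------------

def default_flow_config(seed: int, n_strains: int = 384, hit_fraction: float = 0.05,
                        hit_fold: float = 4.0, n_replicates: int = 8) -> SimConfig:
    """Screen-I conditions: 384 strains, 5% planted hyper-rec at 4-fold,
    8 replicates per strain, wild type on every plate."""
    n_hits = int(round(n_strains * hit_fraction))
    effects = {}
    for i in range(n_strains):
        # hits spread deterministically through the array
        is_hit = i % max(1, n_strains // max(n_hits, 1)) == 0 and len(
            [k for k in effects if effects[k] > 1]) < n_hits
        effects[f"mut{i:04d}"] = hit_fold if is_hit else 1.0
    return SimConfig(seed=seed, n_plates=8, wells_per_plate=96, n_wt_wells=58,
                     n_replicates=n_replicates, hyper_effects=effects)


def default_pinning_config(seed: int, n_strains: int = 96, hit_fraction: float = 0.05,
                           hit_p: float = 0.20) -> SimConfig:
    n_hits = int(round(n_strains * hit_fraction))
    effects = {f"strain{i:03d}": hit_p
               for i in range(0, n_strains, max(1, n_strains // max(n_hits, 1)))[:n_hits]}
    return SimConfig(seed=seed, n_strains_pinning=n_strains, pinning_effects=effects)


def default_wt_pinning_config(seed: int, n_wt_strains: int = 68) -> SimConfig:
    """Pooled wild-type pinning reference: 68 x 48 = 3264 replicate calls."""
    return SimConfig(seed=seed, n_strains_pinning=n_wt_strains)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def run_flow_stage(config: SimConfig, n_groups: int = 10) -> dict:
    measurements, truth = simulate.gen_flow_screen(config)
    normalized = flow_screen.plate_normalize(measurements)
    wt = normalized[normalized["is_wt"]]
    groups = flow_screen.build_comparison_groups(wt, n_groups=n_groups,
                                                 seed=config.seed)
    strains = sorted(normalized.loc[~normalized["is_wt"], "strain_id"].unique())
    group_of_strain = {s: i % n_groups for i, s in enumerate(strains)}
    result = flow_screen.score_strains(normalized, groups,
                                       group_of_strain=group_of_strain)

    truth_map = dict(zip(truth["strain_id"], truth["is_hit"]))
    result["planted_hit"] = result["strain_id"].map(truth_map)
    hits = result[result["planted_hit"]]
    nulls = result[~result["planted_hit"]]
    recall = float(((hits["p_value"] < 0.05) & (hits["direction"] == "hyper")).mean()) \
        if len(hits) else float("nan")
    fpr = float((nulls["p_value"] < 0.05).mean()) if len(nulls) else float("nan")
    return {
        "result": result,
        "groups": groups,
        "metrics": {
            "n_strains": len(result),
            "n_planted_hits": int(result["planted_hit"].sum()),
            "n_groups": len(groups["groups"]),
            "group_size_spread": int(max(len(g) for g in groups["groups"])
                                     - min(len(g) for g in groups["groups"])),
            "recall_planted": recall,
            "false_positive_rate": fpr,
        },
    }


def run_pinning_stage(config: SimConfig, wt_config: SimConfig,
                      size_threshold: float = 1.0) -> dict:
    grids, truth = simulate.gen_pinning_screen(config)
    wt_grids, _ = simulate.gen_pinning_screen(wt_config)
    called = pinning_screen.call_colonies(grids, size_threshold)
    wt_called = pinning_screen.call_colonies(wt_grids, size_threshold)
    result = pinning_screen.score_pinning(called, wt_called)

    planted = truth.loc[truth["pinning_p"] > wt_config.pinning_p_wt, "strain_id"]
    scored = result.set_index("strain_id")
    detected = [s for s in planted if s in scored.index
                and scored.loc[s, "p_value"] < 0.05]
    calls_per_strain = called.groupby("strain_id").size()
    return {
        "result": result,
        "metrics": {
            "replicates_per_strain": int(calls_per_strain.iloc[0]),
            "replicates_uniform": bool((calls_per_strain == calls_per_strain.iloc[0]).all()),
            "n_wt_replicates": int(len(wt_called)),
            "n_planted": int(len(planted)),
            "n_planted_detected": len(detected),
            "wt_frequency": float(wt_called["positive"].mean()),
        },
    }


def run_drip_stage(config: SimConfig) -> dict:
    sim = simulate.gen_drip_experiment(config)
    genes = sim.genes

    calibrated: dict = {}
    ors: dict = {}
    for cond in simulate.CONDITIONS:
        for treat in simulate.TREATMENTS:
            sp_in, sp_ip = sim.spike[(cond, treat)]
            or_val = drip.occupancy_ratio(sp_in, sp_ip)
            ors[f"{cond}_{treat}"] = or_val
            calibrated[(cond, treat)] = {
                strand: drip.calibrate(sim.coverage[(cond, treat, "IP", strand)],
                                       or_val, sp_ip.n_total)
                for strand in ("W", "C")
            }

    dens = {key: drip.gene_density_table(tracks, genes)
            for key, tracks in calibrated.items()}

    # nonspecific-IP background per sample: mean calibrated intergenic density
    n_bins = int(np.ceil(config.genome_length / config.bin_size))
    genic = np.zeros(n_bins, dtype=bool)
    for g in genes.itertuples():
        genic[g.start // config.bin_size: int(np.ceil(g.end / config.bin_size))] = True

    def intergenic_bg(tracks: dict) -> float:
        vals = [tracks[s].bins["count"].to_numpy()[~genic] for s in ("W", "C")]
        return float(np.mean(np.concatenate(vals))) / config.bin_size

    bg = {key: intergenic_bg(tracks) for key, tracks in calibrated.items()}

    def corrected(key, col):
        d = dens[key].set_index("gene_id")[col]
        return np.maximum(d - bg[key], 0.0)

    # condition fold-change and RNase H sensitivity on background-corrected
    # template-strand densities (the background is not hybrid signal)
    tc = corrected(("control", "mock"), "template_density")
    tt = corrected(("treated", "mock"), "template_density")
    tr = corrected(("control", "rnh"), "template_density")
    nc = corrected(("control", "mock"), "nontemplate_density")
    folds = [drip.density_fold_change(tt[g], tc[g], pseudocount=1e-9)
             for g in genes["gene_id"] if tc[g] > 0]
    sens = [drip.rnase_h_sensitivity(tc[g], tr[g])
            for g in genes["gene_id"] if tc[g] > 0]
    with np.errstate(invalid="ignore"):
        spec = np.where(tc + nc > 0, tc / (tc + nc), np.nan)

    scale = calibrated_scale(config, genes)
    background_truth_cal = config.background_density / config.bin_size * scale
    intergenic_mean = bg[("control", "mock")]

    return {
        "sim": sim,
        "calibrated": calibrated,
        "densities": dens,
        "metrics": {
            "occupancy_ratios": {k: float(v) for k, v in ors.items()},
            "median_condition_fold": float(np.median(folds)),
            "median_rnh_sensitivity": float(np.median(sens)),
            "mean_template_specificity": float(np.nanmean(spec)),
            "mean_template_specificity_raw": float(np.nanmean(
                dens[("control", "mock")]["specificity"])),
            "intergenic_over_background_truth": intergenic_mean / background_truth_cal,
            "n_genes": int(len(genes)),
        },
    }


def calibrated_scale(config: SimConfig, genes: pd.DataFrame) -> float:
    """Factor mapping true occupancy density to calibrated units.

    From the generative model: calibrated = 1e6 x spike_fraction_input /
    (ip_efficiency x S_ref) x truth, with S_ref the summed true density of
    the reference (control/mock) sample.
    """
    dens_ref = simulate.true_density_grid(config, genes, "control", "mock")
    s_ref = float(sum(d.sum() for d in dens_ref.values()))
    return 1e6 * config.spike_fraction_input / (config.ip_efficiency * s_ref)


def run_cdho_stage(config: SimConfig, noise_sd: float | None = None) -> dict:
    """Classify per-interval gene orientation against planted fork direction."""
    if noise_sd is not None:
        config = SimConfig.from_dict({**config.to_dict(), "okseq_noise_sd": noise_sd})
    profile, truth = simulate.gen_okseq(config)
    rng = np.random.default_rng([config.seed, 7])
    correct = 0
    n = 0
    for iv in truth.itertuples():
        slope, se = drip.okseq_slope(profile, iv.chrom, iv.start, iv.end)
        gene_strand = "+" if rng.random() < 0.5 else "-"
        call = drip.classify_orientation(slope, se, gene_strand)
        expected_fork = iv.fork_direction
        if expected_fork == "ambiguous":
            expected = "ambiguous"
        else:
            rightward = expected_fork == "right"
            expected = "CD" if rightward == (gene_strand == "+") else "HO"
        correct += call["orientation"] == expected
        n += 1
    return {"metrics": {"accuracy": correct / n, "n_intervals": n,
                        "noise_sd": float(config.okseq_noise_sd)}}


def run_foci_stage(config: SimConfig, n_fields: int = 2) -> dict:
    fields_clean = simulate.gen_foci_images(config, n_fields=n_fields, noise=False)
    fields_noisy = simulate.gen_foci_images(config, n_fields=n_fields, noise=True)

    def recover(fields):
        exact_nuclei = 0
        exact = 0
        within_one = 0
        total_nuclei = 0
        all_counts = []
        for stack, truth in fields:
            measured = foci.measure_field(stack)
            mask = foci.segment_nuclei(foci.max_project(
                np.asarray(stack.channels["DAPI"])))
            exact_nuclei += int(len(measured) == len(truth))
            counts_by_label = dict(zip(measured["nucleus_id"], measured["foci_count"]))
            for t in truth.itertuples():
                lab = int(mask[int(round(t.cy)), int(round(t.cx))])
                got = counts_by_label.get(lab, 0)
                exact += int(got == t.n_foci)
                within_one += int(abs(got - t.n_foci) <= 1)
                total_nuclei += 1
                all_counts.append(got)
        return {
            "fields_with_exact_nucleus_count": exact_nuclei,
            "n_fields": len(fields),
            "fraction_exact": exact / total_nuclei,
            "fraction_within_one_focus": within_one / total_nuclei,
            "counts": all_counts,
        }

    clean = recover(fields_clean)
    noisy = recover(fields_noisy)
    identical = foci.compare_foci_proportions(clean["counts"], clean["counts"])
    return {"metrics": {
        "noiseless": {k: v for k, v in clean.items() if k != "counts"},
        "noisy": {k: v for k, v in noisy.items() if k != "counts"},
        "fisher_identical_groups_p": identical["p_value"],
    }}


def run_integration_stage(seed: int, n_mutants: int = 39) -> dict:
    """Screen-III style integration: hybrid levels vs recombination.

    Simulates dot-blot-derived hybrid levels for the confirmed hyper-rec
    mutants, splits them into quartiles, and correlates levels with
    (independent) recombination indices — emulating the observed lack of
    correlation between global hybrid load and recombination rate.
    """
    rng = np.random.default_rng([seed, 11])
    levels = pd.DataFrame({
        "strain_id": [f"hit{i:02d}" for i in range(n_mutants)],
        "relative_level": rng.lognormal(0.0, 0.8, size=n_mutants),
    })
    quart = hybrid_levels.assign_quartiles(levels)
    recomb = rng.uniform(50, 100, size=n_mutants)  # independent of levels
    corr = hybrid_levels.correlate_levels_recombination(
        levels["relative_level"], recomb)
    sizes = quart["quartile"].value_counts().to_dict()
    return {
        "quartiles": quart,
        "metrics": {
            "quartile_sizes": {q: int(sizes[q]) for q in sorted(sizes)},
            "spearman_rho": corr["rho"],
            "spearman_p": corr["p_value"],
        },
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level configuration of an end-to-end synthetic run."""

    seed: int = 0
    outdir: str = "rloopkit_run"
    flow_n_strains: int = 384
    flow_hit_fraction: float = 0.05
    flow_hit_fold: float = 4.0
    flow_n_replicates: int = 8
    pinning_n_strains: int = 96
    drip: SimConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.drip is None:
            self.drip = SimConfig(seed=self.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, score and report every stage; write TSVs + a JSON summary.

    The JSON summary is byte-identical across runs with the same seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    logger.info("run_pipeline: seed=%d outdir=%s", seed, outdir)

    stages = {}

    flow_cfg = default_flow_config(seed, n_strains=config.flow_n_strains,
                                   hit_fraction=config.flow_hit_fraction,
                                   hit_fold=config.flow_hit_fold,
                                   n_replicates=config.flow_n_replicates)
    flow = run_flow_stage(flow_cfg)
    write_tsv(flow["result"].drop(columns=["indices"]), outdir / "flow_screen.tsv")
    stages["flow_screen"] = flow["metrics"]

    pin = run_pinning_stage(default_pinning_config(seed, config.pinning_n_strains),
                            default_wt_pinning_config(seed + 1))
    write_tsv(pin["result"], outdir / "pinning_screen.tsv")
    stages["pinning_screen"] = pin["metrics"]

    dr = run_drip_stage(config.drip)
    for key, table in dr["densities"].items():
        write_tsv(table, outdir / f"gene_density.{key[0]}.{key[1]}.tsv")
    stages["drip"] = dr["metrics"]

    stages["cdho_noiseless"] = run_cdho_stage(config.drip, noise_sd=0.0)["metrics"]
    half_slope = config.drip.okseq_slope_per_kb / 2.0
    stages["cdho_noisy"] = run_cdho_stage(config.drip, noise_sd=half_slope)["metrics"]

    stages["foci"] = run_foci_stage(SimConfig(seed=seed))["metrics"]

    integ = run_integration_stage(seed)
    write_tsv(integ["quartiles"], outdir / "hybrid_quartiles.tsv")
    stages["integration"] = integ["metrics"]

    # definitional identities recomputed at run time
    group = np.arange(1, 101, dtype=float)
    stages["identities"] = {
        "recombination_index_above_all_wt": flow_screen.recombination_index(
            group.max() + 1.0, group),
        "qpcr_percent_ip_equal_ct": drip.qpcr_percent_ip(20.0, 20.0,
                                                         input_fraction=0.05),
        "qpcr_adjust_invariance": drip.qpcr_adjust(1.0, 50.0)
        == drip.qpcr_adjust(0.5, 25.0),
    }

    summary = {"seed": seed, "stages": stages}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj
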