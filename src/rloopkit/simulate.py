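"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of one arm of the study:

* ``gen_flow_screen`` — per-well fractions of fluorescent (recombined) cells
  with shared multiplicative plate effects and planted hyper-recombination
  fold-changes for named mutant strains.
* ``gen_pinning_screen`` — binary colony calls from a replica-pinned array
  (16 array positions x 3 selective plates = 48 Bernoulli calls per strain).
* ``gen_drip_experiment`` — strand-specific binned IP/input coverage on an
  experimental genome plus spike-in read counts, with hybrid signal placed
  only on each gene's template strand, proportional to transcription.
* ``gen_okseq`` — a piecewise-linear replication-direction proxy with known
  per-interval slopes.
* ``gen_foci_images`` — DAPI nuclei plus focal point sources at known counts.

Every generator emits a machine-readable truth table alongside the data so
that downstream recovery can be scored, and is byte-deterministic under a
fixed ``SimConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimConfig
from .drip import SpikeInCounts, StrandedCoverage, template_strand
from .foci import ImageStack

CONDITIONS = ("control", "treated")
TREATMENTS = ("mock", "rnh")
CHROM = "chrS"

# fixed stream ids so each generator draws from an independent substream
_STREAMS = {"flow": 1, "pinning": 2, "drip": 3, "okseq": 4, "foci": 5}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# screen I: flow cytometry
# ---------------------------------------------------------------------------

def gen_flow_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-well YFP+ fractions for wild type and mutant strains.

    Fractions are logit-normal: logit(frac) = logit(baseline x fold) +
    plate effect + well noise, which keeps values in [0, 1] while making
    plate effects and planted fold-changes multiplicative at small baseline
    fractions.  Wild-type wells fill ``n_wt_wells`` slots per plate; each
    mutant strain gets ``n_replicates`` wells spread over plates.

    Returns ``(measurements, truth)``: measurements with columns
    strain_id/plate_id/replicate/frac_positive/is_wt, and a truth table of
    planted fold-changes.
    """
    rng = _rng(config, "flow")
    plate_effects = rng.normal(0.0, config.plate_effect_sd, size=config.n_plates)

    rows = []

    def draw(mean_frac: float, plate: int) -> float:
        x = logit(np.clip(mean_frac, 1e-9, 1 - 1e-9))
        x += plate_effects[plate] + rng.normal(0.0, config.well_noise_sd)
        return float(expit(x))

    # wild-type wells on every plate
    for plate in range(config.n_plates):
        for w in range(config.n_wt_wells):
            rows.append(("wt", f"plate{plate}", w, draw(config.wt_baseline, plate), True))

    # mutant strains: n_replicates wells each, cycling over plates
    strains = sorted(config.hyper_effects)
    for s_idx, strain in enumerate(strains):
        fold = config.hyper_effects[strain]
        for rep in range(config.n_replicates):
            plate = (s_idx + rep) % config.n_plates
            frac = draw(min(config.wt_baseline * fold, 1.0 - 1e-9), plate)
            rows.append((strain, f"plate{plate}", rep, frac, False))

    measurements = pd.DataFrame(
        rows, columns=["strain_id", "plate_id", "replicate", "frac_positive", "is_wt"]
    )
    truth = pd.DataFrame(
        {
            "strain_id": strains,
            "fold_change": [config.hyper_effects[s] for s in strains],
            "is_hit": [config.hyper_effects[s] > 1.0 for s in strains],
        }
    )
    return measurements, truth


# ---------------------------------------------------------------------------
# screen II: replica pinning
# ---------------------------------------------------------------------------

def gen_pinning_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replica-pinned colony array.

    Each strain occupies ``array_replicates`` (16) positions, each pinned onto
    ``selective_plates`` (3) selective plates, yielding 48 independent
    Bernoulli colony calls per strain at its planted recombination
    probability.  Strains listed in ``poor_growth_strains`` have their
    pre-selection growth flag set to False at every position.

    Positive colonies get a size of 2.0 (arbitrary units), negatives 0.0, so
    any threshold in (0, 2] reproduces the planted calls.
    """
    rng = _rng(config, "pinning")
    strains = [f"strain{i:03d}" for i in range(config.n_strains_pinning)]
    probs = {s: config.pinning_effects.get(s, config.pinning_p_wt) for s in strains}
    poor = set(config.poor_growth_strains)

    rows = []
    side = int(np.ceil(np.sqrt(config.array_replicates)))
    for strain in strains:
        p = probs[strain]
        growth = strain not in poor
        for pos in range(config.array_replicates):
            row, col = divmod(pos, side)
            for plate in range(1, config.selective_plates + 1):
                positive = bool(rng.random() < p) if growth else False
                size = 2.0 if positive else 0.0
                rows.append((strain, row, col, plate, size, growth))

    grids = pd.DataFrame(
        rows,
        columns=["strain_id", "row", "col", "selective_plate", "colony_size", "growth_ok"],
    )
    truth = pd.DataFrame(
        {
            "strain_id": strains,
            "pinning_p": [probs[s] for s in strains],
            "poor_growth": [s in poor for s in strains],
        }
    )
    return grids, truth


# ---------------------------------------------------------------------------
# DRIP experiment
# ---------------------------------------------------------------------------

@dataclass
class DripSim:
    """A simulated spike-in-calibrated strand-specific DRIP experiment.

    ``coverage`` maps (condition, treatment, fraction, strand) to a
    ``StrandedCoverage`` on the experimental genome; ``spike`` maps
    (condition, treatment) to (input, IP) ``SpikeInCounts``; ``truth`` holds
    the true per-gene template-strand hybrid density per condition/treatment.
    """

    genes: pd.DataFrame
    coverage: dict
    spike: dict
    truth: pd.DataFrame


def _make_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    slot = config.genome_length // config.n_genes
    body = max(config.bin_size, (int(slot * 0.6) // config.bin_size) * config.bin_size)
    rows = []
    for i in range(config.n_genes):
        start = i * slot + ((slot - body) // (2 * config.bin_size)) * config.bin_size
        strand = "+" if rng.random() < 0.5 else "-"
        txn = float(config.txn_level_mean * rng.lognormal(0.0, config.txn_level_sd))
        rows.append((f"gene{i:04d}", CHROM, start, start + body, strand, txn))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "txn_level"]
    )


def _bin_grid(config: SimConfig) -> pd.DataFrame:
    starts = np.arange(0, config.genome_length, config.bin_size)
    ends = np.minimum(starts + config.bin_size, config.genome_length)
    return pd.DataFrame({"chrom": CHROM, "start": starts, "end": ends})


def true_density_grid(config: SimConfig, genes: pd.DataFrame,
                      condition: str, treatment: str) -> dict[str, np.ndarray]:
    """True IP occupancy per bin and strand (arbitrary occupancy units).

    Background is flat on both strands; hybrid signal sits only on each
    gene's template strand over the gene body, proportional to
    txn_level x hybrid_per_txn, scaled by condition_fold when treated and by
    rnh_residual under in vitro RNase H.
    """
    n_bins = int(np.ceil(config.genome_length / config.bin_size))
    dens = {"W": np.full(n_bins, config.background_density, dtype=float),
            "C": np.full(n_bins, config.background_density, dtype=float)}
    scale = config.hybrid_per_txn
    if condition == "treated":
        scale *= config.condition_fold
    if treatment == "rnh":
        scale *= config.rnh_residual
    for g in genes.itertuples():
        tmpl = template_strand(g.strand)
        b0 = g.start // config.bin_size
        b1 = int(np.ceil(g.end / config.bin_size))
        dens[tmpl][b0:b1] += g.txn_level * scale
    return dens


def gen_drip_experiment(config: SimConfig) -> DripSim:
    """Simulate IP/input coverage and spike-in counts for a 2x2 design.

    The IP read pool of each sample splits between the experimental genome
    and the spike genome in proportion to their immunoprecipitable material:
    experimental signal S (the summed true density) versus a fixed spike
    contribution K = ip_efficiency x S_ref, with S_ref the control/mock
    total.  Per-bin counts are Poisson around the sample's expected
    experimental depth times the bin's density share; input coverage is flat
    with the spike genome at ``spike_fraction_input`` of reads.
    """
    rng = _rng(config, "drip")
    genes = _make_genes(config, rng)
    grid = _bin_grid(config)

    dens_ref = true_density_grid(config, genes, "control", "mock")
    s_ref = float(sum(d.sum() for d in dens_ref.values()))
    k_spike = config.ip_efficiency * s_ref

    coverage: dict = {}
    spike: dict = {}
    truth_rows = []
    n_bins = len(grid)

    for condition in CONDITIONS:
        for treatment in TREATMENTS:
            dens = true_density_grid(config, genes, condition, treatment)
            s_total = float(sum(d.sum() for d in dens.values()))

            # --- input fraction: flat coverage, fixed spike share ---
            n_spike_in = int(rng.binomial(config.input_depth, config.spike_fraction_input))
            exp_reads_in = config.input_depth - n_spike_in
            lam_in = exp_reads_in / (2 * n_bins)
            for strand in ("W", "C"):
                bins = grid.copy()
                bins["count"] = rng.poisson(lam_in, size=n_bins)
                coverage[(condition, treatment, "input", strand)] = StrandedCoverage(
                    sample_id=f"{condition}_{treatment}", condition=condition,
                    treatment=treatment, fraction="input", genome="experimental",
                    strand=strand, bins=bins,
                )

            # --- IP fraction: spike share set by occupancy competition ---
            p_spike_ip = k_spike / (s_total + k_spike)
            n_spike_ip = int(rng.binomial(config.ip_depth, p_spike_ip))
            exp_reads_ip = config.ip_depth - n_spike_ip
            for strand in ("W", "C"):
                bins = grid.copy()
                lam = exp_reads_ip * dens[strand] / s_total
                bins["count"] = rng.poisson(lam)
                coverage[(condition, treatment, "IP", strand)] = StrandedCoverage(
                    sample_id=f"{condition}_{treatment}", condition=condition,
                    treatment=treatment, fraction="IP", genome="experimental",
                    strand=strand, bins=bins,
                )

            spike[(condition, treatment)] = (
                SpikeInCounts(sample_id=f"{condition}_{treatment}", fraction="input",
                              n_spike=n_spike_in, n_total=config.input_depth),
                SpikeInCounts(sample_id=f"{condition}_{treatment}", fraction="IP",
                              n_spike=n_spike_ip, n_total=config.ip_depth),
            )

            scale = config.hybrid_per_txn
            if condition == "treated":
                scale *= config.condition_fold
            if treatment == "rnh":
                scale *= config.rnh_residual
            for g in genes.itertuples():
                truth_rows.append(
                    (g.gene_id, condition, treatment,
                     g.txn_level * scale / config.bin_size,
                     config.background_density / config.bin_size)
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "condition", "treatment",
                 "true_template_density", "true_background_density"],
    )
    return DripSim(genes=genes, coverage=coverage, spike=spike, truth=truth)


# ---------------------------------------------------------------------------
# OK-seq profile
# ---------------------------------------------------------------------------

def gen_okseq(config: SimConfig,
              slopes_per_kb: Sequence[float] | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a piecewise-linear OK-seq replication-direction proxy.

    Each of ``okseq_n_intervals`` intervals gets a known slope (by default
    alternating +/- ``okseq_slope_per_kb`` per kb, overridable via
    ``slopes_per_kb``); the signal is continuous across intervals with
    Gaussian noise of SD ``okseq_noise_sd``.  Truth direction per interval is
    "right" for positive slope, "left" for negative, "ambiguous" for zero
    (under the positive-slope-means-rightward convention).
    """
    rng = _rng(config, "okseq")
    n = config.okseq_n_intervals
    if slopes_per_kb is None:
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        slopes_per_kb = signs * config.okseq_slope_per_kb
    slopes_per_kb = np.asarray(slopes_per_kb, dtype=float)
    if len(slopes_per_kb) != n:
        raise ValueError("slopes_per_kb length must equal okseq_n_intervals")

    positions, signal = [], []
    level = 0.0
    truth_rows = []
    for i, s_kb in enumerate(slopes_per_kb):
        start = i * config.okseq_interval_bp
        end = start + config.okseq_interval_bp
        pos = np.arange(start, end, config.okseq_step_bp)
        slope_bp = s_kb / 1000.0
        sig = level + slope_bp * (pos - start)
        level = level + slope_bp * config.okseq_interval_bp
        positions.append(pos)
        signal.append(sig)
        direction = "right" if s_kb > 0 else ("left" if s_kb < 0 else "ambiguous")
        truth_rows.append((CHROM, start, end, s_kb, direction))

    positions = np.concatenate(positions)
    signal = np.concatenate(signal)
    if config.okseq_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.okseq_noise_sd, size=signal.shape)

    profile = pd.DataFrame({"chrom": CHROM, "position": positions, "signal": signal})
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "slope_per_kb", "fork_direction"]
    )
    return profile, truth


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def _place_points(rng: np.random.Generator, n: int, shape: tuple,
                  min_dist: float, margin: float, max_tries: int = 10_000) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        cand = np.array([rng.uniform(margin, shape[0] - margin),
                         rng.uniform(margin, shape[1] - margin)])
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise RuntimeError("could not place non-overlapping points; reduce count or radius")
    return np.array(pts)


def gen_foci_images(config: SimConfig, n_fields: int = 1, noise: bool = True
                    ) -> list[tuple[ImageStack, pd.DataFrame]]:
    """Simulate image fields: a DAPI channel with disk nuclei and a focal
    channel z-stack with point sources of known count per nucleus.

    Foci are small Gaussian spots (sigma 1.2 px) whose peak amplitude equals
    ``foci_snr`` x sqrt(background), i.e. SNR is peak over Poisson-noise SD.
    With ``noise=False`` the images are the noiseless expectations.
    Returns (stack, truth) pairs; truth has one row per nucleus with its
    center, radius and planted focus count.
    """
    rng = _rng(config, "foci")
    shape = tuple(config.image_shape)
    r = config.nucleus_radius
    out = []
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    for field_idx in range(n_fields):
        centers = _place_points(rng, config.n_nuclei, shape,
                                min_dist=2 * r + 6, margin=r + 3)
        dapi = np.full(shape, config.image_background, dtype=float)
        foci3d = np.full((config.n_z,) + shape, config.image_background, dtype=float)
        amp = config.foci_snr * np.sqrt(config.image_background)

        truth_rows = []
        for nid, (cy, cx) in enumerate(centers, start=1):
            dapi[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] += 10 * np.sqrt(config.image_background)
            n_foci = config.foci_per_nucleus
            if n_foci > 0:
                # spots inside the nucleus, mutually separated
                spots = []
                for _ in range(1000):
                    if len(spots) == n_foci:
                        break
                    rho = rng.uniform(0, 0.75 * r)
                    theta = rng.uniform(0, 2 * np.pi)
                    cand = (cy + rho * np.sin(theta), cx + rho * np.cos(theta))
                    # Chebyshev separation well above the detector's
                    # min_distance so planted spots stay resolvable
                    if all(max(abs(cand[0] - s[0]), abs(cand[1] - s[1])) >= 9
                           for s in spots):
                        spots.append(cand)
                if len(spots) < n_foci:
                    raise RuntimeError("could not place separated foci; enlarge nuclei")
                for sy, sx in spots:
                    z = int(rng.integers(0, config.n_z))
                    g = amp * np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * 1.2 ** 2))
                    foci3d[z] += g
            truth_rows.append((nid, float(cy), float(cx), float(r), config.foci_per_nucleus))

        if noise:
            dapi = rng.poisson(dapi).astype(float)
            foci3d = rng.poisson(foci3d).astype(float)

        stack = ImageStack(channels={"DAPI": dapi, "foci": foci3d},
                           z_spacing=0.3, pixel_size=0.1)
        truth = pd.DataFrame(
            truth_rows, columns=["nucleus_id", "cy", "cx", "radius", "n_foci"]
        )
        truth["field"] = field_idx
        out.append((stack, truth))
    return out
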