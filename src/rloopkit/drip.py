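"""Spike-in-calibrated strand-specific DRIP quantification.

Strand-specific DRIP-seq coverage comes as 20-bp binned counts per strand
(Watson/Crick) for input and immunoprecipitated fractions, on both the
experimental genome and a spike-in genome mixed at a fixed cell ratio.
Signal is calibrated across samples with an occupancy ratio computed from
spike-in read fractions, converted into per-gene template/non-template
densities, metagene matrices, RNase H sensitivities, gene-vs-fork
orientation calls (co-directional vs head-on) from OK-seq slopes, and
spike-normalized DRIP-qPCR percentages of input.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StrandedCoverage:
    """Binned single-strand coverage for one sample/fraction/genome.

    ``bins`` has columns chrom/start/end/count, sorted, non-overlapping,
    half-open.
    """

    sample_id: str
    condition: str
    treatment: str
    fraction: str  # "input" | "IP"
    genome: str    # "experimental" | "spike"
    strand: str    # "W" | "C"
    bins: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        b = self.bins
        if (b["count"] < 0).any():
            raise ValueError("negative bin counts")
        for chrom, grp in b.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (np.all(np.diff(starts) > 0) and np.all(ends[:-1] <= starts[1:])):
                raise ValueError(f"bins on {chrom} are unsorted or overlapping")
            if not np.all(starts < ends):
                raise ValueError(f"empty or inverted bin on {chrom}")


@dataclass
class SpikeInCounts:
    """Read counts on the spike-in genome for one sample fraction."""

    sample_id: str
    fraction: str
    n_spike: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_spike <= self.n_total:
            raise ValueError("need 0 <= n_spike <= n_total")

    @property
    def spike_fraction(self) -> float:
        return self.n_spike / self.n_total


def template_strand(gene_strand: str) -> str:
    """Strand carrying hybrids of a transcription-born R-loop.

    The RNA anneals to the strand it was templated on: for a gene on the
    ``+`` strand that is the Crick strand, for ``-`` the Watson strand.
    """
    if gene_strand == "+":
        return "C"
    if gene_strand == "-":
        return "W"
    raise ValueError(f"gene strand must be '+' or '-', got {gene_strand!r}")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def occupancy_ratio(input_counts: SpikeInCounts, ip_counts: SpikeInCounts) -> float:
    """Spike-in occupancy ratio OR = spike fraction in input / spike fraction in IP.

    Multiplying IP signal by OR (after depth normalization) makes it
    invariant to sequencing depth and linear in true occupancy, because the
    spike genome contributes the same immunoprecipitable material to every
    sample.
    """
    if input_counts.n_spike == 0 or ip_counts.n_spike == 0:
        raise ValueError(
            "zero spike-in reads; sequence (or simulate) deeper to calibrate"
        )
    return input_counts.spike_fraction / ip_counts.spike_fraction


def calibrate(ip_coverage: StrandedCoverage, or_value: float, ip_total: int) -> StrandedCoverage:
    """Scale raw IP bin counts to calibrated occupancy units.

    calibrated = count x 1e6 / ip_total x OR (counts per million, spike-in
    adjusted).  Only experimental-genome coverage is calibrated.
    """
    if or_value <= 0:
        raise ValueError("occupancy ratio must be positive")
    if ip_total <= 0:
        raise ValueError("ip_total must be positive")
    if ip_coverage.genome != "experimental":
        raise ValueError("only experimental-genome coverage is calibrated")
    bins = ip_coverage.bins.copy()
    bins["count"] = bins["count"] * (1e6 / ip_total) * or_value
    out = StrandedCoverage(
        sample_id=ip_coverage.sample_id, condition=ip_coverage.condition,
        treatment=ip_coverage.treatment, fraction=ip_coverage.fraction,
        genome=ip_coverage.genome, strand=ip_coverage.strand, bins=bins,
    )
    return out


# ---------------------------------------------------------------------------
# gene-level densities
# ---------------------------------------------------------------------------

def _interval_mean(bins: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Mean per-bp value over [start, end), weighting edge bins by overlap."""
    sub = bins[bins["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"chromosome {chrom!r} absent from coverage")
    b_start = sub["start"].to_numpy()
    b_end = sub["end"].to_numpy()
    counts = sub["count"].to_numpy(dtype=float)
    overlap = np.minimum(b_end, end) - np.maximum(b_start, start)
    sel = overlap > 0
    if not sel.any():
        return 0.0
    width = b_end[sel] - b_start[sel]
    # count is per bin; density per bp within a bin is count/width
    total = np.sum(counts[sel] / width * overlap[sel])
    return float(total / (end - start))


def gene_density(tracks: dict[str, StrandedCoverage], gene) -> dict:
    """Template/non-template calibrated densities (per bp) over a gene body.

    ``tracks`` maps strand ("W"/"C") to calibrated IP coverage.  ``gene`` is
    any object with gene_id/chrom/start/end/strand attributes (e.g. a
    DataFrame itertuples row).  Specificity is template / (template +
    non-template), NaN when both are zero.
    """
    tmpl = template_strand(gene.strand)
    nontmpl = "W" if tmpl == "C" else "C"
    t = _interval_mean(tracks[tmpl].bins, gene.chrom, gene.start, gene.end)
    n = _interval_mean(tracks[nontmpl].bins, gene.chrom, gene.start, gene.end)
    total = t + n
    return {
        "gene_id": gene.gene_id,
        "template_density": t,
        "nontemplate_density": n,
        "specificity": t / total if total > 0 else np.nan,
    }


def gene_density_table(tracks: dict[str, StrandedCoverage], genes: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame([gene_density(tracks, g) for g in genes.itertuples()])


def rnase_h_sensitivity(density_mock: float, density_rnh: float) -> float:
    """Fractional loss of signal after in vitro RNase H: 1 - rnh/mock."""
    if density_mock <= 0:
        raise ValueError("mock density must be positive (sensitivity undefined)")
    return min(1.0, 1.0 - density_rnh / density_mock)


def density_fold_change(density_treated: float, density_control: float,
                        pseudocount: float = 0.0) -> float:
    """(treated + pc) / (control + pc); pc guards zero/zero cases."""
    if density_treated < 0 or density_control < 0:
        raise ValueError("densities must be non-negative")
    denom = density_control + pseudocount
    if denom == 0:
        raise ValueError("zero control density; use a positive pseudocount")
    return (density_treated + pseudocount) / denom


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

def _gene_profile(bins: pd.DataFrame, chrom: str, start: int, end: int,
                  bin_size: int = 20) -> np.ndarray:
    """Per-bin values over [start, end) resampled onto a uniform grid."""
    n = max(1, (end - start) // bin_size)
    edges = np.linspace(start, end, n + 1)
    return np.array([
        _interval_mean(bins, chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])
    ])


def metagene(tracks: dict[str, StrandedCoverage], genes: pd.DataFrame,
             flank_bp: int = 500, body_bins: int = 50,
             bin_size: int = 20) -> dict:
    """Metagene matrices around gene bodies, per strand class.

    Each row covers ``flank_bp`` upstream of the TSS in fixed ``bin_size``
    bins, the gene body rescaled to ``body_bins`` bins, and ``flank_bp``
    downstream of the TES, oriented 5'->3' of the gene.  Rows are sorted by
    template-strand body density, descending.  Returns a dict with
    "template" and "nontemplate" matrices plus the row order of gene ids.
    """
    flank_bins = flank_bp // bin_size
    mats = {"template": [], "nontemplate": []}
    order_stat = []
    ids = []
    for g in genes.itertuples():
        tmpl = template_strand(g.strand)
        nontmpl = "W" if tmpl == "C" else "C"
        for cls, strand in (("template", tmpl), ("nontemplate", nontmpl)):
            bins = tracks[strand].bins
            up = _gene_profile(bins, g.chrom, g.start - flank_bp, g.start, bin_size)
            body = _body_profile(bins, g.chrom, g.start, g.end, body_bins)
            down = _gene_profile(bins, g.chrom, g.end, g.end + flank_bp, bin_size)
            row = np.concatenate([up, body, down])
            if g.strand == "-":
                row = row[::-1]
            mats[cls].append(row)
        order_stat.append(float(np.mean(mats["template"][-1][flank_bins:flank_bins + body_bins])))
        ids.append(g.gene_id)

    order = np.argsort(order_stat)[::-1]
    return {
        "template": np.array(mats["template"])[order],
        "nontemplate": np.array(mats["nontemplate"])[order],
        "gene_ids": [ids[i] for i in order],
    }


def _body_profile(bins: pd.DataFrame, chrom: str, start: int, end: int,
                  body_bins: int) -> np.ndarray:
    edges = np.linspace(start, end, body_bins + 1)
    out = np.empty(body_bins)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        b = max(b, a + 1e-9)
        out[i] = _interval_mean(bins, chrom, int(np.floor(a)), max(int(np.ceil(b)), int(np.floor(a)) + 1))
    return out


# ---------------------------------------------------------------------------
# replication-fork orientation
# ---------------------------------------------------------------------------

def okseq_slope(profile: pd.DataFrame, chrom: str, start: int, end: int
                ) -> tuple[float, float]:
    """OLS slope (per bp) and its standard error of the OK-seq signal over a window."""
    sub = profile[(profile["chrom"] == chrom)
                  & (profile["position"] >= start)
                  & (profile["position"] < end)]
    if len(sub) < 3:
        raise ValueError("need at least 3 profile points in the window")
    res = stats.linregress(sub["position"].to_numpy(dtype=float),
                           sub["signal"].to_numpy(dtype=float))
    return float(res.slope), float(res.stderr)


def classify_orientation(slope: float, slope_se: float, gene_strand: str,
                         sign_convention: str = "positive_slope_means_rightward",
                         ambiguity_k: float = 2.0) -> dict:
    """Call a gene co-directional (CD) or head-on (HO) with the replication fork.

    Fork direction comes from the sign of the OK-seq slope under the given
    convention; |slope| < ambiguity_k x SE is called ambiguous.  CD means the
    fork travels in the gene's direction of transcription.
    """
    if sign_convention not in ("positive_slope_means_rightward",
                               "positive_slope_means_leftward"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    if gene_strand not in ("+", "-"):
        raise ValueError("gene strand must be '+' or '-'")
    if abs(slope) < ambiguity_k * slope_se:
        return {"fork_direction": "ambiguous", "orientation": "ambiguous"}
    rightward = slope > 0
    if sign_convention == "positive_slope_means_leftward":
        rightward = not rightward
    fork = "right" if rightward else "left"
    gene_right = gene_strand == "+"
    orientation = "CD" if (rightward == gene_right) else "HO"
    return {"fork_direction": fork, "orientation": orientation}


# ---------------------------------------------------------------------------
# DRIP-qPCR
# ---------------------------------------------------------------------------

def qpcr_percent_ip(ct_input: float, ct_ip: float, input_fraction: float = 0.05,
                    efficiency: float = 2.0) -> float:
    """%IP from qPCR cycle thresholds, anchored at the input fraction.

    With perfect doubling (efficiency 2), each cycle the IP runs ahead of the
    input doubles the recovered fraction: %IP = 100 x input_fraction x
    efficiency^(ct_input - ct_ip).
    """
    if not (np.isfinite(ct_input) and np.isfinite(ct_ip)):
        raise ValueError("cycle thresholds must be finite")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input fraction must lie in (0, 1]")
    return 100.0 * input_fraction * efficiency ** (ct_input - ct_ip)


def qpcr_adjust(percent_ip_locus: float, percent_ip_spike: float,
                reference_spike: float = 100.0) -> float:
    """Adjusted %IP: locus %IP normalized to the synthetic spike-in's %IP."""
    if percent_ip_spike <= 0:
        raise ValueError("spike-in %IP must be positive")
    return percent_ip_locus * reference_spike / percent_ip_spike
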