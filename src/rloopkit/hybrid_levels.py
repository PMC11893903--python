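"""Relative DNA:RNA hybrid levels from dot-blot dilution series, and the
integration analyses tying hybrid levels to recombination and expression.

A dot blot probes serial dilutions of genomic DNA with a hybrid-specific
antibody (S9.6) and a double-stranded-DNA loading control.  A standard curve
fitted on a reference sample's dilution series converts intensities into
relative DNA amounts; a sample's hybrid level is its S9.6/dsDNA amount ratio
relative to the reference.  Mutants are stratified into quartiles by hybrid
level (Q1 = highest), transcripts classified by differential-expression
thresholds, and hybrid levels correlated with recombination metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    """log(intensity) = intercept + slope * log(amount), over the linear range."""

    slope: float
    intercept: float
    r_squared: float
    used_points: int
    amount_range: tuple[float, float]

    def amount(self, intensity: float) -> float:
        """Invert the curve: relative DNA amount giving this intensity."""
        if intensity <= 0:
            raise ValueError("intensity must be positive to interpolate")
        return float(np.exp((np.log(intensity) - self.intercept) / self.slope))


def fit_standard(dilutions, intensities, r2_threshold: float = 0.98) -> StandardCurve:
    """Fit the reference dilution series in log-log space.

    Points with non-positive intensity are unusable.  If the fit's R^2 falls
    below ``r2_threshold``, the highest-amount point (the usual saturation
    culprit) is dropped and the line refitted, as long as >= 3 points remain.
    """
    amounts = np.asarray(dilutions, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    ok = inten > 0
    amounts, inten = amounts[ok], inten[ok]
    order = np.argsort(amounts)
    amounts, inten = amounts[order], inten[order]
    if len(amounts) < 3:
        raise ValueError("need at least 3 dilution points with positive intensity")

    while True:
        res = stats.linregress(np.log(amounts), np.log(inten))
        r2 = float(res.rvalue ** 2)
        if r2 >= r2_threshold or len(amounts) <= 3:
            break
        amounts, inten = amounts[:-1], inten[:-1]
    if r2 < r2_threshold:
        logger.warning("standard curve R^2=%.4f below threshold %.3f", r2, r2_threshold)
    return StandardCurve(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
        used_points=len(amounts),
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


def relative_level(sample_s96: float, sample_dsdna: float,
                   ref_s96: float, ref_dsdna: float,
                   std_s96: StandardCurve, std_dsdna: StandardCurve,
                   allow_extrapolation: bool = False) -> float:
    """Hybrid level of a sample relative to the reference sample.

    Intensities (one per channel, typically from a mid-range dilution spot)
    are converted to relative DNA amounts through the channel's standard
    curve; the level is (S9.6/dsDNA)_sample / (S9.6/dsDNA)_reference, so the
    reference scores exactly 1 and membrane-wide exposure changes cancel.
    """
    def _amount(curve: StandardCurve, intensity: float, channel: str) -> float:
        a = curve.amount(intensity)
        lo, hi = curve.amount_range
        if not (lo <= a <= hi):
            msg = (f"{channel} intensity maps to amount {a:.3g} outside the "
                   f"standard range [{lo:.3g}, {hi:.3g}]")
            if not allow_extrapolation:
                raise ValueError(msg + "; pass allow_extrapolation=True to override")
            logger.warning("%s; extrapolating", msg)
        return a

    s = _amount(std_s96, sample_s96, "S9.6") / _amount(std_dsdna, sample_dsdna, "dsDNA")
    r = _amount(std_s96, ref_s96, "S9.6") / _amount(std_dsdna, ref_dsdna, "dsDNA")
    return s / r


def assign_quartiles(levels: pd.DataFrame) -> pd.DataFrame:
    """Split samples into quartiles by hybrid level; Q1 holds the highest.

    ``levels`` needs strain_id and relative_level columns (>= 4 rows).
    Samples are ranked descending, ties broken by stable input order, and cut
    into 4 contiguous rank blocks whose sizes differ by at most 1.
    """
    if len(levels) < 4:
        raise ValueError("need at least 4 samples for quartiles")
    order = levels["relative_level"].to_numpy()
    idx = np.argsort(-order, kind="stable")
    blocks = np.array_split(idx, 4)
    out = levels.copy()
    out["quartile"] = ""
    for q, block in enumerate(blocks, start=1):
        out.iloc[block, out.columns.get_loc("quartile")] = f"Q{q}"
    return out


def classify_de(log2_fc: float, p_value: float, fc_thresh: float = 0.58,
                p_thresh: float = 0.05) -> str:
    """Post-hoc differential-expression category from printed thresholds.

    up if log2FC > fc_thresh and p < p_thresh (strict inequalities), down if
    log2FC < -fc_thresh and p < p_thresh, else unaffected.
    """
    if not (np.isfinite(log2_fc) and np.isfinite(p_value)):
        raise ValueError("log2_fc and p_value must be finite")
    if p_value < p_thresh:
        if log2_fc > fc_thresh:
            return "up"
        if log2_fc < -fc_thresh:
            return "down"
    return "unaffected"


def classify_de_table(de: pd.DataFrame, fc_thresh: float = 0.58,
                      p_thresh: float = 0.05) -> pd.DataFrame:
    out = de.copy()
    out["category"] = [classify_de(fc, p, fc_thresh, p_thresh)
                       for fc, p in zip(out["log2_fc"], out["p_value"])]
    return out


def correlate_levels_recombination(levels, recombination) -> dict:
    """Spearman rank correlation between hybrid levels and recombination.

    Both inputs are paired numeric sequences (>= 5 observations).  Returns
    ``{"rho", "p_value", "n"}``; a constant input vector makes the
    correlation undefined (rho = NaN, flagged).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(recombination, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input vector: correlation undefined")
        return {"rho": float("nan"), "p_value": float("nan"), "n": len(x)}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": len(x)}


def _tukey_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {"n": int(len(values)), "q1": float(q1), "median": float(med),
            "q3": float(q3), "whisker_low": float(lo), "whisker_high": float(hi)}


def stratified_fold_change(fold_changes: pd.DataFrame) -> dict:
    """Hybrid fold-change distributions stratified by DE category.

    ``fold_changes`` needs ``fold_change`` and ``category`` columns.  Returns
    Tukey box summaries per category and two-sided Mann-Whitney rank-sum
    p-values for every category pair; pairs with an empty side are skipped
    with a warning.
    """
    summaries, tests = {}, {}
    cats = ["up", "down", "unaffected"]
    groups = {c: fold_changes.loc[fold_changes["category"] == c, "fold_change"].to_numpy()
              for c in cats}
    for c, v in groups.items():
        if len(v):
            summaries[c] = _tukey_summary(v)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            if len(groups[a]) == 0 or len(groups[b]) == 0:
                logger.warning("empty category in pair (%s, %s); comparison skipped", a, b)
                continue
            p = float(stats.mannwhitneyu(groups[a], groups[b],
                                         alternative="two-sided").pvalue)
            tests[f"{a}_vs_{b}"] = p
    return {"summaries": summaries, "tests": tests}
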