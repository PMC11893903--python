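"""Scoring of the flow-cytometry hyper-recombination screen (screen I).

Each well measurement is the fraction of fluorescent (recombined) cells for
one strain on one plate.  Scoring proceeds in four steps: plate-median
normalization, a percentile prescreen against pooled wild-type wells,
construction of pooled wild-type comparison groups, and per-strain
recombination indices (0-100 percentile statistics) plus two-sided
Mann-Whitney p-values against the pooled wild-type distribution.

A recombination index of 100 means every wild-type measurement in the
comparison group was lower than the mutant measurement (hyper-recombination);
0 means every wild-type measurement was higher (hypo-recombination).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def plate_normalize(measurements: pd.DataFrame) -> pd.DataFrame:
    """Divide each well's fraction by the median of its plate.

    Requires columns strain_id/plate_id/replicate/frac_positive/is_wt; every
    plate must have at least 3 wells and a positive median.  Returns a copy
    with an added ``norm_value`` column.
    """
    out = measurements.copy()
    if ((out["frac_positive"] < 0) | (out["frac_positive"] > 1)).any():
        raise ValueError("frac_positive must lie in [0, 1]")
    medians = out.groupby("plate_id")["frac_positive"].median()
    sizes = out.groupby("plate_id").size()
    small = sizes[sizes < 3]
    if not small.empty:
        raise ValueError(f"plates with fewer than 3 wells: {list(small.index)}")
    zero = medians[medians <= 0]
    if not zero.empty:
        raise ValueError(f"plate median is zero for plates: {list(zero.index)}")
    out["norm_value"] = out["frac_positive"] / out["plate_id"].map(medians)
    return out


def prescreen_hits(normalized: pd.DataFrame, percentile: float = 95.0,
                   min_reps: int = 2, n_reps: int = 4) -> list[str]:
    """Strains above the pooled-wt percentile threshold in >= min_reps replicates.

    The threshold is the given percentile of all wild-type ``norm_value``s
    (linear-interpolation definition).  Strains may have up to ``n_reps``
    replicate values.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    wt = normalized.loc[normalized["is_wt"], "norm_value"].to_numpy()
    if wt.size == 0:
        raise ValueError("no wild-type measurements to define the threshold")
    threshold = float(np.percentile(wt, percentile))
    hits = []
    for strain, grp in normalized[~normalized["is_wt"]].groupby("strain_id", sort=True):
        if len(grp) > n_reps:
            raise ValueError(f"strain {strain!r} has more than n_reps={n_reps} replicates")
        if int((grp["norm_value"] > threshold).sum()) >= min_reps:
            hits.append(strain)
    return hits


def build_comparison_groups(wt_normalized: pd.DataFrame, n_groups: int = 10,
                            by_batch: bool = False, seed: int = 0) -> dict:
    """Partition pooled wild-type measurements into comparison groups.

    Random mode (default): a seeded equal-size partition (sizes differ by at
    most 1).  Batch mode: groups follow the ``batch`` column, which must
    contain exactly ``n_groups`` distinct labels.  Returns
    ``{"groups": [arrays], "assignment": {batch_or_index: group_idx}}``.
    """
    values = wt_normalized["norm_value"].to_numpy()
    if len(values) < n_groups:
        raise ValueError("fewer wild-type measurements than groups requested")
    if by_batch:
        if "batch" not in wt_normalized:
            raise ValueError("by_batch requires a 'batch' column")
        batches = sorted(wt_normalized["batch"].unique())
        if len(batches) != n_groups:
            raise ValueError(f"found {len(batches)} batches, expected {n_groups}")
        groups = [wt_normalized.loc[wt_normalized["batch"] == b, "norm_value"].to_numpy()
                  for b in batches]
        assignment = {b: i for i, b in enumerate(batches)}
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(values))
        groups = [values[idx] for idx in np.array_split(perm, n_groups)]
        assignment = {int(i): int(g) for g, idx in
                      enumerate(np.array_split(perm, n_groups)) for i in idx}
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty comparison group")
    return {"groups": groups, "assignment": assignment}


def recombination_index(value: float, group: np.ndarray) -> float:
    """Percentile of the wild-type comparison group below ``value``, 0-100.

    Ties are split with midranks: index = 100 x (#{w < v} + 0.5 #{w = v}) / n.
    Returns exactly 100 when the value exceeds every group member and 0 when
    every member is larger.
    """
    group = np.asarray(group, dtype=float)
    if group.size == 0:
        raise ValueError("empty comparison group")
    lower = np.count_nonzero(group < value)
    equal = np.count_nonzero(group == value)
    return 100.0 * (lower + 0.5 * equal) / group.size


def score_strains(normalized: pd.DataFrame, groups: dict,
                  group_of_strain: dict | None = None,
                  p_thresh: float = 0.05,
                  add_bh: bool = True) -> pd.DataFrame:
    """Score every non-wt strain against its pooled wild-type comparison group.

    Per strain: recombination indices of each measurement against the group,
    the median index, a two-sided Mann-Whitney rank-sum p-value of the
    strain's normalized values against the group, and a direction call
    (hyper if median index > 50 and p < p_thresh, hypo if < 50, else none).
    ``group_of_strain`` maps strain_id -> group index (default: group 0 for
    all, preserving the pooled-but-grouped structure).  Output is sorted by
    p-value; an optional Benjamini-Hochberg column is appended.
    """
    group_list = groups["groups"]
    rows = []
    for strain, grp in normalized[~normalized["is_wt"]].groupby("strain_id", sort=True):
        values = grp["norm_value"].to_numpy()
        if values.size == 0:
            logger.warning("strain %s has no measurements; skipped", strain)
            continue
        gidx = (group_of_strain or {}).get(strain, 0)
        wt_group = np.asarray(group_list[gidx], dtype=float)
        indices = [recombination_index(v, wt_group) for v in values]
        median_index = float(np.median(indices))
        p = float(stats.mannwhitneyu(values, wt_group, alternative="two-sided").pvalue)
        if p < p_thresh and median_index > 50:
            direction = "hyper"
        elif p < p_thresh and median_index < 50:
            direction = "hypo"
        else:
            direction = "none"
        rows.append((strain, gidx, median_index, p, direction, indices))
    result = pd.DataFrame(
        rows, columns=["strain_id", "group", "median_index", "p_value",
                       "direction", "indices"],
    ).sort_values("p_value", kind="mergesort").reset_index(drop=True)
    if add_bh and len(result):
        result["p_bh"] = _benjamini_hochberg(result["p_value"].to_numpy())
    return result


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
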