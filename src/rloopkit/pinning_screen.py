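"""Scoring of the replica-pinning hyper-recombination screen (screen II).

Strains are arrayed at 16 positions and pinned onto 3 selective plates,
giving 48 independent colony calls per strain.  Colonies are called positive
by a size threshold, strains with poor pre-selection growth are excluded,
and each remaining strain's recombinant frequency is compared to the pooled
wild-type calls with a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def call_colonies(grids: pd.DataFrame, size_threshold: float) -> pd.DataFrame:
    """Set the ``positive`` call: colony_size >= size_threshold.

    The boundary counts as positive.  Requires a non-negative
    ``colony_size`` column; returns a copy with ``positive`` added.
    """
    if size_threshold <= 0:
        raise ValueError("size threshold must be positive")
    if (grids["colony_size"] < 0).any():
        raise ValueError("negative colony sizes")
    out = grids.copy()
    out["positive"] = out["colony_size"] >= size_threshold
    logger.info("called colonies at size threshold %.3g", size_threshold)
    return out


def filter_growth(grids: pd.DataFrame, min_fraction: float = 0.75
                  ) -> tuple[list[str], list[str]]:
    """Split strains into kept/excluded by pre-selection growth.

    A strain is excluded when the fraction of its positions with
    ``growth_ok`` falls below ``min_fraction``; excluded strains never
    receive p-values downstream.
    """
    kept, excluded = [], []
    for strain, grp in grids.groupby("strain_id", sort=True):
        frac_ok = float(grp["growth_ok"].mean())
        (kept if frac_ok >= min_fraction else excluded).append(strain)
    return kept, excluded


def score_pinning(grids: pd.DataFrame, wt_calls: pd.DataFrame | np.ndarray,
                  growth_min_fraction: float = 0.75) -> pd.DataFrame:
    """Recombinant frequency and Fisher exact p-value per strain.

    ``grids`` must carry ``positive`` calls (see :func:`call_colonies`);
    ``wt_calls`` is the pooled wild-type reference, either a boolean array of
    calls or a called grid DataFrame.  The 2x2 table per strain is
    [[strain+, strain-], [wt+, wt-]], tested two-sided.
    """
    if isinstance(wt_calls, pd.DataFrame):
        wt = wt_calls["positive"].to_numpy(dtype=bool)
    else:
        wt = np.asarray(wt_calls, dtype=bool)
    if wt.size == 0:
        raise ValueError("empty pooled wild-type reference")
    wt_pos = int(wt.sum())
    wt_neg = int(wt.size - wt_pos)

    kept, excluded = filter_growth(grids, growth_min_fraction)
    rows = []
    for strain, grp in grids.groupby("strain_id", sort=True):
        n_calls = int(len(grp))
        if n_calls == 0:
            logger.warning("strain %s has no calls; excluded", strain)
            continue
        n_pos = int(grp["positive"].sum())
        is_excluded = strain in set(excluded)
        if is_excluded:
            p = np.nan
        else:
            table = [[n_pos, n_calls - n_pos], [wt_pos, wt_neg]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((strain, n_calls, n_pos, n_pos / n_calls, p, is_excluded))
    result = pd.DataFrame(
        rows, columns=["strain_id", "n_calls", "n_positive", "frequency",
                       "p_value", "excluded"],
    )
    # excluded strains trail the ranked output and carry no p-value
    ranked = result[~result["excluded"]].sort_values("p_value", kind="mergesort")
    return pd.concat([ranked, result[result["excluded"]]]).reset_index(drop=True)
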