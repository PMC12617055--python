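"""Expression-divergence statistic for directional selection on expression.

For each gene the statistic compares divergence of mean expression between a
focal species and a related species with the within-focal-species replicate
spread, on log2(TPM + pseudocount) values:

    d = (mean_focal - mean_related) / mean_focal      (relative divergence)
    r = (max_focal - min_focal) / mean_focal          (relative range)
    f = sqrt((m*N - 1) / (m*N - m))                   (sample-size correction)
    delta_x = d / (f * r)

with m the focal sample size and N the reference (most common) sample size,
3 by default. |delta_x| > 1 flags putative directional selection: > 1
upregulation in the focal species, < -1 downregulation. Genes under
directional selection show both large between-species divergence and tight
replicate agreement, so the ratio rewards low within-species variance.

The printed form of d is ambiguous about parenthesisation; this module uses
d = (mean_focal - mean_related)/mean_focal, the reading in which d is a
relative (unitless) divergence like r. The alternative,
mean_focal - mean_related/mean_focal, is available via
``divergence_form="unnormalized_focal"`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DxRecord:
    gene_id: str
    d: float
    r: float
    f: float
    delta_x: float
    selection_class: str  # up | down | none | undefined


def sample_size_factor(m: int, N: int = 3) -> float:
    """f = sqrt((m*N - 1)/(m*N - m)); corrects the range for sample size m."""
    if m < 1:
        raise ValueError("sample size m must be >= 1")
    if m * N <= m:
        raise ValueError("m*N must exceed m (need N > 1)")
    return math.sqrt((m * N - 1) / (m * N - m))


def relative_range(values) -> float:
    """(max - min)/mean of the focal replicates; NaN when the mean is 0."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("relative range needs >= 2 replicate values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float((v.max() - v.min()) / mean)


def relative_divergence(
    focal_values, related_values, form: str = "relative"
) -> float:
    """Relative divergence d of focal vs related mean expression."""
    f = np.asarray(focal_values, float)
    r = np.asarray(related_values, float)
    if f.size == 0 or r.size == 0:
        raise ValueError("divergence needs at least one replicate per species")
    mf, mr = f.mean(), r.mean()
    if form == "relative":
        return float((mf - mr) / mf) if mf != 0 else float("nan")
    if form == "unnormalized_focal":
        return float(mf - mr / mf) if mf != 0 else float("nan")
    raise ValueError(f"unknown divergence form {form!r}")


def delta_x(
    focal_values,
    related_values,
    m: int | None = None,
    N: int = 3,
    gene_id: str = "",
    divergence_form: str = "relative",
) -> DxRecord:
    """The full statistic for one gene from log2-TPM replicate vectors."""
    focal = np.asarray(focal_values, float)
    if m is None:
        m = focal.size
    d = relative_divergence(focal, related_values, form=divergence_form)
    r = relative_range(focal)
    f = sample_size_factor(m, N)
    if not np.isfinite(d) or not np.isfinite(r) or r == 0:
        # mean_focal = 0 or zero range: statistic undefined rather than +/-inf
        dx = float("nan")
        cls = "undefined" if (not np.isfinite(d) or d != 0) else "none"
        if np.isfinite(d) and d == 0:
            dx, cls = 0.0, "none"
        return DxRecord(gene_id, d, r, f, dx, cls)
    dx = d / (f * r)
    cls = "up" if dx > 1 else ("down" if dx < -1 else "none")
    return DxRecord(gene_id, d, r, f, dx, cls)


def delta_x_table(
    focal: pd.DataFrame,
    related: pd.DataFrame,
    N: int = 3,
    divergence_form: str = "relative",
) -> pd.DataFrame:
    """Per-gene delta_x over two genes x replicates log2-TPM tables.

    Gene universes are intersected; the focal sample size m is the focal
    table's replicate count.
    """
    shared = focal.index.intersection(related.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between focal and related tables")
    F = focal.loc[shared].to_numpy(float)
    R = related.loc[shared].to_numpy(float)
    m = F.shape[1]
    if m < 2:
        raise ValueError("focal species needs >= 2 replicates")
    mf = F.mean(axis=1)
    mr = R.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if divergence_form == "relative":
            d = np.where(mf != 0, (mf - mr) / mf, np.nan)
        elif divergence_form == "unnormalized_focal":
            d = np.where(mf != 0, mf - mr / mf, np.nan)
        else:
            raise ValueError(f"unknown divergence form {divergence_form!r}")
        r = np.where(mf != 0, (F.max(axis=1) - F.min(axis=1)) / mf, np.nan)
    f = sample_size_factor(m, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        dx = np.where(np.isfinite(d) & np.isfinite(r) & (r != 0), d / (f * r), np.nan)
    dx = np.where(np.isfinite(r) & (r == 0) & (d == 0), 0.0, dx)
    cls = np.full(len(shared), "none", dtype=object)
    cls[np.isfinite(dx) & (dx > 1)] = "up"
    cls[np.isfinite(dx) & (dx < -1)] = "down"
    cls[~np.isfinite(dx)] = "undefined"
    return pd.DataFrame(
        {
            "gene_id": shared,
            "d": d,
            "r": r,
            "f": f,
            "delta_x": dx,
            "selection_class": cls,
        }
    ).reset_index(drop=True)


def selection_enrichment(
    dx: pd.DataFrame,
    categories: pd.Series,
    category_a: str,
    category_b: str,
    undefined_policy: str = "exclude",
) -> dict:
    """Fisher test: are category-A genes under selection more often than B?

    The 2x2 table crosses (|delta_x| > 1 vs not) with gene category (e.g.
    SBG vs unbiased, female- vs male-biased). ``undefined_policy`` controls
    genes whose statistic is undefined: "exclude" drops them (default),
    "not_selected" counts them in the not-under-selection cell.
    """
    cats = categories.reindex(dx["gene_id"])
    sel = dx["selection_class"].to_numpy()
    defined = sel != "undefined"
    if undefined_policy == "exclude":
        mask = defined
        under = np.isin(sel, ("up", "down"))
    elif undefined_policy == "not_selected":
        mask = np.ones(len(sel), bool)
        under = np.isin(sel, ("up", "down"))
    else:
        raise ValueError(f"unknown undefined_policy {undefined_policy!r}")
    in_a = (cats.to_numpy() == category_a) & mask
    in_b = (cats.to_numpy() == category_b) & mask
    table = np.array(
        [
            [int((under & in_a).sum()), int((~under & in_a).sum())],
            [int((under & in_b).sum()), int((~under & in_b).sum())],
        ]
    )
    if table[0].sum() == 0 or table[1].sum() == 0:
        return {
            "table": table,
            "odds_ratio": float("nan"),
            "pvalue": float("nan"),
            "prop_a": float("nan"),
            "prop_b": float("nan"),
            "note": "empty category",
        }
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(odds),
        "pvalue": float(p),
        "prop_a": table[0, 0] / table[0].sum(),
        "prop_b": table[1, 0] / table[1].sum(),
    }
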