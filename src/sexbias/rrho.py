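"""Rank-rank hypergeometric overlap (RRHO) between two species' sex-bias profiles.

Each gene gets a signed degree of differential expression,
DDE = -log10(p) * sign(LFC), negative for female-biased and positive for
male-biased genes. Both species' gene lists (restricted to genes expressed in
both) are ranked by DDE (rank 1 = most female-biased), and for every pair of
list prefixes (i*stepsize, j*stepsize) the overlap between the two prefixes
is scored with a hypergeometric tail test. Concordant sex bias shows up as
signal along the grid diagonal; discordance in the anti-diagonal corners.
Grid p-values are corrected with Benjamini-Yekutieli, which is valid under
the arbitrary dependence the overlapping prefixes induce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


@dataclass(frozen=True)
class RRHOMap:
    stepsize: int
    n_genes: int
    overlap: np.ndarray  # (K, K) counts, cell (i, j) = |top_{i+1}(A) & top_{j+1}(B)|
    pvalue: np.ndarray  # directional hypergeometric tail p per cell
    direction: np.ndarray  # +1 over-enrichment, -1 depletion
    signed_score: np.ndarray  # direction * -log10(p)
    pvalue_by: np.ndarray | None = None
    signed_score_by: np.ndarray | None = None


def compute_dde(de: pd.DataFrame, p_source: str = "padj", p_floor: float = P_FLOOR) -> pd.DataFrame:
    """Signed degree of differential expression per gene.

    dde = -log10(p) * sign(lfc), with p floored at ``p_floor`` to avoid
    infinities; genes with missing p are dropped. lfc = 0 gives dde = 0.
    """
    if p_source not in ("pvalue", "padj"):
        raise ValueError("p_source must be 'pvalue' or 'padj'")
    ok = de[p_source].notna()
    sub = de.loc[ok, ["gene_id", "lfc", p_source]].copy()
    p = np.maximum(sub[p_source].to_numpy(float), p_floor)
    sub["dde"] = -np.log10(p) * np.sign(sub["lfc"].to_numpy(float))
    return sub[["gene_id", "lfc", "dde"]].reset_index(drop=True)


def default_stepsize(n_genes: int) -> int:
    """ceil(sqrt(n)): the conventional RRHO bin width."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    return math.ceil(math.sqrt(n_genes))


def _ranked_positions(profile: pd.DataFrame) -> pd.Series:
    """1-based rank by ascending dde (most female-biased first), ties by gene id."""
    ordered = profile.sort_values(["dde", "gene_id"], kind="mergesort")
    return pd.Series(np.arange(1, len(ordered) + 1), index=ordered["gene_id"].to_numpy())


def rrho_map(
    profile_a: pd.DataFrame, profile_b: pd.DataFrame, stepsize: int | None = None
) -> RRHOMap:
    """Hypergeometric overlap grid between two ranked DDE profiles.

    Profiles are intersected on gene id first. Cell (i, j) tests the overlap
    of the first (i+1)*stepsize genes of A with the first (j+1)*stepsize of
    B against the hypergeometric null; its p-value is the tail matching the
    observed direction (over- vs under-enrichment relative to expectation).
    """
    shared = pd.Index(profile_a["gene_id"]).intersection(profile_b["gene_id"])
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes for an RRHO map")
    a = profile_a[profile_a["gene_id"].isin(shared)]
    b = profile_b[profile_b["gene_id"].isin(shared)]
    n = len(shared)
    if stepsize is None:
        stepsize = default_stepsize(n)
    if stepsize < 1:
        raise ValueError("stepsize must be >= 1")
    pos_a = _ranked_positions(a)
    pos_b = _ranked_positions(b)
    pos_b = pos_b.reindex(pos_a.index)
    K = math.ceil(n / stepsize)
    # genes binned by prefix index; 2D cumulative sum yields all overlaps
    bin_a = (pos_a.to_numpy() - 1) // stepsize
    bin_b = (pos_b.to_numpy() - 1) // stepsize
    hist = np.zeros((K, K))
    np.add.at(hist, (bin_a, bin_b), 1)
    overlap = hist.cumsum(axis=0).cumsum(axis=1)
    sizes = np.minimum((np.arange(1, K + 1)) * stepsize, n)
    sa = sizes[:, None]
    sb = sizes[None, :]
    expected = sa * sb / n
    over = overlap >= expected
    p_over = stats.hypergeom.sf(overlap - 1, n, sa, sb)
    p_under = stats.hypergeom.cdf(overlap, n, sa, sb)
    pvalue = np.where(over, p_over, p_under)
    direction = np.where(over, 1, -1)
    signed = direction * -np.log10(np.maximum(pvalue, P_FLOOR))
    return RRHOMap(
        stepsize=int(stepsize),
        n_genes=n,
        overlap=overlap.astype(int),
        pvalue=pvalue,
        direction=direction,
        signed_score=signed,
    )


def adjust_by(rrho: RRHOMap) -> RRHOMap:
    """Benjamini-Yekutieli step-up over all grid cells; scores recomputed."""
    flat = rrho.pvalue.ravel()
    corrected = stats.false_discovery_control(flat, method="by").reshape(rrho.pvalue.shape)
    signed = rrho.direction * -np.log10(np.maximum(corrected, P_FLOOR))
    return replace(rrho, pvalue_by=corrected, signed_score_by=signed)


def concordance_summary(profile_a: pd.DataFrame, profile_b: pd.DataFrame) -> dict:
    """Sign concordance and Spearman correlation of two DDE profiles.

    ``proportion_concordant`` is the fraction of shared genes whose DDE signs
    agree, among genes with nonzero DDE in both species; ``spearman_rho`` is
    over all shared genes.
    """
    merged = profile_a.merge(profile_b, on="gene_id", suffixes=("_a", "_b"))
    if len(merged) < 10:
        raise ValueError("need >= 10 shared genes for a concordance summary")
    da = merged["dde_a"].to_numpy(float)
    db = merged["dde_b"].to_numpy(float)
    if (da == 0).all() or (db == 0).all():
        return {"proportion_concordant": float("nan"), "spearman_rho": float("nan"),
                "n_tested": len(merged), "n_signed": 0}
    rho = stats.spearmanr(da, db).statistic
    signed = (da != 0) & (db != 0)
    n_signed = int(signed.sum())
    prop = float((np.sign(da[signed]) == np.sign(db[signed])).mean()) if n_signed else float("nan")
    return {
        "proportion_concordant": prop,
        "spearman_rho": float(rho),
        "n_tested": len(merged),
        "n_signed": n_signed,
    }
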