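"""Chromosome-level landscape of sex-biased expression.

Genes are partitioned, per species, into sex-chromosome (one label per
declared sex-linked linkage group), autosome, and excluded (mitochondrial or
on unplaced scaffolds; these never enter sex-chromosome-vs-autosome
contrasts). A species with unknown heterogamety contributes no
sex-chromosome labels. On top of this classing the module reports SBG
proportions per chromosome, Fisher enrichment of SBGs on a chromosome vs the
autosomes, cross-species sharing of sex-biased genes, rank tests on LFC
between chromosome groups, and feminisation/masculinisation summaries
(median SBG LFC, mean |LFC| of FBGs and MBGs, FBG:MBG ratio per group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    chromosome: str
    table: np.ndarray  # [[focal SBG, focal non-SBG], [autosome SBG, autosome non-SBG]]
    odds_ratio: float
    fisher_p: float
    direction: str  # enriched | depleted | none


def classify_chromosomes(
    annotation: pd.DataFrame, sex_systems: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Per-gene chromosome class for one species.

    Returns columns gene_id, chromosome, chrom_class in
    {sex_chromosome, autosome, excluded} and sex_linked_lg (the linkage-group
    name when sex-linked, else NA). Mitochondrial and unplaced genes are
    excluded regardless of the declared list.
    """
    row = sex_systems[sex_systems["species"] == species]
    if len(row) == 0:
        raise KeyError(f"species {species!r} missing from the sex-system table")
    sex_linked = list(row.iloc[0]["sex_linked_chromosomes"])
    present = set(annotation["chromosome"].astype(str))
    missing = [c for c in sex_linked if c not in present]
    if missing:
        raise ValueError(f"declared sex-linked chromosomes absent from annotation: {missing}")
    out = annotation[["gene_id", "chromosome"]].copy()
    excluded = annotation["is_mitochondrial"].to_numpy() | ~annotation["is_placed"].to_numpy()
    on_sex = annotation["chromosome"].astype(str).isin(sex_linked).to_numpy() & ~excluded
    cls = np.where(excluded, "excluded", np.where(on_sex, "sex_chromosome", "autosome"))
    out["chrom_class"] = cls
    out["sex_linked_lg"] = np.where(on_sex, annotation["chromosome"].astype(str), pd.NA)
    return out.reset_index(drop=True)


def _merge(de: pd.DataFrame, classing: pd.DataFrame) -> pd.DataFrame:
    merged = de.merge(classing, on="gene_id", how="left")
    if merged["chrom_class"].isna().any():
        missing = merged.loc[merged["chrom_class"].isna(), "gene_id"].tolist()[:5]
        raise KeyError(f"classing does not cover tested genes, e.g. {missing}")
    return merged


def sbg_proportions(de: pd.DataFrame, classing: pd.DataFrame, by: str = "all") -> pd.DataFrame:
    """SBG count and proportion of expressed genes, per chromosome.

    ``by`` selects all SBGs, or only FBGs / MBGs. Denominator: expressed
    (tested) genes on that chromosome.
    """
    if by not in ("all", "FBG", "MBG"):
        raise ValueError("by must be one of all|FBG|MBG")
    merged = _merge(de, classing)
    wanted = ("FBG", "MBG") if by == "all" else (by,)
    merged["is_hit"] = merged["bias_class"].isin(wanted)
    grp = merged.groupby("chromosome", sort=True)
    out = grp.agg(
        n_expressed=("gene_id", "size"),
        n_sbg=("is_hit", "sum"),
        chrom_class=("chrom_class", "first"),
    ).reset_index()
    out["proportion"] = np.where(
        out["n_expressed"] > 0, out["n_sbg"] / out["n_expressed"], np.nan
    )
    return out


def enrichment_fisher(
    de: pd.DataFrame,
    classing: pd.DataFrame,
    chromosome: str,
    bias: str = "all",
    exclude_chromosomes: tuple[str, ...] = (),
) -> EnrichmentResult:
    """Two-sided Fisher test: SBGs on ``chromosome`` vs on the autosomes.

    Excluded (mitochondrial/unplaced) genes are removed; additional
    chromosomes can be left out of the autosomal background via
    ``exclude_chromosomes`` (used when a species has two sex-linked LGs).
    """
    merged = _merge(de, classing)
    merged = merged[merged["chrom_class"] != "excluded"]
    wanted = ("FBG", "MBG") if bias == "all" else (bias,)
    is_sbg = merged["bias_class"].isin(wanted).to_numpy()
    on_chrom = (merged["chromosome"].astype(str) == chromosome).to_numpy()
    background = (
        (merged["chrom_class"] == "autosome")
        & ~merged["chromosome"].astype(str).isin(set(exclude_chromosomes) | {chromosome})
    ).to_numpy()
    table = np.array(
        [
            [int((is_sbg & on_chrom).sum()), int((~is_sbg & on_chrom).sum())],
            [int((is_sbg & background).sum()), int((~is_sbg & background).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    prop_chrom = table[0, 0] / table[0].sum() if table[0].sum() else np.nan
    prop_auto = table[1, 0] / table[1].sum() if table[1].sum() else np.nan
    if np.isnan(prop_chrom) or np.isnan(prop_auto) or prop_chrom == prop_auto:
        direction = "none"
    else:
        direction = "enriched" if prop_chrom > prop_auto else "depleted"
    return EnrichmentResult(chromosome, table, float(odds), float(p), direction)


def shared_sbg_fisher(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    classing: pd.DataFrame,
    chromosome: str,
    bias: str = "FBG",
    exclude_chromosomes: tuple[str, ...] = (),
) -> EnrichmentResult:
    """Do two species share more genes of a bias type on one chromosome?

    Gene universes are intersected; a gene counts as shared when it carries
    the same bias class in both species. The 2x2 table crosses shared/not
    with chromosome/autosomes (two-sided Fisher).
    """
    shared_genes = pd.Index(de_a["gene_id"]).intersection(de_b["gene_id"])
    if len(shared_genes) == 0:
        raise ValueError("species have no genes in common")
    a = de_a.set_index("gene_id").loc[shared_genes]
    b = de_b.set_index("gene_id").loc[shared_genes]
    shared_bias = (a["bias_class"] == bias) & (b["bias_class"] == bias)
    pseudo = pd.DataFrame(
        {
            "gene_id": shared_genes,
            "bias_class": np.where(shared_bias.to_numpy(), bias, "unbiased"),
        }
    )
    res = enrichment_fisher(pseudo, classing, chromosome, bias=bias,
                            exclude_chromosomes=exclude_chromosomes)
    return res


def lfc_distribution_tests(
    de: pd.DataFrame, classing: pd.DataFrame, groups: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Rank tests on SBG LFC values between chromosome groups.

    Two groups: Wilcoxon-Mann-Whitney; three or more: Kruskal-Wallis.
    ``groups`` maps group name -> chromosome names; by default the groups are
    the chromosome classes sex_chromosome vs autosome. Only SBGs enter.
    """
    merged = _merge(de, classing)
    sbg = merged[merged["bias_class"].isin(("FBG", "MBG"))]
    if groups is None:
        samples = {
            name: sub["lfc"].to_numpy(float)
            for name, sub in sbg.groupby("chrom_class")
            if name != "excluded"
        }
    else:
        samples = {
            name: sbg.loc[sbg["chromosome"].astype(str).isin(chroms), "lfc"].to_numpy(float)
            for name, chroms in groups.items()
        }
    samples = {k: v for k, v in samples.items() if len(v) >= 2}
    if len(samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 SBGs each")
    names = sorted(samples)
    if len(names) == 2:
        test = "wilcoxon_mann_whitney"
        stat, p = stats.mannwhitneyu(samples[names[0]], samples[names[1]],
                                     alternative="two-sided")
    else:
        test = "kruskal_wallis"
        stat, p = stats.kruskal(*[samples[n] for n in names])
    return pd.DataFrame(
        [
            {
                "test": test,
                "groups": ",".join(names),
                "group_sizes": ",".join(str(len(samples[n])) for n in names),
                "statistic": float(stat),
                "pvalue": float(p),
            }
        ]
    )


def feminisation_summary(de: pd.DataFrame, classing: pd.DataFrame) -> pd.DataFrame:
    """Feminisation/masculinisation metrics per chromosome group.

    For each chromosome class (and each sex-linked LG separately): median LFC
    of SBGs (negative = feminised), mean |LFC| of FBGs and of MBGs, and the
    FBG:MBG count ratio. Groups without SBGs get NaN metrics.
    """
    merged = _merge(de, classing)
    merged = merged[merged["chrom_class"] != "excluded"]
    groups: list[tuple[str, pd.DataFrame]] = [("autosome", merged[merged["chrom_class"] == "autosome"])]
    sexpart = merged[merged["chrom_class"] == "sex_chromosome"]
    if len(sexpart):
        groups.append(("sex_chromosome", sexpart))
        for lg, sub in sexpart.groupby("sex_linked_lg"):
            groups.append((f"sex_chromosome:{lg}", sub))
    rows = []
    for name, sub in groups:
        sbg = sub[sub["bias_class"].isin(("FBG", "MBG"))]
        fbg = sbg[sbg["bias_class"] == "FBG"]
        mbg = sbg[sbg["bias_class"] == "MBG"]
        rows.append(
            {
                "group": name,
                "n_genes": len(sub),
                "n_sbg": len(sbg),
                "n_fbg": len(fbg),
                "n_mbg": len(mbg),
                "median_sbg_lfc": float(sbg["lfc"].median()) if len(sbg) else np.nan,
                "mean_abs_lfc_fbg": float(fbg["lfc"].abs().mean()) if len(fbg) else np.nan,
                "mean_abs_lfc_mbg": float(mbg["lfc"].abs().mean()) if len(mbg) else np.nan,
                "fbg_mbg_ratio": (len(fbg) / len(mbg)) if len(mbg) else np.nan,
            }
        )
    return pd.DataFrame(rows)
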