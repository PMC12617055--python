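"""Synthetic multi-species, two-sex, multi-tissue RNA-seq count generator.

The generator emulates the design of a bulk RNA-seq study of closely related
cichlid species with young, homomorphic sex chromosomes: per species, five
tissues (gonad, brain, gills, liver, lower pharyngeal jaw) x two sexes x
three replicates, ~25,000 genes laid out on 22 linkage groups plus a
mitochondrial contig and unplaced scaffolds. Each species declares a sex
system (XY / ZW / unknown) with its sex-linked linkage group(s); the
fraction of sex-biased genes is higher on sex-linked chromosomes, and the
direction of bias there is skewed towards females in ZW species and towards
males in XY species (feminisation / masculinisation).

Counts are negative-binomial with variance mu + alpha*mu^2 around

    mu = 2^(baseline_g + tissue_effect_gt + s_j * lfc_g / 2) * size_factor_j

where s_j is +1 for males and -1 for females, so the male/female log2 ratio
of a gene equals its true lfc while its overall level is unchanged.

Randomness is split into one "universe" stream (gene baselines, lengths,
tissue effects, the shared sex-bias assignments) plus one stream per species
derived from the seed and a CRC-32 of the species name, so adding or
reordering species never perturbs another species' data. A configurable
fraction of sex-bias assignments is shared across species (same genes, same
sign and magnitude), giving downstream cross-species sharing and RRHO
concordance something real to recover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

TISSUES = ("gonad", "brain", "gills", "liver", "lower_pharyngeal_jaw")


def default_chromosomes(n_genes: int = 25000) -> list[tuple[str, int]]:
    """22 linkage groups, one mitochondrial contig, unplaced scaffolds."""
    n_mito = min(37, max(1, n_genes // 500))
    n_unplaced = max(2, int(round(n_genes * 0.03)))
    n_placed = n_genes - n_mito - n_unplaced
    if n_placed < 22:
        raise ValueError("n_genes too small for the default 22-linkage-group layout")
    base, extra = divmod(n_placed, 22)
    chroms = [(f"LG{i + 1:02d}", base + (1 if i < extra else 0)) for i in range(22)]
    chroms.append(("MT", n_mito))
    n_scaffolds = max(1, n_unplaced // 20)
    sbase, sextra = divmod(n_unplaced, n_scaffolds)
    chroms.extend(
        (f"scaffold_{i + 1:03d}", sbase + (1 if i < sextra else 0))
        for i in range(n_scaffolds)
    )
    return chroms


@dataclass
class SimConfig:
    """All knobs of the generator; defaults mirror the emulated study design."""

    n_genes: int = 25000
    chromosomes: list[tuple[str, int]] | None = None
    species_specs: list[tuple[str, str, tuple[str, ...]]] = field(
        default_factory=lambda: [("species_A", "ZW", ("LG05",))]
    )
    tissues: tuple[str, ...] = TISSUES
    replicates_per_sex: int = 3
    baseline_log_mean: float = 5.0  # log2 scale
    baseline_log_sd: float = 2.0
    tissue_effect_sd: float = 1.0  # log2 units
    dispersion: float = 0.15  # NB alpha, var = mu + alpha*mu^2
    sbg_fraction_autosome: float = 0.02
    sbg_fraction_sexchrom: float = 0.10
    female_bias_prob_sexchrom: float = 0.8  # applies to ZW; mirrored for XY
    lfc_magnitude_mean: float = 2.0  # |log2 fold change| of true SBGs
    lfc_magnitude_sd: float = 0.5
    library_size_spread: float = 1.5  # size factors log-uniform in [1/s, s]
    gene_length_range: tuple[int, int] = (200, 20000)  # bp
    outgroup_shift_fraction: float = 0.05  # unbiased genes with a divergence shift
    outgroup_shift_fraction_sbg: float = 0.40  # sex-biased genes with a shift
    outgroup_shift_magnitude: float = 2.0  # log2 units
    replicate_cv: float = 0.1  # within-species CV of the divergence tables
    shared_sbg_fraction: float = 0.7  # bias assignments shared across species
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosomes is None:
            self.chromosomes = default_chromosomes(self.n_genes)
        total = sum(n for _, n in self.chromosomes)
        if total != self.n_genes:
            raise ValueError(
                f"chromosome gene counts sum to {total}, expected n_genes={self.n_genes}"
            )
        for prop_name in (
            "sbg_fraction_autosome",
            "sbg_fraction_sexchrom",
            "female_bias_prob_sexchrom",
            "outgroup_shift_fraction",
            "outgroup_shift_fraction_sbg",
            "shared_sbg_fraction",
        ):
            v = getattr(self, prop_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prop_name}={v} outside [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.replicates_per_sex < 2:
            raise ValueError(
                "replicates_per_sex must be >= 2 (the relative range of a "
                "single replicate is undefined)"
            )
        for name, system, linked in self.species_specs:
            if system not in ("XY", "ZW", "unknown"):
                raise ValueError(f"unknown sex system {system!r} for {name}")
            if system == "unknown" and linked:
                raise ValueError(f"{name}: unknown system must not declare sex chromosomes")
            chrom_names = {c for c, _ in self.chromosomes}
            missing = set(linked) - chrom_names
            if missing:
                raise ValueError(f"{name}: sex-linked chromosomes not simulated: {missing}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the counts, for recovery tests."""

    lfc: pd.DataFrame  # long: gene_id, species, tissue, true_lfc, true_bias_class
    size_factors: pd.Series  # per sample
    shift: pd.DataFrame | None = None  # gene_id, true_shift (divergence sims)

    def lfc_for(self, species: str) -> pd.Series:
        """Per-gene true lfc of one species (constant across tissues)."""
        sub = self.lfc[self.lfc["species"] == species]
        return sub.drop_duplicates("gene_id").set_index("gene_id")["true_lfc"]

    def class_for(self, species: str) -> pd.Series:
        sub = self.lfc[self.lfc["species"] == species]
        return sub.drop_duplicates("gene_id").set_index("gene_id")["true_bias_class"]


def species_rng(seed: int, species: str) -> np.random.Generator:
    """Per-species stream: SeedSequence(seed) keyed by CRC-32 of the name."""
    key = zlib.crc32(species.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, key)))


def _universe_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def _annotation(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom_col = np.repeat(
        [c for c, _ in config.chromosomes], [n for _, n in config.chromosomes]
    )
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(config.n_genes)])
    starts = np.zeros(config.n_genes, dtype=int)
    offset = 0
    prev = None
    for i, c in enumerate(chrom_col):
        if c != prev:
            offset = 0
            prev = c
        starts[i] = offset
        offset += lengths[i] + 1000  # intergenic gap
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chrom_col,
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
            "is_mitochondrial": chrom_col == "MT",
            "is_placed": ~np.char.startswith(chrom_col.astype(str), "scaffold"),
        }
    )


def _shared_bias_draws(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Universe-level randomness behind the cross-species shared assignments."""
    n = config.n_genes
    return {
        "u_sbg": rng.random(n),
        "u_sign": rng.random(n),
        "magnitude": np.abs(rng.normal(config.lfc_magnitude_mean, config.lfc_magnitude_sd, n)),
        "is_shared": rng.random(n) < config.shared_sbg_fraction,
    }


def _species_lfc(
    config: SimConfig,
    annotation: pd.DataFrame,
    species: str,
    system: str,
    sex_linked: Sequence[str],
    shared: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """True per-gene log2 male/female fold changes for one species.

    A gene's assignment comes from the shared (universe) draws with
    probability ``shared_sbg_fraction`` and from the species' own stream
    otherwise; both routes use the same class-dependent fractions, so the
    marginal SBG fraction per chromosome class is unchanged.
    """
    n = config.n_genes
    on_sex = annotation["chromosome"].isin(sex_linked).to_numpy()
    frac = np.where(on_sex, config.sbg_fraction_sexchrom, config.sbg_fraction_autosome)
    if system == "ZW":
        p_female = np.where(on_sex, config.female_bias_prob_sexchrom, 0.5)
    elif system == "XY":
        p_female = np.where(on_sex, 1.0 - config.female_bias_prob_sexchrom, 0.5)
    else:
        p_female = np.full(n, 0.5)
    own = {
        "u_sbg": rng.random(n),
        "u_sign": rng.random(n),
        "magnitude": np.abs(rng.normal(config.lfc_magnitude_mean, config.lfc_magnitude_sd, n)),
    }
    use_shared = shared["is_shared"]
    u_sbg = np.where(use_shared, shared["u_sbg"], own["u_sbg"])
    u_sign = np.where(use_shared, shared["u_sign"], own["u_sign"])
    magnitude = np.where(use_shared, shared["magnitude"], own["magnitude"])
    is_sbg = u_sbg < frac
    sign = np.where(u_sign < p_female, -1.0, 1.0)  # negative lfc = female-biased
    return np.where(is_sbg, sign * magnitude, 0.0)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (counts, sample table, gene annotation, ground truth).

    The gene universe (ids, chromosomes, lengths, baselines, tissue effects)
    is shared across species — orthology by identifier. Deterministic for a
    given config, including the seed.
    """
    uni = _universe_rng(config.seed)
    annotation = _annotation(config, uni)
    n = config.n_genes
    baseline = uni.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    tissue_effects = {
        t: uni.normal(0.0, config.tissue_effect_sd, n) for t in config.tissues
    }
    shared = _shared_bias_draws(config, uni)

    columns: list[np.ndarray] = []
    sample_rows: list[dict] = []
    truth_rows: list[pd.DataFrame] = []
    sf_values: dict[str, float] = {}
    for species, system, sex_linked in config.species_specs:
        rng = species_rng(config.seed, species)
        lfc = _species_lfc(config, annotation, species, system, sex_linked, shared, rng)
        bias_class = np.where(lfc < 0, "FBG", np.where(lfc > 0, "MBG", "unbiased"))
        for tissue in config.tissues:
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": annotation["gene_id"],
                        "species": species,
                        "tissue": tissue,
                        "true_lfc": lfc,
                        "true_bias_class": bias_class,
                    }
                )
            )
        for tissue in config.tissues:
            for sex, s in (("female", -1.0), ("male", 1.0)):
                for rep in range(1, config.replicates_per_sex + 1):
                    sid = f"{species}_{tissue}_{sex}_{rep}"
                    log_spread = np.log(config.library_size_spread)
                    sf = float(np.exp(rng.uniform(-log_spread, log_spread)))
                    mu = np.exp2(baseline + tissue_effects[tissue] + s * lfc / 2.0) * sf
                    columns.append(_nb_counts(rng, mu, config.dispersion))
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "species": species,
                            "sex": sex,
                            "tissue": tissue,
                            "replicate": rep,
                        }
                    )
                    sf_values[sid] = sf
    samples = pd.DataFrame(sample_rows)
    cm = CountMatrix(
        pd.Index(annotation["gene_id"]),
        pd.Index(samples["sample_id"]),
        np.column_stack(columns),
    )
    truth = SimTruth(
        lfc=pd.concat(truth_rows, ignore_index=True),
        size_factors=pd.Series(sf_values, name="size_factor_true"),
    )
    return cm, samples, annotation, truth


def simulate_species_pair_for_dx(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Focal-vs-related expression tables for the divergence statistic.

    Both species share the gene universe. The related species draws linear
    (TPM-like) expression around the gene baseline; in the focal species a
    fraction of genes (higher among sex-biased ones) carries an additional
    log2 shift of ``outgroup_shift_magnitude``. Replicate noise is
    multiplicative log-normal with CV ``replicate_cv``. The tables represent
    one tissue of one sex, ``replicates_per_sex`` replicates each.

    Returns (focal genes x replicates, related genes x replicates, truth
    whose ``shift`` frame carries true_shift and the focal bias class).
    """
    uni = _universe_rng(config.seed)
    annotation = _annotation(config, uni)
    n = config.n_genes
    baseline = uni.normal(config.baseline_log_mean, config.baseline_log_sd, n)
    uni.normal(0.0, config.tissue_effect_sd, (len(config.tissues), n))  # keep stream aligned
    shared = _shared_bias_draws(config, uni)

    focal_name, system, sex_linked = config.species_specs[0]
    related_name = (
        config.species_specs[1][0] if len(config.species_specs) > 1 else "related"
    )
    frng = species_rng(config.seed, focal_name)
    lfc = _species_lfc(config, annotation, focal_name, system, sex_linked, shared, frng)
    is_sbg = lfc != 0
    shift_prob = np.where(
        is_sbg, config.outgroup_shift_fraction_sbg, config.outgroup_shift_fraction
    )
    shifted = frng.random(n) < shift_prob
    true_shift = np.where(shifted, config.outgroup_shift_magnitude, 0.0)

    sigma = np.sqrt(np.log1p(config.replicate_cv**2))
    m = config.replicates_per_sex
    rrng = species_rng(config.seed, related_name)
    focal_mean = np.exp2(baseline + true_shift)
    related_mean = np.exp2(baseline)
    focal = focal_mean[:, None] * np.exp(frng.normal(0.0, sigma, (n, m)) - sigma**2 / 2)
    related = related_mean[:, None] * np.exp(rrng.normal(0.0, sigma, (n, m)) - sigma**2 / 2)
    gene_index = pd.Index(annotation["gene_id"], name="gene_id")
    rep_cols = [f"rep{i + 1}" for i in range(m)]
    truth = SimTruth(
        lfc=pd.DataFrame(
            {
                "gene_id": annotation["gene_id"],
                "species": focal_name,
                "tissue": "pooled",
                "true_lfc": lfc,
                "true_bias_class": np.where(
                    lfc < 0, "FBG", np.where(lfc > 0, "MBG", "unbiased")
                ),
            }
        ),
        size_factors=pd.Series(dtype=float),
        shift=pd.DataFrame({"gene_id": annotation["gene_id"], "true_shift": true_shift}),
    )
    return (
        pd.DataFrame(focal, index=gene_index, columns=rep_cols),
        pd.DataFrame(related, index=gene_index, columns=rep_cols),
        truth,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["chromosomes"] = [list(c) for c in config.chromosomes]
    d["species_specs"] = [[s, sys_, list(l)] for s, sys_, l in config.species_specs]
    return d
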