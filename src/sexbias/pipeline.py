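"""End-to-end orchestration: simulate or load, DE in both designs, landscape,
divergence statistics and RRHO, with one JSON summary per run.

Every stage writes its tables under the output directory, so each module is
independently re-runnable from files. Runs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import io as io_mod
from . import landscape as land_mod
from . import normalize as norm_mod
from . import rrho as rrho_mod
from . import selection as sel_mod
from .simulate import SimConfig, simulate_dataset, config_to_dict

log = logging.getLogger("sexbias")

KNOWN_KEYS = {
    "simulate", "counts", "samples", "annotation", "sex_systems", "alpha",
    "pseudocount", "min_count", "min_samples_exclusive", "stepsize",
    "dx_pairs", "rrho_pairs", "out_dir", "seed", "log_level",
}


@dataclass
class RunConfig:
    sex_systems: list[dict]
    simulate: dict | None = None
    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    alpha: float = 0.05
    pseudocount: float = 1.0
    min_count: int = 5
    min_samples_exclusive: int = 3
    stepsize: int | str = "auto"
    dx_pairs: list[list[str]] = field(default_factory=list)
    rrho_pairs: list[list[str]] | None = None
    out_dir: str = "sexbias_out"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(source: str | Path | dict, strict: bool = True) -> RunConfig:
    """Parse and validate a YAML/JSON run config; raises with named errors."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    errors: list[str] = []
    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        msg = f"unknown config keys: {sorted(unknown)} (known: {sorted(KNOWN_KEYS)})"
        if strict:
            errors.append(msg)
        else:
            log.warning(msg)
            for k in unknown:
                raw.pop(k)
    if "sex_systems" not in raw:
        errors.append("sex_systems: required — list of {species, heterogamety, sex_linked_chromosomes}")
    has_sim = raw.get("simulate") is not None
    has_files = all(raw.get(k) for k in ("counts", "samples", "annotation"))
    if not has_sim and not has_files:
        errors.append("either simulate: {...} or counts/samples/annotation paths are required")
    alpha = raw.get("alpha", 0.05)
    if not 0 < alpha < 1:
        errors.append(f"alpha: {alpha} outside (0, 1)")
    declared = {s["species"] for s in raw.get("sex_systems", [])}
    for pair in raw.get("dx_pairs", []):
        if len(pair) != 2 or pair[0] == pair[1]:
            errors.append(f"dx_pairs: {pair} must name two distinct species")
        for sp in pair:
            if sp not in declared:
                errors.append(f"dx_pairs: species {sp!r} has no sex_systems entry")
    if errors:
        raise ValueError("invalid run config:\n  - " + "\n  - ".join(errors))
    return RunConfig(**raw)


def _sex_system_frame(config: RunConfig) -> pd.DataFrame:
    return io_mod.validate_sex_systems(pd.DataFrame(config.sex_systems))


def _load_or_simulate(config: RunConfig):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault(
            "species_specs",
            [
                (s["species"], s["heterogamety"],
                 tuple(s.get("sex_linked_chromosomes", []) or []))
                for s in config.sex_systems
            ],
        )
        sim = SimConfig(**sim_kwargs)
        cm, samples, annotation, truth = simulate_dataset(sim)
        return cm, samples, annotation, truth, sim
    cm = io_mod.read_counts(config.counts)
    samples = io_mod.read_samples(config.samples, cm)
    annotation = io_mod.read_annotation(config.annotation, counts=cm)
    return cm, samples, annotation, None, None


def run_full(config: RunConfig) -> dict:
    """Run every stage for every species and write the report bundle.

    Per species: tissue-combined and per-tissue DE tables plus the
    chromosome landscape; per configured pair: divergence (delta-x) tables
    with selection-enrichment tests, and RRHO grids with concordance
    summaries. Partial failures are isolated per species/stage and recorded
    in the summary.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sex_systems = _sex_system_frame(config)
    cm, samples, annotation, truth, sim = _load_or_simulate(config)
    summary: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "thresholds": {
            "min_count": config.min_count,
            "min_samples_exclusive": config.min_samples_exclusive,
            "pseudocount": config.pseudocount,
        },
        "n_genes_input": cm.n_genes,
        "n_samples": cm.n_samples,
        "species": {},
        "errors": [],
    }
    if sim is not None:
        io_mod.write_counts(cm, out_dir / "counts.tsv")
        io_mod.write_samples(samples, out_dir / "samples.tsv")
        io_mod.write_annotation(annotation, out_dir / "annotation.tsv")
        truth.lfc.to_csv(out_dir / "sim_truth_lfc.tsv", sep="\t", index=False)
        (out_dir / "sim_config.json").write_text(
            json.dumps(config_to_dict(sim), indent=2, default=str)
        )

    de_tables: dict[str, pd.DataFrame] = {}
    for species in samples["species"].unique():
        sp_dir = out_dir / species
        sp_dir.mkdir(exist_ok=True)
        sp_samples = samples[samples["species"] == species]
        sp_summary: dict = {}
        try:
            tissues = sorted(sp_samples["tissue"].unique())
            if len(tissues) >= 2:
                res = de_mod.run_de(
                    cm, sp_samples, de_mod.DesignSpec("tissue_combined"),
                    alpha=config.alpha, min_count=config.min_count,
                    min_samples_exclusive=config.min_samples_exclusive,
                )
            else:
                res = de_mod.run_de(
                    cm, sp_samples, de_mod.DesignSpec("tissue_specific"),
                    alpha=config.alpha, min_count=config.min_count,
                    min_samples_exclusive=config.min_samples_exclusive,
                )
            de_tables[species] = res
            res.to_csv(sp_dir / "de_tissue_combined.tsv", sep="\t", index=False)
            counts_by_class = res["bias_class"].value_counts().to_dict()
            sp_summary["tissue_combined"] = {
                "n_tested": len(res),
                "n_fbg": int(counts_by_class.get("FBG", 0)),
                "n_mbg": int(counts_by_class.get("MBG", 0)),
            }
            log.info(
                "%s tissue-combined: %d tested, %d FBG, %d MBG",
                species, len(res),
                counts_by_class.get("FBG", 0), counts_by_class.get("MBG", 0),
            )
            per_tissue = {}
            for tissue in tissues:
                t_samples = sp_samples[sp_samples["tissue"] == tissue]
                t_res = de_mod.run_de(
                    cm, t_samples, de_mod.DesignSpec("tissue_specific"),
                    alpha=config.alpha, min_count=config.min_count,
                    min_samples_exclusive=config.min_samples_exclusive,
                )
                t_res.to_csv(sp_dir / f"de_{tissue}.tsv", sep="\t", index=False)
                vc = t_res["bias_class"].value_counts().to_dict()
                per_tissue[tissue] = {
                    "n_tested": len(t_res),
                    "n_fbg": int(vc.get("FBG", 0)),
                    "n_mbg": int(vc.get("MBG", 0)),
                }
            sp_summary["per_tissue"] = per_tissue
        except Exception as exc:  # noqa: BLE001 - isolate per-species failures
            summary["errors"].append(f"de/{species}: {exc}")
            summary["species"][species] = sp_summary
            continue

        system = sex_systems.loc[sex_systems["species"] == species].iloc[0]
        try:
            classing = land_mod.classify_chromosomes(annotation, sex_systems, species)
            props = land_mod.sbg_proportions(de_tables[species], classing)
            props.to_csv(sp_dir / "sbg_proportions.tsv", sep="\t", index=False)
            fem = land_mod.feminisation_summary(de_tables[species], classing)
            fem.to_csv(sp_dir / "feminisation.tsv", sep="\t", index=False)
            enrich = {}
            if system["heterogamety"] != "unknown":
                for lg in system["sex_linked_chromosomes"]:
                    others = tuple(c for c in system["sex_linked_chromosomes"] if c != lg)
                    r = land_mod.enrichment_fisher(
                        de_tables[species], classing, lg, exclude_chromosomes=others
                    )
                    enrich[lg] = {"odds_ratio": r.odds_ratio, "fisher_p": r.fisher_p,
                                  "direction": r.direction}
            sp_summary["sex_chromosome_enrichment"] = enrich
            sp_summary["feminisation"] = fem.to_dict(orient="records")
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append(f"landscape/{species}: {exc}")
        summary["species"][species] = sp_summary

    # divergence statistic per configured (focal, related) pair
    summary["dx"] = {}
    for focal, related in config.dx_pairs:
        try:
            summary["dx"][f"{focal}_vs_{related}"] = _run_dx_pair(
                cm, samples, annotation, de_tables, focal, related, config, out_dir
            )
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append(f"dx/{focal}_vs_{related}: {exc}")

    # RRHO for species pairs
    summary["rrho"] = {}
    pairs = (
        config.rrho_pairs
        if config.rrho_pairs is not None
        else [list(p) for p in combinations(sorted(de_tables), 2)]
    )
    for a, b in pairs:
        try:
            summary["rrho"][f"{a}_vs_{b}"] = _run_rrho_pair(
                de_tables[a], de_tables[b], a, b, config, out_dir
            )
        except Exception as exc:  # noqa: BLE001
            summary["errors"].append(f"rrho/{a}_vs_{b}: {exc}")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=io_mod._json_default)
    return summary


def _run_dx_pair(cm, samples, annotation, de_tables, focal, related, config, out_dir):
    """delta-x per tissue and sex for one species pair, plus enrichment."""
    filtered = norm_mod.filter_low_counts(cm, config.min_count, config.min_samples_exclusive)
    tpm = norm_mod.tpm(filtered, annotation)
    log_tpm = norm_mod.log2_with_pseudocount(tpm, config.pseudocount)
    pair_summary = {}
    all_records = []
    bias = de_tables[focal].set_index("gene_id")["bias_class"]
    shared_tissues = sorted(
        set(samples.loc[samples["species"] == focal, "tissue"])
        & set(samples.loc[samples["species"] == related, "tissue"])
    )
    for tissue in shared_tissues:
        for sex in io_mod.SEXES:
            f_cols = samples[
                (samples["species"] == focal) & (samples["tissue"] == tissue)
                & (samples["sex"] == sex)
            ]["sample_id"]
            r_cols = samples[
                (samples["species"] == related) & (samples["tissue"] == tissue)
                & (samples["sex"] == sex)
            ]["sample_id"]
            if len(f_cols) < 2 or len(r_cols) < 1:
                continue
            dx = sel_mod.delta_x_table(log_tpm[list(f_cols)], log_tpm[list(r_cols)])
            dx.insert(0, "tissue", tissue)
            dx.insert(1, "sex", sex)
            all_records.append(dx)
            enr = sel_mod.selection_enrichment(dx, bias_map(bias), "SBG", "unbiased")
            pair_summary[f"{tissue}/{sex}"] = {
                "n_genes": len(dx),
                "prop_selected_sbg": enr["prop_a"],
                "prop_selected_unbiased": enr["prop_b"],
                "fisher_p": enr["pvalue"],
            }
    if all_records:
        pd.concat(all_records, ignore_index=True).to_csv(
            out_dir / f"dx_{focal}_vs_{related}.tsv", sep="\t", index=False
        )
    return pair_summary


def bias_map(bias_class: pd.Series) -> pd.Series:
    """Collapse FBG/MBG to 'SBG' for SBG-vs-unbiased selection contrasts."""
    return bias_class.map(lambda c: "SBG" if c in ("FBG", "MBG") else c)


def _run_rrho_pair(de_a, de_b, name_a, name_b, config, out_dir):
    prof_a = rrho_mod.compute_dde(de_a)
    prof_b = rrho_mod.compute_dde(de_b)
    stepsize = None if config.stepsize == "auto" else int(config.stepsize)
    rmap = rrho_mod.adjust_by(rrho_mod.rrho_map(prof_a, prof_b, stepsize))
    pd.DataFrame(rmap.signed_score_by).to_csv(
        out_dir / f"rrho_{name_a}_vs_{name_b}_by.tsv", sep="\t",
        index=False, header=False,
    )
    conc = rrho_mod.concordance_summary(prof_a, prof_b)
    conc["stepsize"] = rmap.stepsize
    conc["max_diagonal_score_by"] = float(np.max(np.diag(rmap.signed_score_by)))
    return conc
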