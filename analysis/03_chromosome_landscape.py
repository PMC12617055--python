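"""Chromosome landscape of sex bias.

For every species with a known sex system: SBG proportions per chromosome,
Fisher enrichment of SBGs on the sex-linked linkage group(s) vs autosomes,
rank tests on SBG fold changes between chromosome groups, and the
feminisation/masculinisation summary. Also tests whether the two ZW species
share more female-biased genes on their common sex chromosome than on
autosomes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import DATA_DIR, RESULTS

from sexbias import io
from sexbias.landscape import (
    classify_chromosomes,
    enrichment_fisher,
    feminisation_summary,
    lfc_distribution_tests,
    sbg_proportions,
    shared_sbg_fisher,
)


def main() -> None:
    annotation = io.read_annotation(DATA_DIR / "annotation.tsv")
    systems = io.read_sex_systems(DATA_DIR / "sex_systems.tsv")
    de_dir = RESULTS / "de"
    out = RESULTS / "landscape"
    out.mkdir(parents=True, exist_ok=True)

    de_tables = {
        row["species"]: pd.read_csv(
            de_dir / f"{row['species']}_tissue_combined.tsv", sep="\t"
        )
        for _, row in systems.iterrows()
    }

    enrich_rows = []
    for _, row in systems.iterrows():
        species = row["species"]
        classing = classify_chromosomes(annotation, systems, species)
        de = de_tables[species]
        sbg_proportions(de, classing).to_csv(
            out / f"{species}_sbg_proportions.tsv", sep="\t", index=False
        )
        fem = feminisation_summary(de, classing)
        fem.to_csv(out / f"{species}_feminisation.tsv", sep="\t", index=False)
        if row["heterogamety"] == "unknown":
            print(f"{species}: unknown sex system, excluded from sex-chromosome contrasts")
            continue
        for lg in row["sex_linked_chromosomes"]:
            others = tuple(c for c in row["sex_linked_chromosomes"] if c != lg)
            r = enrichment_fisher(de, classing, lg, exclude_chromosomes=others)
            enrich_rows.append(
                {"species": species, "chromosome": lg, "odds_ratio": r.odds_ratio,
                 "fisher_p": r.fisher_p, "direction": r.direction}
            )
            print(f"{species} {lg}: SBG enrichment OR={r.odds_ratio:.2f} "
                  f"p={r.fisher_p:.2e} ({r.direction})")
        med = fem.set_index("group").loc["sex_chromosome", "median_sbg_lfc"]
        rank = lfc_distribution_tests(de, classing)
        print(f"  median sex-chromosome SBG LFC {med:+.2f} "
              f"(sex vs autosome rank test p={rank['pvalue'].iloc[0]:.3g})")
    pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # do the two ZW species share FBGs on their common sex chromosome?
    classing = classify_chromosomes(annotation, systems, "zw_lg05_a")
    shared = shared_sbg_fisher(
        de_tables["zw_lg05_a"], de_tables["zw_lg05_lg13"], classing, "LG05", bias="FBG"
    )
    print(f"\nshared FBGs on LG05 (both ZW species): OR={shared.odds_ratio:.2f} "
          f"p={shared.fisher_p:.2e} ({shared.direction})")


if __name__ == "__main__":
    main()
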