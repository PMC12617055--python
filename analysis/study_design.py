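"""Shared study configuration for the numbered analysis scripts.

Five synthetic species emulate a clade with rapid sex-chromosome turnover:
two ZW species with LG05 sex-linked (one with an additional younger LG13
segment), an XY species with LG05, an XY species with LG15, and one species
whose sex system is unknown (it is excluded from sex-chromosome contrasts).
Each species: five tissues x two sexes x three replicates. Gene count is
desk-scale (4,000 genes on the standard 22-LG + MT + scaffold layout).
"""

from pathlib import Path

from sexbias.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"

SPECIES_SPECS = [
    ("zw_lg05_a", "ZW", ("LG05",)),
    ("zw_lg05_lg13", "ZW", ("LG05", "LG13")),
    ("xy_lg05", "XY", ("LG05",)),
    ("xy_lg15", "XY", ("LG15",)),
    ("unknown_sys", "unknown", ()),
]

SEX_SYSTEMS = [
    {"species": name, "heterogamety": system,
     "sex_linked_chromosomes": ",".join(linked)}
    for name, system, linked in SPECIES_SPECS
]

#: (focal, related) pairings for the divergence statistic: each sex-chromosome
#: species against the unknown-system outgroup, and the outgroup against the
#: most distant XY species.
DX_PAIRS = [
    ("zw_lg05_a", "unknown_sys"),
    ("zw_lg05_lg13", "unknown_sys"),
    ("xy_lg05", "unknown_sys"),
    ("unknown_sys", "xy_lg15"),
]

SEED = 20260921


def study_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        n_genes=4000,
        species_specs=SPECIES_SPECS,
        seed=seed,
    )
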