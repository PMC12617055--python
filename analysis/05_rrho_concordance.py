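"""Cross-species concordance of sex-biased expression via RRHO.

For every species pair: signed DDE profiles from the tissue-combined DE
tables, the BY-corrected rank-rank hypergeometric overlap grid, and the sign
concordance / Spearman correlation summary.
"""

import sys
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import RESULTS, SEX_SYSTEMS

from sexbias.rrho import adjust_by, compute_dde, concordance_summary, rrho_map


def main() -> None:
    out = RESULTS / "rrho"
    out.mkdir(parents=True, exist_ok=True)
    species = [s["species"] for s in SEX_SYSTEMS]
    profiles = {
        sp: compute_dde(
            pd.read_csv(RESULTS / "de" / f"{sp}_tissue_combined.tsv", sep="\t")
        )
        for sp in species
    }
    rows = []
    for a, b in combinations(species, 2):
        rmap = adjust_by(rrho_map(profiles[a], profiles[b]))
        pd.DataFrame(rmap.signed_score_by).to_csv(
            out / f"rrho_{a}_vs_{b}_by.tsv", sep="\t", index=False, header=False
        )
        conc = concordance_summary(profiles[a], profiles[b])
        diag_p = float(np.min(np.diag(rmap.pvalue_by)[:-1]))
        rows.append(
            {"pair": f"{a} vs {b}", "n_shared": conc["n_tested"],
             "concordant_pct": 100 * conc["proportion_concordant"],
             "spearman_rho": conc["spearman_rho"], "min_diag_by_p": diag_p}
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "concordance_summary.tsv", sep="\t", index=False)
    with pd.option_context("display.width", 120):
        print(summary.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
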