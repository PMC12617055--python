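"""Differential expression by sex, per species.

Fits the tissue-combined NB GLM (sex + tissue) and the per-tissue models
(sex only) for every species, writes the DE tables under results/de/, and
reports how many female- and male-biased genes each species shows.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import DATA_DIR, RESULTS

from sexbias import io
from sexbias.de import DesignSpec, run_de


def main() -> None:
    cm = io.read_counts(DATA_DIR / "counts.tsv")
    samples = io.read_samples(DATA_DIR / "samples.tsv", cm)
    out = RESULTS / "de"
    out.mkdir(parents=True, exist_ok=True)
    print(f"{'species':>14} {'tested':>7} {'FBG':>5} {'MBG':>5}  %SBG")
    for species in samples["species"].unique():
        sp = samples[samples["species"] == species]
        res = run_de(cm, sp, DesignSpec("tissue_combined"))
        res.to_csv(out / f"{species}_tissue_combined.tsv", sep="\t", index=False)
        vc = res["bias_class"].value_counts()
        fbg, mbg = vc.get("FBG", 0), vc.get("MBG", 0)
        print(f"{species:>14} {len(res):>7} {fbg:>5} {mbg:>5}  "
              f"{100 * (fbg + mbg) / len(res):.2f}%")
        for tissue in sorted(sp["tissue"].unique()):
            t_res = run_de(cm, sp[sp["tissue"] == tissue], DesignSpec("tissue_specific"))
            t_res.to_csv(out / f"{species}_{tissue}.tsv", sep="\t", index=False)
    print(f"\nDE tables written to {out}")


if __name__ == "__main__":
    main()
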