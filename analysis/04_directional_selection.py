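"""Directional selection on gene expression via the divergence statistic.

For each configured (focal, related) species pair, computes per-gene
delta_x = d/(f*r) from log2 TPM replicate values, separately per tissue and
sex, then asks (Fisher exact) whether sex-biased genes are under putative
directional selection (|delta_x| > 1) more often than unbiased genes, and
whether female-biased genes are under selection more often than male-biased
ones.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_design import DATA_DIR, DX_PAIRS, RESULTS

from sexbias import io
from sexbias.normalize import filter_low_counts, log2_with_pseudocount, tpm
from sexbias.pipeline import bias_map
from sexbias.selection import delta_x_table, selection_enrichment


def main() -> None:
    cm = io.read_counts(DATA_DIR / "counts.tsv")
    samples = io.read_samples(DATA_DIR / "samples.tsv", cm)
    annotation = io.read_annotation(DATA_DIR / "annotation.tsv")
    out = RESULTS / "dx"
    out.mkdir(parents=True, exist_ok=True)

    log_tpm = log2_with_pseudocount(tpm(filter_low_counts(cm), annotation))

    def replicate_cols(species, tissue, sex):
        sel = samples[
            (samples["species"] == species)
            & (samples["tissue"] == tissue)
            & (samples["sex"] == sex)
        ]
        return list(sel["sample_id"])

    for focal, related in DX_PAIRS:
        de = pd.read_csv(RESULTS / "de" / f"{focal}_tissue_combined.tsv", sep="\t")
        bias = de.set_index("gene_id")["bias_class"]
        records = []
        for tissue in sorted(samples["tissue"].unique()):
            for sex in ("female", "male"):
                f_cols = replicate_cols(focal, tissue, sex)
                r_cols = replicate_cols(related, tissue, sex)
                dx = delta_x_table(log_tpm[f_cols], log_tpm[r_cols])
                dx.insert(0, "tissue", tissue)
                dx.insert(1, "sex", sex)
                records.append(dx)
        table = pd.concat(records, ignore_index=True)
        table.to_csv(out / f"dx_{focal}_vs_{related}.tsv", sep="\t", index=False)

        pooled = selection_enrichment(table, bias_map(bias), "SBG", "unbiased")
        print(f"{focal} vs {related}:")
        print(f"  SBGs under selection {100 * pooled['prop_a']:.1f}% vs unbiased "
              f"{100 * pooled['prop_b']:.1f}% (Fisher p={pooled['pvalue']:.2e})")
        fm = selection_enrichment(table, bias, "FBG", "MBG")
        print(f"  FBGs {100 * fm['prop_a']:.1f}% vs MBGs {100 * fm['prop_b']:.1f}% "
              f"under selection (Fisher p={fm['pvalue']:.3g})")


if __name__ == "__main__":
    main()
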