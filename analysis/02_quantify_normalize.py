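#!/usr/bin/env python
"""Quality filtering, feature aggregation and normalization.

Applies the identification-quality gates (PIF > 0.75; PEP-2D < 0.001 for
glycopeptide classes; 0% peptide-level target-decoy FDR), sums redundant
PSMs into features keyed by peptide + modifications + glycan, then log2
transforms with per-channel median centering.  Writes raw and normalized
feature matrices per peptide class.
"""

from pathlib import Path

from glycopanel import quant, simulate

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = simulate.SyntheticConfig(seed=1).groups
    out = BASE / "quant"
    out.mkdir(parents=True, exist_ok=True)
    for cls in ("intact_n", "desialo_o", "de_n", "nonmod"):
        table = quant.read_psm_table(BASE / "cohort" / f"psm_{cls}.tsv")
        filtered = quant.filter_psms(table, apply_pep2d=(cls != "nonmod"))
        filtered = quant.fdr_filter(filtered)
        matrix = quant.aggregate_to_features(filtered, cls, groups=design)
        matrix.to_tsv(out / f"raw_{cls}.tsv")
        quant.normalize(matrix).to_tsv(out / f"normalized_{cls}.tsv")
        print(f"{cls:10s}: {len(table):5d} PSMs -> {len(filtered):5d} after filters "
              f"-> {len(matrix.values):4d} features")
    print(f"wrote matrices to {out}")


if __name__ == "__main__":
    main()
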