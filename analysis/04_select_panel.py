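#!/usr/bin/env python
"""Panel selection and ground-truth scoring.

Applies the four gates (q <= 0.25; ratio > 1.3 or < 0.77; de-N site
corroboration; serum-glycoform whitelist) to the differential intact
N-glycopeptides, cross-references protein-level behavior from the
non-modified fraction, and scores the selected panel against the planted
truth (sensitivity over recoverable planted features; empirical FDR).
"""

from pathlib import Path

import pandas as pd

from glycopanel import panel as pm
from glycopanel import quant, simulate, stats

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = simulate.SyntheticConfig(seed=1).groups
    out = BASE / "panel"
    out.mkdir(parents=True, exist_ok=True)

    matrices = {
        cls: quant.QuantMatrix.from_tsv(BASE / "quant" / f"raw_{cls}.tsv", groups=design)
        for cls in ("intact_n", "de_n", "nonmod")
    }
    diff = {
        cls: pd.read_csv(BASE / "diff" / f"diff_{cls}.tsv", sep="\t", index_col=0)
        for cls in matrices
    }
    corr = pm.corroborate_sites(matrices["intact_n"].meta, matrices["de_n"].meta)
    panel = pm.select_panel(diff["intact_n"], matrices["intact_n"].meta, corroboration=corr)
    panel = pm.crossref_protein_level(panel, diff["nonmod"], matrices["nonmod"].meta)
    panel.to_csv(out / "panel.tsv", sep="\t", float_format="%.6g")
    print(f"panel entries: {len(panel)} "
          f"({(panel.direction == 'Up').sum()} up, {(panel.direction == 'Down').sum()} down; "
          f"{panel.glyco_specific.sum()} glyco-specific)")

    truth = pd.read_csv(BASE / "cohort" / "truth.tsv", sep="\t", index_col=0)
    planted = truth[(truth.peptide_class == "intact_n") & truth.planted]
    recoverable = planted[
        planted.feature_key.isin(diff["intact_n"].index)
        & planted.feature_key.map(lambda k: bool(corr["corroborated"].get(k, False)))
    ]
    sens = recoverable.feature_key.isin(panel.index).mean()
    fdr = (~panel.index.isin(set(truth.loc[truth.planted, "feature_key"]))).mean()
    print(f"sensitivity on recoverable planted features: {sens:.3f} "
          f"({recoverable.feature_key.isin(panel.index).sum()}/{len(recoverable)})")
    print(f"empirical FDR among selected: {fdr:.3f}")


if __name__ == "__main__":
    main()
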