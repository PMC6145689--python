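"""Synthetic TMT10 glycoproteomics cohorts with known ground truth.

No raw data accompany the study this pipeline models, so every downstream
stage is exercised on simulated PSM tables carrying the statistical
structure the analysis assumes: a 5-case vs 5-control TMT10 design (case =
PCa-like channels 126-128C, control = BPH-like channels 129N-131), four
peptide populations (intact N-glycopeptides, desialo-O-glycopeptides,
de-N-glycosylated peptides, non-modified peptides), log-normal baseline
abundances, per-channel multiplicative reporter noise, PSM redundancy,
precursor co-isolation (low PIF compresses ratios toward 1), one globally
shifted outlier control channel, feature-wise missingness and a separable
target/decoy score model.

Differential structure is planted from the packaged 56-entry panel fixture:
the intact glycopeptides carry the fixture's PCa/BPH ratios, the
corroborating de-N peptides carry the fixture's site-level ratios, and the
non-modified peptides carry each protein's average ratio, so the full
selection cascade (q gate, fold-change gate, site corroboration, whitelist,
protein-level cross-reference) can be validated end to end.

Reporter intensity model, per feature f, channel c and PSM:

    I = 2^(b_f + log2(r_f) * 1[c in case] + outlier shift) / n_psms * noise

with b_f ~ Normal(baseline_mean, baseline_sd) and multiplicative log-normal
noise of coefficient of variation ``noise_cv``.  All randomness flows from a
single seed; a fixed seed reproduces the tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import load_table1_fixture
from .glycans import GlycanComposition, find_sequons, oxonium_ions, parse_composition
from .quant import TMT10_CHANNELS, _mods_key
from .spectra import SpectrumPeaks

__all__ = ["SyntheticConfig", "generate_cohort", "generate_spectrum"]

_AA = np.array(list("ACDEFGHIKLMNQRSVWY"))  # no P (kept out of random cores), no B/Z/X


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the modeled study conditions."""

    n_case: int = 5
    n_control: int = 5
    channels: tuple[str, ...] = TMT10_CHANNELS
    #: null (non-differential) features generated per peptide class
    n_null_features: dict = field(
        default_factory=lambda: {"intact_n": 1000, "desialo_o": 150, "de_n": 150, "nonmod": 150}
    )
    plant_table1: bool = True
    #: extra/override effects: feature id -> linear case/control ratio
    effects: dict = field(default_factory=dict)
    #: ratio applied to all Fuc-containing desialo-O features (class-level effect)
    fuc_effect_o: float = 1.0
    baseline_mean: float = 17.0
    baseline_sd: float = 1.5
    noise_cv: float = 0.2
    psm_redundancy: float = 3.0  # mean PSMs per feature (>= 1)
    clean_pif_fraction: float = 0.9
    outlier_channel: str | None = "131"
    outlier_shift_log2: float = 2.0
    missing_rate: float = 0.05
    decoy_fraction: float = 0.1
    n_neugc_mislabeled: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 channels per group")
        if self.n_case + self.n_control != len(self.channels):
            raise ValueError("channel list must cover n_case + n_control")
        if self.noise_cv <= 0:
            raise ValueError("noise CV must be positive")
        if self.psm_redundancy < 1:
            raise ValueError("mean PSM redundancy must be >= 1")

    @property
    def case_channels(self) -> tuple[str, ...]:
        return self.channels[: self.n_case]

    @property
    def control_channels(self) -> tuple[str, ...]:
        return self.channels[self.n_case :]

    @property
    def groups(self) -> dict[str, str]:
        g = {c: "case" for c in self.case_channels}
        g.update({c: "control" for c in self.control_channels})
        return g


def _random_sequon_peptide(rng: np.random.Generator) -> str:
    """Random tryptic-looking peptide containing exactly one sequon."""
    length = int(rng.integers(9, 20))
    seq = rng.choice(_AA, size=length)
    pos = int(rng.integers(0, length - 3))
    seq[pos] = "N"
    seq[pos + 1] = rng.choice([a for a in _AA if a != "N"])
    seq[pos + 2] = rng.choice(["S", "T"])
    # no second N upstream of S/T to keep a single sequon
    for i in range(length - 2):
        if i != pos and seq[i] == "N" and seq[i + 2] in "STC":
            seq[i] = "Q"
    seq[-1] = rng.choice(["K", "R"])
    peptide = "".join(seq)
    assert find_sequons(peptide), peptide
    return peptide


def _random_n_glycan(rng: np.random.Generator) -> GlycanComposition:
    hexnac = int(rng.integers(2, 7))
    hx = int(rng.integers(3, 9))
    fuc = int(rng.integers(0, 3))
    neuac = int(rng.integers(0, 4))
    return GlycanComposition(hexnac, hx, fuc, neuac, 0)


def _random_o_glycan(rng: np.random.Generator) -> GlycanComposition:
    hexnac = int(rng.integers(1, 4))
    hx = int(rng.integers(0, 3))
    fuc = int(rng.integers(0, 2))
    comp = GlycanComposition(hexnac, hx, fuc, 0, 0)
    return comp if not comp.is_empty() else GlycanComposition(1, 0, 0, 0, 0)


def _build_feature_frames(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per feature across all classes, with true ratios."""
    rows: list[dict] = []

    if config.plant_table1:
        t1 = load_table1_fixture()
        seen: set[tuple[str, str]] = set()
        for r in t1.itertuples():
            # Glycoforms sharing (carrier, composition) are emitted as missed-
            # cleavage carrier variants so they stay distinct quant features.
            peptide = r.peptide
            while (peptide, r.composition) in seen:
                peptide = "K" + peptide
            seen.add((peptide, r.composition))
            rows.append(
                dict(
                    feature_id=r.feature_id, peptide_class="intact_n", peptide=peptide,
                    modifications="TMT@N-term", glycan=r.composition, protein=r.uniprot,
                    gene=r.gene, ratio=float(r.ratio), planted=True,
                )
            )
        den = t1.drop_duplicates(subset=["uniprot", "den_sequence", "den_position"])
        for i, r in enumerate(den.itertuples()):
            rows.append(
                dict(
                    feature_id=f"DN-T1-{i:02d}", peptide_class="de_n", peptide=r.den_sequence,
                    modifications=f"TMT@N-term;Deamidated@{int(r.den_position)}", glycan="",
                    protein=r.uniprot, gene=r.gene, ratio=float(r.den_ratio), planted=True,
                )
            )
        nm = t1.drop_duplicates(subset=["uniprot"])
        for r in nm.itertuples():
            n_pep = 0 if pd.isna(r.n_nonmod) else int(r.n_nonmod)
            avg = 1.0 if pd.isna(r.nonmod_avg_ratio) else float(r.nonmod_avg_ratio)
            for j in range(n_pep):
                rows.append(
                    dict(
                        feature_id=f"NM-{r.gene}-{j:02d}", peptide_class="nonmod",
                        peptide=_random_sequon_peptide(rng), modifications="TMT@N-term",
                        glycan="", protein=r.uniprot, gene=r.gene, ratio=avg, planted=True,
                    )
                )

    makers = {
        "intact_n": lambda: str(_random_n_glycan(rng)),
        "desialo_o": lambda: str(_random_o_glycan(rng)),
        "de_n": lambda: "",
        "nonmod": lambda: "",
    }
    for cls, n in config.n_null_features.items():
        for i in range(n):
            peptide = _random_sequon_peptide(rng)
            mods = "TMT@N-term"
            if cls == "de_n":
                mods += f";Deamidated@{find_sequons(peptide)[0]}"
            glycan = makers[cls]()
            ratio = 1.0
            if cls == "desialo_o" and config.fuc_effect_o != 1.0:
                if parse_composition(glycan).fuc > 0:
                    ratio = config.fuc_effect_o
            rows.append(
                dict(
                    feature_id=f"{cls.upper()}-{i:04d}", peptide_class=cls, peptide=peptide,
                    modifications=mods, glycan=glycan, protein=f"SYN{i:04d}-{cls[:2].upper()}",
                    gene=f"SYN{cls[:2].upper()}{i:04d}", ratio=ratio, planted=False,
                )
            )

    feats = pd.DataFrame(rows)
    dup = feats["feature_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated feature id {feats.loc[dup, 'feature_id'].iloc[0]!r}")
    unknown = set(config.effects) - set(feats["feature_id"])
    if unknown:
        raise ValueError(f"effect table names unknown feature id(s): {sorted(unknown)[:3]}")
    if config.effects:
        override = feats["feature_id"].map(config.effects)
        feats["ratio"] = override.fillna(feats["ratio"])
        feats.loc[override.notna(), "planted"] = True
    return feats


def _plant_mislabels(feats: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Replace the nominal composition of a few null intact features with the
    isobaric Fuc+NeuGc variant of their (true) Hex+NeuAc composition."""
    feats = feats.copy()
    feats["neugc_mislabel"] = False
    feats["true_glycan"] = feats["glycan"]
    if config.n_neugc_mislabeled == 0:
        return feats
    eligible = feats.index[
        (feats["peptide_class"] == "intact_n")
        & ~feats["planted"]
        & feats["glycan"].map(lambda g: bool(g) and parse_composition(g).neuac >= 1 and parse_composition(g).hex >= 1)
    ]
    chosen = rng.choice(eligible, size=min(config.n_neugc_mislabeled, len(eligible)), replace=False)
    for idx in chosen:
        true = parse_composition(feats.at[idx, "glycan"])
        nominal = GlycanComposition(true.hexnac, true.hex - 1, true.fuc + 1, true.neuac - 1, 1)
        feats.at[idx, "glycan"] = str(nominal)
        feats.at[idx, "neugc_mislabel"] = True
    return feats


def generate_cohort(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate per-class PSM tables and the ground-truth table.

    Returns ``(tables, truth)`` where ``tables`` maps peptide class to a PSM
    DataFrame in the dialect ``quant.read_psm_table`` accepts, and ``truth``
    has one row per generated feature: true ratio, differential class
    (up/down/null), nominal and true glycan, mislabel flag, whether the
    feature was dropped by the missingness process, and the quant-pipeline
    feature key for joining against downstream results.
    """
    rng = np.random.default_rng(config.seed)
    feats = _build_feature_frames(config, rng)
    feats = _plant_mislabels(feats, config, rng)

    channels = list(config.channels)
    is_case = np.array([config.groups[c] == "case" for c in channels])
    n_ch = len(channels)

    feats["baseline"] = rng.normal(config.baseline_mean, config.baseline_sd, len(feats))
    feats["missing"] = rng.random(len(feats)) < config.missing_rate
    n_extra = rng.poisson(max(config.psm_redundancy - 1.0, 0.0), len(feats))
    feats["n_psms"] = 1 + n_extra

    sigma_ln = np.sqrt(np.log1p(config.noise_cv**2))
    outlier_factor = np.ones(n_ch)
    if config.outlier_channel is not None:
        outlier_factor[channels.index(config.outlier_channel)] = 2.0**config.outlier_shift_log2

    tables: dict[str, pd.DataFrame] = {}
    spectrum_counter = 0
    for cls in ("intact_n", "desialo_o", "de_n", "nonmod"):
        sub = feats.loc[(feats["peptide_class"] == cls) & ~feats["missing"]]
        if sub.empty:
            tables[cls] = _empty_psm_table(channels)
            continue
        idx = np.repeat(np.arange(len(sub)), sub["n_psms"].to_numpy())
        n_rows = len(idx)
        lfc = np.log2(sub["ratio"].to_numpy())[idx]
        base = sub["baseline"].to_numpy()[idx]
        mu = base[:, None] + lfc[:, None] * is_case[None, :]
        signal = np.exp2(mu) / sub["n_psms"].to_numpy()[idx][:, None]
        noise = np.exp(rng.normal(0.0, sigma_ln, size=(n_rows, n_ch)))
        intens = signal * noise

        clean = rng.random(n_rows) < config.clean_pif_fraction
        pif = np.where(clean, rng.uniform(0.9, 1.0, n_rows), rng.uniform(0.3, 0.75, n_rows))
        background = intens.mean(axis=1, keepdims=True)
        contaminated = ~clean
        intens[contaminated] = (
            pif[contaminated, None] * intens[contaminated]
            + (1.0 - pif[contaminated, None]) * background[contaminated]
        )
        intens *= outlier_factor[None, :]

        table = pd.DataFrame(
            {
                "spectrum_id": [f"scan{spectrum_counter + i:06d}" for i in range(n_rows)],
                "peptide": sub["peptide"].to_numpy()[idx],
                "modifications": sub["modifications"].to_numpy()[idx],
                "glycan": sub["glycan"].to_numpy()[idx],
                "charge": rng.integers(2, 5, n_rows),
                "score": rng.normal(150.0, 15.0, n_rows),
                "pep2d": 10.0 ** rng.uniform(-6.0, -3.5, n_rows),
                "pif": pif,
                "decoy": False,
                "rt": rng.uniform(10.0, 60.0, n_rows),
                "protein": sub["protein"].to_numpy()[idx],
                "gene": sub["gene"].to_numpy()[idx],
            }
        )
        spectrum_counter += n_rows
        for j, c in enumerate(channels):
            table[f"intensity_{c}"] = intens[:, j]

        n_decoys = int(round(config.decoy_fraction * n_rows))
        if n_decoys:
            pick = rng.integers(0, n_rows, n_decoys)
            decoys = table.iloc[pick].copy().reset_index(drop=True)
            decoys["spectrum_id"] = [f"scan{spectrum_counter + i:06d}" for i in range(n_decoys)]
            spectrum_counter += n_decoys
            decoys["peptide"] = [p[::-1] for p in decoys["peptide"]]
            decoys["decoy"] = True
            decoys["score"] = rng.normal(100.0, 10.0, n_decoys)
            decoys["pep2d"] = 10.0 ** rng.uniform(-3.0, -1.0, n_decoys)
            table = pd.concat([table, decoys], ignore_index=True)
        tables[cls] = table

    truth = feats[
        ["feature_id", "peptide_class", "peptide", "modifications", "glycan", "true_glycan",
         "protein", "gene", "ratio", "planted", "neugc_mislabel", "missing"]
    ].copy()
    truth = truth.rename(columns={"ratio": "true_ratio"})
    truth["diff_class"] = np.select(
        [truth["true_ratio"] > 1.0, truth["true_ratio"] < 1.0], ["up", "down"], default="null"
    )
    truth["feature_key"] = (
        truth["peptide"] + "|" + truth["modifications"].map(_mods_key) + "|" + truth["glycan"]
    )
    return tables, truth.set_index("feature_id")


def _empty_psm_table(channels: list[str]) -> pd.DataFrame:
    cols = ["spectrum_id", "peptide", "modifications", "glycan", "charge", "score",
            "pep2d", "pif", "decoy", "rt", "protein", "gene"] + [f"intensity_{c}" for c in channels]
    return pd.DataFrame({c: [] for c in cols})


def generate_spectrum(
    peptide: str,
    comp: GlycanComposition,
    mislabel: bool = False,
    n_background: int = 20,
    rng: np.random.Generator | None = None,
) -> SpectrumPeaks:
    """Toy HCD peak list carrying the oxonium ions of the TRUE composition.

    With ``mislabel=True`` the nominal composition's NeuGc is a mis-assignment:
    the emitted diagnostic ions are those of the true (NeuAc-bearing)
    composition, so NeuGc diagnostics are absent.  Background peaks avoid
    +/- 1 Da around every diagnostic ion so they can never fake evidence.
    """
    rng = rng or np.random.default_rng(0)
    if mislabel and comp.neugc > 0:
        true_comp = GlycanComposition(comp.hexnac, comp.hex, comp.fuc, comp.neuac + comp.neugc, 0)
    else:
        true_comp = comp
    mzs: list[float] = []
    intens: list[float] = []
    for _, mz in oxonium_ions(true_comp):
        mzs.append(mz)
        intens.append(float(rng.uniform(1e4, 1e6)))
    guard = [mz for _, mz in oxonium_ions(GlycanComposition(1, 1, 1, 1, 1))]
    added = 0
    while added < n_background:
        mz = float(rng.uniform(120.0, 2000.0))
        if all(abs(mz - g) > 1.0 for g in guard):
            mzs.append(mz)
            intens.append(float(rng.uniform(1e2, 1e4)))
            added += 1
    order = np.argsort(mzs)
    return SpectrumPeaks(np.asarray(mzs)[order], np.asarray(intens)[order])
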