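"""PSM ingestion, identification-quality filtering, feature aggregation and
reporter-intensity normalization for TMT10 glycoproteomics.

The unit of input is a PSM (peptide-spectrum match) table in tab-separated
text as exported by glycopeptide search engines: one row per identified
MS/MS spectrum with the peptide, its modifications, an optional glycan
composition string, search-engine score, PEP-2D (posterior error
probability), PIF (precursor ion fraction), a decoy flag, retention time and
ten TMT reporter-ion intensities.

Quantification proceeds: quality filters (PIF > 0.75 strictly, PEP-2D <
0.001 strictly for glycopeptide classes; target-decoy FDR at 0% on the
peptide level) -> summation of redundant PSMs into features keyed by
peptide + modifications + glycan composition (charge states collapsed) ->
log2 transform with per-channel median (or mean) centering.  Zeros are
treated as missing, never as log(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glycans import find_sequons, parse_composition

__all__ = [
    "TMT10_CHANNELS",
    "QuantMatrix",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "fdr_filter",
    "aggregate_to_features",
    "normalize",
    "prm_quantify",
]

#: TMT10plex channel labels, in reporter-mass order.
TMT10_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

PEPTIDE_CLASSES = ("intact_n", "desialo_o", "de_n", "nonmod")

_BASE_COLUMNS = (
    "spectrum_id", "peptide", "modifications", "glycan", "charge",
    "score", "pep2d", "pif", "decoy", "rt", "protein", "gene",
)


def _intensity_columns(channels: tuple[str, ...] = TMT10_CHANNELS) -> list[str]:
    return [f"intensity_{c}" for c in channels]


def read_psm_table(path, channels: tuple[str, ...] = TMT10_CHANNELS) -> pd.DataFrame:
    """Read a tab-separated PSM table, validating columns and compositions.

    Glycan composition strings are parsed (and canonicalized) via the glycan
    model; a row with an unparsable composition raises with its row number.
    Missing required columns raise naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"glycan": "string", "modifications": "string"})
    required = list(_BASE_COLUMNS) + _intensity_columns(channels)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"PSM table {path} is missing required column {col!r}")
    canonical = []
    for i, text in enumerate(df["glycan"]):
        if pd.isna(text) or text == "":
            canonical.append("")
            continue
        try:
            canonical.append(str(parse_composition(text)))
        except ValueError as exc:
            raise ValueError(f"row {i + 2} of {path}: {exc}") from exc
    df["glycan"] = canonical
    df["modifications"] = df["modifications"].fillna("")
    df["decoy"] = df["decoy"].astype(bool)
    bad_pif = ~df["pif"].between(0.0, 1.0)
    if bad_pif.any():
        raise ValueError(f"PIF outside [0, 1] at row {int(np.flatnonzero(bad_pif)[0]) + 2}")
    return df


def write_psm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_psms(
    records: pd.DataFrame,
    pif_min: float = 0.75,
    pep2d_max: float = 0.001,
    apply_pep2d: bool = True,
) -> pd.DataFrame:
    """Keep PSMs with PIF strictly above and PEP-2D strictly below threshold.

    Both comparisons are strict, so boundary values are excluded.  The
    non-modified peptide class is quantified without the glyco-specific
    PEP-2D gate (``apply_pep2d=False``).
    """
    if not (0 < pif_min < 1) or not (0 < pep2d_max < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    keep = records["pif"] > pif_min
    if apply_pep2d:
        keep &= records["pep2d"] < pep2d_max
    return records.loc[keep].copy()


def fdr_filter(records: pd.DataFrame, peptide_fdr_max: float = 0.0) -> pd.DataFrame:
    """Target-decoy FDR filter on the PSM score.

    Sorts by score descending and computes the running FDR
    ``#decoys / #targets`` at each score cutoff; returns the targets at the
    most permissive cutoff whose running FDR stays within
    ``peptide_fdr_max``.  At 0.0 this keeps exactly the targets scoring
    strictly above the best decoy.
    """
    if records.empty:
        return records.copy()
    order = records.sort_values("score", ascending=False, kind="mergesort")
    is_decoy = order["decoy"].to_numpy()
    n_decoys = np.cumsum(is_decoy)
    n_targets = np.cumsum(~is_decoy)
    with np.errstate(divide="ignore", invalid="ignore"):
        running = np.where(n_targets > 0, n_decoys / np.maximum(n_targets, 1), np.inf)
    admissible = np.flatnonzero(running <= peptide_fdr_max)
    if admissible.size == 0:
        return order.iloc[0:0].copy()
    cut = admissible[-1] + 1
    kept = order.iloc[:cut]
    return kept.loc[~kept["decoy"]].copy()


@dataclass
class QuantMatrix:
    """Feature x channel intensity table with per-feature metadata.

    ``values`` is indexed by the feature key (peptide|modifications|glycan)
    with one column per TMT channel; ``meta`` shares the index and carries
    peptide, modifications, glycan, protein, gene, peptide class, site and
    PSM count.  ``groups`` maps channel label -> group label.  ``scale``
    records whether values are linear reporter sums or normalized log2.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    scale: str = "linear"

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    def group_channels(self, group: str) -> list[str]:
        return [c for c in self.channels if self.groups.get(c) == group]

    def drop_channels(self, channels) -> "QuantMatrix":
        keep = [c for c in self.values.columns if c not in set(channels)]
        groups = {c: g for c, g in self.groups.items() if c in keep}
        return replace(self, values=self.values[keep].copy(), groups=groups)

    def to_tsv(self, path) -> None:
        out = self.meta.join(self.values)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, groups: dict[str, str], scale: str = "linear") -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        value_cols = [c for c in df.columns if c in TMT10_CHANNELS]
        return cls(values=df[value_cols], meta=df.drop(columns=value_cols), groups=dict(groups), scale=scale)


def _mods_key(mods: str) -> str:
    tokens = sorted(t.strip() for t in str(mods).split(";") if t.strip())
    return ";".join(tokens)


def _deamidation_site(mods: str) -> int | None:
    for token in str(mods).split(";"):
        name, _, site = token.strip().partition("@")
        if name == "Deamidated" and site.isdigit():
            return int(site)
    return None


def aggregate_to_features(
    records: pd.DataFrame,
    peptide_class: str,
    groups: dict[str, str] | None = None,
    channels: tuple[str, ...] = TMT10_CHANNELS,
) -> QuantMatrix:
    """Sum reporter intensities of redundant PSMs into feature rows.

    The feature key is peptide + modifications + glycan composition; charge
    states of the same glycopeptide are merged by summation.  The per-feature
    PSM count is retained.  Row order of the input is irrelevant.
    """
    if peptide_class not in PEPTIDE_CLASSES:
        raise ValueError(f"unknown peptide class {peptide_class!r}")
    df = records.copy()
    df["_mods"] = df["modifications"].map(_mods_key)
    df["_key"] = df["peptide"] + "|" + df["_mods"] + "|" + df["glycan"].fillna("")
    icols = [f"intensity_{c}" for c in channels]
    summed = df.groupby("_key", sort=True)[icols].sum()
    summed.columns = list(channels)
    firsts = df.groupby("_key", sort=True).agg(
        peptide=("peptide", "first"),
        modifications=("_mods", "first"),
        glycan=("glycan", "first"),
        protein=("protein", "first"),
        gene=("gene", "first"),
        n_psms=("peptide", "size"),
    )
    firsts["peptide_class"] = peptide_class
    if peptide_class == "de_n":
        site = firsts["modifications"].map(_deamidation_site)
    else:
        site = firsts["peptide"].map(lambda p: (find_sequons(p) or [None])[0])
    firsts["site"] = site
    return QuantMatrix(values=summed, meta=firsts, groups=dict(groups or {}), scale="linear")


def normalize(matrix: QuantMatrix, center: str = "median") -> QuantMatrix:
    """Log2 transform and per-channel centering of a raw QuantMatrix.

    Zeros become missing before the log.  ``center`` is ``"median"``
    (default) or ``"mean"``; afterwards each channel's center over finite
    values is 0.  Idempotent on already-normalized input.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"center must be 'median' or 'mean', got {center!r}")
    if matrix.scale == "log2":
        log2 = matrix.values.copy()
    else:
        vals = matrix.values.where(matrix.values > 0)
        log2 = np.log2(vals)
    if log2.notna().sum().eq(0).any():
        empty = [c for c in log2.columns if log2[c].notna().sum() == 0]
        raise ValueError(f"channel(s) with no finite values: {empty}")
    offsets = log2.median(axis=0) if center == "median" else log2.mean(axis=0)
    return replace(matrix, values=log2 - offsets, scale="log2")


def prm_quantify(
    records: pd.DataFrame,
    channel_totals: dict[str, float] | pd.Series,
    rt_window: tuple[float, float] | None = None,
    channels: tuple[str, ...] = TMT10_CHANNELS,
) -> pd.Series:
    """PRM-style abundance of one glycopeptide across TMT channels.

    Sums the reporter intensities over the glycopeptide's spectra (optionally
    restricted to a closed retention-time window, in minutes) and divides by
    the total reporter intensity of each channel over the whole run.
    """
    totals = pd.Series(channel_totals).astype(float)
    if (totals <= 0).any():
        raise ValueError("channel totals must be positive")
    df = records
    if rt_window is not None:
        lo, hi = rt_window
        df = df.loc[(df["rt"] >= lo) & (df["rt"] <= hi)]
    icols = [f"intensity_{c}" for c in channels]
    summed = df[icols].sum()
    summed.index = list(channels)
    return summed / totals.reindex(list(channels))
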