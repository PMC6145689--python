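"""Biomarker panel selection: the multi-criteria cascade that turns
differential intact-glycopeptide statistics into a reportable panel.

An intact N-glycopeptide enters the panel only if all four gates hold:

1. significance: q <= 0.25 (inclusive, so borderline q = 0.25 rows pass);
2. effect size: linear case/control ratio strictly > 1.3 or strictly < 0.77;
3. site corroboration: the glycosylation site is independently observed in
   the de-N-glycosylated peptide fraction (a deamidated Asn sitting on a
   sequon of a peptide from the same protein);
4. glycoform plausibility: the glycan composition belongs to a whitelist of
   serum-type glycoforms.

Selected entries are then cross-referenced against the non-modified peptide
fraction to distinguish glyco-specific regulation (glycoform moves while the
protein level does not) from plain protein-level abundance change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fixtures import default_whitelist
from .glycans import find_sequons

__all__ = ["corroborate_sites", "select_panel", "crossref_protein_level"]


def corroborate_sites(intact_meta: pd.DataFrame, den_meta: pd.DataFrame) -> pd.DataFrame:
    """Match intact glycopeptides to de-N-glycosylated site evidence.

    ``intact_meta``/``den_meta`` are QuantMatrix.meta frames (peptide,
    protein, site columns).  A de-N peptide corroborates an intact
    glycopeptide when both map to the same protein and the deamidation site
    (validated to lie on a sequon of the de-N peptide) coincides with a
    sequon of the intact peptide: same peptide string, or one sequence
    containing the other with the site aligned.

    Returns a frame indexed like ``intact_meta`` with ``corroborated`` and
    ``den_peptide`` columns.
    """
    valid_den = []
    for key, row in den_meta.iterrows():
        site = row.get("site")
        if site is None or (isinstance(site, float) and np.isnan(site)):
            continue
        site = int(site)
        if site in find_sequons(row["peptide"]):
            valid_den.append((row["protein"], row["peptide"], site, key))
    by_protein: dict[str, list[tuple[str, int, object]]] = {}
    for protein, pep, site, key in valid_den:
        by_protein.setdefault(protein, []).append((pep, site, key))

    flags, partners = [], []
    for _, row in intact_meta.iterrows():
        matched = None
        for den_pep, den_site, _ in by_protein.get(row["protein"], ()):
            if _sites_overlap(row["peptide"], den_pep, den_site):
                matched = den_pep
                break
        flags.append(matched is not None)
        partners.append(matched or "")
    return pd.DataFrame({"corroborated": flags, "den_peptide": partners}, index=intact_meta.index)


def _sites_overlap(intact_pep: str, den_pep: str, den_site: int) -> bool:
    """Does the de-N deamidation site fall on a sequon of the intact peptide?"""
    if intact_pep == den_pep:
        return den_site in find_sequons(intact_pep)
    if den_pep in intact_pep:
        offset = intact_pep.index(den_pep)
        return den_site + offset in find_sequons(intact_pep)
    if intact_pep in den_pep:
        offset = den_pep.index(intact_pep)
        return den_site - offset in find_sequons(intact_pep)
    return False


def select_panel(
    diff: pd.DataFrame,
    meta: pd.DataFrame,
    corroboration: pd.DataFrame | None = None,
    whitelist: frozenset[str] | set[str] | None = None,
    q_max: float = 0.25,
    fc_up: float = 1.3,
    fc_down: float = 0.77,
) -> pd.DataFrame:
    """Apply the four panel gates to differential intact-glycopeptide results.

    ``diff`` carries q and ratio per feature; ``meta`` the glycan/protein
    annotations; ``corroboration`` the output of :func:`corroborate_sites`
    (``None`` means corroboration is not gated, e.g. when replaying an
    already-corroborated table).  Gates are an intersection of independent
    predicates, so their order is irrelevant.  Every returned row re-asserts
    the gate invariants.
    """
    if whitelist is None:
        whitelist = default_whitelist()
    if not whitelist:
        raise ValueError("glycoform whitelist must be nonempty")
    q_ok = diff["q"] <= q_max
    fc_ok = (diff["ratio"] > fc_up) | (diff["ratio"] < fc_down)
    wl_ok = meta.loc[diff.index, "glycan"].isin(whitelist)
    keep = q_ok & fc_ok & wl_ok
    out = diff.loc[keep].join(meta.loc[keep, [c for c in ("peptide", "glycan", "protein", "gene") if c in meta.columns]])
    if corroboration is not None:
        corr = corroboration.reindex(out.index)
        out = out.loc[corr["corroborated"].fillna(False).astype(bool)]
        out = out.join(corroboration.loc[out.index, "den_peptide"])
    out = out.copy()
    out["direction"] = np.where(out["ratio"] > 1.0, "Up", "Down")
    assert (out["q"] <= q_max).all()
    assert ((out["ratio"] > fc_up) | (out["ratio"] < fc_down)).all()
    return out.sort_values(["protein", "ratio"], kind="mergesort")


def crossref_protein_level(
    panel: pd.DataFrame,
    nonmod_diff: pd.DataFrame,
    nonmod_meta: pd.DataFrame,
    flat_low: float = 0.77,
    flat_high: float = 1.3,
) -> pd.DataFrame:
    """Annotate panel entries with non-modified (protein-level) behavior.

    For each entry: the number of non-modified peptides quantified for its
    protein and their average ratio.  The entry is flagged ``glyco_specific``
    when the glycopeptide's change is not explained by protein level -- the
    protein-level average ratio is flat (within [flat_low, flat_high]) or
    moves in the opposite direction.  Proteins absent from the non-modified
    data are annotated ``no protein-level evidence``.
    """
    nm = nonmod_diff.join(nonmod_meta["protein"])
    per_protein = nm.groupby("protein")["ratio"].agg(["size", "mean"])
    out = panel.copy()
    out["n_nonmod_peptides"] = per_protein["size"].reindex(out["protein"]).fillna(0).astype(int).to_numpy()
    out["nonmod_avg_ratio"] = per_protein["mean"].reindex(out["protein"]).to_numpy()
    notes, glyco_specific = [], []
    for _, row in out.iterrows():
        pr = row["nonmod_avg_ratio"]
        if row["n_nonmod_peptides"] == 0 or pd.isna(pr):
            notes.append("no protein-level evidence")
            glyco_specific.append(False)
            continue
        notes.append("")
        flat = flat_low <= pr <= flat_high
        opposite = (row["ratio"] > 1.0) != (pr > 1.0)
        glyco_specific.append(bool(flat or opposite))
    out["protein_level_note"] = notes
    out["glyco_specific"] = glyco_specific
    return out
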