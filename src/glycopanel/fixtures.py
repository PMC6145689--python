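"""Packaged study fixtures.

``data/table1.tsv`` is a transcription of the published table of 56
differentially abundant intact N-glycopeptides distinguishing prostate cancer
(PCa) from benign prostatic hyperplasia (BPH) urine (q <= 0.25, fold change
> 1.3 or < 0.77, site corroborated by de-N-glycosylated peptide evidence,
serum-type glycoform).  The printed table identifies each glycoform by its
protein, monosaccharide counts and corroborating de-N peptide; the intact
carrier peptide is reconstructed here from the de-N peptide of the same site.
The file is guarded by a checksum so silent edits are caught on load.

The packaged glycoform whitelist (a stand-in for a curated serum-glycoform
resource) is derived from the compositions occurring in this fixture and is
user-replaceable wherever it is consumed.
"""

from __future__ import annotations

import hashlib
import io
import re
from importlib import resources

import numpy as np
import pandas as pd

from .glycans import GlycanComposition, find_sequons

__all__ = [
    "load_table1_fixture",
    "default_whitelist",
    "split_deamidation_notation",
    "psa_fixture",
]

TABLE1_SHA256 = "ecbbc382ee6d7018e03aaa4984c97c17cb3ab898f07f428acd2048677cde34be"

_DE_RE = re.compile(r"\(de\)")


def split_deamidation_notation(marked: str) -> tuple[str, int]:
    """Split ``"LNAENN(de)ATFYFK"`` into ``("LNAENNATFYFK", 6)``.

    The ``(de)`` marker follows the deamidated Asn; the returned position is
    1-based in the stripped sequence.  Exactly one marker is required.
    """
    matches = list(_DE_RE.finditer(marked))
    if len(matches) != 1:
        raise ValueError(f"expected exactly one (de) marker in {marked!r}")
    pos = matches[0].start()
    if pos == 0 or marked[pos - 1] != "N":
        raise ValueError(f"(de) marker must follow an Asn in {marked!r}")
    return _DE_RE.sub("", marked), pos


def _read_packaged_table1() -> str:
    return resources.files("glycopanel").joinpath("data/table1.tsv").read_text()


def load_table1_fixture(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the 56-entry differential glycopeptide panel fixture.

    Returns a DataFrame with one row per panel entry carrying: protein
    identifiers, glycan composition (counts + canonical string), q-value,
    PCa/BPH ratio, direction, the corroborating de-N peptide (stripped
    sequence + 1-based deamidation position, validated to sit on a sequon)
    and protein-level non-modified peptide evidence.
    """
    text = _read_packaged_table1()
    if verify_checksum:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != TABLE1_SHA256:
            raise ValueError(
                f"table1.tsv checksum mismatch: {digest} != {TABLE1_SHA256}; "
                "the packaged fixture has been modified"
            )
    df = pd.read_csv(io.StringIO(text), sep="\t")
    df["neugc"] = 0
    comps = [
        GlycanComposition(int(r.hexnac), int(r.hex), int(r.fuc), int(r.neuac), 0)
        for r in df.itertuples()
    ]
    df["composition"] = [str(c) for c in comps]
    stripped = [split_deamidation_notation(p) for p in df["den_peptide"]]
    df["den_sequence"] = [s for s, _ in stripped]
    df["den_position"] = [p for _, p in stripped]
    for seq, pos in stripped:
        if pos not in find_sequons(seq):
            raise ValueError(f"deamidation at {pos} of {seq} is not on a sequon")
    # Intact carrier peptide reconstructed from the de-N peptide of the site.
    df["peptide"] = df["den_sequence"]
    df["feature_id"] = [f"T1-{int(r):02d}" for r in df["row"]]
    # Re-assert the panel gates the table was built under.
    if not ((df["q"] <= 0.25).all() and ((df["ratio"] > 1.3) | (df["ratio"] < 0.77)).all()):
        raise ValueError("fixture row violates the panel selection gates")
    if len(df) != 56 or df["feature_id"].nunique() != 56:
        raise ValueError(f"expected 56 unique panel entries, got {len(df)}")
    if df["uniprot"].nunique() != 21:
        raise ValueError(f"expected 21 proteins, got {df['uniprot'].nunique()}")
    return df


def default_whitelist() -> frozenset[str]:
    """Serum-type glycoform whitelist: compositions occurring in the fixture.

    A synthetic stand-in for a curated human serum glycoform list; replace
    with your own set of canonical composition strings where available.
    """
    return frozenset(load_table1_fixture()["composition"])


def psa_fixture() -> tuple[np.ndarray, np.ndarray]:
    """Serum PSA levels (ng/ml) matching the reported cohort summary stats.

    Synthetic vectors constructed to reproduce exactly the published group
    summaries: PCa 7.17 +/- 3.02 (n=6), BPH 8.02 +/- 7.30 (n=6).  Used to
    verify that PSA does not separate the groups (t-test p >= 0.05).
    """

    def with_moments(mean: float, sd: float, n: int = 6) -> np.ndarray:
        base = np.arange(n, dtype=float)
        z = (base - base.mean()) / base.std(ddof=1)
        return mean + sd * z

    return with_moments(7.17, 3.02), with_moments(8.02, 7.30)
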