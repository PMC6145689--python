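"""PSM ingestion, quality/FDR filtering, aggregation and normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycopanel import quant


def make_psms(rows, channels=quant.TMT10_CHANNELS):
    """Build a PSM DataFrame from dicts, filling sensible defaults."""
    defaults = dict(
        spectrum_id="s", peptide="PEPTIDEK", modifications="", glycan="",
        charge=2, score=100.0, pep2d=1e-5, pif=0.95, decoy=False, rt=30.0,
        protein="P1", gene="G1",
    )
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r["spectrum_id"] = f"s{i}"
        for c in channels:
            r.setdefault(f"intensity_{c}", 100.0)
        out.append(r)
    return pd.DataFrame(out)


class TestReadPsmTable:
    def test_round_trip(self, tmp_path):
        df = make_psms([{"glycan": "Hex(5)HexNAc(4)NeuAc(1)"}, {}, {}])
        path = tmp_path / "psms.tsv"
        quant.write_psm_table(df, path)
        back = quant.read_psm_table(path)
        assert len(back) == 3
        # composition canonicalized into HexNAc,Hex,Fuc,NeuAc order
        assert back.loc[0, "glycan"] == "HexNAc(4)Hex(5)NeuAc(1)"

    def test_missing_column_named(self, tmp_path):
        df = make_psms([{}]).drop(columns=["pif"])
        path = tmp_path / "psms.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="pif"):
            quant.read_psm_table(path)

    def test_bad_composition_reports_row(self, tmp_path):
        df = make_psms([{}, {"glycan": "Pent(1)"}])
        path = tmp_path / "psms.tsv"
        quant.write_psm_table(df, path)
        with pytest.raises(ValueError, match="row 3"):
            quant.read_psm_table(path)


class TestFilterPsms:
    def test_pif_boundary_is_strict(self):
        df = make_psms([{"pif": 0.80}, {"pif": 0.75}, {"pif": 0.60}])
        kept = quant.filter_psms(df)
        assert kept["pif"].tolist() == [0.80]

    def test_pep2d_boundary_is_strict(self):
        df = make_psms([{"pep2d": 0.0005}, {"pep2d": 0.001}])
        kept = quant.filter_psms(df)
        assert kept["pep2d"].tolist() == [0.0005]

    def test_nonmod_class_exempt_from_pep2d(self):
        df = make_psms([{"pep2d": 0.5, "pif": 0.9}])
        assert len(quant.filter_psms(df, apply_pep2d=False)) == 1
        assert len(quant.filter_psms(df, apply_pep2d=True)) == 0

    def test_empty_input(self):
        df = make_psms([]).reindex(columns=make_psms([{}]).columns)
        assert quant.filter_psms(df).empty


def brute_force_fdr(scores, decoys, fdr_max):
    """Oracle: try every cutoff, keep targets at the best admissible one."""
    best = []
    for cut in sorted(set(scores), reverse=True):
        kept = [(s, d) for s, d in zip(scores, decoys) if s >= cut]
        n_t = sum(1 for _, d in kept if not d)
        n_d = len(kept) - n_t
        if n_t and n_d / n_t <= fdr_max and n_t > len(best):
            best = [s for s, d in kept if not d]
    return sorted(best)


class TestFdrFilter:
    def test_keeps_targets_above_best_decoy(self):
        df = make_psms(
            [{"score": 0.9}, {"score": 0.8}, {"score": 0.6}, {"score": 0.7, "decoy": True}]
        )
        kept = quant.fdr_filter(df, 0.0)
        assert sorted(kept["score"]) == [0.8, 0.9]

    def test_no_decoys_keeps_everything(self):
        df = make_psms([{"score": s} for s in (1.0, 2.0, 3.0)])
        assert len(quant.fdr_filter(df, 0.0)) == 3

    def test_all_decoys_outscore_targets(self):
        df = make_psms([{"score": 0.5}, {"score": 0.9, "decoy": True}])
        assert quant.fdr_filter(df, 0.0).empty

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(30):
            n = int(rng.integers(2, 15))
            scores = rng.choice(np.arange(n * 3), size=n, replace=False).astype(float)
            decoys = rng.random(n) < 0.4
            fdr_max = float(rng.choice([0.0, 0.25, 0.5]))
            df = make_psms([{"score": s, "decoy": bool(d)} for s, d in zip(scores, decoys)])
            kept = sorted(quant.fdr_filter(df, fdr_max)["score"])
            assert kept == brute_force_fdr(scores, decoys, fdr_max), (scores, decoys, fdr_max)


class TestAggregate:
    def test_redundant_psms_summed(self):
        df = make_psms([{"intensity_126": 100.0}, {"intensity_126": 50.0}])
        m = quant.aggregate_to_features(df, "intact_n")
        assert len(m.values) == 1
        assert m.values.iloc[0]["126"] == 150.0
        assert m.meta.iloc[0]["n_psms"] == 2

    def test_single_psm_identity(self):
        df = make_psms([{"intensity_127N": 42.0}])
        m = quant.aggregate_to_features(df, "intact_n")
        assert m.values.iloc[0]["127N"] == 42.0

    def test_glycoforms_stay_distinct(self):
        df = make_psms([{"glycan": "HexNAc(2)Hex(2)"}, {"glycan": "HexNAc(4)Hex(5)NeuAc(2)"}])
        m = quant.aggregate_to_features(df, "intact_n")
        assert len(m.values) == 2

    def test_charge_states_collapse(self):
        df = make_psms([{"charge": 2}, {"charge": 3}])
        m = quant.aggregate_to_features(df, "intact_n")
        assert len(m.values) == 1

    def test_order_independence(self, rng):
        rows = [
            {"peptide": p, "glycan": gl, "intensity_126": float(i)}
            for i, (p, gl) in enumerate(
                itertools.product(["AAANSSK", "BBBNSSK"], ["HexNAc(2)Hex(2)", "HexNAc(2)Hex(3)"])
            )
        ]
        df = make_psms(rows * 2)
        shuffled = df.sample(frac=1.0, random_state=7)
        a = quant.aggregate_to_features(df, "intact_n").values
        b = quant.aggregate_to_features(shuffled, "intact_n").values
        pd.testing.assert_frame_equal(a, b)

    def test_de_n_site_from_deamidation(self):
        df = make_psms([{"peptide": "LNAENNATFYFK", "modifications": "TMT@N-term;Deamidated@6"}])
        m = quant.aggregate_to_features(df, "de_n")
        assert m.meta.iloc[0]["site"] == 6


class TestNormalize:
    def _matrix(self, values, channels=("126", "127N", "127C")):
        vals = pd.DataFrame({c: v for c, v in zip(channels, np.asarray(values).T)})
        vals.index = [f"f{i}" for i in range(len(vals))]
        meta = pd.DataFrame(index=vals.index)
        return quant.QuantMatrix(values=vals, meta=meta, groups={}, scale="linear")

    def test_log2_then_median_center(self):
        m = self._matrix([[2.0], [4.0], [8.0]])
        out = quant.normalize(m)
        assert out.values["126"].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        m = self._matrix(np.exp2(np.random.default_rng(1).normal(10, 1, (20, 3))))
        once = quant.normalize(m)
        twice = quant.normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_channel_medians_vanish(self):
        m = self._matrix(np.exp2(np.random.default_rng(2).normal(10, 2, (51, 3))))
        out = quant.normalize(m)
        assert np.allclose(out.values.median(axis=0), 0.0, atol=1e-9)

    def test_mean_centering_differs_under_outlier(self):
        vals = np.exp2(np.vstack([np.full((9, 1), 10.0), [[30.0]]]))
        med = quant.normalize(self._matrix(vals, channels=("126",)), center="median")
        mean = quant.normalize(self._matrix(vals, channels=("126",)), center="mean")
        assert med.values.iloc[0, 0] == 0.0
        assert mean.values.iloc[0, 0] == pytest.approx(-2.0)

    def test_preserves_within_channel_rank_order(self):
        raw = np.exp2(np.random.default_rng(3).normal(12, 2, (30, 3)))
        out = quant.normalize(self._matrix(raw))
        for j, c in enumerate(out.values.columns):
            assert (np.argsort(raw[:, j]) == np.argsort(out.values[c].to_numpy())).all()

    def test_zero_becomes_missing(self):
        m = self._matrix([[1.0], [0.0], [4.0]])
        out = quant.normalize(m)
        assert out.values["126"].isna().tolist() == [False, True, False]

    def test_all_missing_channel_rejected(self):
        m = self._matrix([[0.0], [0.0]])
        with pytest.raises(ValueError, match="no finite values"):
            quant.normalize(m)


class TestPrmQuantify:
    def test_fractional_abundance(self):
        df = make_psms([{f"intensity_{c}": 100.0 for c in quant.TMT10_CHANNELS}] * 10)
        totals = {c: 1_000_000.0 for c in quant.TMT10_CHANNELS}
        out = quant.prm_quantify(df, totals)
        assert out["126"] == pytest.approx(1e-3)

    def test_retention_time_window_is_closed(self):
        df = make_psms(
            [{"rt": 31.2}, {"rt": 32.0}, {"rt": 32.9}, {"rt": 33.0}, {"rt": 30.0}]
        )
        totals = {c: 1.0 for c in quant.TMT10_CHANNELS}
        out = quant.prm_quantify(df, totals, rt_window=(31.2, 32.9))
        assert out["126"] == pytest.approx(300.0)  # exactly the 3 in-window PSMs

    def test_29_spectra_inclusion_fixture(self):
        df = make_psms([{"rt": 31.2 + 0.05 * i} for i in range(29)] + [{"rt": 40.0}])
        totals = {c: 29.0 * 100.0 for c in quant.TMT10_CHANNELS}
        out = quant.prm_quantify(df, totals, rt_window=(31.2, 32.9))
        assert out["126"] == pytest.approx(1.0)

    def test_zero_channel_total_rejected(self):
        df = make_psms([{}])
        totals = {c: 1.0 for c in quant.TMT10_CHANNELS}
        totals["131"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            quant.prm_quantify(df, totals)
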