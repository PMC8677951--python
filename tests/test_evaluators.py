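"""Fixture tables, synthetic landscapes, and the external-evaluator contract."""

from importlib import resources

import numpy as np
import pytest

from hexanlo import chemspace as cs
from hexanlo import contrast as ct
from hexanlo import evaluators as ev
from hexanlo import nlo_tensor as nt
from hexanlo.evaluators import (
    EvaluatorLookupError,
    ExternalEvaluator,
    FixtureError,
    SyntheticLandscapeSpec,
    load_fixtures,
    synthetic_evaluator,
    table_evaluator,
)


class TestLoadFixtures:
    def test_parent_static_and_dynamic_values(self, fixtures):
        assert fixtures.beta("26R(H)", 0.0) == 2347.0
        assert fixtures.beta("28M(H)", 1.165) == 5679.0
        assert fixtures.beta("28R(H)", 0.0) == 0.0

    def test_tilde_zero_stored_as_zero_with_ci(self, fixtures):
        rec = fixtures.get("28R(F)", table="table2")
        assert rec.beta_at(0.0) == 0.0
        assert rec.symmetry == "Ci"

    def test_descriptor_metadata_round_trip(self, fixtures):
        rec = fixtures.get("28M(H)", table="table1")
        assert rec.descriptors["phi_p"] == pytest.approx(31.54)
        assert rec.descriptors["pi_index"] == pytest.approx(-0.45)

    def test_table2_contrast_columns_recompute(self, fixtures):
        """Every printed Table 2 contrast cell agrees with recomputation
        from its stored ON/OFF betas within printed rounding."""
        contrasts = fixtures.contrast_tables["table2"]
        for _, row in contrasts.iterrows():
            sub = row["substituent"]
            off = fixtures.beta(f"28R({sub})", table="table2")
            for on_key, rcol, dcol in (
                (f"26R({sub})", "ratio_26R_28R", "diff_26R_28R"),
                (f"28M({sub})", "ratio_28M_28R", "diff_28M_28R"),
            ):
                on = fixtures.beta(on_key, table="table2")
                pair = ct.SwitchPair(beta_on=on, beta_off=off)
                ratio, _ = ct.ratio_contrast(pair)
                diff = ct.difference_contrast(pair)
                assert ratio == pytest.approx(float(row[rcol]), rel=0.011)
                assert diff == pytest.approx(float(row[dcol]), rel=0.011)

    def test_malformed_row_reported_by_name(self, tmp_path):
        src = resources.files("hexanlo") / "data"
        for f in src.iterdir():
            if f.name.endswith(".csv"):
                (tmp_path / f.name).write_text(f.read_text())
        bad = (tmp_path / "table1.csv").read_text().replace(
            "26R(H),26R", "26R(H),29Z", 1
        )
        (tmp_path / "table1.csv").write_text(bad)
        with pytest.raises(FixtureError, match="26R\\(H\\)"):
            load_fixtures(tmp_path)

    def test_missing_file_reported(self, tmp_path):
        with pytest.raises(FixtureError, match="table1.csv"):
            load_fixtures(tmp_path)

    def test_ci_with_nonzero_beta_rejected(self, tmp_path):
        src = resources.files("hexanlo") / "data"
        for f in src.iterdir():
            if f.name.endswith(".csv"):
                (tmp_path / f.name).write_text(f.read_text())
        text = (tmp_path / "table3.csv").read_text().replace(
            "28R(F_H_H),28R,A2B2C2,F,R1/R4,,,,,,,,,0",
            "28R(F_H_H),28R,A2B2C2,F,R1/R4,,,,,,,,,5",
        )
        (tmp_path / "table3.csv").write_text(text)
        with pytest.raises(FixtureError, match="Ci"):
            load_fixtures(tmp_path)


class TestTableEvaluator:
    def test_pairwise_prestudy_lookup(self, fixtures, a2b2c2):
        evaluate = table_evaluator(fixtures)
        a = cs.Assignment(a2b2c2, ("NH2", "H", "H"))
        assert evaluate("26R", a) == 1.56e4

    def test_centrosymmetric_fixture_zero(self, fixtures):
        evaluate = table_evaluator(fixtures)
        assert evaluate("28R", "28R(F)") == 0.0

    def test_c2_override_of_formal_centrosymmetry(self, fixtures, a2b2c2):
        """NO2 on R1/R4 is formally C_i but the fixture records beta > 0."""
        a = cs.Assignment(a2b2c2, ("NO2", "H", "H"))
        m = cs.expand_assignment(a)
        assert cs.is_formally_centrosymmetric("28R", m)
        assert table_evaluator(fixtures)("28R", a) == 1340.0

    def test_missing_record_raises_with_key(self, fixtures, a2b2c2):
        evaluate = table_evaluator(fixtures)
        a = cs.Assignment(a2b2c2, ("NH2", "NH2", "CN"))
        with pytest.raises(EvaluatorLookupError, match="28M\\(NH2_NH2_CN\\)"):
            evaluate("28M", a)


class TestSyntheticEvaluator:
    def test_centrosymmetry_cancellation(self, a2b2c2, default_library):
        spec = SyntheticLandscapeSpec(pattern=a2b2c2, library=default_library, seed=0)
        evaluate = synthetic_evaluator(spec)
        all_h = cs.Assignment(a2b2c2, ("H", "H", "H"))
        assert evaluate("28R", all_h) == 0.0
        assert evaluate("26R", all_h) > 0.0

    def test_symmetry_breaker_exempt(self, a2b2c2, default_library):
        spec = SyntheticLandscapeSpec(pattern=a2b2c2, library=default_library, seed=0)
        evaluate = synthetic_evaluator(spec)
        assert evaluate("28R", cs.Assignment(a2b2c2, ("NO2", "H", "H"))) > 0.0

    def test_additive_regime_is_sum_of_bases(self, a2b2c2, default_library):
        spec = SyntheticLandscapeSpec(
            pattern=a2b2c2, library=default_library, seed=5,
            coupling_scale=0.0, symmetry_cancellation=False,
        )
        base, _ = spec.tables()
        evaluate = synthetic_evaluator(spec)
        a = cs.Assignment(a2b2c2, ("CN", "OH", "F"))
        idx = [default_library.index(c) for c in a.choices]
        expected = sum(base["26R"][g, f] for g, f in enumerate(idx))
        assert evaluate("26R", a) == pytest.approx(expected)

    def test_deterministic_for_seed(self, a2b2c2, default_library):
        spec = SyntheticLandscapeSpec(pattern=a2b2c2, library=default_library, seed=9)
        e1, e2 = synthetic_evaluator(spec), synthetic_evaluator(spec)
        for a in cs.enumerate_space(a2b2c2, default_library[:3]):
            assert e1("26R", a) == e2("26R", a)

    def test_clamped_ratio_regime(self, a2b2c2, default_library):
        """Cancellation drives clamped ratio contrasts into the >= 1e5 regime
        whenever the ON response exceeds 100 a.u."""
        spec = SyntheticLandscapeSpec(pattern=a2b2c2, library=default_library, seed=1)
        evaluate = synthetic_evaluator(spec)
        for choices in (("H", "H", "H"), ("OH", "OH", "OH"), ("F", "CN", "F")):
            a = cs.Assignment(a2b2c2, choices)
            on, off = evaluate("26R", a), evaluate("28R", a)
            if off == 0.0 and on >= 100.0:
                ratio, clamped = ct.ratio_contrast(
                    ct.SwitchPair(beta_on=on, beta_off=off)
                )
                assert clamped and ratio >= 1e5

    def test_unknown_fragment_rejected(self, a2b2c2):
        spec = SyntheticLandscapeSpec(pattern=a2b2c2, library=("H", "F"), seed=0)
        evaluate = synthetic_evaluator(spec)
        with pytest.raises(cs.ChemSpaceError):
            evaluate("26R", cs.Assignment(a2b2c2, ("OH", "H", "F")))


class TestExternalEvaluator:
    def test_round_trip_with_stub_responder(self, tmp_path, a2b2c2):
        tensor = nt.BetaTensor.from_dict({"zzz": 1000.0}, sparse=True)

        def responder(request_path):
            nt.write_beta_tensor(tensor, ev.response_path_for(request_path))

        evaluate = ExternalEvaluator(tmp_path, responder=responder, timeout=5)
        a = cs.Assignment(a2b2c2, ("H", "H", "H"))
        value = evaluate("26R", a)
        assert value == pytest.approx(nt.beta_hrs(tensor).beta_hrs)

    def test_zero_tensor_gives_zero(self, tmp_path, a2b2c2):
        def responder(request_path):
            nt.write_beta_tensor(
                nt.BetaTensor(np.zeros((3, 3, 3))), ev.response_path_for(request_path)
            )

        evaluate = ExternalEvaluator(tmp_path, responder=responder, timeout=5)
        assert evaluate("28R", cs.Assignment(a2b2c2, ("H", "H", "H"))) == 0.0

    def test_malformed_response_propagates(self, tmp_path, a2b2c2):
        def responder(request_path):
            ev.response_path_for(request_path).write_text("{not json")

        evaluate = ExternalEvaluator(tmp_path, responder=responder, timeout=5)
        with pytest.raises(nt.BetaTensorError):
            evaluate("26R", cs.Assignment(a2b2c2, ("H", "H", "H")))

    def test_timeout_when_no_response(self, tmp_path, a2b2c2):
        evaluate = ExternalEvaluator(tmp_path, timeout=0.3, poll_interval=0.05)
        with pytest.raises(TimeoutError):
            evaluate("26R", cs.Assignment(a2b2c2, ("H", "H", "H")))
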