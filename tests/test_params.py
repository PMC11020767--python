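import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abtau import (
    CalibrationTargets,
    HealthReference,
    ModelParams,
    calibrate_health_fixed_point,
    clinical_unit_to_density,
    default_params,
    load_param_table,
    neuron_death_rate,
)
from abtau.params import health_residual


class TestClinicalUnits:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (1000, "ng/g", 1.00e-6),      # gray-matter amyloid in health
            (137, "pg/ml", 1.37e-10),     # tau in health
            (6700, "ng/g", 6.70e-6),      # amyloid in AD
            (490, "pg/ml", 4.90e-10),     # tau in AD
            (0, "ng/g", 0.0),
            (0, "pg/ml", 0.0),
            (2.5e-3, "g/cm3", 2.5e-3),
        ],
    )
    def test_conversion(self, value, unit, expected):
        assert clinical_unit_to_density(value, unit) == pytest.approx(expected, rel=1e-12)

    def test_unknown_unit_names_accepted_units(self):
        with pytest.raises(ValueError, match="ng/g"):
            clinical_unit_to_density(1.0, "mol/l")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            clinical_unit_to_density(-1.0, "ng/g")

    @given(st.floats(1e-6, 1e6), st.sampled_from(["ng/g", "pg/ml", "g/cm3"]))
    def test_linear_and_invertible(self, value, unit):
        d = clinical_unit_to_density(value, unit)
        assert clinical_unit_to_density(2 * value, unit) == pytest.approx(2 * d)
        factor = clinical_unit_to_density(1.0, unit)
        assert d / factor == pytest.approx(value)


class TestNeuronDeathRate:
    def test_reference_survival(self, ref):
        d = neuron_death_rate(0.66, 3650.0)
        assert ref.N0 * math.exp(-d * 3650.0) == pytest.approx(3.96e-2, rel=5e-3)

    def test_rate_scaling_spans_life_expectancy_range(self, ref):
        # halved rate (15-year expectancy) and doubled rate (5-year)
        d = neuron_death_rate(0.66, 3650.0)
        assert ref.N0 * math.exp(-0.5 * d * 3650.0) == pytest.approx(4.87e-2, rel=5e-3)
        assert ref.N0 * math.exp(-2.0 * d * 3650.0) == pytest.approx(2.61e-2, rel=5e-3)

    @given(
        st.floats(0.05, 0.95), st.floats(100.0, 1e4), st.floats(0.1, 10.0)
    )
    def test_group_property(self, f, horizon, c):
        # rate(f, T) == rate(f**c, T) / c
        assert neuron_death_rate(f, horizon) == pytest.approx(
            neuron_death_rate(f**c, horizon) / c, rel=1e-9
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_fraction_domain(self, bad):
        with pytest.raises(ValueError):
            neuron_death_rate(bad, 3650.0)


class TestCalibration:
    def test_health_is_exact_fixed_point(self, params, ref):
        resid = health_residual(params, ref)
        scale = ref.as_state_vector()
        assert np.all(np.abs(resid) <= 1e-14 * scale)

    def test_idempotent(self, params, ref):
        again = calibrate_health_fixed_point(params, ref)
        assert again == params

    def test_production_identities(self, params, ref):
        assert params.lam_abi == pytest.approx(params.d_abi * ref.abi_ss)
        assert params.lam_tau == pytest.approx(params.d_tau * ref.tau_ss)
        assert params.lam_M == pytest.approx(params.d_M * ref.M0)

    def test_inconsistent_inputs_rejected(self, ref):
        # astrocytic production exceeding gross clearance implies a
        # negative constitutive production rate
        bad = ModelParams().replace(lam_abo_A=1e3)
        with pytest.raises(ValueError, match="lam_abo"):
            calibrate_health_fixed_point(bad, ref)

    def test_health_reference_requires_positive(self):
        with pytest.raises(ValueError):
            HealthReference(N0=0.0)

    def test_targets_ordering_enforced(self):
        with pytest.raises(ValueError):
            CalibrationTargets(abo_ad=1e-8)


class TestParamTable:
    def test_partial_override_keeps_defaults(self, tmp_path, params):
        table = tmp_path / "params.csv"
        table.write_text("# comment line\nd_abi, 2.0\n")
        loaded = load_param_table(table)
        assert loaded.d_abi == 2.0
        assert loaded.lam_abi == pytest.approx(2.0 * 1.0e-6)  # recalibrated
        assert loaded.d_tau == params.d_tau

    def test_empty_table_is_defaults(self, tmp_path, params):
        table = tmp_path / "empty.csv"
        table.write_text("\n# nothing here\n")
        assert load_param_table(table) == params

    def test_negative_rate_rejected(self, tmp_path):
        table = tmp_path / "neg.csv"
        table.write_text("d_abi, -1.0\n")
        with pytest.raises(ValueError, match="non-negative"):
            load_param_table(table)

    def test_malformed_number_reports_line(self, tmp_path):
        table = tmp_path / "bad.tsv"
        table.write_text("d_abi\t1.0\nd_tau\tabc\n")
        with pytest.raises(ValueError, match=":2"):
            load_param_table(table)

    def test_unknown_name_rejected(self, tmp_path):
        table = tmp_path / "unk.csv"
        table.write_text("lambda_nonsense, 1.0\n")
        with pytest.raises(ValueError, match="lambda_nonsense"):
            load_param_table(table)

    def test_incomplete_standalone_table_lists_gaps(self, tmp_path):
        # base=None requires the table to be complete
        table = tmp_path / "incomplete.csv"
        table.write_text("d_abi, 1.8\n")
        with pytest.raises(ValueError, match="d_tau"):
            load_param_table(table, base=None)

    def test_units_and_notes_columns_ignored(self, tmp_path):
        table = tmp_path / "full.csv"
        table.write_text("d_abi, 1.9, 1/day, clearance of intraneural amyloid\n")
        assert load_param_table(table).d_abi == 1.9


def test_default_params_positive_and_finite():
    p = default_params()
    for name in ("lam_abi", "lam_abo", "lam_tau", "lam_M", "lam_A"):
        assert getattr(p, name) >= 0
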