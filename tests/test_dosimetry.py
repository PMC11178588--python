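"""MIRD self-dose under the three chain-partitioning methods."""

import numpy as np
import pandas as pd
import pytest

from acdose.chain import (
    ChainSegment,
    DecayChain,
    Nuclide,
    alpha_energy_per_decay,
    bi_segment,
    fr_segment,
    full_segment,
)
from acdose.dosimetry import (
    DoseConfig,
    DoseResult,
    SValueTable,
    dose_method1,
    dose_method2,
    dose_method3,
    local_alpha_svalue,
    method_percent_difference,
)
from acdose.errors import InvalidInputError, UndefinedRatioError
from acdose.kinetics import MonoExpFit, time_integrated_activity

J_PER_MEV = 1.602e-13


def _unit_segment():
    """A single-nuclide chain emitting exactly 1 MeV of alpha per decay."""
    nuc = Nuclide("Ac-225", 1.0, alpha_emissions=((1.0, 1.0),))
    chain = DecayChain(members=(nuc,), branches={})
    return ChainSegment("unit", ("Ac-225",), "Ac-225", chain)


class TestLocalAlphaSValue:
    def test_unit_conversion(self):
        assert local_alpha_svalue(_unit_segment(), 1.0) == pytest.approx(1.602e-10, rel=1e-12)

    def test_bi_segment_lesion_mass(self, chain):
        s = local_alpha_svalue(bi_segment(chain), 23.0)
        assert s == pytest.approx(8.345 * J_PER_MEV / 0.023, rel=1e-9)
        assert s == pytest.approx(5.81e-11, rel=1e-2)

    def test_inverse_in_mass(self, chain):
        seg = fr_segment(chain)
        assert local_alpha_svalue(seg, 100.0) == pytest.approx(
            local_alpha_svalue(seg, 200.0) * 2.0, rel=1e-12
        )

    def test_nonpositive_mass_rejected(self, chain):
        with pytest.raises(InvalidInputError):
            local_alpha_svalue(fr_segment(chain), 0.0)


@pytest.fixture
def cfg():
    return DoseConfig(rbe=5.0)


class TestMethods:
    def test_inverse_construction_one_gray(self, chain, cfg):
        """A TAC whose time-integrated activity is 1/S Bq·s yields 1 Gy."""
        full = full_segment(chain)
        mass = 200.0
        s = local_alpha_svalue(full, mass)
        t_eff = 27.0
        a_t0 = (1.0 / s) / (t_eff * 3600.0 / np.log(2))
        fit = MonoExpFit(a_t0, t_eff, 2, 0.0)
        res = dose_method1(fit, full, cfg, mass, injected_mbq=7.7)
        assert res.absorbed_dose == pytest.approx(1.0, rel=1e-12)
        assert res.rbe_weighted == pytest.approx(5.0, rel=1e-12)

    def test_identical_fits_make_all_methods_equal(self, chain, cfg):
        fit = MonoExpFit(5.0e5, 27.0, 2, 0.0)
        full, frs, bis = full_segment(chain), fr_segment(chain), bi_segment(chain)
        m1 = dose_method1(fit, full, cfg, 200.0, 7.7)
        m2 = dose_method2(fit, full, cfg, 200.0, 7.7)
        m3 = dose_method3(fit, fit, frs, bis, cfg, 200.0, 7.7)
        assert m1.absorbed_dose == pytest.approx(m2.absorbed_dose, rel=1e-12)
        assert m1.absorbed_dose == pytest.approx(m3.absorbed_dose, rel=1e-12)
        assert m1.rbe_weighted == pytest.approx(m3.rbe_weighted, rel=1e-12)

    def test_method3_between_methods_when_fits_differ(self, chain, cfg):
        """Fr T_eff 24 h < Bi T_eff 27 h with equal amplitudes: the combined
        estimate lies strictly between the two single-TAC estimates."""
        bi_fit = MonoExpFit(5.0e5, 27.0, 2, 0.0)
        fr_fit = MonoExpFit(5.0e5, 24.0, 2, 0.0)
        full, frs, bis = full_segment(chain), fr_segment(chain), bi_segment(chain)
        m1 = dose_method1(bi_fit, full, cfg, 200.0, 7.7).absorbed_dose
        m2 = dose_method2(fr_fit, full, cfg, 200.0, 7.7).absorbed_dose
        m3 = dose_method3(fr_fit, bi_fit, frs, bis, cfg, 200.0, 7.7).absorbed_dose
        assert m2 < m3 < m1
        # direct evaluation oracle
        expected = (
            time_integrated_activity(fr_fit) * 3600 * local_alpha_svalue(frs, 200.0)
            + time_integrated_activity(bi_fit) * 3600 * local_alpha_svalue(bis, 200.0)
        )
        assert m3 == pytest.approx(expected, rel=1e-12)

    def test_method3_records_components(self, chain, cfg):
        m3 = dose_method3(
            MonoExpFit(5e5, 24.0, 2, 0.0), MonoExpFit(5e5, 27.0, 2, 0.0),
            fr_segment(chain), bi_segment(chain), cfg, 200.0, 7.7,
        )
        assert set(m3.components) == {"Fr-segment", "Bi-segment"}
        assert sum(m3.components.values()) == pytest.approx(m3.absorbed_dose, rel=1e-12)

    def test_dose_linear_in_amplitude(self, chain, cfg):
        full = full_segment(chain)
        d1 = dose_method1(MonoExpFit(1e5, 27.0, 2, 0.0), full, cfg, 200.0, 7.7)
        d2 = dose_method1(MonoExpFit(2e5, 27.0, 2, 0.0), full, cfg, 200.0, 7.7)
        assert d2.absorbed_dose == pytest.approx(2 * d1.absorbed_dose, rel=1e-12)

    def test_rbe_commutes_with_per_mbq(self, chain):
        full = full_segment(chain)
        fit = MonoExpFit(1e5, 27.0, 2, 0.0)
        d_rbe1 = dose_method1(fit, full, DoseConfig(rbe=1.0), 200.0, 7.7)
        d_rbe5 = dose_method1(fit, full, DoseConfig(rbe=5.0), 200.0, 7.7)
        assert d_rbe5.per_mbq == pytest.approx(5.0 * d_rbe1.per_mbq, rel=1e-12)
        assert d_rbe5.rbe_weighted == pytest.approx(5.0 * d_rbe5.absorbed_dose, rel=1e-12)


class TestSValueTableModel:
    def test_table_built_from_local_alpha_agrees(self, chain):
        """An S-value table whose entries equal the local-alpha S-values
        reproduces the alpha_local energy model to 1e-12."""
        mass = 150.0
        rows = []
        for name in chain.names:
            nuc = chain[name]
            rows.append({
                "nuclide": name,
                "mass_g": mass,
                "s_gy_per_bq_s": max(nuc.alpha_energy_per_decay * J_PER_MEV / (mass * 1e-3), 1e-30),
                "alpha_fraction": 1.0,
            })
        table = SValueTable(pd.DataFrame(rows), provenance="local-alpha mirror")
        fit = MonoExpFit(5e5, 27.0, 2, 0.0)
        full = full_segment(chain)
        local = dose_method1(fit, full, DoseConfig(rbe=5.0), mass, 7.7)
        tabular = dose_method1(
            fit, full, DoseConfig(rbe=5.0, energy_model="svalue_table", svalue_table=table),
            mass, 7.7,
        )
        assert tabular.absorbed_dose == pytest.approx(local.absorbed_dose, rel=1e-12)
        assert tabular.rbe_weighted == pytest.approx(local.rbe_weighted, rel=1e-12)

    def test_log_log_mass_interpolation(self):
        table = SValueTable(pd.DataFrame({
            "nuclide": ["Bi-213"] * 2, "mass_g": [10.0, 1000.0],
            "s_gy_per_bq_s": [1e-10, 1e-12],
        }))
        s, interpolated = table.lookup("Bi-213", 100.0)
        assert interpolated
        assert s == pytest.approx(1e-11, rel=1e-9)  # geometric midpoint


class TestPercentDifference:
    def _res(self, dose):
        return DoseResult(dose / 5.0, dose, dose / 7.7, 1)

    def test_identical_zero(self):
        assert method_percent_difference(self._res(0.17), self._res(0.17)) == pytest.approx(0.0)

    def test_both_conventions(self):
        a, b = self._res(0.18), self._res(0.16)
        assert method_percent_difference(a, b, "symmetric") == pytest.approx(11.76, abs=0.01)
        assert method_percent_difference(a, b, "relative_to_second") == pytest.approx(12.5, abs=1e-9)

    def test_symmetric_convention_is_symmetric(self):
        a, b = self._res(0.36), self._res(0.38)
        assert method_percent_difference(a, b) == pytest.approx(method_percent_difference(b, a))

    def test_zero_doses_rejected(self):
        with pytest.raises(UndefinedRatioError):
            method_percent_difference(self._res(0.0), self._res(0.0))
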