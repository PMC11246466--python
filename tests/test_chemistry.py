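import numpy as np
import pytest
from scipy.integrate import solve_ivp

import auxindisk as ad
from auxindisk._arrays import compile_arrays
from auxindisk.chemistry import (ChemParams, auxin_substep, cuc_substep,
                                 dilute_concentrations, draw_noise, init_pin,
                                 pin_sensitivity, run_chemistry, update_pin)
from auxindisk.mesh import TissueMesh, update_areas

from conftest import mesh_from_polygons, three_cell_strip, unequal_neighbor_mesh


def single_cell():
    m = mesh_from_polygons([[(0, 0), (5, 0), (5, 5), (0, 5)]])
    init_pin(m)
    return m


class TestPinSensitivity:
    @pytest.mark.parametrize("cuc,thres,expect", [
        (0.0, 2.0, 1),
        (3.0, 2.0, 2),
        (2.0, 2.0, 2),   # tie goes to the high-sensitivity branch
        (1.999, 2.0, 1),
    ])
    def test_exponent(self, cuc, thres, expect):
        assert pin_sensitivity(cuc, thres) == expect


class TestInitPin:
    def test_equal_interior_walls(self):
        """Three equal-length interfaces share PIN 1/3 each."""
        tri = [(0.0, 0.0), (1.0, 0.0), (0.5, np.sqrt(3) / 2)]
        cx, cy = 0.5, np.sqrt(3) / 6
        outer = [(0.5 + 3 * (x - 0.5), np.sqrt(3) / 6 + 3 * (y - np.sqrt(3) / 6))
                 for x, y in tri]
        polys = [tri]
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            oa, ob = outer[i], outer[(i + 1) % 3]
            polys.append([a, ob if False else oa, ob, b][::-1])
        m = mesh_from_polygons(polys)
        init_pin(m)
        center = m.cells[0]
        interior = [w for w in (m.walls[i] for i in center.wall_ids)
                    if len(w.cells) == 2]
        assert len(interior) == 3
        for w in interior:
            assert w.pin[0] == pytest.approx(1 / 3)

    def test_length_proportional(self):
        m = unequal_neighbor_mesh()
        init_pin(m)
        center = m.cells[1]  # the pentagon with interfaces of lengths 1 and 2
        pins = sorted(m.walls[w].pin[1] for w in center.wall_ids
                      if len(m.walls[w].cells) == 2)
        assert pins == [pytest.approx(1 / 3), pytest.approx(2 / 3)]

    def test_boundary_walls_zero(self):
        m = three_cell_strip()
        init_pin(m)
        for w in m.walls.values():
            if len(w.cells) == 1:
                assert w.pin[w.cells[0]] == 0.0
        # middle cell: two equal interior interfaces -> 1/2 each
        mid = m.cells[1]
        pins = [m.walls[w].pin[1] for w in mid.wall_ids
                if len(m.walls[w].cells) == 2]
        assert pins == [pytest.approx(0.5)] * 2

    def test_isolated_cell_flagged(self):
        m = single_cell()
        assert any("isolated" in w for w in m.warnings)


class TestUpdatePin:
    def _strip_with_aux(self, aux_left, aux_right, cuc_mid):
        m = three_cell_strip()
        init_pin(m)
        m.cells[0].aux = aux_left
        m.cells[2].aux = aux_right
        m.cells[1].cuc = cuc_mid
        return m

    def test_linear_target(self):
        """Neighbours (aux 2, L 1) and (aux 1, L 1): targets 2/3 and 1/3."""
        m = self._strip_with_aux(2.0, 1.0, cuc_mid=0.0)
        update_pin(m, ChemParams(alpha=0.01))
        pins = {w.cells[0] if w.cells[0] != 1 else w.cells[1]: w.pin[1]
                for w in m.walls.values() if len(w.cells) == 2}
        assert pins[0] == pytest.approx(0.99 * 0.5 + 0.01 * 2 / 3, abs=1e-9)
        assert pins[2] == pytest.approx(0.99 * 0.5 + 0.01 * 1 / 3, abs=1e-9)

    def test_quadratic_target_above_cuc_threshold(self):
        """cuc above threshold squares the auxin weighting: targets 0.8/0.2."""
        m = self._strip_with_aux(2.0, 1.0, cuc_mid=3.0)
        update_pin(m, ChemParams(alpha=0.01))
        pins = {w.cells[0] if w.cells[0] != 1 else w.cells[1]: w.pin[1]
                for w in m.walls.values() if len(w.cells) == 2}
        assert pins[0] == pytest.approx(0.503, abs=1e-9)
        assert pins[2] == pytest.approx(0.497, abs=1e-9)

    def test_zero_aux_falls_back_to_lengths(self):
        m = self._strip_with_aux(0.0, 0.0, cuc_mid=0.0)
        update_pin(m, ChemParams(alpha=0.5))
        pins = [w.pin[1] for w in m.walls.values() if len(w.cells) == 2]
        assert pins == [pytest.approx(0.5)] * 2

    def test_per_cell_sums_preserved(self, disk):
        rng = np.random.default_rng(0)
        for c in disk.cells.values():
            c.aux = rng.random() * 5
            c.cuc = rng.random() * 4
        for _ in range(20):
            update_pin(disk, ChemParams(alpha=0.1))
        for cell in disk.cells.values():
            s = sum(disk.walls[w].pin.get(cell.id, 0.0)
                    for w in cell.wall_ids)
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_cuc(self):
        """Raising cuc above threshold increases the high-auxin target share."""
        low = self._strip_with_aux(2.0, 1.0, cuc_mid=0.0)
        high = self._strip_with_aux(2.0, 1.0, cuc_mid=5.0)
        update_pin(low, ChemParams(alpha=1.0))
        update_pin(high, ChemParams(alpha=1.0))
        def share(m):
            return max(w.pin[1] for w in m.walls.values()
                       if len(w.cells) == 2)
        assert share(high) > share(low)


class TestNoise:
    def test_sd_zero_gives_unity(self, disk):
        draw_noise(disk, 0.0, False, np.random.default_rng(0))
        assert all(c.delta_aux == 1.0 for c in disk.cells.values())

    def test_negative_draws_clamped(self, disk):
        draw_noise(disk, 5.0, False, np.random.default_rng(1))
        vals = [c.delta_aux for c in disk.cells.values()]
        assert min(vals) >= 0.0
        assert any(v == 0.0 for v in vals)  # SD 5 surely produced negatives

    def test_frozen_noise_kept(self, disk):
        rng = np.random.default_rng(2)
        draw_noise(disk, 1.0, True, rng, at_init=True)
        before = {c.id: c.delta_aux for c in disk.cells.values()}
        for _ in range(5):
            draw_noise(disk, 1.0, True, rng)
        assert {c.id: c.delta_aux for c in disk.cells.values()} == before


class TestConcentrationSteps:
    def test_isolated_cell_auxin_fixed_point(self):
        """No neighbours: aux converges to Prod/Dec = 5."""
        m = single_cell()
        p = ChemParams()
        for _ in range(600):
            run_chemistry(m, p)
        assert m.cells[0].aux == pytest.approx(5.0, rel=1e-3)

    def test_transport_conserves_total_amount(self):
        m = three_cell_strip()
        init_pin(m)
        rng = np.random.default_rng(3)
        for c in m.cells.values():
            c.aux = rng.random() * 10
        # dt small enough that no concentration is driven below zero (the
        # clamp would otherwise create auxin); transport then conserves the
        # total amount exactly
        p = ChemParams(prod_aux=0.0, dec_aux=0.0, alpha=0.0, prod_cuc=0.0,
                       dt_chem=1e-4)
        arrays = compile_arrays(m)
        amount0 = float((arrays.aux * arrays.areas()).sum())
        for _ in range(50):
            auxin_substep(m, p)
        arrays = compile_arrays(m)
        amount1 = float((arrays.aux * arrays.areas()).sum())
        assert amount1 == pytest.approx(amount0, rel=1e-12)

    def test_zero_state_stays_zero(self):
        m = three_cell_strip()
        init_pin(m)
        for c in m.cells.values():
            c.delta_aux = 0.0
        run_chemistry(m, ChemParams(prod_cuc=0.0))
        assert all(c.aux == 0 for c in m.cells.values())

    def test_cuc_fixed_points(self):
        """cuc* = 2.5 at aux = K_aux (production halved) and 5 at aux = 0."""
        m = three_cell_strip()
        m.cells[0].aux = 5.0
        m.cells[1].aux = 0.0
        m.cells[2].aux = 1000.0
        p = ChemParams()
        for _ in range(6000):
            cuc_substep(m, p)
        assert m.cells[0].cuc == pytest.approx(2.5, rel=1e-3)
        assert m.cells[1].cuc == pytest.approx(5.0, rel=1e-3)
        assert m.cells[2].cuc == pytest.approx(0.0, abs=1e-6)

    def test_cuc_decays_without_production(self):
        m = three_cell_strip()
        for c in m.cells.values():
            c.cuc = 4.0
        p = ChemParams(prod_cuc=0.0)
        run_chemistry(m, p)
        assert all(0 < c.cuc < 4.0 for c in m.cells.values())


class TestChemistryOracle:
    def test_matches_independent_ode_integration(self):
        """3-cell chain with frozen PIN vs high-accuracy RK45 integration."""
        m = three_cell_strip()
        init_pin(m)
        m.cells[0].aux, m.cells[1].aux, m.cells[2].aux = 1.0, 0.2, 3.0
        m.cells[1].cuc = 1.0
        for i, c in enumerate(m.cells.values()):
            c.delta_aux = [1.0, 0.5, 1.5][i]
        arrays = compile_arrays(m)
        areas = arrays.areas()
        pin = arrays.pair_pins()
        src, dst = arrays.pair_src, arrays.pair_dst
        delta = arrays.delta.copy()
        p = ChemParams(alpha=0.0)  # frozen PIN

        def rhs(_t, y):
            aux, cuc = y[:3], y[3:]
            influx = np.bincount(dst, weights=aux[src] * pin, minlength=3)
            outflux = aux * np.bincount(src, weights=pin, minlength=3)
            daux = (p.prod_aux * delta - p.dec_aux * aux
                    + p.tran_aux * (influx - outflux) / areas)
            dcuc = (p.prod_cuc / (1 + (aux / p.k_aux) ** p.hill)
                    - p.dec_cuc * cuc)
            return np.concatenate([daux, dcuc])

        y0 = np.concatenate([arrays.aux, arrays.cuc])
        t_end = 0.1
        sol = solve_ivp(rhs, (0, t_end), y0, rtol=1e-11, atol=1e-12)
        expect_aux, expect_cuc = sol.y[:3, -1], sol.y[3:, -1]

        fine = ChemParams(alpha=0.0, dt_chem=1e-5,
                          n_substeps=int(round(t_end / 1e-5)))
        run_chemistry(m, fine)
        got_aux = np.array([c.aux for c in m.cells.values()])
        got_cuc = np.array([c.cuc for c in m.cells.values()])
        assert np.max(np.abs(got_aux - expect_aux) / np.abs(expect_aux)) < 1e-3
        assert np.max(np.abs(got_cuc - expect_cuc) / np.abs(expect_cuc)) < 1e-3

    def test_all_rates_zero_is_identity(self):
        m = three_cell_strip()
        init_pin(m)
        m.cells[0].aux = 2.0
        p = ChemParams(alpha=1e-12, prod_aux=0, dec_aux=0, tran_aux=0,
                       prod_cuc=0, dec_cuc=0)
        before = [(c.aux, c.cuc) for c in m.cells.values()]
        run_chemistry(m, p)
        after = [(c.aux, c.cuc) for c in m.cells.values()]
        assert np.allclose(before, after)

    def test_substep_count(self):
        assert ChemParams().n_substeps == 10


class TestDilution:
    def test_area_doubling_halves_concentrations(self):
        m = three_cell_strip()
        m.cells[0].aux, m.cells[0].cuc = 4.0, 2.0
        before = {c: 1.0 for c in m.cells}
        after = {c: 2.0 for c in m.cells}
        dilute_concentrations(m, before, after)
        assert m.cells[0].aux == pytest.approx(2.0)
        assert m.cells[0].cuc == pytest.approx(1.0)

    def test_amount_conserved(self):
        m = three_cell_strip()
        rng = np.random.default_rng(0)
        for c in m.cells.values():
            c.aux = rng.random() * 3
        before = {c.id: c.area for c in m.cells.values()}
        after = {cid: a * rng.uniform(0.5, 2.0) for cid, a in before.items()}
        amount0 = sum(m.cells[c].aux * before[c] for c in m.cells)
        dilute_concentrations(m, before, after)
        amount1 = sum(m.cells[c].aux * after[c] for c in m.cells)
        assert amount1 == pytest.approx(amount0, rel=1e-12)

    def test_zero_area_raises(self):
        m = three_cell_strip()
        with pytest.raises(FloatingPointError):
            dilute_concentrations(m, {c: 1.0 for c in m.cells},
                                  {c: 0.0 for c in m.cells})


class TestEquivariance:
    def test_chemistry_commutes_with_rotation(self, disk):
        rng = np.random.default_rng(4)
        for c in disk.cells.values():
            c.aux = rng.random() * 6
            c.cuc = rng.random() * 4
        rot = disk.transform(rotation_deg=77.0)
        p = ChemParams()
        run_chemistry(disk, p)
        run_chemistry(rot, p)
        for cid in disk.cells:
            assert rot.cells[cid].aux == pytest.approx(disk.cells[cid].aux,
                                                       rel=1e-9)
            assert rot.cells[cid].cuc == pytest.approx(disk.cells[cid].cuc,
                                                       rel=1e-9)
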