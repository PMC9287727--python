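import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import nitrosite as ns
from nitrosite.decomposition import (COULOMB_KCAL, ChargeTopology,
                                     EnergeticsParameters, born_radii,
                                     coulomb_energy, gb_atom_energies,
                                     gb_energy, lj_energy)
from nitrosite.synthetic_data import EnsembleSpec, make_ensemble


def pair_coords(d):
    return np.array([[0.0, 0, 0], [d, 0, 0]])


class TestCoulomb:
    def test_conversion_constant_at_one_angstrom(self):
        e = coulomb_energy(pair_coords(1.0), np.array([1.0, 1.0]), [0], [1])
        assert e == pytest.approx(332.0636, abs=1e-4)

    def test_zero_charges(self):
        e = coulomb_energy(pair_coords(2.0), np.array([0.0, 1.0]), [0], [1])
        assert e == 0.0

    def test_inverse_distance_law(self):
        q = np.array([1.0, -1.0])
        e1 = coulomb_energy(pair_coords(2.0), q, [0], [1])
        e2 = coulomb_energy(pair_coords(4.0), q, [0], [1])
        assert e1 == pytest.approx(2 * e2)

    def test_interior_dielectric_scales(self):
        q = np.array([1.0, 1.0])
        p = EnergeticsParameters(interior_dielectric=4.0)
        assert coulomb_energy(pair_coords(1.0), q, [0], [1], p) == \
            pytest.approx(332.0636 / 4, abs=1e-4)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            coulomb_energy(np.zeros((2, 3)), np.ones(2), [0], [1])


class TestLennardJones:
    def test_zero_at_sigma(self):
        eps = np.array([0.2, 0.2])
        sig = np.array([3.5, 3.5])
        assert lj_energy(pair_coords(3.5), eps, sig, [0], [1]) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_minus_epsilon(self):
        eps = np.array([0.25, 0.25])
        sig = np.array([3.4, 3.4])
        r = 2 ** (1 / 6) * 3.4
        assert lj_energy(pair_coords(r), eps, sig, [0], [1]) == pytest.approx(-0.25, abs=1e-12)

    def test_lorentz_berthelot_three_atom_hand_sum(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [0, 4.2, 0.5]])
        eps = np.array([0.1, 0.2, 0.3])
        sig = np.array([3.2, 3.5, 3.0])
        total = lj_energy(coords, eps, sig, [0], [1, 2])

        def pair(i, j):
            r = np.linalg.norm(coords[i] - coords[j])
            e = np.sqrt(eps[i] * eps[j])
            s = 0.5 * (sig[i] + sig[j])
            return 4 * e * ((s / r) ** 12 - (s / r) ** 6)

        assert total == pytest.approx(pair(0, 1) + pair(0, 2), abs=1e-12)


def hct_descreening_quadrature(rho_i, s_j, d):
    """Direct numerical integral of (1/4pi) r^-4 over neighbour j's scaled
    sphere, excluding the region inside atom i's own radius."""
    lo, hi = max(rho_i, d - s_j), d + s_j
    if hi <= rho_i:
        return 0.0

    def integrand(u):
        cos_t = (u * u + d * d - s_j * s_j) / (2 * u * d)
        return np.clip((1 - cos_t) / 2, 0, 1) / (u * u)

    val, _ = quad(integrand, lo, hi, limit=300)
    return val


class TestBornRadii:
    def test_isolated_atom_offset_corrected(self):
        p = EnergeticsParameters()
        R = born_radii(np.zeros((1, 3)), np.array([1.6]), np.array([0.8]), p)
        assert R[0] == pytest.approx(1.6 - p.gb_offset, abs=1e-12)

    @pytest.mark.parametrize("d", [2.4, 3.0, 4.0, 6.0])
    def test_two_atom_descreening_matches_quadrature(self, d):
        p = EnergeticsParameters()
        rho = np.array([1.5, 1.7])
        scr = np.array([0.8, 0.85])
        rho_t = rho - p.gb_offset
        s1 = scr[1] * rho_t[1]
        # reproduce the analytic pairwise integral through the public radii
        R = born_radii(pair_coords(d), rho, scr, p)
        I_expected = hct_descreening_quadrature(rho_t[0], s1, d)
        psi = rho_t[0] * I_expected
        arg = p.obc_alpha * psi - p.obc_beta * psi ** 2 + p.obc_gamma * psi ** 3
        R_expected = 1.0 / (1.0 / rho_t[0] - np.tanh(arg) / rho[0])
        assert R[0] == pytest.approx(R_expected, rel=1e-6)

    def test_burial_monotonically_increases_radius(self):
        p = EnergeticsParameters()
        rho = np.array([1.5, 1.5])
        scr = np.array([0.8, 0.8])
        radii = [born_radii(pair_coords(d), rho, scr, p)[0]
                 for d in (6.0, 5.0, 4.0, 3.0, 2.5)]
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_radius_below_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            born_radii(np.zeros((1, 3)), np.array([0.05]), np.array([0.8]))


class TestGeneralizedBorn:
    def test_single_ion_born_equation(self):
        p = EnergeticsParameters()
        R = np.array([2.0])
        e = gb_energy(np.zeros((1, 3)), np.array([1.0]), R, p)
        assert e == pytest.approx(-0.5 * COULOMB_KCAL * p.tau / 2.0, rel=1e-12)

    def test_charge_bilinearity(self):
        p = EnergeticsParameters()
        coords = pair_coords(4.0)
        R = np.array([1.5, 1.5])
        e1 = gb_energy(coords, np.array([1.0, -0.5]), R, p)
        e2 = gb_energy(coords, np.array([2.0, -1.0]), R, p)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_far_pair_solvent_screening_limit(self):
        p = EnergeticsParameters()
        coords = pair_coords(60.0)
        q = np.array([1.0, 1.0])
        rho = np.array([1.5, 1.5])
        scr = np.array([0.8, 0.8])
        R = born_radii(coords, rho, scr, p)
        self_term = -0.5 * COULOMB_KCAL * p.tau * (1 / R[0] + 1 / R[1])
        cross = gb_energy(coords, q, R, p) - self_term
        total = coulomb_energy(coords, q, [0], [1], p) + cross
        screened = COULOMB_KCAL / (p.solvent_dielectric * 60.0)
        assert total == pytest.approx(screened, rel=0.01)

    def test_atom_split_sums_to_total(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 8, size=(12, 3))
        q = rng.normal(size=12)
        R = np.full(12, 1.6)
        per_atom = gb_atom_energies(coords, q, R)
        assert per_atom.sum() == pytest.approx(gb_energy(coords, q, R), rel=1e-12)


class TestChargeTopology:
    def test_tsv_round_trip(self, toy_site, tmp_path):
        p = tmp_path / "topo.tsv"
        toy_site.topology.to_tsv(p)
        back = ChargeTopology.from_tsv(p)
        assert len(back) == len(toy_site.topology)
        assert np.allclose(back.charges, toy_site.topology.charges)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ChargeTopology(pd.DataFrame({"entity": ["x"]}))

    def test_model_mismatch_detected(self, toy_site):
        broken = ChargeTopology(toy_site.topology.table.iloc[:-1])
        with pytest.raises(ValueError, match="atoms but topology"):
            broken.match_model(toy_site.model)

    def test_unknown_atom_detected(self, toy_site):
        tbl = toy_site.topology.table.copy()
        tbl.loc[0, "atomname"] = "ZZ9"
        with pytest.raises(ValueError, match="without frame atoms"):
            ChargeTopology(tbl).match_model(toy_site.model)


@pytest.fixture(scope="module")
def toy_decomposition(toy_site):
    ens, _ = make_ensemble(toy_site, EnsembleSpec(
        moiety_sigmas={"chain L": 0.1}, n_frames=6, seed=3))
    return ens, ns.binding_decomposition(ens)


class TestBindingDecomposition:
    def test_per_frame_conservation_against_direct_totals(self, toy_decomposition):
        """Sum of per-residue rows equals the independently computed
        dE = E(complex) - E(receptor) - E(ligand) each frame."""
        ens, dec = toy_decomposition
        topo = ens.topology
        p = dec.params
        lig = topo.entity_indices("ligand")
        rec = np.flatnonzero(~np.isin(topo.table.entity, ["ligand", "water"]))
        both = np.concatenate([rec, lig])
        scr = topo.screen_factors(p)
        for f, frame in enumerate(ens.frames):
            e_cross = (coulomb_energy(frame, topo.charges, lig, rec, p)
                       + lj_energy(frame, topo.lj_epsilon, topo.lj_sigma, lig, rec))

            def gb_state(idx):
                R = born_radii(frame[idx], topo.gb_radii[idx], scr[idx], p)
                return gb_energy(frame[idx], topo.charges[idx], R, p)

            d_gb = gb_state(both) - gb_state(rec) - gb_state(lig)
            assert dec.per_frame_total[f] == pytest.approx(e_cross + d_gb, abs=1e-6)

    def test_rows_sum_to_total(self, toy_decomposition):
        _, dec = toy_decomposition
        assert dec.table.total.sum() == pytest.approx(dec.total, abs=1e-6)

    def test_frame_order_invariance(self, toy_site, toy_decomposition):
        ens, dec = toy_decomposition
        reversed_ens = ns.Ensemble(ens.frames[::-1].copy(), ens.topology)
        dec2 = ns.binding_decomposition(reversed_ens)
        assert np.allclose(dec.table.total.sort_index(),
                           dec2.table.total.sort_index(), atol=1e-9)

    def test_stride_subsampling_within_two_sems(self, toy_site):
        ens, _ = make_ensemble(toy_site, EnsembleSpec(
            moiety_sigmas={"chain L": 0.15}, n_frames=40, seed=9))
        full = ns.binding_decomposition(ens)
        half = ns.binding_decomposition(ns.Ensemble(ens.frames[::2].copy(),
                                                    ens.topology))
        for key in full.table.index:
            diff = abs(full.table.total[key] - half.table.total[key])
            band = 2 * (full.table["sem"][key] + half.table["sem"][key]) + 1e-9
            assert diff <= band

    def test_inert_ligand_contributes_nothing(self, toy_site):
        p = EnergeticsParameters()
        tbl = toy_site.topology.table.copy()
        lig = tbl.entity == "ligand"
        tbl.loc[lig, ["charge_e", "lj_epsilon_kcal"]] = 0.0
        tbl.loc[lig, "gb_radius_A"] = p.gb_offset + 1e-9
        topo = ChargeTopology(tbl)
        idx = topo.match_model(toy_site.model)
        ens = ns.Ensemble(toy_site.model.coords()[idx][None, :, :], topo)
        dec = ns.binding_decomposition(ens, params=p)
        assert np.abs(dec.table.total.to_numpy()).max() < 1e-6

    def test_single_residue_receptor_matches_direct_pair_terms(self):
        rows = []
        coords = []
        for i, (entity, ch, rn, rname, aname, q, xyz) in enumerate([
                ("protein", "A", 1, "ARG", "NH1", 0.5, (0, 0, 0)),
                ("protein", "A", 1, "ARG", "NH2", 0.5, (1.9, 0, 0)),
                ("ligand", "L", 9, "LIG", "O1", -0.5, (0, 3.0, 0)),
                ("ligand", "L", 9, "LIG", "O2", -0.5, (1.9, 3.0, 0))]):
            rows.append({"entity": entity, "chain": ch, "resnum": rn,
                         "resname": rname, "atomname": aname, "charge_e": q,
                         "lj_epsilon_kcal": 0.2, "lj_sigma_A": 3.0,
                         "gb_radius_A": 1.6, "element": aname[0]})
            coords.append(xyz)
        topo = ChargeTopology(pd.DataFrame(rows))
        frame = np.asarray(coords, dtype=float)
        ens = ns.Ensemble(frame[None, :, :], topo)
        dec = ns.binding_decomposition(ens)
        p = dec.params
        scr = topo.screen_factors(p)
        direct_cross = (coulomb_energy(frame, topo.charges, [2, 3], [0, 1], p)
                        + lj_energy(frame, topo.lj_epsilon, topo.lj_sigma,
                                    [2, 3], [0, 1]))

        def gb_state(idx):
            idx = np.asarray(idx)
            R = born_radii(frame[idx], topo.gb_radii[idx], scr[idx], p)
            return gb_energy(frame[idx], topo.charges[idx], R, p)

        d_gb = gb_state([0, 1, 2, 3]) - gb_state([0, 1]) - gb_state([2, 3])
        assert dec.table.total.sum() == pytest.approx(direct_cross + d_gb, abs=1e-9)
        assert set(dec.table.index) == {"A/ARG1", "ligand"}

    def test_unassigned_entity_rejected(self, toy_site):
        tbl = toy_site.topology.table.copy()
        tbl.loc[0, "entity"] = ""
        topo = ChargeTopology(tbl)
        idx = topo.match_model(toy_site.model)
        ens = ns.Ensemble(toy_site.model.coords()[idx][None, :, :], topo)
        with pytest.raises(ValueError, match="entity"):
            ns.binding_decomposition(ens)

    def test_outputs_serialize(self, toy_decomposition, tmp_path):
        _, dec = toy_decomposition
        tsv = dec.to_tsv(tmp_path / "dec.tsv")
        assert "kcal/mol" in tsv
        js = dec.to_json(tmp_path / "dec.json")
        assert '"total_mean"' in js
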