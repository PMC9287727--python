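import hashlib
import json

import numpy as np
import pytest

import nitrosite as ns
from nitrosite.synthetic_data import (MIN_NONBONDED, EnsembleSpec, ToySiteSpec,
                                      make_ensemble, make_reaction_states,
                                      make_toy_site, write_bundle)


class TestToySite:
    def test_designed_distances_exact(self, toy_site):
        model = toy_site.model
        sg = model.residue("A", 149).atom("SG").coords
        ne2 = model.residue("A", 176).atom("NE2").coords
        n150 = model.residue("A", 150).atom("N").coords
        sgl = model.residue("L", 2).atom("SG").coords
        assert np.linalg.norm(sg - ne2) == pytest.approx(3.30, abs=0.01)
        assert np.linalg.norm(sg - n150) == pytest.approx(3.25, abs=0.01)
        assert np.linalg.norm(sg - sgl) == pytest.approx(5.00, abs=0.01)

    def test_custom_geometry_honoured(self):
        site = make_toy_site(ToySiteSpec(dyad_distance=3.8, ligand_s_distance=4.0))
        sg = site.model.residue("A", 149).atom("SG").coords
        ne2 = site.model.residue("A", 176).atom("NE2").coords
        assert np.linalg.norm(sg - ne2) == pytest.approx(3.8, abs=1e-9)

    def test_clash_free(self, toy_site):
        views = list(toy_site.model.atoms())
        bonded = {frozenset([("L", 1, "CD"), ("L", 2, "N")]),
                  frozenset([("L", 2, "C"), ("L", 3, "N")])}
        for i, vi in enumerate(views):
            for vj in views[i + 1:]:
                if vi.residue.id == vj.residue.id:
                    continue
                key = frozenset([(vi.chain_id, vi.residue.seqid, vi.atom.name),
                                 (vj.chain_id, vj.residue.seqid, vj.atom.name)])
                if key in bonded:
                    continue
                assert np.linalg.norm(vi.atom.coords - vj.atom.coords) >= MIN_NONBONDED

    def test_formal_charges(self, toy_site):
        t = toy_site.topology.table
        lig = t[t.entity == "ligand"].charge_e.sum()
        cof = t[t.entity == "cofactor"].charge_e.sum()
        cys = t[(t.chain == "A") & (t.resnum == 149)].charge_e.sum()
        his = t[(t.chain == "A") & (t.resnum == 176)].charge_e.sum()
        assert lig == pytest.approx(-1.0, abs=1e-9)
        assert cof == pytest.approx(-2.0, abs=1e-9)
        assert cys == pytest.approx(-1.0, abs=1e-9)
        assert his == pytest.approx(+1.0, abs=1e-9)

    def test_charge_override(self):
        site = make_toy_site(ToySiteSpec(charge_overrides={("A149", "SG"): -0.5}))
        t = site.topology.table
        sg = t[(t.resnum == 149) & (t.atomname == "SG")].charge_e.iloc[0]
        assert sg == -0.5
        with pytest.raises(KeyError):
            make_toy_site(ToySiteSpec(charge_overrides={("A999", "XX"): 0.0}))

    def test_ligandless_spec_refused(self):
        with pytest.raises(ValueError, match="ligand"):
            make_toy_site(ToySiteSpec(include_ligand=False))

    def test_cofactor_optional(self):
        site = make_toy_site(ToySiteSpec(include_cofactor=False))
        assert "cofactor" not in set(site.topology.table.entity)
        assert len(site.model.chains) == 2


class TestReactionStates:
    def test_charge_conservation_across_states(self, toy_states):
        r, t, p = toy_states
        assert r.net_charge == pytest.approx(t.net_charge, abs=1e-9)
        assert r.net_charge == pytest.approx(p.net_charge, abs=1e-9)

    def test_lambda_zero_gives_null_fingerprint(self, toy_site, toy_frame):
        r, t, _ = make_reaction_states(toy_site, ts_fraction=0.0)
        table = ns.barrier_fingerprint(r, t, toy_frame, toy_site.topology).table
        assert np.allclose(table.ddE, 0.0, atol=1e-12)

    def test_lambda_one_fixed_geometry_equals_product_difference(
            self, toy_site, toy_frame):
        r, t, p = make_reaction_states(toy_site, ts_fraction=1.0,
                                       geometry="fixed")
        assert np.allclose(t.charges, p.charges)
        assert np.allclose(t.coords, r.coords)      # fixed-geometry mode
        table = ns.barrier_fingerprint(r, t, toy_frame, toy_site.topology,
                                       cutoff=6.0).table
        # rows whose atoms duplicate QM coordinates cannot be fed back through
        # state_interaction; check the pure-environment rows against it
        pure = [k for k in table.index if k not in ("ligand", "A/CYS149")]
        assert pure
        for key in pure:
            e_r = ns.state_interaction(r, toy_frame, toy_site.topology, key)
            e_p = ns.state_interaction(
                ns.ReactionState("product-fixed", r.atom_names, r.coords,
                                 p.charges),
                toy_frame, toy_site.topology, key)
            assert table.ddE[key] == pytest.approx(e_p - e_r, abs=1e-9)

    def test_ts_geometry_midpoint(self, toy_site):
        _, t, _ = make_reaction_states(toy_site, ts_fraction=0.5)
        sg_p = t.coords[t.atom_names.index("SG_prot")]
        sg_l = t.coords[t.atom_names.index("SG_lig")]
        nd = t.coords[t.atom_names.index("ND")]
        d1, d2 = np.linalg.norm(nd - sg_p), np.linalg.norm(nd - sg_l)
        assert d1 == pytest.approx(d2, abs=1e-9)   # exactly midway

    def test_bad_fraction_rejected(self, toy_site):
        with pytest.raises(ValueError):
            make_reaction_states(toy_site, ts_fraction=1.5)


class TestEnsembleGenerator:
    def test_zero_sigma_static(self, toy_site):
        ens, _ = make_ensemble(toy_site, EnsembleSpec(
            moiety_sigmas={"chain L": 0.0}, n_frames=5, seed=0))
        assert np.allclose(ens.frames, ens.frames[0])

    def test_seed_reproducibility(self, toy_site):
        spec = EnsembleSpec(moiety_sigmas={"chain L": 0.4}, n_frames=8,
                            rigid_jitter=(2.0, 0.3), seed=5)
        a, _ = make_ensemble(toy_site, spec)
        b, _ = make_ensemble(toy_site, spec)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self, toy_site):
        a, _ = make_ensemble(toy_site, EnsembleSpec(
            moiety_sigmas={"chain L": 0.4}, n_frames=8, seed=1))
        b, _ = make_ensemble(toy_site, EnsembleSpec(
            moiety_sigmas={"chain L": 0.4}, n_frames=8, seed=2))
        assert not np.array_equal(a.frames, b.frames)

    def test_unmatched_moiety_rejected(self, toy_site):
        with pytest.raises(ValueError, match="no atoms"):
            make_ensemble(toy_site, EnsembleSpec(
                moiety_sigmas={"chain Q": 0.4}, n_frames=5, seed=0))


class TestSphereFixture:
    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            ns.make_sphere_fixture([[0, 0, 0]], [1.0, 2.0])

    def test_reference_area_regimes(self):
        import math
        full = 4 * math.pi * (1.85 + 1.4) ** 2
        a1, a2 = ns.two_sphere_reference_areas(1.85, 1.85, 20.0)
        assert a1 == pytest.approx(full) and a2 == pytest.approx(full)
        a1, a2 = ns.two_sphere_reference_areas(2.5, 0.5, 0.1)
        assert a2 == 0.0 and a1 == pytest.approx(4 * math.pi * 3.9 ** 2)


class TestBundle:
    def test_bundle_deterministic_bytes(self, tmp_path):
        spec = ToySiteSpec(seed=3)
        ens = EnsembleSpec(moiety_sigmas={"chain L": 0.3}, n_frames=4, seed=3)
        p1 = write_bundle(tmp_path / "a", spec, ens)
        p2 = write_bundle(tmp_path / "b", spec, ens)
        for name in p1:
            h1 = hashlib.sha256(p1[name].read_bytes()).hexdigest()
            h2 = hashlib.sha256(p2[name].read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_bundle_round_trips_through_pipeline(self, tmp_path):
        paths = write_bundle(tmp_path, ToySiteSpec(seed=1),
                             EnsembleSpec(moiety_sigmas={"chain L": 0.2},
                                          n_frames=12, seed=1))
        topo = ns.ChargeTopology.from_tsv(paths["topology"])
        models = ns.read_structure(paths["ensemble"])
        ens = ns.Ensemble.from_models(models, topo)
        assert len(ens) == 12
        site_model = ns.read_model(paths["site"])
        dyads = ns.find_dyads(site_model)
        assert len(dyads) == 1 and dyads[0].sg_ne2 == pytest.approx(3.30, abs=0.01)
        truth = json.loads(paths["ground_truth"].read_text())
        # every designed contact is recovered by the contact scanner
        for id_a, id_b, d in truth["designed_contacts"]:
            ca, ra, aa = id_a.split("/")
            cb, rb, ab = id_b.split("/")
            found = ns.polar_contacts(
                site_model,
                f"chain {ca} and resi {ra[3:]} and name {aa}",
                f"chain {cb} and resi {rb[3:]} and name {ab}")
            assert len(found) == 1
            assert found[0].distance == pytest.approx(d, abs=2e-3)  # PDB 3dp
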