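"""Seeded generators for every input class the pipeline consumes.

The centrepiece is an idealized miniature S-nitrosylation site: a cysteine
thiolate / protonated-histidine dyad with flanking Thr, Ser and two Arg
fragments, an optional di-anionic cofactor mimic, and a glutathione-like
tripeptide ligand (gamma-Glu / Cys-NO / Gly) whose gamma-glutamyl carboxylate
faces one arginine in a designed bifurcated salt bridge. Every engineered
distance is placed exactly, the full ground truth (contacts, charges, moiety
memberships) is returned alongside the model, and all artifacts are
deterministic for a given seed — so each analysis stage can be tested against
known answers without any external data.

Residues are minimal idealized fragments with simple formal/united-atom
charges: the fixtures probe the analysis code, not force-field realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import ChargeTopology, Ensemble
from .fingerprint import ReactionState
from .structure_io import Atom, Chain, Residue, StructureModel, write_pdb

__all__ = [
    "ToySiteSpec",
    "EnsembleSpec",
    "ToySite",
    "make_toy_site",
    "make_reaction_states",
    "make_ensemble",
    "make_sphere_fixture",
    "two_sphere_reference_areas",
    "write_bundle",
]

# united-atom style nonbonded parameters by element: (eps kcal/mol, sigma Å)
LJ_PARAMS = {"H": (0.0157, 1.07), "C": (0.1094, 3.40), "N": (0.17, 3.25),
             "O": (0.21, 2.96), "S": (0.25, 3.56), "P": (0.20, 3.74)}
GB_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8, "P": 1.85}

MIN_NONBONDED = 1.8   # Å, clash threshold between atoms of different residues


def _u(*v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a)


@dataclass
class ToySiteSpec:
    """Engineered geometry of the miniature active site."""

    dyad_distance: float = 3.30        # Cys SG - His NE2, Å
    thr_n_distance: float = 3.25       # Cys SG - Thr backbone N, Å
    ligand_s_distance: float = 5.00    # Cys SG - ligand S(NO), Å
    ser_hg_distance: float = 2.20      # Cys SG - Ser hydroxyl H, Å
    carboxylate_his_distance: float = 2.85   # His ND1 - ligand carboxylate O
    include_ligand: bool = True
    include_cofactor: bool = True
    seed: int = 0
    charge_overrides: dict = field(default_factory=dict)  # (reskey, atom) -> e


@dataclass
class EnsembleSpec:
    """Gaussian-fluctuation ensemble around a base model."""

    moiety_sigmas: dict[str, float]    # selection expression -> sigma (Å/coord)
    n_frames: int = 200
    rigid_jitter: tuple[float, float] | None = None   # (rot deg, trans Å)
    seed: int = 0


@dataclass
class ToySite:
    model: StructureModel
    topology: ChargeTopology
    designed_contacts: list[tuple[str, str, float]]   # atom ids + distance
    ground_truth: dict
    spec: ToySiteSpec


def _residue(chain: str, seqid: int, name: str, atoms: list[tuple], hetero: bool,
             serial_start: int) -> tuple[Residue, list[dict], int]:
    """atoms: (atomname, element, coords, charge). Returns residue + topo rows."""
    res = Residue(chain, seqid, name, [], "")
    rows = []
    serial = serial_start
    for aname, elem, xyz, q in atoms:
        res.atoms.append(Atom(serial, aname, elem, np.asarray(xyz, float),
                              1.0, "", hetero, 10.0))
        eps, sig = LJ_PARAMS[elem]
        rows.append({"chain": chain, "resnum": seqid, "resname": name,
                     "atomname": aname, "charge_e": q,
                     "lj_epsilon_kcal": eps, "lj_sigma_A": sig,
                     "gb_radius_A": GB_RADII[elem], "element": elem})
        serial += 1
    return res, rows, serial


def make_toy_site(spec: ToySiteSpec | None = None) -> ToySite:
    """Build the miniature active site with exact engineered distances.

    The protein Cys SG sits at the origin; the His imidazole lies along +x at
    the dyad distance, the Thr backbone N below the thiolate, the Ser hydroxyl
    dipole pointing at the sulfur, and the ligand sulfur along +z. The
    gamma-glutamyl carboxylate is anchored to the His ND1 (salt bridge /
    hydrogen bond) and to a bifurcated arginine; a second arginine sits near
    the S...S NO-transfer axis, slightly closer to the ligand sulfur.
    """
    spec = spec or ToySiteSpec()
    if not spec.include_ligand:
        raise ValueError("the toy site requires its ligand: downstream binding "
                         "decomposition and reaction states are undefined "
                         "without it (set include_ligand=True)")

    sg = np.zeros(3)

    # --- protein fragments -------------------------------------------------
    cys = [
        ("N", "N", (-4.0, 1.0, 0.5), -0.30),
        ("CA", "C", (-2.7, 1.2, 0.0), 0.25),
        ("C", "C", (-2.9, 2.2, -1.15), 0.45),
        ("O", "O", (-2.3, 3.25, -1.25), -0.40),
        ("CB", "C", (-1.8, 0.0, 0.0), -0.20),
        ("SG", "S", tuple(sg), -0.80),
    ]

    ne2 = sg + spec.dyad_distance * _u(1, 0, 0)
    w = _u(0.66, 0.14, 0.74)                    # NE2 -> ND1 across the ring
    nd1 = ne2 + 2.19 * w
    mid_ring = 0.5 * (ne2 + nd1)
    perp = _u(*np.cross(w, (0, 1, 0)))
    ce1 = mid_ring - 0.74 * perp
    cg = nd1 + 1.38 * _u(0.5, -0.5, -0.7)
    cd2 = ne2 + 1.37 * _u(0.9, -0.35, -0.42)
    cb_h = cg + 1.50 * _u(1, 0, 0.3)
    ca_h = cb_h + np.array([1.2, 0.6, 0.7])
    his = [
        ("CA", "C", tuple(ca_h), 0.0),
        ("CB", "C", tuple(cb_h), 0.10),
        ("CG", "C", tuple(cg), 0.10),
        ("ND1", "N", tuple(nd1), 0.25),
        ("CE1", "C", tuple(ce1), 0.20),
        ("NE2", "N", tuple(ne2), 0.25),
        ("CD2", "C", tuple(cd2), 0.10),
    ]

    n_thr = sg + spec.thr_n_distance * _u(0, -0.95, 0.312)
    ca_t = n_thr + np.array([0.5, -1.2, 0.6])
    cb_t = ca_t + np.array([1.4, -0.2, 0.55])
    thr = [
        ("N", "N", tuple(n_thr), -0.30),
        ("CA", "C", tuple(ca_t), 0.25),
        ("CB", "C", tuple(cb_t), 0.10),
        ("OG1", "O", tuple(cb_t + 1.38 * _u(-0.5, 1.05, 0.75)), -0.45),
        ("CG2", "C", tuple(cb_t + 1.49 * _u(0.6, -1.3, -0.4)), 0.40),
        ("C", "C", tuple(ca_t + 1.52 * _u(-0.6, -1.1, 0.85)), 0.45),
        ("O", "O", tuple(ca_t + 1.52 * _u(-0.6, -1.1, 0.85)
                         + 1.21 * _u(-1.05, -0.35, -0.45)), -0.45),
    ]

    u3 = _u(-0.55, 0.55, 0.63)
    hg = sg + spec.ser_hg_distance * u3
    og = sg + (spec.ser_hg_distance + 0.8) * u3
    cb_s = og + 1.43 * _u(-0.3, 0.9, 0.3)
    ser = [
        ("CB", "C", tuple(cb_s), 0.25),
        ("OG", "O", tuple(og), -0.65),
        ("HG", "H", tuple(hg), 0.40),
    ]

    # --- ligand: gamma-Glu (GGL) / Cys-NO (SNC) / Gly (GLZ) -----------------
    # the nitroso group sits on the S...S transfer axis, bonded to the ligand S
    sgl = sg + spec.ligand_s_distance * _u(0, 0, 1)
    nd = sgl + 1.80 * _u(0, 0, -1)
    od = nd + 1.16 * _u(0.9, 0.44, 0)
    cb_l = sgl + 1.82 * _u(-0.7, 0, 0.71)
    ca_l = cb_l + 1.53 * _u(-0.6, 0.55, 0.58)
    n_l = ca_l + 1.46 * _u(0.6, 0.7, 0.4)
    c_l = ca_l + 1.52 * _u(-0.85, -0.25, 0.45)
    o_l = c_l + 1.23 * _u(-0.5, 0.85, -0.1)
    snc = [
        ("N", "N", tuple(n_l), -0.45),
        ("CA", "C", tuple(ca_l), 0.25),
        ("CB", "C", tuple(cb_l), 0.20),
        ("SG", "S", tuple(sgl), 0.00),
        ("ND", "N", tuple(nd), 0.20),
        ("OD", "O", tuple(od), -0.20),
        ("C", "C", tuple(c_l), 0.45),
        ("O", "O", tuple(o_l), -0.45),
    ]

    # gamma-glutamyl carboxylate anchored to the His ND1
    o1 = nd1 + spec.carboxylate_his_distance * _u(0.2, 0.45, 0.87)
    c_cb = o1 + 1.25 * _u(0.3, 0.55, 0.78)
    o2 = c_cb + 1.25 * _u(0.85, 0.45, -0.28)
    ca_g = c_cb + 1.52 * _u(-0.75, 0.6, 0.3)
    n_g = ca_g + 1.48 * _u(0.0, 0.75, 0.66)
    ub = _u(*(n_l - ca_g))
    cb_g = ca_g + 1.53 * ub + np.array([0, 0.25, 0.2])
    cg_g = cb_g + 1.52 * ub + np.array([0, -0.2, 0.15])
    cd_g = cg_g + 1.52 * ub + np.array([0, 0.2, -0.1])
    oe_g = cd_g + 1.23 * _u(0.1, 0.9, 0.42)
    ggl = [
        ("N", "N", tuple(n_g), 0.90),
        ("CA", "C", tuple(ca_g), 0.10),
        ("C", "C", tuple(c_cb), 0.45),
        ("O1", "O", tuple(o1), -0.725),
        ("O2", "O", tuple(o2), -0.725),
        ("CB", "C", tuple(cb_g), 0.0),
        ("CG", "C", tuple(cg_g), 0.0),
        ("CD", "C", tuple(cd_g), 0.45),
        ("OE", "O", tuple(oe_g), -0.45),
    ]

    n_y = c_l + 1.33 * _u(-0.3, -0.9, 0.3)
    ca_y = n_y + 1.46 * _u(-0.9, -0.2, 0.4)
    c_y = ca_y + 1.52 * _u(-0.4, -0.85, -0.3)
    glz = [
        ("N", "N", tuple(n_y), -0.30),
        ("CA", "C", tuple(ca_y), 0.25),
        ("C", "C", tuple(c_y), 0.45),
        ("O", "O", tuple(c_y + 1.25 * _u(-0.9, 0.3, -0.3)), -0.70),
        ("OXT", "O", tuple(c_y + 1.25 * _u(0.2, -0.85, -0.5)), -0.70),
    ]

    # --- bifurcated arginine facing the carboxylate (Arg231 analog) ---------
    m = 0.5 * (o1 + o2)
    e2 = _u(*(o2 - o1))
    n_dir = np.cross(o2 - o1, (0.0, 0.0, 1.0))
    e1 = -_u(*n_dir)                      # side away from the ligand body
    cz = m + 3.6 * -e1
    e_in = _u(*(m - cz))
    nh1 = cz + 1.33 * (0.5 * e_in - 0.866 * e2)
    nh2 = cz + 1.33 * (0.5 * e_in + 0.866 * e2)
    ne_r = cz - 1.33 * e_in
    arg_b = [
        ("NE", "N", tuple(ne_r), 0.15),
        ("CZ", "C", tuple(cz), 0.40),
        ("NH1", "N", tuple(nh1), 0.225),
        ("NH2", "N", tuple(nh2), 0.225),
    ]

    # --- arginine near the NO-transfer axis, closer to the ligand S ---------
    nh1_m = np.array([-1.5, -3.2, 3.3])
    cz_m = nh1_m + 1.33 * _u(-0.5, -0.85, 0.2)
    arg_m = [
        ("NE", "N", tuple(cz_m + 1.33 * _u(-0.9, -0.2, -0.35)), 0.15),
        ("CZ", "C", tuple(cz_m), 0.40),
        ("NH1", "N", tuple(nh1_m), 0.225),
        ("NH2", "N", tuple(cz_m + 1.33 * _u(0.3, -0.75, 0.6)), 0.225),
    ]

    # --- di-anionic cofactor mimic (phosphate-like) -------------------------
    p = np.array([2.6, -3.8, -2.2])
    nap = [
        ("P", "P", tuple(p), 1.00),
        ("O1P", "O", (1.35, -3.2, -1.7), -0.75),
        ("O2P", "O", (3.6, -2.9, -1.6), -0.75),
        ("O3P", "O", (2.9, -5.0, -1.3), -0.75),
        ("O4P", "O", (2.4, -4.2, -3.65), -0.75),
    ]

    protein_parts = [(148, "SER", ser), (149, "CYS", cys), (150, "THR", thr),
                     (176, "HIS", his), (195, "ARG", arg_m), (231, "ARG", arg_b)]
    ligand_parts = [(1, "GGL", ggl), (2, "SNC", snc), (3, "GLZ", glz)]

    chain_a = Chain("A")
    chain_l = Chain("L")
    chain_x = Chain("X")
    rows: list[dict] = []
    serial = 1
    for seqid, name, atoms in protein_parts:
        res, rws, serial = _residue("A", seqid, name, atoms, False, serial)
        chain_a.residues.append(res)
        for r in rws:
            r["entity"] = "protein"
        rows.extend(rws)
    for seqid, name, atoms in ligand_parts:
        res, rws, serial = _residue("L", seqid, name, atoms, True, serial)
        chain_l.residues.append(res)
        for r in rws:
            r["entity"] = "ligand"
        rows.extend(rws)
    chains = [chain_a, chain_l]
    if spec.include_cofactor:
        res, rws, serial = _residue("X", 401, "NAP", nap, True, serial)
        chain_x.residues.append(res)
        for r in rws:
            r["entity"] = "cofactor"
        rows.extend(rws)
        chains.append(chain_x)

    for key, q in spec.charge_overrides.items():
        reskey, aname = key
        hit = [r for r in rows
               if f"{r['chain']}{r['resnum']}" == str(reskey) and r["atomname"] == aname]
        if not hit:
            raise KeyError(f"charge override targets unknown atom {key}")
        hit[0]["charge_e"] = q

    model = StructureModel(chains, {}, 1, "toy-site")
    topo = ChargeTopology(pd.DataFrame(rows))

    # clash check: no inter-residue atom pair closer than MIN_NONBONDED,
    # except the tripeptide's covalent links between its residues
    bonded = {frozenset([("L", 1, "CD"), ("L", 2, "N")]),
              frozenset([("L", 2, "C"), ("L", 3, "N")])}
    views = list(model.atoms())
    for i, vi in enumerate(views):
        for vj in views[i + 1:]:
            if vi.residue.id == vj.residue.id:
                continue
            key = frozenset([(vi.chain_id, vi.residue.seqid, vi.atom.name),
                             (vj.chain_id, vj.residue.seqid, vj.atom.name)])
            if key in bonded:
                continue
            d = float(np.linalg.norm(vi.atom.coords - vj.atom.coords))
            if d < MIN_NONBONDED:
                raise AssertionError(
                    f"generator produced a clash: {vi.residue.label}/{vi.atom.name}"
                    f" -- {vj.residue.label}/{vj.atom.name} at {d:.2f} Å")

    def _dist(a, b):
        return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))

    designed = [
        ("A/CYS149/SG", "A/HIS176/NE2", spec.dyad_distance),
        ("A/CYS149/SG", "A/THR150/N", spec.thr_n_distance),
        ("A/HIS176/ND1", "L/GGL1/O1", spec.carboxylate_his_distance),
        ("A/ARG231/NH1", "L/GGL1/O1", _dist(nh1, o1)),
        ("A/ARG231/NH2", "L/GGL1/O2", _dist(nh2, o2)),
    ]
    truth = {
        "seed": spec.seed,
        "dyad_distance_A": spec.dyad_distance,
        "thr_n_distance_A": spec.thr_n_distance,
        "ligand_s_distance_A": spec.ligand_s_distance,
        "designed_contacts": [list(c) for c in designed],
        "net_charges": {"protein": round(sum(r["charge_e"] for r in rows
                                             if r["entity"] == "protein"), 6),
                        "ligand": round(sum(r["charge_e"] for r in rows
                                            if r["entity"] == "ligand"), 6)},
        "moieties": {"glu": "chain L and resi 1", "cys": "chain L and resi 2",
                     "gly": "chain L and resi 3"},
    }
    return ToySite(model, topo, designed, truth, spec)


# ---------------------------------------------------------------------------
# reaction states
# ---------------------------------------------------------------------------

def make_reaction_states(site: ToySite, ts_fraction: float = 0.5,
                         geometry: str = "interpolated"
                         ) -> tuple[ReactionState, ReactionState, ReactionState]:
    """Reactant / TS / product charge states of the NO-transfer subsystem.

    QM region: the protein thiolate sulfur, the ligand sulfur, and the NO
    group. In the reactant the full -1 charge sits on the protein sulfur and
    the NO is bonded to the ligand sulfur; in the product the situation is
    mirrored; the transition state interpolates the charges linearly at
    ``ts_fraction`` (total charge conserved) and, for ``geometry =
    "interpolated"``, moves the NO toward the midpoint of the two sulfurs.
    ``geometry="fixed"`` keeps the reactant geometry in all three states
    (charge-perturbation-only mode).
    """
    if not 0.0 <= ts_fraction <= 1.0:
        raise ValueError("ts_fraction must lie in [0, 1]")
    if geometry not in ("interpolated", "fixed"):
        raise ValueError("geometry must be 'interpolated' or 'fixed'")
    model = site.model
    sg_p = model.residue("A", 149).atom("SG").coords
    snc = model.residue("L", 2)
    sg_l = snc.atom("SG").coords
    nd_r = snc.atom("ND").coords
    od_r = snc.atom("OD").coords
    names = ["SG_prot", "SG_lig", "ND", "OD"]
    q_reactant = np.array([-1.0, 0.0, 0.2, -0.2])
    q_product = np.array([0.0, -1.0, 0.2, -0.2])

    # product geometry: NO bonded to the protein sulfur, pointing at the ligand
    axis = _u(*(sg_l - sg_p))
    nd_p = sg_p + 1.80 * axis
    od_p = nd_p + (od_r - nd_r)

    def geom(lam: float) -> np.ndarray:
        if geometry == "fixed":
            lam = 0.0
        nd = (1 - lam) * nd_r + lam * nd_p
        od = (1 - lam) * od_r + lam * od_p
        return np.vstack([sg_p, sg_l, nd, od])

    reactant = ReactionState("reactant", names, geom(0.0), q_reactant)
    ts = ReactionState("ts", names, geom(ts_fraction),
                       (1 - ts_fraction) * q_reactant + ts_fraction * q_product)
    product = ReactionState("product", names, geom(1.0), q_product)
    return reactant, ts, product


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, sigma_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def make_ensemble(site: ToySite, spec: EnsembleSpec
                  ) -> tuple[Ensemble, dict[str, np.ndarray]]:
    """Gaussian-fluctuation ensemble with known per-moiety amplitudes.

    Each moiety (a selection expression) receives iid isotropic N(0, sigma^2)
    displacements per coordinate per frame; atoms not covered by any moiety
    stay fixed. An optional global rigid-body jitter (to be removed by
    ensemble fitting) is applied last. Returns the ensemble and the per-moiety
    atom-index map (indices into topology row order).
    """
    from .structure_io import select

    model, topo = site.model, site.topology
    order = {(v.chain_id, v.residue.seqid, v.atom.name): i
             for i, v in enumerate(model.atoms())}
    topo_idx = topo.match_model(model)        # topo row -> model atom position
    inv = {int(mi): ti for ti, mi in enumerate(topo_idx)}
    base = model.coords()[topo_idx]

    moiety_indices: dict[str, np.ndarray] = {}
    for expr, sigma in spec.moiety_sigmas.items():
        views = select(model, expr)
        if not views:
            raise ValueError(f"moiety selection {expr!r} matches no atoms")
        idx = np.array(sorted(inv[order[(v.chain_id, v.residue.seqid, v.atom.name)]]
                              for v in views), dtype=int)
        moiety_indices[expr] = idx

    rng = np.random.default_rng(spec.seed)
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for expr, sigma in spec.moiety_sigmas.items():
        idx = moiety_indices[expr]
        if sigma > 0:
            frames[:, idx, :] += rng.normal(0.0, sigma,
                                            size=(spec.n_frames, idx.size, 3))
    if spec.rigid_jitter is not None:
        rot_deg, trans_a = spec.rigid_jitter
        center = base.mean(axis=0)
        for f in range(spec.n_frames):
            R = _random_rotation(rng, rot_deg)
            t = rng.normal(0.0, trans_a, size=3)
            frames[f] = (frames[f] - center) @ R.T + center + t
    return Ensemble(frames, topo), moiety_indices


# ---------------------------------------------------------------------------
# sphere fixtures for the surface-area oracles
# ---------------------------------------------------------------------------

def make_sphere_fixture(centers, radii, elements=None) -> StructureModel:
    """Free-standing spheres as single-atom hetero residues.

    The element list controls which vdW radius the surface-area code assigns;
    to get arbitrary radii, pass a custom radii table in SasaParameters.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if len(radii) != len(centers):
        raise ValueError("need one radius per center")
    elements = elements or ["S"] * len(centers)
    chain = Chain("Z")
    for i, (c, elem) in enumerate(zip(centers, elements), start=1):
        res = Residue("Z", i, "SPH",
                      [Atom(i, elem, elem, c, 1.0, "", True, 0.0)], "")
        chain.residues.append(res)
    return StructureModel([chain], {}, 1, "spheres")


def two_sphere_reference_areas(r1: float, r2: float, d: float,
                               probe: float = 1.4) -> tuple[float, float]:
    """Closed-form accessible areas of two spheres (spherical-cap geometry)."""
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d >= R1 + R2:
        return full1, full2
    if d <= abs(R1 - R2):
        if R1 > R2:
            return full1, 0.0
        return 0.0, full2
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    return full1 - 2 * math.pi * R1 * h1, full2 - 2 * math.pi * R2 * h2


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_bundle(outdir: str | Path, site_spec: ToySiteSpec | None = None,
                 ensemble_spec: EnsembleSpec | None = None) -> dict[str, Path]:
    """Write the full fixture bundle: site PDB, topology TSV, reaction-state
    TSVs, multi-model ensemble PDB and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site = make_toy_site(site_spec)
    seed = site.spec.seed
    ens_spec = ensemble_spec or EnsembleSpec(
        moiety_sigmas={"chain L and resi 1": 0.3, "chain L and resi 2": 0.5,
                       "chain L and resi 3": 0.8},
        n_frames=200, rigid_jitter=(3.0, 0.5), seed=seed)
    ensemble, moieties = make_ensemble(site, ens_spec)
    reactant, ts, product = make_reaction_states(site)

    paths = {}
    remarks = [f"synthetic S-nitrosylation toy site, seed {seed}"]
    paths["site"] = outdir / "site.pdb"
    write_pdb(site.model, paths["site"], remarks=remarks)
    paths["topology"] = outdir / "topology.tsv"
    site.topology.to_tsv(paths["topology"])
    for st in (reactant, ts, product):
        p = outdir / f"state_{st.label}.tsv"
        st.to_tsv(p)
        paths[f"state_{st.label}"] = p
    # ensemble as multi-model PDB in topology atom order
    frame_models = []
    base = site.model
    order = site.topology.match_model(base)
    for f in range(len(ensemble)):
        m = base.copy()
        flat = list(m.atoms())
        for ti, mi in enumerate(order):
            flat[mi].atom.coords = ensemble.frames[f, ti]
        m.model_index = f + 1
        frame_models.append(m)
    paths["ensemble"] = outdir / "ensemble.pdb"
    write_pdb(frame_models, paths["ensemble"], remarks=remarks)
    truth = dict(site.ground_truth)
    truth["ensemble"] = {"n_frames": ens_spec.n_frames,
                         "seed": ens_spec.seed,
                         "rigid_jitter": list(ens_spec.rigid_jitter)
                         if ens_spec.rigid_jitter else None,
                         "moiety_sigmas": ens_spec.moiety_sigmas}
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2))
    return paths
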