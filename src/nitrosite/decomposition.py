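"""Per-residue ligand-binding energy decomposition over an ensemble.

End-point MM/GBSA-style analysis: for each frame of a conformational ensemble
of a receptor-ligand complex, the interaction energy change

    dE = E(complex) - E(receptor) - E(ligand)

is computed term by term (Coulomb, Lennard-Jones 12-6, generalized-Born
polarization, optional gamma*SASA nonpolar) in the single-trajectory scheme
(separated species keep the complex geometry) and attributed to individual
receptor residues and hetero entities. Averages over frames with standard
errors give the per-residue binding contributions that identify a ligand's
binding motif.

The GB model is an OBC-style rescaled Hawkins-Cramer-Truhlar pairwise
descreening: effective Born radii come from the analytic descreening integral
with the OBC tanh rescaling (alpha=1.0, beta=0.8, gamma=4.85, offset 0.09 Å),
and the polarization energy uses the canonical smooth interpolation

    f_GB = sqrt(r^2 + Ri Rj exp(-r^2 / (4 Ri Rj))).

Attribution scheme (exactly conservative per frame):
* Coulomb/LJ cross pairs are assigned to the receptor residue involved.
* GB energies are split per atom (half of every pair term to each partner,
  self terms to their own atom); each atom's contribution to dE is the
  difference of its per-atom energy between the complex and its separated
  state, summed per residue.  Ligand atoms accumulate into the ligand's own
  row, so the table sums to the exact total each frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import StructureModel

__all__ = [
    "ChargeTopology",
    "Ensemble",
    "EnergeticsParameters",
    "DecompositionTable",
    "coulomb_energy",
    "coulomb_matrix",
    "lj_energy",
    "born_radii",
    "gb_energy",
    "gb_atom_energies",
    "binding_decomposition",
]

COULOMB_KCAL = 332.0636   # kcal Å mol^-1 e^-2

# HCT descreening scale factors by element
HCT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85,
              "F": 0.88, "P": 0.86, "S": 0.96}
DEFAULT_SCREEN = 0.80

TOPOLOGY_COLUMNS = ["entity", "chain", "resnum", "resname", "atomname",
                    "charge_e", "lj_epsilon_kcal", "lj_sigma_A", "gb_radius_A"]


@dataclass
class EnergeticsParameters:
    coulomb_constant: float = COULOMB_KCAL
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    gb_variant: str = "OBC2"
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    gb_offset: float = 0.09          # Å, intrinsic-radius offset
    surface_tension: float = 0.0072  # kcal/mol/Å^2
    nonpolar: bool = False
    screen: dict[str, float] = field(default_factory=lambda: dict(HCT_SCREEN))

    def __post_init__(self):
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.solvent_dielectric <= self.interior_dielectric:
            raise ValueError("solvent dielectric must exceed interior dielectric")

    @property
    def tau(self) -> float:
        return 1.0 / self.interior_dielectric - 1.0 / self.solvent_dielectric


class ChargeTopology:
    """Per-atom charge / LJ / GB-radius table with residue assignment.

    Row order is the canonical atom order that every ensemble frame must
    follow. The ``entity`` column groups atoms into protein / ligand /
    cofactor / solvent roles used by the decomposition.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"topology missing columns: {missing}")
        self.table = table.reset_index(drop=True).copy()
        if "element" not in self.table.columns:
            self.table["element"] = [
                next((c for c in str(nm) if c.isalpha()), "X").upper()
                for nm in self.table.atomname]
        num = self.table[["charge_e", "lj_epsilon_kcal", "lj_sigma_A", "gb_radius_A"]]
        if not np.all(np.isfinite(num.to_numpy(dtype=float))):
            raise ValueError("non-finite parameter in topology")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def charges(self) -> np.ndarray:
        return self.table.charge_e.to_numpy(dtype=float)

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self.table.lj_epsilon_kcal.to_numpy(dtype=float)

    @property
    def lj_sigma(self) -> np.ndarray:
        return self.table.lj_sigma_A.to_numpy(dtype=float)

    @property
    def gb_radii(self) -> np.ndarray:
        return self.table.gb_radius_A.to_numpy(dtype=float)

    def screen_factors(self, params: EnergeticsParameters) -> np.ndarray:
        return np.array([params.screen.get(e, DEFAULT_SCREEN)
                         for e in self.table.element])

    def entity_indices(self, entity: str) -> np.ndarray:
        return np.flatnonzero((self.table.entity == entity).to_numpy())

    def residue_keys(self) -> list[str]:
        """Per-atom row label: protein atoms by residue, others by entity."""
        keys = []
        for row in self.table.itertuples():
            if row.entity == "protein":
                keys.append(f"{row.chain}/{row.resname}{row.resnum}")
            else:
                keys.append(str(row.entity))
        return keys

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChargeTopology":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.table[TOPOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)

    def match_model(self, model: StructureModel) -> np.ndarray:
        """Indices mapping topology rows onto a model's atoms.

        Raises if any topology row has no matching atom (chain, resnum,
        atomname) or a frame atom has no topology row.
        """
        pos: dict[tuple, int] = {}
        for i, v in enumerate(model.atoms()):
            pos[(v.chain_id, v.residue.seqid, v.atom.name)] = i
        idx = []
        missing = []
        for row in self.table.itertuples():
            key = (str(row.chain), int(row.resnum), str(row.atomname))
            if key in pos:
                idx.append(pos[key])
            else:
                missing.append(key)
        if missing:
            raise ValueError(f"topology rows without frame atoms: {missing[:5]}"
                             f"{'...' if len(missing) > 5 else ''}")
        if len(pos) != len(self.table):
            raise ValueError(f"frame has {len(pos)} atoms but topology has "
                             f"{len(self.table)} rows")
        return np.array(idx, dtype=int)


@dataclass
class Ensemble:
    """Ordered coordinate frames sharing one topology."""

    frames: np.ndarray                 # (n_frames, n_atoms, 3), Å
    topology: ChargeTopology
    stride_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(f"frames carry {self.frames.shape[1]} atoms but "
                             f"topology has {len(self.topology)} rows")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_models(cls, models: Sequence[StructureModel], topology: ChargeTopology,
                    stride_ps: float | None = None) -> "Ensemble":
        """Build from multi-model structures, reordering atoms to topology order."""
        idx = topology.match_model(models[0])
        frames = np.stack([m.coords()[idx] for m in models])
        return cls(frames, topology, stride_ps)


# ---------------------------------------------------------------------------
# pairwise energy terms
# ---------------------------------------------------------------------------

def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    return coords


def coulomb_matrix(coords: np.ndarray, charges: np.ndarray,
                   idx_a: np.ndarray, idx_b: np.ndarray,
                   params: EnergeticsParameters | None = None) -> np.ndarray:
    """Pairwise Coulomb energies (kcal/mol) between two disjoint atom sets."""
    params = params or EnergeticsParameters()
    coords = _check_coords(coords)
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("atom sets must be disjoint")
    if idx_a.size == 0 or idx_b.size == 0:
        return np.zeros((idx_a.size, idx_b.size))
    r = cdist(coords[idx_a], coords[idx_b])
    if (r < 1e-3).any():
        raise ValueError("overlapping atoms (r < 1e-3 Å) in Coulomb sum")
    q = np.asarray(charges, dtype=float)
    return (params.coulomb_constant / params.interior_dielectric) \
        * np.outer(q[idx_a], q[idx_b]) / r


def coulomb_energy(coords, charges, idx_a, idx_b,
                   params: EnergeticsParameters | None = None) -> float:
    """Total Coulomb cross energy between two disjoint sets, kcal/mol."""
    return float(coulomb_matrix(coords, charges, idx_a, idx_b, params).sum())


def lj_matrix(coords: np.ndarray, epsilon: np.ndarray, sigma: np.ndarray,
              idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pairwise 12-6 Lennard-Jones energies with Lorentz-Berthelot combination."""
    coords = _check_coords(coords)
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("atom sets must be disjoint")
    if idx_a.size == 0 or idx_b.size == 0:
        return np.zeros((idx_a.size, idx_b.size))
    r = cdist(coords[idx_a], coords[idx_b])
    if (r < 1e-3).any():
        raise ValueError("overlapping atoms (r < 1e-3 Å) in LJ sum")
    eps = np.sqrt(np.outer(epsilon[idx_a], epsilon[idx_b]))
    sig = 0.5 * (sigma[idx_a][:, None] + sigma[idx_b][None, :])
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 ** 2 - sr6)


def lj_energy(coords, epsilon, sigma, idx_a, idx_b) -> float:
    return float(lj_matrix(coords, epsilon, sigma, idx_a, idx_b).sum())


def born_radii(coords: np.ndarray, intrinsic: np.ndarray, screen: np.ndarray,
               params: EnergeticsParameters | None = None) -> np.ndarray:
    """Effective Born radii via HCT pairwise descreening with OBC rescaling.

    ``intrinsic`` are the per-atom GB radii (Å); ``screen`` the HCT scale
    factors. For an isolated atom the result is the offset-corrected intrinsic
    radius; descreening by neighbours only ever increases it.
    """
    params = params or EnergeticsParameters()
    coords = _check_coords(coords)
    rho = np.asarray(intrinsic, dtype=float)
    if (rho <= params.gb_offset).any():
        raise ValueError("intrinsic GB radius must exceed the offset")
    rho_t = rho - params.gb_offset          # offset-corrected radii
    s = np.asarray(screen, dtype=float) * rho_t
    n = len(rho)
    r = cdist(coords, coords)
    integral = np.zeros(n)
    for i in range(n):
        rij = r[i]
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= rij + s < 1e9            # all finite
        mask &= rho_t[i] < rij + s       # fully engulfing-j case contributes
        rij_m = rij[mask]
        s_m = s[mask]
        L = np.maximum(np.abs(rij_m - s_m), rho_t[i])
        U = rij_m + s_m
        term = 0.5 * ((1.0 / L - 1.0 / U)
                      + 0.25 * (rij_m - s_m ** 2 / rij_m) * (1.0 / U ** 2 - 1.0 / L ** 2)
                      + 0.5 * np.log(L / U) / rij_m)
        # correction when atom i sits inside neighbour j's descreening sphere
        inside = rho_t[i] < s_m - rij_m
        if inside.any():
            term[inside] += 2.0 * (1.0 / rho_t[i] - 1.0 / L[inside])
        integral[i] = term.sum()
    psi = rho_t * integral
    arg = params.obc_alpha * psi - params.obc_beta * psi ** 2 + params.obc_gamma * psi ** 3
    inv = 1.0 / rho_t - np.tanh(arg) / rho
    return 1.0 / inv


def _f_gb(r: np.ndarray, radii: np.ndarray) -> np.ndarray:
    prod = np.outer(radii, radii)
    return np.sqrt(r ** 2 + prod * np.exp(-(r ** 2) / (4.0 * prod)))


def gb_atom_energies(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
                     params: EnergeticsParameters | None = None) -> np.ndarray:
    """Per-atom split of the GB polarization energy (sums to the total).

    e_i = -1/2 k tau sum_j q_i q_j / f_GB(r_ij, R_i, R_j), self term included.
    """
    params = params or EnergeticsParameters()
    coords = _check_coords(coords)
    q = np.asarray(charges, dtype=float)
    R = np.asarray(radii, dtype=float)
    r = cdist(coords, coords)
    f = _f_gb(r, R)
    qq = np.outer(q, q)
    return -0.5 * params.coulomb_constant * params.tau * (qq / f).sum(axis=1)


def gb_energy(coords, charges, radii,
              params: EnergeticsParameters | None = None) -> float:
    """GB polarization energy of an atom set (self terms included), kcal/mol."""
    return float(gb_atom_energies(coords, charges, radii, params).sum())


# ---------------------------------------------------------------------------
# nonpolar term (gamma * SASA on raw coordinates)
# ---------------------------------------------------------------------------

def _numeric_sasa(coords: np.ndarray, radii: np.ndarray,
                  probe: float = 1.4, n_points: int = 240) -> np.ndarray:
    from .sasa import sphere_lattice
    lattice = sphere_lattice(n_points)
    expanded = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * lattice
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        d2[:, i] = np.inf
        buried = (d2 < (expanded ** 2)[None, :]).any(axis=1)
        out[i] = 4.0 * math.pi * expanded[i] ** 2 * (1.0 - buried.mean())
    return out


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecompositionTable:
    """Per-residue/entity mean binding contributions over an ensemble."""

    table: pd.DataFrame            # rows: residue/entity; cols: term means + sem
    per_frame_total: np.ndarray    # (n_frames,) total dE per frame, kcal/mol
    params: EnergeticsParameters

    @property
    def total(self) -> float:
        return float(self.per_frame_total.mean())

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["# per-residue binding contributions, kcal/mol (mean over frames)"]
        lines.append("residue\t" + "\t".join(self.table.columns))
        for key, row in self.table.iterrows():
            lines.append(key + "\t" + "\t".join(f"{v:.4f}" for v in row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "units": "kcal/mol",
            "n_frames": int(len(self.per_frame_total)),
            "total_mean": self.total,
            "rows": {k: {c: float(v) for c, v in row.items()}
                     for k, row in self.table.iterrows()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def binding_decomposition(ensemble: Ensemble, ligand_entity: str = "ligand",
                          params: EnergeticsParameters | None = None,
                          exclude_entities: tuple[str, ...] = ("water",)
                          ) -> DecompositionTable:
    """Single-trajectory per-residue decomposition of dE(binding).

    Receptor = all atoms whose entity is neither the ligand nor excluded;
    rows are protein residues plus named hetero entities plus the ligand
    itself (which collects the ligand-side GB reorganization). The sum of the
    rows equals the exact frame total to numerical precision.
    """
    params = params or EnergeticsParameters()
    topo = ensemble.topology
    entities = topo.table.entity.to_numpy()
    idx_lig = topo.entity_indices(ligand_entity)
    if idx_lig.size == 0:
        raise ValueError(f"no atoms with entity {ligand_entity!r}")
    keep = ~np.isin(entities, list(exclude_entities))
    unassigned = keep & (entities == "")
    if unassigned.any():
        raise ValueError("atoms with empty entity assignment")
    idx_rec = np.flatnonzero(keep & (entities != ligand_entity))
    if idx_rec.size == 0:
        raise ValueError("receptor set is empty")
    idx_all = np.concatenate([idx_rec, idx_lig])

    keys = np.array(topo.residue_keys())
    lig_key = str(ligand_entity)
    rec_keys = keys[idx_rec]
    row_order = list(dict.fromkeys(rec_keys)) + [lig_key]
    key_pos = {k: i for i, k in enumerate(row_order)}
    rec_rows = np.array([key_pos[k] for k in rec_keys])
    n_rows = len(row_order)

    q = topo.charges
    eps = topo.lj_epsilon
    sig = topo.lj_sigma
    rho = topo.gb_radii
    scr = topo.screen_factors(params)

    n_frames = len(ensemble)
    acc = {t: np.zeros((n_frames, n_rows)) for t in ("coulomb", "lj", "gb", "nonpolar")}

    for fi, frame in enumerate(ensemble.frames):
        cm = coulomb_matrix(frame, q, idx_lig, idx_rec, params)
        lm = lj_matrix(frame, eps, sig, idx_lig, idx_rec)
        np.add.at(acc["coulomb"][fi], rec_rows, cm.sum(axis=0))
        np.add.at(acc["lj"][fi], rec_rows, lm.sum(axis=0))

        # GB: per-atom energies in complex vs separated states
        r_complex = born_radii(frame[idx_all], rho[idx_all], scr[idx_all], params)
        e_complex = gb_atom_energies(frame[idx_all], q[idx_all], r_complex, params)
        r_rec = born_radii(frame[idx_rec], rho[idx_rec], scr[idx_rec], params)
        e_rec = gb_atom_energies(frame[idx_rec], q[idx_rec], r_rec, params)
        r_lig = born_radii(frame[idx_lig], rho[idx_lig], scr[idx_lig], params)
        e_lig = gb_atom_energies(frame[idx_lig], q[idx_lig], r_lig, params)
        n_rec = idx_rec.size
        d_rec = e_complex[:n_rec] - e_rec
        d_lig = e_complex[n_rec:] - e_lig
        np.add.at(acc["gb"][fi], rec_rows, d_rec)
        acc["gb"][fi, key_pos[lig_key]] += d_lig.sum()

        if params.nonpolar:
            from .sasa import CHOTHIA_RADII
            elem = topo.table.element.to_numpy()
            vdw = np.array([CHOTHIA_RADII.get(e, 1.8) for e in elem])
            sas_complex = _numeric_sasa(frame[idx_all], vdw[idx_all])
            sas_rec = _numeric_sasa(frame[idx_rec], vdw[idx_rec])
            sas_lig = _numeric_sasa(frame[idx_lig], vdw[idx_lig])
            dn_rec = params.surface_tension * (sas_complex[:n_rec] - sas_rec)
            dn_lig = params.surface_tension * (sas_complex[n_rec:] - sas_lig)
            np.add.at(acc["nonpolar"][fi], rec_rows, dn_rec)
            acc["nonpolar"][fi, key_pos[lig_key]] += dn_lig.sum()

    per_frame_rows = sum(acc.values())
    per_frame_total = per_frame_rows.sum(axis=1)
    sem = (per_frame_rows.std(axis=0, ddof=1) / math.sqrt(n_frames)
           if n_frames > 1 else np.zeros(n_rows))
    table = pd.DataFrame({
        "coulomb": acc["coulomb"].mean(axis=0),
        "lj": acc["lj"].mean(axis=0),
        "gb": acc["gb"].mean(axis=0),
        "nonpolar": acc["nonpolar"].mean(axis=0),
    }, index=row_order)
    table["total"] = table.sum(axis=1)
    table["sem"] = sem
    table = table.sort_values("total")
    return DecompositionTable(table, per_frame_total, params)
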