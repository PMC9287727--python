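"""Shrake-Rupley solvent-accessible surface area.

A probe sphere (default 1.4 Å) is rolled over the van der Waals spheres of the
heavy atoms; each atom's accessible area is the unoccluded fraction of a
deterministic golden-spiral point lattice on its expanded sphere, times
4*pi*(r_vdw + r_probe)^2. The lattice is fixed (no random points) so results
are exactly reproducible for a given point count.

Radii default to a Chothia-style protein set (aliphatic C 1.87, carbonyl /
aromatic C 1.76, N 1.65, O 1.40, S 1.85, P 1.90 Å); the table is an explicit
parameter because published ASA values from different tools differ by a few
Å^2 purely through the radii convention.

The cysteine report aggregates residue-level and thiol (SG) ASA per chain and
chain-averaged, and classifies each cysteine's accessibility — the quantity
that rationalizes which protein thiols a nitrosylating agent can reach.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AtomView, StructureModel, select

__all__ = [
    "SasaParameters",
    "CHOTHIA_RADII",
    "sphere_lattice",
    "atom_sasa",
    "residue_sasa",
    "cysteine_report",
    "CysteineSiteReport",
]

CHOTHIA_RADII = {
    "C": 1.87,   # aliphatic carbon (carbonyl/aromatic refined below)
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "SE": 1.90,
}

# carbons treated as trigonal (1.76 Å): backbone carbonyl plus aromatic and
# carboxylate/guanidinium side-chain carbons of the standard residues
_TRIGONAL_C = {
    ("*", "C"),
    ("ARG", "CZ"), ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"),
    ("HIS", "CG"), ("HIS", "CD2"), ("HIS", "CE1"),
    ("PHE", "CG"), ("PHE", "CD1"), ("PHE", "CD2"), ("PHE", "CE1"), ("PHE", "CE2"), ("PHE", "CZ"),
    ("TYR", "CG"), ("TYR", "CD1"), ("TYR", "CD2"), ("TYR", "CE1"), ("TYR", "CE2"), ("TYR", "CZ"),
    ("TRP", "CG"), ("TRP", "CD1"), ("TRP", "CD2"), ("TRP", "CE2"), ("TRP", "CE3"),
    ("TRP", "CZ2"), ("TRP", "CZ3"), ("TRP", "CH2"),
}
TRIGONAL_C_RADIUS = 1.76


@dataclass
class SasaParameters:
    probe_radius: float = 1.4          # Å
    n_points: int = 960                # lattice points per atom
    radii: dict[str, float] = field(default_factory=lambda: dict(CHOTHIA_RADII))
    include_hetero: bool = True        # cofactors, ions
    include_water: bool = False
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 60:
            raise ValueError("need at least 60 lattice points")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def radius_for(self, view: AtomView) -> float:
        a = view.atom
        if a.element == "C":
            key = (view.residue.name, a.name)
            if key in _TRIGONAL_C or ("*", a.name) in _TRIGONAL_C:
                return TRIGONAL_C_RADIUS
        try:
            return self.radii[a.element]
        except KeyError:
            raise KeyError(f"no vdW radius for element {a.element!r} "
                           f"(atom {a.name} in {view.residue.label})") from None


def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n near-uniform unit vectors."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _included_views(model: StructureModel, params: SasaParameters) -> list[AtomView]:
    out = []
    for v in model.atoms():
        if v.residue.is_water and not params.include_water:
            continue
        if v.atom.is_hetero and not v.residue.is_water and not params.include_hetero:
            continue
        if v.atom.is_hydrogen and not params.include_hydrogens:
            continue
        out.append(v)
    return out


def atom_sasa(model: StructureModel, params: SasaParameters | None = None) -> pd.DataFrame:
    """Per-atom accessible surface area (Å^2).

    Returns a DataFrame with one row per included atom: chain, seqid, icode,
    resname, atom, element, radius, asa.
    """
    params = params or SasaParameters()
    views = _included_views(model, params)
    if not views:
        raise ValueError("no atoms left after filtering; nothing to compute")
    coords = np.array([v.atom.coords for v in views])
    radii = np.array([params.radius_for(v) for v in views])
    expanded = radii + params.probe_radius
    lattice = sphere_lattice(params.n_points)

    tree = cKDTree(coords)
    asa = np.empty(len(views))
    for i in range(len(views)):
        ri = expanded[i]
        pts = coords[i] + ri * lattice
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        if neighbors:
            nb_c = coords[neighbors]
            nb_r = expanded[neighbors]
            d2 = ((pts[:, None, :] - nb_c[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        asa[i] = 4.0 * math.pi * ri * ri * frac

    return pd.DataFrame({
        "chain": [v.chain_id for v in views],
        "seqid": [v.residue.seqid for v in views],
        "icode": [v.residue.icode for v in views],
        "resname": [v.residue.name for v in views],
        "atom": [v.atom.name for v in views],
        "element": [v.atom.element for v in views],
        "radius": radii,
        "asa": asa,
    })


def residue_sasa(model: StructureModel, params: SasaParameters | None = None) -> pd.DataFrame:
    """Per-residue ASA: the sum of member-atom ASA values."""
    table = atom_sasa(model, params)
    grouped = (table.groupby(["chain", "seqid", "icode", "resname"], sort=False)["asa"]
               .sum().reset_index())
    return grouped


_CLASS_THRESHOLDS = (1.0, 10.0)   # SG ASA: <1 buried, <10 low, else exposed


def _classify(sg_asa: float) -> str:
    if sg_asa < _CLASS_THRESHOLDS[0]:
        return "buried"
    if sg_asa < _CLASS_THRESHOLDS[1]:
        return "low"
    return "exposed"


@dataclass
class CysteineSiteReport:
    """Residue and thiol-group ASA of every cysteine, per chain and averaged."""

    per_chain: pd.DataFrame    # chain, seqid, resname, residue_asa, sg_asa
    averaged: pd.DataFrame     # seqid, residue_asa, sg_asa, n_chains, class
    params: SasaParameters

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["# residue and thiol (SG) accessible surface areas, A^2",
                 "chain\tseqid\tresname\tresidue_asa\tsg_asa\tclass"]
        for _, row in self.per_chain.iterrows():
            lines.append(f"{row.chain}\t{row.seqid}\t{row.resname}\t"
                         f"{row.residue_asa:.2f}\t{row.sg_asa:.2f}\t{_classify(row.sg_asa)}")
        lines.append("# chain-averaged")
        for _, row in self.averaged.iterrows():
            lines.append(f"avg\t{row.seqid}\tCYS\t{row.residue_asa:.2f}\t"
                         f"{row.sg_asa:.2f}\t{row['class']}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_chain": self.per_chain.to_dict(orient="records"),
            "chain_averaged": self.averaged.to_dict(orient="records"),
            "probe_radius_A": self.params.probe_radius,
            "n_points": self.params.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def cysteine_report(model: StructureModel, params: SasaParameters | None = None,
                    strip: str | None = None) -> CysteineSiteReport:
    """ASA report for every cysteine, optionally after stripping entities.

    ``strip`` is a selection expression removed before the computation (e.g.
    ``"resn NAP+NAD"`` to measure how cofactor removal exposes the catalytic
    thiol).
    """
    params = params or SasaParameters()
    work = model
    if strip:
        doomed = select(model, strip)
        work = model.remove_atoms(doomed)
    table = atom_sasa(work, params)
    cys = table[table.resname == "CYS"]
    if cys.empty:
        raise ValueError("model contains no cysteine")
    rows = []
    for (chain, seqid, icode), sub in cys.groupby(["chain", "seqid", "icode"], sort=False):
        res_asa = float(sub.asa.sum())
        sg = sub[sub.atom == "SG"]
        sg_asa = float(sg.asa.sum()) if not sg.empty else 0.0
        rows.append({"chain": chain, "seqid": seqid, "icode": icode,
                     "resname": "CYS", "residue_asa": res_asa, "sg_asa": sg_asa})
    per_chain = pd.DataFrame(rows)
    averaged = (per_chain.groupby("seqid", sort=True)
                .agg(residue_asa=("residue_asa", "mean"), sg_asa=("sg_asa", "mean"),
                     n_chains=("chain", "nunique"))
                .reset_index())
    averaged["class"] = averaged.sg_asa.map(_classify)
    return CysteineSiteReport(per_chain, averaged, params)
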