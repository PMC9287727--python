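"""Distance-based interaction analysis.

Polar contacts between atom sets, catalytic Cys/His dyad detection, the
thiolate-stabilizing microenvironment of a cysteine SG, and contact mapping of
bound anions (e.g. the sulfate ions occupying the phosphate subsites of GAPDH
crystals).

Because crystal structures carry no hydrogens, no donor/acceptor chemistry is
attempted: a "polar contact" is any N/O/S atom pair within the distance cutoff
(3.5 Å by default, the usual convention for hydrogen bonds plus electrostatic
interactions read off a crystal structure).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomView, StructureModel, select

__all__ = [
    "Contact",
    "DyadRecord",
    "polar_contacts",
    "find_dyads",
    "thiol_microenvironment",
    "anion_site_contacts",
    "contacts_to_tsv",
]

POLAR_ELEMENTS = {"N", "O", "S"}

# side-chain atoms carrying formal charge at physiological pH
_BASIC_ATOMS = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_ANION_RES = {"SO4", "PO4", "SUL"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _atom_id(v: AtomView) -> str:
    r = v.residue
    return f"{v.chain_id}/{r.name}{r.seqid}{r.icode}/{v.atom.name}"


@dataclass(frozen=True)
class Contact:
    atom_a: AtomView
    atom_b: AtomView
    distance: float
    category: str = "polar"

    @property
    def id_a(self) -> str:
        return _atom_id(self.atom_a)

    @property
    def id_b(self) -> str:
        return _atom_id(self.atom_b)

    def __repr__(self) -> str:
        return f"Contact({self.id_a} -- {self.id_b}, {self.distance:.2f} Å, {self.category})"


@dataclass(frozen=True)
class DyadRecord:
    """A Cys SG / His imidazole pair within the dyad cutoff."""

    cys: tuple[str, int, str]      # (chain, seqid, icode)
    his: tuple[str, int, str]
    sg_ne2: float                  # Å
    sg_nd1: float                  # Å
    chain: str

    @property
    def min_distance(self) -> float:
        return min(self.sg_ne2, self.sg_nd1)


def _resolve(model: StructureModel, sel) -> list[AtomView]:
    if isinstance(sel, str):
        return select(model, sel)
    return list(sel)


def _charged_kind(v: AtomView) -> str:
    key = (v.residue.name, v.atom.name)
    if key in _BASIC_ATOMS:
        return "basic"
    if key in _ACIDIC_ATOMS or (v.residue.name in _ANION_RES and v.atom.element == "O"):
        return "acidic"
    return ""


def _categorize(a: AtomView, b: AtomView) -> str:
    kinds = {_charged_kind(a), _charged_kind(b)}
    if kinds == {"basic", "acidic"}:
        return "salt-bridge-candidate"
    if a.atom.element in POLAR_ELEMENTS and b.atom.element in POLAR_ELEMENTS:
        return "polar"
    return "generic"


def polar_contacts(model: StructureModel, set_a, set_b,
                   cutoff: float = 3.5, include_water: bool = True) -> list[Contact]:
    """All N/O/S atom pairs across two disjoint sets within ``cutoff`` Å.

    Sets may be selection expressions or AtomView sequences. The result is
    symmetric in A/B (pairs are oriented A->B) and sorted by distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    va = [v for v in _resolve(model, set_a) if v.atom.element in POLAR_ELEMENTS]
    vb = [v for v in _resolve(model, set_b) if v.atom.element in POLAR_ELEMENTS]
    if not include_water:
        va = [v for v in va if not v.residue.is_water]
        vb = [v for v in vb if not v.residue.is_water]
    ids_a = {id(v.atom) for v in va}
    if any(id(v.atom) in ids_a for v in vb):
        raise ValueError("atom sets must be disjoint")
    if not va or not vb:
        return []
    ca = np.array([v.atom.coords for v in va])
    cb = np.array([v.atom.coords for v in vb])
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    out: list[Contact] = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if 0.0 < d <= cutoff:
                out.append(Contact(va[i], vb[j], d, _categorize(va[i], vb[j])))
    out.sort(key=lambda c: (c.distance, c.id_a, c.id_b))
    return out


def find_dyads(model: StructureModel, cutoff: float = 4.0) -> list[DyadRecord]:
    """Every (Cys SG, His imidazole N) pair within ``cutoff`` Å, once per pair.

    The default cutoff of 4.0 Å brackets the canonical catalytic-dyad range
    observed crystallographically (S-N around 3.3-3.4 Å) with margin.
    """
    cys_sg = [v for v in model.atoms()
              if v.residue.name == "CYS" and v.atom.name == "SG"]
    his = {}
    for v in model.atoms():
        if v.residue.name == "HIS" and v.atom.name in ("NE2", "ND1"):
            his.setdefault(v.residue.id, {})[v.atom.name] = v
    out: list[DyadRecord] = []
    for sg in cys_sg:
        for his_id, atoms in his.items():
            d = {name: float(np.linalg.norm(sg.atom.coords - v.atom.coords))
                 for name, v in atoms.items()}
            ne2 = d.get("NE2", np.inf)
            nd1 = d.get("ND1", np.inf)
            if min(ne2, nd1) <= cutoff:
                out.append(DyadRecord(sg.residue.id, his_id, ne2, nd1, sg.chain_id))
    out.sort(key=lambda r: (r.chain, r.cys[1], r.min_distance))
    return out


def thiol_microenvironment(model: StructureModel, cys_id: tuple[str, int] | tuple[str, int, str],
                           cutoff: float = 4.5) -> list[Contact]:
    """N/O atoms within ``cutoff`` of a cysteine's SG, tagged backbone/side-chain.

    These are the interactions that stabilize the thiolate form of a reactive
    cysteine (e.g. the His imidazole and the following residue's backbone N).
    """
    chain, seqid, *rest = cys_id
    icode = rest[0] if rest else ""
    res = model.residue(chain, seqid, icode)
    if res.name != "CYS":
        raise ValueError(f"{res.label} is not a cysteine")
    sg = res.atom("SG")
    if sg is None:
        raise ValueError(f"{res.label} has no SG atom")
    sg_view = AtomView(chain, res, sg)
    out: list[Contact] = []
    for v in model.atoms():
        if v.residue.id == res.id:
            continue
        if v.atom.element not in ("N", "O"):
            continue
        d = float(np.linalg.norm(v.atom.coords - sg.coords))
        if d <= cutoff:
            where = "backbone" if (v.residue.is_protein and v.atom.name in BACKBONE_NAMES) \
                else "side-chain"
            out.append(Contact(sg_view, v, d, where))
    out.sort(key=lambda c: c.distance)
    return out


def anion_site_contacts(model: StructureModel, anion_id: tuple[str, int] | tuple[str, int, str],
                        cutoff: float = 3.5) -> list[Contact]:
    """Protein/water/cofactor atoms within ``cutoff`` of any O of a bound anion."""
    chain, seqid, *rest = anion_id
    icode = rest[0] if rest else ""
    res = model.residue(chain, seqid, icode)
    if not any(a.is_hetero for a in res.atoms):
        raise ValueError(f"{res.label} is not a hetero entity")
    anion_o = [AtomView(chain, res, a) for a in res.atoms if a.element == "O"]
    if not anion_o:
        raise ValueError(f"{res.label} has no oxygen atoms")
    out: list[Contact] = []
    for v in model.atoms():
        if v.residue.id == res.id or v.atom.element not in POLAR_ELEMENTS:
            continue
        for o in anion_o:
            d = float(np.linalg.norm(v.atom.coords - o.atom.coords))
            if d <= cutoff:
                out.append(Contact(o, v, d, _categorize(o, v)))
    out.sort(key=lambda c: (c.distance, c.id_a, c.id_b))
    return out


def contacts_to_tsv(contacts: Iterable[Contact], path: str | Path | None = None) -> str:
    """TSV report: chainA resA atomA chainB resB atomB distance category."""
    lines = ["chain_a\tres_a\tatom_a\tchain_b\tres_b\tatom_b\tdistance_A\tcategory"]
    for c in contacts:
        ra, rb = c.atom_a.residue, c.atom_b.residue
        lines.append("\t".join([
            c.atom_a.chain_id, f"{ra.name}{ra.seqid}{ra.icode}", c.atom_a.atom.name,
            c.atom_b.chain_id, f"{rb.name}{rb.seqid}{rb.icode}", c.atom_b.atom.name,
            f"{c.distance:.3f}", c.category]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
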