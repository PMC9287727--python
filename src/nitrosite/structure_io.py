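"""Structure and sequence I/O.

Hierarchical coordinate containers (Atom/Residue/Chain/StructureModel), PDB and
mmCIF reading (backed by gemmi), a plain PDB/FASTA writer, rigid-body
transforms for assembly generation, a small PyMOL-flavoured atom-selection
language, and sequence-derived physical properties (average mass, molar
extinction coefficient at 280 nm).

Conventions
-----------
* Residue numbering is taken verbatim from the file (author numbering) and
  never renumbered, so literature residue labels (e.g. the catalytic Cys149 of
  photosynthetic GAPDH) match directly.
* Alternate locations: only the highest-occupancy conformer of each atom is
  kept (ties resolved toward altloc 'A').
* Elements come from PDB columns 77-78 when present, otherwise they are
  inferred from the atom name.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "AtomView",
    "SequenceProperties",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_model",
    "write_pdb",
    "write_fasta",
    "apply_transform",
    "combine",
    "select",
    "sequence_properties",
]

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Average residue masses (Da) of amino acids in a peptide chain (monomer minus
# water) and the mass of one water, standard atomic weights.
WATER_MASS = 18.01528
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Molar extinction coefficients at 280 nm, M^-1 cm^-1 (Pace/Gill-von-Hippel
# convention: Trp 5500, Tyr 1490, cystine 125 per disulfide pair).
EPS280_TRP = 5500.0
EPS280_TYR = 1490.0
EPS280_CYSTINE = 125.0


class ParseError(ValueError):
    """A structure file could not be parsed."""


class SelectionError(ValueError):
    """A selection expression is malformed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    bfactor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        a = _copy.copy(self)
        a.coords = self.coords.copy()
        return a


@dataclass
class Residue:
    chain_id: str
    seqid: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seqid}{self.icode}"

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_protein(self) -> bool:
        return self.name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seqid, self.name,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class Chain:
    cid: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.cid, [r.copy() for r in self.residues])


class AtomView(NamedTuple):
    """An atom together with its residue context; the selection currency."""

    chain_id: str
    residue: Residue
    atom: Atom

    @property
    def coords(self) -> np.ndarray:
        return self.atom.coords


@dataclass
class StructureModel:
    """One coordinate model: ordered chains plus optional per-chain sequence."""

    chains: list[Chain] = field(default_factory=list)
    seqres: dict[str, str] = field(default_factory=dict)
    model_index: int = 1
    name: str = ""

    def __post_init__(self):
        ids = [c.cid for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.cid == cid:
                return c
        raise KeyError(f"no chain {cid!r}; have {[c.cid for c in self.chains]}")

    def residue(self, chain_id: str, seqid: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}/{seqid}{icode}")

    def atoms(self) -> Iterator[AtomView]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield AtomView(c.cid, r, a)

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        return np.array([v.atom.coords for v in self.atoms()], dtype=float).reshape(-1, 3)

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains], dict(self.seqres),
                              self.model_index, self.name)

    def modeled_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the modeled (non-hetero) residues of a chain."""
        return "".join(STANDARD_AA.get(r.name, "X")
                       for r in self.chain(chain_id).residues
                       if not r.is_water and r.name in STANDARD_AA)

    def remove_atoms(self, views: Iterable[AtomView]) -> "StructureModel":
        """Copy of the model without the given atoms (empty residues dropped)."""
        doomed = {(v.chain_id, v.residue.seqid, v.residue.icode, v.atom.name, v.atom.altloc)
                  for v in views}
        out = StructureModel([], dict(self.seqres), self.model_index, self.name)
        for c in self.chains:
            nc = Chain(c.cid)
            for r in c.residues:
                kept = [a.copy() for a in r.atoms
                        if (c.cid, r.seqid, r.icode, a.name, a.altloc) not in doomed]
                if kept:
                    nc.residues.append(Residue(c.cid, r.seqid, r.name, kept, r.icode))
            if nc.residues:
                out.chains.append(nc)
        return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, resname: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    # two-character elements in common hetero groups (e.g. FE, ZN, MG, CL)
    head = re.sub(r"[0-9']", "", name)
    if resname not in STANDARD_AA and len(head) >= 2 and head[:2].capitalize() in (
            "Fe", "Zn", "Mg", "Mn", "Cl", "Br", "Na", "Ca", "Cu", "Ni", "Se"):
        return head[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> altloc 'A'."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        prev = best.get(a.name)
        if prev is None:
            best[a.name] = a
            order.append(a.name)
        elif (a.occupancy, -ord(a.altloc or "~")) > (prev.occupancy, -ord(prev.altloc or "~")):
            best[a.name] = a
    return [best[n] for n in order]


def _from_gemmi_model(gmodel: gemmi.Model, seqres: dict[str, str],
                      model_index: int, name: str) -> StructureModel:
    chains: list[Chain] = []
    for gchain in gmodel:
        chain = Chain(gchain.name)
        for gres in gchain:
            het = gres.het_flag == "H" or gres.name in WATER_NAMES
            atoms = []
            for ga in gres:
                elem = ga.element.name if ga.element and ga.element.name != "X" else ""
                if not elem:
                    elem = _infer_element(ga.name, gres.name)
                    warnings.warn(f"element missing for atom {ga.name} in "
                                  f"{gres.name}{gres.seqid.num}; inferred {elem}")
                atoms.append(Atom(
                    serial=ga.serial, name=ga.name, element=elem.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                    is_hetero=het, bfactor=ga.b_iso))
            atoms = _dedupe_altlocs(atoms)
            if atoms:
                chain.residues.append(Residue(gchain.name, gres.seqid.num, gres.name,
                                              atoms, gres.seqid.icode.strip()))
        if chain.residues:
            chains.append(chain)
    return StructureModel(chains, seqres, model_index, name)


def read_structure(path: str | Path, format: str = "auto") -> list[StructureModel]:
    """Read a PDB or mmCIF file; one StructureModel per coordinate model."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    st.setup_entities()
    seqres: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            seq = gemmi.one_letter_code(ent.full_sequence).upper()
            for sub in ent.subchains:
                cname = sub[0] if sub else ""
                for gchain in st[0]:
                    if any(r.subchain == sub for r in gchain):
                        seqres[gchain.name] = seq
    models = [_from_gemmi_model(gm, seqres, i + 1, path.stem)
              for i, gm in enumerate(st)]
    if not models or all(m.n_atoms == 0 for m in models):
        raise ParseError(f"{path.name}: no atoms found")
    return [m for m in models if m.n_atoms > 0]


def read_model(path: str | Path, format: str = "auto") -> StructureModel:
    """First model of a structure file."""
    return read_structure(path, format)[0]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _pdb_atom_record(view: AtomView, serial: int) -> str:
    a, r = view.atom, view.residue
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name
    # atom-name column convention: 1-char elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    x, y, z = a.coords
    return (f"{record}{serial:>5d} {name:<4s}{a.altloc or ' '}{r.name:>3s} "
            f"{view.chain_id:>1s}{r.seqid:>4d}{r.icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
            f"          {a.element:>2s}")


def write_pdb(models: StructureModel | Sequence[StructureModel],
              path: str | Path, remarks: Sequence[str] = ()) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = [f"REMARK   6 {r}" for r in remarks]
    multi = len(models) > 1
    for k, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4d}")
        serial = 0
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(_pdb_atom_record(AtomView(chain.cid, res, atom), serial))
            serial += 1
            last = chain.residues[-1]
            lines.append(f"TER   {serial:>5d}      {last.name:>3s} "
                         f"{chain.cid:>1s}{last.seqid:>4d}{last.icode or ' '}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write named sequences as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

def apply_transform(model: StructureModel, rot: np.ndarray, trans: np.ndarray,
                    relabel: Mapping[str, str] | None = None) -> StructureModel:
    """Rigidly transform a copy of the model: x -> rot @ x + trans.

    ``relabel`` renames chains in the transformed copy (needed before combining
    with the original, since chain ids must stay unique).
    """
    rot = np.asarray(rot, dtype=float)
    trans = np.asarray(trans, dtype=float).reshape(3)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation must be a 3x3 orthonormal matrix (tol 1e-6)")
    out = model.copy()
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + trans
    if relabel:
        for chain in out.chains:
            new = relabel.get(chain.cid)
            if new:
                chain.cid = new
                for res in chain.residues:
                    res.chain_id = new
        out.seqres = {relabel.get(k, k): v for k, v in out.seqres.items()}
    return out


def combine(*models: StructureModel, name: str = "") -> StructureModel:
    """Concatenate models into one assembly; chain ids must be disjoint."""
    chains: list[Chain] = []
    seqres: dict[str, str] = {}
    for m in models:
        chains.extend(c.copy() for c in m.chains)
        seqres.update(m.seqres)
    return StructureModel(chains, seqres, 1, name or (models[0].name if models else ""))


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------
#
# Grammar (PyMOL-flavoured):
#   expr     := or_expr
#   or_expr  := and_expr ("or" and_expr)*
#   and_expr := not_expr ("and" not_expr)*
#   not_expr := "not" not_expr | primary
#   primary  := "(" expr ")" | keyword clause
# Clauses: chain A+B | resn CYS+HIS | resi 149+150-160 | name SG+CA |
#          elem S | hetero | water | protein | hydrogen | all | none |
#          within 3.5 of (expr)

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    def __init__(self, expr: str, views: list[AtomView]):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0
        self.views = views
        self.coords = (np.array([v.atom.coords for v in views]).reshape(-1, 3)
                       if views else np.zeros((0, 3)))

    def _peek(self):
        return self.tokens[self.i][0].lower() if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise SelectionError("unexpected end of expression", len(self.expr))
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(f"unexpected token {tok!r}", pos)
        return mask

    def _or(self) -> np.ndarray:
        mask = self._and()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and()
        return mask

    def _and(self) -> np.ndarray:
        mask = self._not()
        while self._peek() == "and":
            self._next()
            mask = mask & self._not()
        return mask

    def _not(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._not()
        return self._primary()

    def _values(self) -> tuple[list[str], int]:
        tok, pos = self._next()
        return tok.split("+"), pos

    def _primary(self) -> np.ndarray:
        tok, pos = self._next()
        kw = tok.lower()
        n = len(self.views)
        if tok == "(":
            mask = self._or()
            close, cpos = self._next()
            if close != ")":
                raise SelectionError("expected ')'", cpos)
            return mask
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw == "none":
            return np.zeros(n, dtype=bool)
        if kw == "hetero":
            return np.array([v.atom.is_hetero for v in self.views], dtype=bool)
        if kw == "water":
            return np.array([v.residue.is_water for v in self.views], dtype=bool)
        if kw == "protein":
            return np.array([v.residue.is_protein for v in self.views], dtype=bool)
        if kw == "hydrogen":
            return np.array([v.atom.is_hydrogen for v in self.views], dtype=bool)
        if kw == "chain":
            vals, _ = self._values()
            wanted = set(vals)
            return np.array([v.chain_id in wanted for v in self.views], dtype=bool)
        if kw == "resn":
            vals, _ = self._values()
            wanted = {s.upper() for s in vals}
            return np.array([v.residue.name in wanted for v in self.views], dtype=bool)
        if kw == "name":
            vals, _ = self._values()
            wanted = {s.upper() for s in vals}
            return np.array([v.atom.name.upper() in wanted for v in self.views], dtype=bool)
        if kw in ("elem", "element"):
            vals, _ = self._values()
            wanted = {s.upper() for s in vals}
            return np.array([v.atom.element in wanted for v in self.views], dtype=bool)
        if kw == "resi":
            vals, vpos = self._values()
            wanted: set[int] = set()
            for v in vals:
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise SelectionError(f"bad residue number {v!r}", vpos)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                wanted.update(range(lo, hi + 1))
            return np.array([v.residue.seqid in wanted for v in self.views], dtype=bool)
        if kw == "within":
            dtok, dpos = self._next()
            try:
                cutoff = float(dtok)
            except ValueError:
                raise SelectionError(f"expected distance, got {dtok!r}", dpos) from None
            of, opos = self._next()
            if of.lower() != "of":
                raise SelectionError(f"expected 'of', got {of!r}", opos)
            ref = self._not()
            if not ref.any():
                return np.zeros(n, dtype=bool)
            from scipy.spatial import cKDTree
            tree = cKDTree(self.coords[ref])
            d, _ = tree.query(self.coords, k=1)
            return d <= cutoff
        raise SelectionError(f"unknown keyword {tok!r}", pos)


def select(model: StructureModel, expr: str) -> list[AtomView]:
    """Evaluate a selection expression; returns matching atoms in model order."""
    views = list(model.atoms())
    mask = _SelParser(expr, views).parse()
    return [v for v, m in zip(views, mask) if m]


# ---------------------------------------------------------------------------
# sequence properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceProperties:
    n_residues: int
    average_mass: float            # Da
    epsilon280: float              # M^-1 cm^-1, per cystine_convention
    epsilon280_reduced: float      # all Cys as free thiols
    epsilon280_cystine: float      # all Cys paired as cystines
    n_trp: int
    n_tyr: int
    n_cys: int
    cystine_convention: str
    coefficient_set: str = "Trp 5500 / Tyr 1490 / cystine 125 M^-1 cm^-1"


def sequence_properties(seq: str, cystine_convention: str = "reduced") -> SequenceProperties:
    """Average molecular mass and 280 nm extinction coefficient of a protein.

    Mass is the sum of average residue masses plus one water; the extinction
    coefficient uses the standard 280 nm chromophore coefficients. Both the
    free-thiol and the all-cystine value are reported; ``cystine_convention``
    ("reduced" or "cystine") picks which one goes into ``epsilon280``.
    """
    seq = seq.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in RESIDUE_MASS:
            raise ValueError(f"unknown amino-acid letter {ch!r} at position {i + 1}")
    if cystine_convention not in ("reduced", "cystine"):
        raise ValueError(f"cystine_convention must be 'reduced' or 'cystine', "
                         f"got {cystine_convention!r}")
    mass = sum(RESIDUE_MASS[ch] for ch in seq) + (WATER_MASS if seq else 0.0)
    n_trp, n_tyr, n_cys = seq.count("W"), seq.count("Y"), seq.count("C")
    eps_red = EPS280_TRP * n_trp + EPS280_TYR * n_tyr
    eps_cys = eps_red + EPS280_CYSTINE * (n_cys // 2)
    return SequenceProperties(
        n_residues=len(seq), average_mass=mass,
        epsilon280=(eps_red if cystine_convention == "reduced" else eps_cys),
        epsilon280_reduced=eps_red, epsilon280_cystine=eps_cys,
        n_trp=n_trp, n_tyr=n_tyr, n_cys=n_cys,
        cystine_convention=cystine_convention)
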