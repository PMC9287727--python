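"""Electrostatic fingerprint of a trans-nitrosylation activation barrier.

A reacting subsystem (the QM region: the protein thiolate sulfur, the ligand's
S-NO group and their immediate covalent context) is described in two states —
reactant and transition state — each with its own geometry and point charges.
Every surrounding residue's Coulomb interaction with the QM region is
evaluated in both states; the difference

    ddE_i = E_i(TS) - E_i(reactant)        [kcal/mol]

is the residue's electrostatic effect on the activation barrier: negative
values lower the barrier (stabilizing), positive values raise it
(destabilizing). Non-protein entities (e.g. the nicotinamide cofactor) appear
as rows of their own.

Charges and geometries of the states are inputs; no quantum chemistry is
performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .decomposition import ChargeTopology, EnergeticsParameters

__all__ = [
    "ReactionState",
    "FingerprintTable",
    "state_interaction",
    "barrier_fingerprint",
]


@dataclass
class ReactionState:
    """Geometry + point charges of the reacting subsystem in one state."""

    label: str                     # reactant | ts | product
    atom_names: list[str]
    coords: np.ndarray             # (n, 3), Å
    charges: np.ndarray            # (n,), e

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.atom_names) != len(self.coords) or len(self.charges) != len(self.coords):
            raise ValueError("atom names, coords and charges must have equal length")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "ReactionState":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(label or Path(path).stem, list(df.atomname),
                   df[["x", "y", "z"]].to_numpy(dtype=float),
                   df.charge_e.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"atomname": self.atom_names,
                           "x": self.coords[:, 0], "y": self.coords[:, 1],
                           "z": self.coords[:, 2], "charge_e": self.charges})
        df.to_csv(path, sep="\t", index=False)


def _check_states(*states: ReactionState) -> None:
    names = states[0].atom_names
    for st in states[1:]:
        if st.atom_names != names:
            raise ValueError(f"states {states[0].label!r} and {st.label!r} "
                             "differ in atom identities")
    qs = [round(st.net_charge, 6) for st in states]
    if max(qs) - min(qs) > 1e-6:
        raise ValueError(f"net charge differs across states: {qs}")


def _residue_indices(topo: ChargeTopology, residue_id) -> np.ndarray:
    t = topo.table
    if isinstance(residue_id, str):
        mask = (t.entity == residue_id).to_numpy()
        if not mask.any():
            keys = np.array(topo.residue_keys())
            mask = keys == residue_id
    else:
        chain, resnum = residue_id[0], int(residue_id[1])
        mask = ((t.chain == chain) & (t.resnum == resnum)).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(f"no topology atoms for residue {residue_id!r}")
    return idx


def state_interaction(state: ReactionState, env_frame: np.ndarray,
                      topo: ChargeTopology, residue_id,
                      params: EnergeticsParameters | None = None) -> float:
    """Coulomb energy between one state's QM region and one residue, kcal/mol."""
    params = params or EnergeticsParameters()
    env_frame = np.asarray(env_frame, dtype=float).reshape(-1, 3)
    idx = _residue_indices(topo, residue_id)
    r = cdist(state.coords, env_frame[idx])
    shared = np.argwhere(r < 1e-3)
    if shared.size:
        names = [(state.atom_names[i], topo.table.atomname.iloc[idx[j]])
                 for i, j in shared[:5]]
        raise ValueError(f"residue {residue_id!r} overlaps the QM region: {names}")
    qq = np.outer(state.charges, topo.charges[idx])
    return float((params.coulomb_constant / params.interior_dielectric) * (qq / r).sum())


@dataclass
class FingerprintTable:
    """Per-residue reactant/TS interaction energies and their difference."""

    table: pd.DataFrame    # index: residue key; E_reactant, E_ts, ddE, class
    cutoff: float
    neutral_threshold: float

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["# electrostatic barrier fingerprint, kcal/mol "
                 "(ddE < 0 stabilizes the transition state)",
                 "residue\tE_reactant\tE_ts\tddE\tclass"]
        for key, row in self.table.iterrows():
            lines.append(f"{key}\t{row.E_reactant:.4f}\t{row.E_ts:.4f}\t"
                         f"{row.ddE:.4f}\t{row['class']}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"units": "kcal/mol", "cutoff_A": self.cutoff,
                   "neutral_threshold": self.neutral_threshold,
                   "rows": {k: {"E_reactant": float(r.E_reactant),
                                "E_ts": float(r.E_ts), "ddE": float(r.ddE),
                                "class": r["class"]}
                            for k, r in self.table.iterrows()}}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def barrier_fingerprint(reactant: ReactionState, ts: ReactionState,
                        env_frame: np.ndarray, topo: ChargeTopology,
                        cutoff: float = 5.0, neutral_threshold: float = 0.1,
                        params: EnergeticsParameters | None = None,
                        exclude_entities: tuple[str, ...] = ()) -> FingerprintTable:
    """Per-residue electrostatic effect on the activation barrier.

    Environment membership: whole residues/entities with any atom within
    ``cutoff`` Å of any QM atom in either state's geometry. Each state is
    evaluated with its own QM geometry against the fixed environment frame.
    """
    params = params or EnergeticsParameters()
    _check_states(reactant, ts)
    env_frame = np.asarray(env_frame, dtype=float).reshape(-1, 3)
    if len(env_frame) != len(topo):
        raise ValueError("environment frame does not match topology length")

    qm_coords = np.vstack([reactant.coords, ts.coords])
    dmin = cdist(env_frame, qm_coords).min(axis=1)
    keys = np.array(topo.residue_keys())
    entities = topo.table.entity.to_numpy()
    excluded = np.isin(entities, list(exclude_entities))
    # drop environment atoms that are QM-region duplicates (distance ~ 0)
    duplicate = dmin < 1e-3
    qualifying = (dmin <= cutoff) & ~excluded & ~duplicate
    member_keys = list(dict.fromkeys(keys[qualifying]))

    rows = []
    for key in member_keys:
        idx = np.flatnonzero((keys == key) & ~duplicate)
        sub_coords = env_frame[idx]
        sub_q = topo.charges[idx]
        def inter(state: ReactionState) -> float:
            r = cdist(state.coords, sub_coords)
            return float((params.coulomb_constant / params.interior_dielectric)
                         * (np.outer(state.charges, sub_q) / r).sum())
        e_r = inter(reactant)
        e_t = inter(ts)
        dd = e_t - e_r
        cls = ("neutral" if abs(dd) < neutral_threshold
               else "stabilizing" if dd < 0 else "destabilizing")
        rows.append({"residue": key, "E_reactant": e_r, "E_ts": e_t,
                     "ddE": dd, "class": cls})
    table = pd.DataFrame(rows).set_index("residue") if rows else pd.DataFrame(
        columns=["E_reactant", "E_ts", "ddE", "class"])
    if len(table):
        table = table.reindex(table.ddE.abs().sort_values(ascending=False).index)
    return FingerprintTable(table, cutoff, neutral_threshold)
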