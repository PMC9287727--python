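"""Rigid-body least-squares superposition (Kabsch).

Closed-form SVD solution for the proper rotation (det = +1, reflections
excluded) minimizing weighted RMSD between paired point sets, plus residue
correspondence by global sequence alignment, chain-level and assembly-level
superposition with automatic chain mapping.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align

from .structure_io import Chain, StructureModel

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "pair_residues",
    "superpose_chains",
    "superpose_assemblies",
]

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, proper (det +1)
    translation: np.ndarray       # 3-vector, Å
    rmsd: float                   # Å
    n_aligned: int
    correspondence: list[tuple[tuple, tuple]] | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted motion: x -> R x + t (maps the mobile set onto the reference)."""
        return coords @ self.rotation.T + self.translation

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd_A": self.rmsd,
            "n_aligned": self.n_aligned,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def kabsch(P: np.ndarray, Q: np.ndarray,
           weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal rigid motion mapping mobile points P onto reference points Q.

    Returns rotation R and translation t minimizing the weighted RMSD of
    R @ P_i + t versus Q_i. Reflections are excluded. Degenerate (collinear)
    point sets produce a warning with the rank of the covariance matrix.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    rank = int((S > S[0] * 1e-9).sum()) if S[0] > 0 else 0
    if rank < 2:
        warnings.warn(f"degenerate point set: covariance rank {rank} < 2; "
                      "rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(R, t, rmsd, n)


def _modeled(chain: Chain):
    from .structure_io import STANDARD_AA
    return [r for r in chain.residues if r.name in STANDARD_AA]


def pair_residues(chain_a: Chain, chain_b: Chain,
                  mode: str = "ca") -> list[tuple[tuple, tuple, list[str]]]:
    """Residue correspondence by global alignment of the modeled sequences.

    Returns (residue_id_a, residue_id_b, atom_names) triples for aligned
    positions with identical residue types where the atoms required by
    ``mode`` ("ca", "backbone", "heavy") are present in both residues.
    """
    res_a = _modeled(chain_a)
    res_b = _modeled(chain_b)
    from .structure_io import STANDARD_AA
    seq_a = "".join(STANDARD_AA[r.name] for r in res_a)
    seq_b = "".join(STANDARD_AA[r.name] for r in res_b)
    if not seq_a or not seq_b:
        raise ValueError("both chains must contain protein residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[tuple, tuple, list[str]]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for ia, ib in zip(range(a0, a1), range(b0, b1)):
            ra, rb = res_a[ia], res_b[ib]
            if ra.name != rb.name:
                continue
            if mode == "ca":
                wanted = ["CA"]
            elif mode == "backbone":
                wanted = list(BACKBONE)
            elif mode == "heavy":
                names_a = {a.name for a in ra.atoms if not a.is_hydrogen}
                names_b = {a.name for a in rb.atoms if not a.is_hydrogen}
                wanted = sorted(names_a & names_b)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if mode != "heavy" and not all(ra.atom(nm) and rb.atom(nm) for nm in wanted):
                continue
            if not wanted:
                continue
            pairs.append((ra.id, rb.id, wanted))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} residue pairs; need at least 3")
    return pairs


def _paired_coords(model_a: StructureModel, model_b: StructureModel,
                   pairs) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = [], []
    for id_a, id_b, names in pairs:
        ra = model_a.residue(*id_a)
        rb = model_b.residue(*id_b)
        for nm in names:
            pa.append(ra.atom(nm).coords)
            pb.append(rb.atom(nm).coords)
    return np.array(pa), np.array(pb)


def superpose_chains(model_a: StructureModel, chain_a: str,
                     model_b: StructureModel, chain_b: str,
                     mode: str = "ca") -> SuperpositionResult:
    """Superpose one chain onto another; chain A is mobile, B is reference."""
    pairs = pair_residues(model_a.chain(chain_a), model_b.chain(chain_b), mode)
    pa, pb = _paired_coords(model_a, model_b, pairs)
    result = kabsch(pa, pb)
    result.correspondence = [(a, b) for a, b, _ in pairs]
    return result


def superpose_assemblies(model_a: StructureModel, model_b: StructureModel,
                         mapping: dict[str, str] | str = "auto",
                         mode: str = "ca") -> SuperpositionResult:
    """Superpose whole assemblies with one rigid transform.

    ``mapping`` maps chains of A onto chains of B; "auto" tries every
    bijection consistent with sequence identity and keeps the minimal rmsd.
    """
    ids_a = [c.cid for c in model_a.chains]
    ids_b = [c.cid for c in model_b.chains]
    if len(ids_a) != len(ids_b):
        raise ValueError(f"chain counts differ: {len(ids_a)} vs {len(ids_b)}")

    def fit(cmap: dict[str, str]) -> SuperpositionResult | None:
        all_pairs = []
        try:
            for ca, cb in cmap.items():
                pairs = pair_residues(model_a.chain(ca), model_b.chain(cb), mode)
                all_pairs.extend(pairs)
        except ValueError:
            return None
        pa, pb = _paired_coords(model_a, model_b, all_pairs)
        res = kabsch(pa, pb)
        res.correspondence = [(a, b) for a, b, _ in all_pairs]
        return res

    if isinstance(mapping, dict):
        result = fit(mapping)
        if result is None:
            raise ValueError("supplied chain mapping yields no residue pairs")
        return result

    best: SuperpositionResult | None = None
    seqs_a = {c: model_a.modeled_sequence(c) for c in ids_a}
    seqs_b = {c: model_b.modeled_sequence(c) for c in ids_b}
    for perm in itertools.permutations(ids_b):
        cmap = dict(zip(ids_a, perm))
        # prune: require similar sequence lengths for every matched pair
        if any(abs(len(seqs_a[a]) - len(seqs_b[b])) > 0.2 * max(len(seqs_a[a]), 1)
               for a, b in cmap.items()):
            continue
        res = fit(cmap)
        if res is not None and (best is None or res.rmsd < best.rmsd):
            best = res
    if best is None:
        raise ValueError("no chain mapping produced a valid superposition")
    return best
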