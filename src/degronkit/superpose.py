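"""Optimal rigid-body superposition (Kabsch) and Cα RMSD over residue ranges.

The Kabsch algorithm gives the closed-form rotation/translation minimizing
the RMSD between two paired point sets, with the reflection branch of the
SVD corrected so the result is a proper rotation (det = +1).

``pocket_rmsd`` applies it to the Cα atoms of a residue range — e.g. a
degron-binding pocket — pairing residues either by author number or through
an explicit correspondence (such as one derived from a sequence alignment
when comparing orthologs).  Two modes are exposed:

* ``all_pairs`` — one fit over every paired Cα;
* ``reject`` — iterative outlier rejection emulating the default behaviour
  of molecular-viewer "align" commands: up to 5 refinement cycles, each
  discarding pairs whose residual exceeds 2.0 × the current cycle's RMSD
  and re-fitting on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import SuperpositionError
from .structure import ResidueID, Structure

__all__ = ["SuperpositionResult", "PocketSpec", "kabsch", "pocket_rmsd", "apply_transform"]

_REJECT_CYCLES = 5
_REJECT_FACTOR = 2.0
_REJECT_FLOOR = 1e-8  # Å; keeps an exact fit (rmsd ≈ 0) from rejecting everything


@dataclass(frozen=True)
class PocketSpec:
    """Inclusive author-number range delimiting the region to superpose."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"invalid pocket range [{self.first}, {self.last}]")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rotation/translation, the minimized RMSD and the pairs used.

    The transform maps the *mobile* coordinates onto the *reference* frame:
    ``x_fit = rotation @ x_mobile + translation``.
    """

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int
    pairs: tuple[tuple[ResidueID, ResidueID], ...] = ()

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def apply_transform(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    """Apply ``x ↦ R x + t`` to every atom of a structure."""
    coords = s.all_coords()
    return s.with_coords(coords @ np.asarray(rotation, dtype=float).T + np.asarray(translation))


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal superposition of point set ``Q`` (mobile) onto ``P`` (reference).

    Parameters are (n, 3) arrays of paired coordinates in Å, n ≥ 3 and not
    all collinear.  Returns the proper rotation and translation minimizing
    the RMSD, and the minimized RMSD itself.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise SuperpositionError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError(f"expected (n, 3) coordinate arrays, got {P.shape}")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {n}")

    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    P0 = P - Pc
    Q0 = Q - Qc
    if np.linalg.matrix_rank(np.vstack([P0, Q0]), tol=1e-10) < 2:
        raise SuperpositionError("points are collinear; rotation is not determined")

    # cross-covariance of mobile against reference
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Pc - R @ Qc
    fitted = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((P - fitted) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _ca_coord(structure: Structure, number: int, chain: str | None) -> np.ndarray | None:
    for res in structure.residues:
        if res.rid.number != number:
            continue
        if chain is not None and res.rid.chain != chain:
            continue
        for atom in res.atoms:
            if atom.name == "CA":
                return atom.xyz
    return None


def _pair_ca(
    model: Structure,
    reference: Structure,
    pocket: PocketSpec,
    mapping: Mapping[int, int] | None,
    model_chain: str | None,
    reference_chain: str | None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[ResidueID, ResidueID]]]:
    """Collect paired Cα coordinates for reference pocket residues.

    ``mapping`` takes *reference* author numbers to *model* author numbers;
    identity when omitted.
    """
    ref_res = [
        r
        for r in reference.residues
        if pocket.first <= r.rid.number <= pocket.last
        and (reference_chain is None or r.rid.chain == reference_chain)
    ]
    P, Q, pairs = [], [], []
    for res in ref_res:
        ref_ca = next((a.xyz for a in res.atoms if a.name == "CA"), None)
        if ref_ca is None:
            continue
        model_number = mapping.get(res.rid.number) if mapping is not None else res.rid.number
        if model_number is None:
            continue
        mob_ca = _ca_coord(model, model_number, model_chain)
        if mob_ca is None:
            continue
        P.append(ref_ca)
        Q.append(mob_ca)
        mob_rid = next(
            r.rid
            for r in model.residues
            if r.rid.number == model_number and (model_chain is None or r.rid.chain == model_chain)
        )
        pairs.append((mob_rid, res.rid))
    return np.array(P, dtype=float), np.array(Q, dtype=float), pairs


def pocket_rmsd(
    model: Structure,
    reference: Structure,
    pocket: PocketSpec,
    mapping: Mapping[int, int] | None = None,
    mode: str = "all_pairs",
    model_chain: str | None = None,
    reference_chain: str | None = None,
) -> SuperpositionResult:
    """Cα RMSD of a model against a reference over a pocket residue range.

    Residues are paired by author number (or via ``mapping``: reference
    number → model number, e.g. alignment-derived for cross-ortholog
    comparisons); only residues with a Cα in both structures contribute.

    ``mode="all_pairs"`` fits once on every pair; ``mode="reject"`` runs the
    iterative outlier-rejection refinement described in the module docstring
    and reports the surviving ``n_pairs``.
    """
    if mode not in ("all_pairs", "reject"):
        raise ValueError(f"unknown mode {mode!r}; expected 'all_pairs' or 'reject'")
    P, Q, pairs = _pair_ca(model, reference, pocket, mapping, model_chain, reference_chain)
    if len(P) < 3:
        raise SuperpositionError(
            f"only {len(P)} paired Cα atoms in pocket [{pocket.first}, {pocket.last}]; "
            "need at least 3"
        )

    result = kabsch(P, Q)
    if mode == "all_pairs":
        return SuperpositionResult(
            rotation=result.rotation,
            translation=result.translation,
            rmsd=result.rmsd,
            n_pairs=result.n_pairs,
            pairs=tuple(pairs),
        )

    keep = np.arange(len(P))
    for _ in range(_REJECT_CYCLES):
        fitted = Q[keep] @ result.rotation.T + result.translation
        residuals = np.linalg.norm(P[keep] - fitted, axis=1)
        surviving = residuals <= max(_REJECT_FACTOR * result.rmsd, _REJECT_FLOOR)
        if surviving.all():
            break
        if surviving.sum() < 3:
            break
        keep = keep[surviving]
        result = kabsch(P[keep], Q[keep])
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_pairs=len(keep),
        pairs=tuple(pairs[i] for i in keep),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
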