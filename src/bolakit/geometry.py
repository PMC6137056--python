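"""Rigid-body superposition and ensemble RMSD statistics.

The ensemble-spread statistics follow the CYANA/MOLMOL convention: each
conformer is least-squares superposed onto the iteratively converged mean
structure over a stated selection, and the reported ensemble RMSD is the mean
over conformers of each conformer's RMSD to that mean.  Average-pairwise RMSD
is exposed as an alternative convention.

All routines operate on author residue numbering and angstrom coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import ResidueRange, StructureEnsemble

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "mean_structure",
    "ensemble_rmsd",
    "pairwise_rmsd",
    "per_residue_rmsd",
    "element_rmsd",
    "atom_distance",
]


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body fit of a mobile onto a reference coordinate set.

    ``transform(x)`` maps mobile-frame coordinates into the reference frame:
    ``R @ (x - mobile_centroid) + ref_centroid``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray
    ref_centroid: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.ref_centroid


def _check_nondegenerate(centered: np.ndarray) -> None:
    if centered.shape[0] < 3:
        raise ValueError(f"need >= 3 atoms for superposition, got {centered.shape[0]}")
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear or coincident) coordinates")


def kabsch_superpose(
    coords_ref: np.ndarray,
    coords_mov: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares optimal proper rotation/translation (Kabsch).

    The reflection branch is excluded (det = +1 always).  ``weights`` are
    per-atom; default uniform.
    """
    a = np.asarray(coords_ref, dtype=float)
    b = np.asarray(coords_mov, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match and be (N, 3): {a.shape} vs {b.shape}")
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    ca = (w[:, None] * a).sum(axis=0) / wsum
    cb = (w[:, None] * b).sum(axis=0) / wsum
    a0, b0 = a - ca, b - cb
    _check_nondegenerate(b0)
    rot, rssd = Rotation.align_vectors(a0, b0, weights=w)
    R = rot.as_matrix()
    rmsd = float(rssd / np.sqrt(wsum))
    return Superposition(
        rotation=R,
        translation=ca - R @ cb,
        rmsd=rmsd,
        mobile_centroid=cb,
        ref_centroid=ca,
    )


def _superpose_stack(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose every model in (m, n, 3) onto ref (n, 3)."""
    out = np.empty_like(coords)
    for i, c in enumerate(coords):
        out[i] = kabsch_superpose(ref, c).transform(c)
    return out


def mean_structure_coords(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively converged mean of a coordinate stack (m, n, 3).

    Superpose all models onto the current mean, recompute the coordinate-wise
    mean, repeat until the mean shifts by < ``tol`` angstrom (max coordinate
    change).  Returns (mean, superposed stack).
    """
    coords = np.asarray(coords, dtype=float)
    mean = coords[0]
    fitted = coords
    for _ in range(max_iter):
        fitted = _superpose_stack(coords, mean)
        new_mean = fitted.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    return mean, fitted


def mean_structure(
    ensemble: StructureEnsemble,
    ranges: Sequence[ResidueRange] | None = None,
    atom_set: str = "backbone",
    tol: float = 1e-6,
) -> np.ndarray:
    """Converged mean coordinates over a selection (n_atoms, 3)."""
    keys = ensemble.selection_keys(ranges, atom_set)
    coords = ensemble.select_coords(keys)
    mean, _ = mean_structure_coords(coords, tol=tol)
    return mean


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    ranges: Sequence[ResidueRange] | None = None,
    atom_set: str = "backbone",
    combine: str = "mean",
) -> float:
    """Ensemble spread about the mean structure over a selection, in angstrom.

    ``combine='mean'``: mean over models of each model's RMSD to the mean
    structure (CYANA/MOLMOL convention).  ``combine='rms'``: root mean square
    of the same per-model RMSDs, which aggregates exactly from the
    per-residue profile.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble RMSD is undefined for a single-model ensemble")
    keys = ensemble.selection_keys(ranges, atom_set)
    coords = ensemble.select_coords(keys)
    mean, fitted = mean_structure_coords(coords)
    per_model = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=1))
    if combine == "mean":
        return float(per_model.mean())
    if combine == "rms":
        return float(np.sqrt((per_model**2).mean()))
    raise ValueError(f"unknown combine mode {combine!r}")


def pairwise_rmsd(
    ensemble: StructureEnsemble,
    ranges: Sequence[ResidueRange] | None = None,
    atom_set: str = "backbone",
) -> float:
    """Average RMSD over all model pairs (alternative ensemble convention)."""
    keys = ensemble.selection_keys(ranges, atom_set)
    coords = ensemble.select_coords(keys)
    m = len(coords)
    if m < 2:
        raise ValueError("pairwise RMSD needs >= 2 models")
    vals = [
        kabsch_superpose(coords[i], coords[j]).rmsd
        for i in range(m)
        for j in range(i + 1, m)
    ]
    return float(np.mean(vals))


def per_residue_rmsd(
    ensemble: StructureEnsemble,
    atom_set: str = "backbone",
    reference_ranges: Sequence[ResidueRange] | None = None,
) -> pd.DataFrame:
    """Per-residue RMSD profile after one global superposition.

    All models are superposed onto the converged mean over
    ``reference_ranges`` (default: all residues) using ``atom_set`` atoms;
    each residue's value is then the RMS deviation of its atoms across models
    from the mean structure.  Returns columns ``res_seq, rmsd, n_atoms``.
    """
    ref_keys = ensemble.selection_keys(reference_ranges, atom_set)
    all_keys = ensemble.selection_keys(None, atom_set)
    ref_coords = ensemble.select_coords(ref_keys)
    all_coords = ensemble.select_coords(all_keys)
    ref_mean, _ = mean_structure_coords(ref_coords)
    ref_idx = {k: i for i, k in enumerate(all_keys)}
    sel = np.array([ref_idx[k] for k in ref_keys])
    fitted = np.empty_like(all_coords)
    for i in range(len(all_coords)):
        sup = kabsch_superpose(ref_mean, all_coords[i][sel])
        fitted[i] = sup.transform(all_coords[i])
    mean_all = fitted.mean(axis=0)
    sq = ((fitted - mean_all) ** 2).sum(axis=2)  # (m, n_atoms)
    res_seqs = np.array([k[0] for k in all_keys])
    rows = []
    for res in np.unique(res_seqs):
        cols = res_seqs == res
        rows.append((int(res), float(np.sqrt(sq[:, cols].mean())), int(cols.sum())))
    return pd.DataFrame(rows, columns=["res_seq", "rmsd", "n_atoms"])


def element_rmsd(
    ensemble: StructureEnsemble,
    rng: ResidueRange,
    atom_set: str = "backbone",
    local_superposition: bool = True,
    combine: str = "mean",
) -> float:
    """Ensemble RMSD of one secondary-structure element.

    With ``local_superposition`` (default) the superposition itself is
    restricted to the element's residues; otherwise models are superposed on
    all residues and only the RMSD is restricted.
    """
    if local_superposition:
        return ensemble_rmsd(ensemble, [rng], atom_set, combine=combine)
    all_keys = ensemble.selection_keys(None, atom_set)
    coords = ensemble.select_coords(all_keys)
    mean, fitted = mean_structure_coords(coords)
    cols = np.array([k[0] in rng for k in all_keys])
    per_model = np.sqrt(((fitted[:, cols] - mean[cols]) ** 2).sum(axis=2).mean(axis=1))
    if combine == "mean":
        return float(per_model.mean())
    return float(np.sqrt((per_model**2).mean()))


def atom_distance(
    model: pd.DataFrame, res_i: int, atom_i: str, res_j: int, atom_j: str
) -> float:
    """Euclidean distance between two atoms of a single model, in angstrom."""

    def _xyz(res: int, atom: str) -> np.ndarray:
        sel = model[(model["res_seq"] == res) & (model["atom_name"] == atom)]
        if sel.empty:
            raise KeyError(f"atom {atom} of residue {res} not found in model")
        return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]

    return float(np.linalg.norm(_xyz(res_i, atom_i) - _xyz(res_j, atom_j)))
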