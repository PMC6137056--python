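"""Geometric search for Ser-His-(Glu/Asp/Thr) catalytic triads.

A serine nucleophile, a histidine base and an acid partner (Glu, Asp or the
Thr hydroxyl variant) form the classical covalent-catalysis triad.  The
search takes every Ser OG, looks for His imidazole nitrogens within a
hydrogen-bond-like cutoff, and requires the *other* imidazole nitrogen to
contact an acceptor atom of a Glu/Asp/Thr side chain — the two legs must use
distinct nitrogens, and both ND1/NE2 role assignments are tried (the
tautomer is not modelled).  Candidates can be filtered by conformer
consensus across an NMR ensemble and ranked with a side-chain
solvent-exposure tie-break, which is what separates a buried acid partner
from a solvent-protruding decoy at equal distances.

Solvent accessibility uses an in-package Shrake-Rupley surface (probe 1.4
angstrom, 92 sphere points, element van der Waals radii) so the point set
and radii are explicit and testable against the analytic sphere area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import StructureEnsemble

__all__ = [
    "TriadConfig",
    "TriadCandidate",
    "find_triads",
    "consensus_over_ensemble",
    "shrake_rupley_sasa",
    "solvent_exposure",
    "rank_candidates",
]

#: van der Waals radii (angstrom) by element for surface computation
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA"}


@dataclass(frozen=True)
class TriadConfig:
    """Cutoffs and atom sets for the triad search."""

    d_ser_his_max: float = 4.0
    d_his_third_max: float = 4.0
    ser_atom: str = "OG"
    his_atoms: tuple[str, ...] = ("ND1", "NE2")
    third_atoms: dict = field(
        default_factory=lambda: {
            "GLU": ("OE1", "OE2"),
            "ASP": ("OD1", "OD2"),
            "THR": ("OG1",),
        }
    )
    consensus_min_models: int | None = None  # default ceil(m/2), set at call time

    def __post_init__(self) -> None:
        if self.d_ser_his_max <= 0 or self.d_his_third_max <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not self.his_atoms or not self.third_atoms:
            raise ValueError("atom sets must be non-empty")


@dataclass(frozen=True)
class TriadCandidate:
    ser_res: int
    his_res: int
    third_res: int
    third_type: str
    d_ser_his: float
    d_his_third: float
    his_atom_nucleophile_leg: str
    his_atom_acid_leg: str
    models_supporting: int = 1

    @property
    def key(self) -> tuple[int, int, int, str]:
        return (self.ser_res, self.his_res, self.third_res, self.third_type)

    @property
    def distance_sum(self) -> float:
        return self.d_ser_his + self.d_his_third


def _atom_xyz(model: pd.DataFrame, res_seq: int, atom: str) -> np.ndarray | None:
    sel = model[(model["res_seq"] == res_seq) & (model["atom_name"] == atom)]
    if sel.empty:
        return None
    return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]


def find_triads(model: pd.DataFrame, config: TriadConfig | None = None) -> list[TriadCandidate]:
    """All Ser-His-(Glu/Asp/Thr) triples satisfying the two-leg geometry.

    Residues missing the needed side-chain atoms are skipped with a warning.
    """
    import warnings

    config = config or TriadConfig()
    residues = model[["res_seq", "res_name"]].drop_duplicates("res_seq")
    sers = residues[residues["res_name"] == "SER"]["res_seq"].tolist()
    hises = residues[residues["res_name"] == "HIS"]["res_seq"].tolist()
    thirds = residues[residues["res_name"].isin(config.third_atoms)][
        ["res_seq", "res_name"]
    ]

    candidates: list[TriadCandidate] = []
    for ser in sers:
        og = _atom_xyz(model, ser, config.ser_atom)
        if og is None:
            warnings.warn(f"SER {ser}: missing {config.ser_atom}, skipped", stacklevel=2)
            continue
        for his in hises:
            n_xyz = {}
            for n_name in config.his_atoms:
                xyz = _atom_xyz(model, his, n_name)
                if xyz is not None:
                    n_xyz[n_name] = xyz
            if len(n_xyz) < 2:
                warnings.warn(f"HIS {his}: missing imidazole nitrogen(s), skipped", stacklevel=2)
                continue
            for third in thirds.itertuples():
                if third.res_seq in (ser, his):
                    continue
                acceptors = [
                    (a, _atom_xyz(model, third.res_seq, a))
                    for a in config.third_atoms[third.res_name]
                ]
                acceptors = [(a, x) for a, x in acceptors if x is not None]
                if not acceptors:
                    continue
                # try both nitrogen role assignments; keep the best valid one
                best = None
                names = list(n_xyz)
                for n_nuc in names:
                    n_acid = [n for n in names if n != n_nuc][0]
                    d1 = float(np.linalg.norm(og - n_xyz[n_nuc]))
                    if d1 > config.d_ser_his_max:
                        continue
                    d2 = min(
                        float(np.linalg.norm(n_xyz[n_acid] - x)) for _, x in acceptors
                    )
                    if d2 > config.d_his_third_max:
                        continue
                    if best is None or d1 + d2 < best[0] + best[1]:
                        best = (d1, d2, n_nuc, n_acid)
                if best is not None:
                    candidates.append(
                        TriadCandidate(
                            ser_res=int(ser),
                            his_res=int(his),
                            third_res=int(third.res_seq),
                            third_type=third.res_name,
                            d_ser_his=best[0],
                            d_his_third=best[1],
                            his_atom_nucleophile_leg=best[2],
                            his_atom_acid_leg=best[3],
                        )
                    )
    return candidates


def consensus_over_ensemble(
    ensemble: StructureEnsemble, config: TriadConfig | None = None
) -> list[TriadCandidate]:
    """Triad candidates supported by at least ``consensus_min_models``
    conformers (default: a majority, ceil(m/2)); distances are averaged over
    the supporting conformers."""
    config = config or TriadConfig()
    m = ensemble.n_models
    min_models = config.consensus_min_models or -(-m // 2)
    by_key: dict = {}
    for i in range(m):
        for cand in find_triads(ensemble.model(i + 1), config):
            by_key.setdefault(cand.key, []).append(cand)
    out = []
    for key, cands in sorted(by_key.items()):
        if len(cands) >= min_models:
            c0 = cands[0]
            out.append(
                TriadCandidate(
                    ser_res=c0.ser_res,
                    his_res=c0.his_res,
                    third_res=c0.third_res,
                    third_type=c0.third_type,
                    d_ser_his=float(np.mean([c.d_ser_his for c in cands])),
                    d_his_third=float(np.mean([c.d_his_third for c in cands])),
                    his_atom_nucleophile_leg=c0.his_atom_nucleophile_leg,
                    his_atom_acid_leg=c0.his_atom_acid_leg,
                    models_supporting=len(cands),
                )
            )
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str] | np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 92,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (angstrom^2), Shrake-Rupley.

    Each atom's solvent sphere (vdW radius + probe) is sampled with
    ``n_points`` golden-spiral points; a point survives if it lies outside
    every neighbouring atom's solvent sphere.  For a single isolated atom the
    result converges to 4*pi*(r + probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe_radius
    unit = _fibonacci_sphere(n_points)
    n = len(coords)
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.where((d < radii + radii[i]) & (np.arange(n) != i))[0]
        if len(neigh):
            dist2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (dist2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * n_acc / n_points
    return areas


def solvent_exposure(
    model: pd.DataFrame,
    res_seq: int,
    probe_radius: float = 1.4,
    n_points: int = 92,
) -> float:
    """Relative side-chain solvent exposure of one residue, in [0, ~1.5].

    Accessible area of the residue's side-chain heavy atoms in the full
    structure, divided by the same side chain's area recomputed with all
    other residues removed (a conformation-matched isolated reference).  A
    residue with no neighbours scores 1 by construction; a fully occluded
    side chain scores ~0.  Glycine (no side chain) raises an error.
    """
    heavy = model[model["element"] != "H"].reset_index(drop=True)
    res_rows = heavy[heavy["res_seq"] == res_seq]
    if res_rows.empty:
        raise KeyError(f"residue {res_seq} not in model")
    sc_mask_local = ~res_rows["atom_name"].isin(BACKBONE_NAMES)
    if not sc_mask_local.any():
        raise ValueError(f"residue {res_seq} ({res_rows['res_name'].iloc[0]}) has no side-chain heavy atoms")
    full_areas = shrake_rupley_sasa(
        heavy[["x", "y", "z"]].to_numpy(),
        heavy["element"].tolist(),
        probe_radius,
        n_points,
    )
    is_target_sc = (
        (heavy["res_seq"] == res_seq) & ~heavy["atom_name"].isin(BACKBONE_NAMES)
    ).to_numpy()
    area_in_context = float(full_areas[is_target_sc].sum())
    iso = res_rows.reset_index(drop=True)
    iso_areas = shrake_rupley_sasa(
        iso[["x", "y", "z"]].to_numpy(), iso["element"].tolist(), probe_radius, n_points
    )
    area_reference = float(iso_areas[sc_mask_local.to_numpy()].sum())
    if area_reference == 0:
        raise ValueError(f"zero reference area for residue {res_seq}")
    return area_in_context / area_reference


def rank_candidates(
    candidates: list[TriadCandidate], model: pd.DataFrame
) -> list[TriadCandidate]:
    """Order candidates: ascending leg-distance sum, then lower third-residue
    side-chain exposure, then residue numbers."""
    if not candidates:
        raise ValueError("no candidates to rank")

    exposures = {}
    for c in candidates:
        if c.third_res not in exposures:
            try:
                exposures[c.third_res] = solvent_exposure(model, c.third_res)
            except (KeyError, ValueError):
                exposures[c.third_res] = float("inf")
    return sorted(
        candidates,
        key=lambda c: (
            round(c.distance_sum, 6),
            exposures[c.third_res],
            c.ser_res,
            c.his_res,
            c.third_res,
        ),
    )


def candidates_table(candidates: list[TriadCandidate]) -> pd.DataFrame:
    """Flatten candidates to a report table."""
    return pd.DataFrame(
        [
            {
                "ser": c.ser_res,
                "his": c.his_res,
                "third": c.third_res,
                "third_type": c.third_type,
                "d_ser_his_A": c.d_ser_his,
                "d_his_third_A": c.d_his_third,
                "support": c.models_supporting,
            }
            for c in candidates
        ]
    )
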