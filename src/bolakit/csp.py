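"""Chemical-shift-perturbation (CSP) mapping of ligand binding.

Amide peak lists of the free and ligand-bound protein are paired by
assignment label and the combined perturbation per residue is

    CSP = sqrt(dH^2 + (dN / 10)^2)        [ppm]

where dH and dN are the bound-minus-free 1HN and 15N shift changes and the
factor 10 rescales the nitrogen axis to the proton shift range of folded
proteins.  Significant residues are flagged against a mean + k*SD rule with
an absolute floor, and can be annotated with spatial context on a structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .structure_io import StructureEnsemble

__all__ = [
    "CSPThreshold",
    "pair_peaks",
    "compute_csp",
    "flag_significant",
    "annotate_on_structure",
]


@dataclass(frozen=True)
class CSPThreshold:
    """Significance rule for CSPs.

    ``mean_plus_sd``: flag residues with csp > mean + k*SD (and above the
    absolute floor).  ``absolute``: flag residues with csp > floor.
    """

    method: str = "mean_plus_sd"
    k: float = 1.0
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in ("mean_plus_sd", "absolute"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.k < 0 or self.floor < 0:
            raise ValueError("k and floor must be non-negative")


def _validate_peaklist(peaks: pd.DataFrame, name: str) -> pd.DataFrame:
    required = {"res_seq", "dH_ppm", "dN_ppm"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"{name} peak list missing columns {sorted(missing)}")
    dup = peaks["res_seq"][peaks["res_seq"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{name} peak list has duplicate residues {sorted(set(dup))}")
    if not np.all(np.isfinite(peaks[["dH_ppm", "dN_ppm"]].to_numpy())):
        raise ValueError(f"{name} peak list has non-finite shifts")
    return peaks


def pair_peaks(
    free: pd.DataFrame, bound: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair free/bound peak lists on the residue label.

    Returns (pairs, unmatched): ``pairs`` has one row per residue present in
    both states with free and bound shifts; ``unmatched`` lists residues seen
    in only one state (e.g. peaks broadened out on binding) with a ``state``
    column.  Pairing is by assignment label only, never by shift proximity.
    """
    free = _validate_peaklist(free, "free")
    bound = _validate_peaklist(bound, "bound")
    pairs = free.merge(
        bound, on="res_seq", suffixes=("_free", "_bound"), how="inner"
    ).sort_values("res_seq").reset_index(drop=True)
    matched = set(pairs["res_seq"])
    rows = [
        (int(r), "free_only") for r in free["res_seq"] if r not in matched
    ] + [(int(r), "bound_only") for r in bound["res_seq"] if r not in matched]
    unmatched = pd.DataFrame(rows, columns=["res_seq", "state"])
    return pairs, unmatched


def compute_csp(pairs: pd.DataFrame, nitrogen_scale: float = 10.0) -> pd.DataFrame:
    """Combined CSP per paired residue.

    Returns columns ``res_seq, dH, dN, csp`` with dH/dN signed
    (bound - free) and csp = sqrt(dH^2 + (dN/scale)^2) >= 0.
    """
    dH = pairs["dH_ppm_bound"] - pairs["dH_ppm_free"]
    dN = pairs["dN_ppm_bound"] - pairs["dN_ppm_free"]
    csp = np.sqrt(dH**2 + (dN / nitrogen_scale) ** 2)
    return pd.DataFrame(
        {"res_seq": pairs["res_seq"].astype(int), "dH": dH, "dN": dN, "csp": csp}
    )


def flag_significant(
    records: pd.DataFrame, threshold: CSPThreshold | None = None
) -> pd.DataFrame:
    """Add a boolean ``significant`` column to a CSP table.

    The default rule flags csp > mean + k*SD (k = 1) with a 0.01 ppm floor;
    raising k can only unflag residues, never add new ones.
    """
    threshold = threshold or CSPThreshold()
    if threshold.method == "mean_plus_sd" and len(records) < 5:
        raise ValueError("mean_plus_sd rule needs at least 5 residues")
    out = records.copy()
    if threshold.method == "absolute":
        cut = threshold.floor
    else:
        cut = max(
            float(records["csp"].mean() + threshold.k * records["csp"].std(ddof=1)),
            threshold.floor,
        )
    out["significant"] = records["csp"] > cut
    out.attrs["threshold"] = {
        "method": threshold.method,
        "k": threshold.k,
        "floor": threshold.floor,
        "cut_ppm": float(cut),
    }
    return out


def annotate_on_structure(
    flagged: pd.DataFrame,
    ensemble: StructureEnsemble,
    site_atoms: pd.DataFrame | None = None,
    model_index: int = 1,
    linkage_cutoff: float = 8.0,
) -> pd.DataFrame:
    """Spatial context for significant residues on a structure.

    For every flagged residue: its CA coordinates from the chosen model, the
    minimum CA-to-site-atom distance when ``site_atoms`` (a DataFrame with
    x, y, z) is given, and a single-linkage cluster id grouping flagged
    residues whose CA atoms are within ``linkage_cutoff`` angstrom.  Flagged
    residues missing from the structure are dropped with a warning column in
    the report rather than an error.
    """
    model = ensemble.model(model_index)
    cas = model[model["atom_name"] == "CA"].set_index(model.loc[model["atom_name"] == "CA", "res_seq"].astype(int))
    wanted = [int(r) for r in flagged.loc[flagged["significant"], "res_seq"]]
    present = [r for r in wanted if r in cas.index]
    missing = sorted(set(wanted) - set(present))
    if missing:
        import warnings

        warnings.warn(f"flagged residues missing from structure: {missing}", stacklevel=2)
    if not present:
        return pd.DataFrame(
            columns=["res_seq", "csp", "min_site_distance", "cluster"]
        )
    xyz = cas.loc[present, ["x", "y", "z"]].to_numpy(dtype=float)
    dmat = cdist(xyz, xyz)
    adj = csr_matrix(dmat <= linkage_cutoff)
    _, labels = connected_components(adj, directed=False)
    if site_atoms is not None and len(site_atoms):
        site_xyz = site_atoms[["x", "y", "z"]].to_numpy(dtype=float)
        min_site = cdist(xyz, site_xyz).min(axis=1)
    else:
        min_site = np.full(len(present), np.nan)
    csp_map = dict(zip(flagged["res_seq"].astype(int), flagged["csp"]))
    return pd.DataFrame(
        {
            "res_seq": present,
            "csp": [csp_map[r] for r in present],
            "min_site_distance": min_site,
            "cluster": labels,
        }
    )
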