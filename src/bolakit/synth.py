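"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from its own pseudo-random stream, derived from the
seed plus a stage tag, so adding one stage never perturbs another stage's
fixtures and identical arguments reproduce byte-identical outputs.

The fixtures are statistical stand-ins, not physical models: the toy
ensemble is a smooth helix/strand/loop backbone trace with region-dependent
Gaussian coordinate noise (a rigid core and a mobile loop), decay series are
exact exponentials plus intensity noise on the experimental delay schedules,
titration peak lists perturb a chosen residue subset, and the melting,
band-shift and calorimetric curves come from the same models the fitting
code estimates.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .relaxation import (
    T1_DELAYS_S,
    T1_DUPLICATE_DELAYS_S,
    T2_DELAYS_S,
    T2_DUPLICATE_DELAYS_S,
    DecaySeries,
)
from .structure_io import ATOM_COLUMNS, ResidueRange, StructureEnsemble
from .thermo import (
    BindingCurve,
    ITCExperiment,
    MeltingCurve,
    SequentialSitesModel,
    itc_sequential_heats,
)

__all__ = [
    "stage_rng",
    "make_toy_ensemble",
    "make_triad_structure",
    "make_decay_series",
    "make_titration_peaklists",
    "make_melting_curve",
    "make_binding_curve",
    "make_itc_isotherm",
]


def stage_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent generator for (seed, stage tag)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(tag.encode()),))
    )


# ---------------------------------------------------------------------------
# toy structural ensemble
# ---------------------------------------------------------------------------

_SEQ_CYCLE = ("ALA", "LEU", "GLU", "LYS", "VAL", "ASP", "PHE", "ILE")


def _backbone_template(
    n_helix: int = 10, n_strand1: int = 6, n_loop: int = 23, n_strand2: int = 6
) -> tuple[np.ndarray, list[str]]:
    """CA trace of helix + strand + loop + strand segments.

    Helix: 1.5 angstrom rise, 2.3 angstrom radius, 100 degrees per residue.
    Strands: straight 3.3 angstrom steps.  Loop: a wide arc between the two
    strands.  Returns (CA coordinates, segment label per residue).
    """
    cas: list[np.ndarray] = []
    labels: list[str] = []
    for i in range(n_helix):
        a = np.deg2rad(100.0 * i)
        cas.append(np.array([2.3 * np.cos(a), 2.3 * np.sin(a), 1.5 * i]))
        labels.append("helix")
    start = cas[-1] + np.array([4.0, 0.0, 2.0])
    for i in range(n_strand1):
        cas.append(start + np.array([3.3 * i, 0.5 * (i % 2), 0.0]))
        labels.append("strand")
    # loop: arc out of the sheet plane
    loop_start = cas[-1]
    loop_end = loop_start + np.array([0.0, 5.0, 0.0])
    for i in range(1, n_loop + 1):
        t = i / (n_loop + 1)
        arc = np.array(
            [12.0 * np.sin(np.pi * t), 5.0 * t, 8.0 * np.sin(2 * np.pi * t)]
        )
        cas.append(loop_start + (loop_end - loop_start) * t + arc)
        labels.append("loop")
    start2 = loop_end
    for i in range(n_strand2):
        cas.append(start2 + np.array([-3.3 * i, 0.5 * (i % 2), 0.0]))
        labels.append("strand")
    return np.array(cas), labels


def _residue_atoms(ca: np.ndarray, res_name: str) -> list[tuple[str, str, np.ndarray]]:
    """Fixed local offsets give each residue N, CA, C (+O, CB, CG heavies)."""
    atoms = [
        ("N", "N", ca + np.array([-1.20, 0.60, -0.40])),
        ("CA", "C", ca),
        ("C", "C", ca + np.array([1.25, 0.55, 0.35])),
        ("O", "O", ca + np.array([1.90, 1.55, 0.45])),
    ]
    if res_name != "GLY":
        atoms.append(("CB", "C", ca + np.array([-0.45, -1.30, 0.75])))
        atoms.append(("CG", "C", ca + np.array([-0.80, -2.45, 1.55])))
    return atoms


def make_toy_ensemble(
    n_models: int = 10,
    sigma_core: float = 0.3,
    sigma_loop: float = 1.5,
    start_res: int = 34,
    seed: int = 0,
    template: tuple[np.ndarray, list[str]] | None = None,
) -> tuple[StructureEnsemble, ResidueRange]:
    """Gaussian-noise conformer bundle around a helix/strand/loop template.

    Every conformer is the template plus iid per-coordinate noise with
    standard deviation ``sigma_core`` in the helix/strand segments and
    ``sigma_loop`` in the loop.  Returns the ensemble and the loop's residue
    range.  Deterministic per (seed, arguments).
    """
    if sigma_core < 0 or sigma_loop < 0:
        raise ValueError("noise sigmas must be non-negative")
    rng = stage_rng(seed, "toy_ensemble")
    cas, labels = template if template is not None else _backbone_template()
    res_names = [_SEQ_CYCLE[i % len(_SEQ_CYCLE)] for i in range(len(cas))]
    loop_idx = [i for i, lab in enumerate(labels) if lab == "loop"]
    if not loop_idx:
        raise ValueError("template has no loop region")
    loop_range = ResidueRange(start_res + loop_idx[0], start_res + loop_idx[-1])
    models = []
    for _ in range(n_models):
        rows = []
        for i, (ca, res_name, lab) in enumerate(zip(cas, res_names, labels)):
            sigma = sigma_loop if lab == "loop" else sigma_core
            for atom_name, element, xyz in _residue_atoms(ca, res_name):
                noisy = xyz + rng.normal(0.0, sigma, size=3)
                rows.append(
                    ("A", start_res + i, res_name, atom_name, element, *noisy)
                )
        models.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    return StructureEnsemble(models=models, source="synthetic"), loop_range


# ---------------------------------------------------------------------------
# triad fixture
# ---------------------------------------------------------------------------


def make_triad_structure(
    d1: float = 2.8,
    d2: float = 2.9,
    decoys: int = 0,
    seed: int = 0,
    n_models: int = 1,
    loop_noise: float = 0.0,
) -> StructureEnsemble:
    """Single Ser-His-Thr triple at prescribed leg distances, plus decoys.

    Ser OG sits ``d1`` angstrom from His NE2 and Thr OG1 ``d2`` angstrom
    from His ND1.  Decoy residues (Ala plus extra Ser/Glu far from any His)
    are placed at least 8 angstrom away.  ``loop_noise`` adds Gaussian noise
    to the Ser side chain in every model, for consensus-breaking fixtures.
    """
    rng = stage_rng(seed, "triad_structure")
    his_ne2 = np.array([0.0, 0.0, 0.0])
    his_nd1 = np.array([2.1, 0.0, 0.0])  # across the imidazole ring
    ser_og = his_ne2 + np.array([0.0, d1, 0.0])
    thr_og1 = his_nd1 + np.array([0.0, -d2, 0.0])

    def bb(center: np.ndarray, res_seq: int, res_name: str, extra):
        rows = [
            ("A", res_seq, res_name, "N", "N", *(center + [-1.2, 0.5, 2.5])),
            ("A", res_seq, res_name, "CA", "C", *(center + [0.0, 0.0, 2.5])),
            ("A", res_seq, res_name, "C", "C", *(center + [1.3, 0.5, 2.5])),
            ("A", res_seq, res_name, "O", "O", *(center + [2.0, 1.4, 2.5])),
            ("A", res_seq, res_name, "CB", "C", *(center + [0.0, -0.4, 1.2])),
        ]
        rows.extend(extra)
        return rows

    models = []
    for _ in range(n_models):
        og = ser_og + (rng.normal(0.0, loop_noise, 3) if loop_noise > 0 else 0.0)
        rows = []
        rows += bb(og, 10, "SER", [("A", 10, "SER", "OG", "O", *og)])
        rows += bb(
            (his_ne2 + his_nd1) / 2,
            20,
            "HIS",
            [
                ("A", 20, "HIS", "ND1", "N", *his_nd1),
                ("A", 20, "HIS", "NE2", "N", *his_ne2),
            ],
        )
        rows += bb(thr_og1, 30, "THR", [("A", 30, "THR", "OG1", "O", *thr_og1)])
        for k in range(decoys):
            # decoy shell well outside both cutoffs
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = direction * (12.0 + 3.0 * rng.random())
            name = ("ALA", "SER", "GLU")[k % 3]
            extra = []
            if name == "SER":
                extra = [("A", 100 + k, "SER", "OG", "O", *(center + [0.0, -1.0, 0.3]))]
            elif name == "GLU":
                extra = [
                    ("A", 100 + k, "GLU", "OE1", "O", *(center + [0.3, -1.1, 0.2])),
                    ("A", 100 + k, "GLU", "OE2", "O", *(center + [-0.3, -1.2, 0.4])),
                ]
            rows += bb(center, 100 + k, name, extra)
        models.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    return StructureEnsemble(models=models, source="synthetic")


# ---------------------------------------------------------------------------
# relaxation decays
# ---------------------------------------------------------------------------


def make_decay_series(
    R: float,
    delays: Sequence[float] | str = "t1",
    duplicate_delays: Sequence[float] | None = None,
    noise_frac: float = 0.0,
    I0: float = 1.0,
    res_seq: int = 1,
    seed: int = 0,
) -> DecaySeries:
    """Exponential decay I0*exp(-R t) on an experimental delay schedule.

    ``delays='t1'``/``'t2'`` selects the inversion-recovery or CPMG schedule
    (starred delays recorded twice); an explicit list may be given instead.
    ``noise_frac`` is Gaussian intensity noise relative to I0.
    """
    if delays == "t1":
        base, dups = T1_DELAYS_S, T1_DUPLICATE_DELAYS_S
    elif delays == "t2":
        base, dups = T2_DELAYS_S, T2_DUPLICATE_DELAYS_S
    else:
        base = tuple(float(d) for d in delays)
        dups = tuple(duplicate_delays or ())
    all_delays, dup_mask = [], []
    for d in base:
        reps = 2 if d in dups else 1
        for _ in range(reps):
            all_delays.append(d)
            dup_mask.append(d in dups)
    t = np.array(all_delays)
    rng = stage_rng(seed, f"decay_{res_seq}")
    y = I0 * np.exp(-R * t)
    if noise_frac > 0:
        y = y + rng.normal(0.0, noise_frac * I0, size=len(t))
    return DecaySeries(
        res_seq=res_seq, delays=t, intensities=y, duplicate_mask=np.array(dup_mask)
    )


def make_decay_table(
    rates: dict[int, float],
    delays: str = "t2",
    noise_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy decay table (res_seq, delay_s, intensity, is_duplicate) for many residues."""
    frames = []
    for res, R in sorted(rates.items()):
        s = make_decay_series(
            R, delays=delays, noise_frac=noise_frac, res_seq=res, seed=seed
        )
        frames.append(
            pd.DataFrame(
                {
                    "res_seq": s.res_seq,
                    "delay_s": s.delays,
                    "intensity": s.intensities,
                    "is_duplicate": s.duplicate_mask,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# titration peak lists
# ---------------------------------------------------------------------------


def make_titration_peaklists(
    residues: Sequence[int] = tuple(range(24, 124)),
    perturbed_residues: Sequence[int] = (),
    magnitudes: tuple[float, float] = (0.05, 0.5),
    jitter_ppm: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(free, bound) amide peak lists with a perturbed residue subset.

    Base shifts are drawn once (1HN ~ 8.3 +/- 0.5 ppm, 15N ~ 119 +/- 4 ppm);
    the bound list moves ``perturbed_residues`` by ``magnitudes`` = (dH, dN)
    ppm with random signs and jitters every other residue by ``jitter_ppm``.
    """
    rng = stage_rng(seed, "titration")
    residues = sorted(residues)
    dH_base = 8.3 + 0.5 * rng.standard_normal(len(residues))
    dN_base = 119.0 + 4.0 * rng.standard_normal(len(residues))
    free = pd.DataFrame(
        {"res_seq": residues, "dH_ppm": dH_base, "dN_ppm": dN_base}
    )
    perturbed = set(perturbed_residues)
    dH_b, dN_b = dH_base.copy(), dN_base.copy()
    for i, res in enumerate(residues):
        if res in perturbed:
            sh = rng.choice([-1.0, 1.0])
            sn = rng.choice([-1.0, 1.0])
            dH_b[i] += sh * magnitudes[0]
            dN_b[i] += sn * magnitudes[1]
        elif jitter_ppm > 0:
            dH_b[i] += rng.normal(0.0, jitter_ppm)
            dN_b[i] += rng.normal(0.0, jitter_ppm)
    bound = pd.DataFrame({"res_seq": residues, "dH_ppm": dH_b, "dN_ppm": dN_b})
    return free, bound


# ---------------------------------------------------------------------------
# thermodynamic curves
# ---------------------------------------------------------------------------


def make_melting_curve(
    Tm: float = 54.0,
    width: float = 4.0,
    theta_F: float = -20.0,
    theta_U: float = -2.0,
    noise_frac: float = 0.0,
    T_min: float = 20.0,
    T_max: float = 90.0,
    step: float = 1.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state CD melt on the 20-90 Celsius acquisition grid."""
    rng = stage_rng(seed, "melt")
    T = np.arange(T_min, T_max + 0.5 * step, step)
    frac_u = 1.0 / (1.0 + np.exp((Tm - T) / width))
    theta = theta_F + (theta_U - theta_F) * frac_u
    if noise_frac > 0:
        theta = theta + rng.normal(0.0, noise_frac * abs(theta_F - theta_U), len(T))
    return MeltingCurve(temperatures=T, ellipticities=theta, theta_F=theta_F, theta_U=theta_U)


def make_binding_curve(
    Kd: float = 1.1,
    Vmax: float = 1.0,
    x: Sequence[float] = (0.5, 1.0, 2.0),
    replicates: int = 3,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Hyperbolic band-intensity titration (x in uM), replicated design."""
    rng = stage_rng(seed, "binding")
    xs = np.repeat(np.asarray(x, dtype=float), replicates)
    y = Vmax * xs / (Kd + xs)
    if noise_frac > 0:
        y = y + rng.normal(0.0, noise_frac * Vmax, len(xs))
    return BindingCurve(x=xs, y=y)


def make_itc_isotherm(
    model: SequentialSitesModel,
    cell_volume_ml: float = 1.445,
    cell_conc_uM: float = 75.0,
    syringe_conc_uM: float = 2000.0,
    injection_volume_uL: float = 5.0,
    n_injections: int = 28,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ITCExperiment:
    """Sequential-sites titration with the calorimeter geometry used for the
    protein-DNA measurements (75 uM cell, 2 mM syringe, 5 uL injections).

    ``noise_frac`` is Gaussian heat noise relative to the largest predicted
    injection heat.
    """
    exp = ITCExperiment(
        cell_volume_ml=cell_volume_ml,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        injection_volumes_uL=np.full(n_injections, injection_volume_uL),
    )
    heats = itc_sequential_heats(model, exp)
    if noise_frac > 0:
        rng = stage_rng(seed, "itc")
        heats = heats + rng.normal(0.0, noise_frac * np.abs(heats).max(), len(heats))
    exp.heats_ucal = heats
    return exp
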