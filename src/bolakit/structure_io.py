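"""Reading and writing the formats the pipeline touches.

Multi-model PDB ensembles are parsed with :mod:`gemmi` into a lightweight
:class:`StructureEnsemble` container (one :class:`pandas.DataFrame` of atom
records per conformer).  CYANA-style upper-limit distance restraints and the
pipeline's tabular inputs are handled here as well.

Residue numbering is always the author numbering found in the file; ranges
are inclusive on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "ParseError",
    "ResidueRange",
    "RestraintCategory",
    "DistanceRestraint",
    "SequenceRecord",
    "StructureEnsemble",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_restraints",
    "classify_restraint",
    "extract_sequence",
    "average_mass",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ATOM_COLUMNS = ["chain", "res_seq", "res_name", "atom_name", "element", "x", "y", "z"]

BACKBONE_ATOMS = ("N", "CA", "C")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range, e.g. 33-53."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid range {self.start}-{self.end}: start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, res_seq: int) -> bool:
        return self.start <= res_seq <= self.end

    @classmethod
    def parse(cls, text: str) -> "ResidueRange":
        """Parse '33-53' (or a single number '35') into a range."""
        parts = text.split("-")
        if len(parts) == 1:
            n = int(parts[0])
            return cls(n, n)
        return cls(int(parts[0]), int(parts[1]))


def parse_ranges(text: str) -> list[ResidueRange]:
    """Parse a comma-separated range list such as '33-53,76-122'."""
    return [ResidueRange.parse(tok) for tok in text.split(",") if tok.strip()]


class RestraintCategory(str, Enum):
    INTRARESIDUE = "intraresidue"
    SEQUENTIAL = "sequential"
    MEDIUM = "medium"
    LONG = "long"
    HBOND = "hbond"


@dataclass(frozen=True)
class DistanceRestraint:
    """An upper-bound distance restraint between two atoms.

    Categories follow the standard NMR bookkeeping: intraresidue (i = j),
    sequential (|i - j| = 1), medium range (2 <= |i - j| <= 4) and long range
    (|i - j| >= 5); hydrogen-bond restraints keep their explicit category.
    """

    res_i: int
    res_j: int
    atom_i: str
    atom_j: str
    upper_bound: float
    category: RestraintCategory

    def __post_init__(self) -> None:
        if not self.upper_bound > 0:
            raise ValueError(f"upper bound must be positive, got {self.upper_bound}")


@dataclass(frozen=True)
class SequenceRecord:
    """Author-numbered one-letter sequence."""

    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        nums = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def one_letter(self) -> str:
        return "".join(code for _, code in self.residues)

    @property
    def span(self) -> tuple[int, int]:
        return self.residues[0][0], self.residues[-1][0]


@dataclass
class StructureEnsemble:
    """An ordered bundle of conformer models.

    Each model is a DataFrame with columns ``chain, res_seq, res_name,
    atom_name, element, x, y, z``.  Model order follows the MODEL records of
    the source file.  Consistency of atom keys across models is enforced at
    selection time (see :meth:`select_coords`), not at load time.
    """

    models: list[pd.DataFrame]
    source: str = ""
    _keyed: list[pd.DataFrame] = field(default_factory=list, repr=False)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_span(self) -> tuple[int, int]:
        rs = self.models[0]["res_seq"]
        return int(rs.min()), int(rs.max())

    def model(self, index: int = 1) -> pd.DataFrame:
        """Return one model by 1-based index (MODEL-record convention)."""
        return self.models[index - 1]

    def selection_keys(
        self,
        ranges: Sequence[ResidueRange] | None = None,
        atom_set: str = "backbone",
    ) -> list[tuple[int, str]]:
        """(res_seq, atom_name) keys of the selection, from model 1.

        ``atom_set`` is ``backbone`` ({N, CA, C}), ``heavy`` (all
        non-hydrogen atoms) or ``ca`` (CA only).
        """
        m = self.models[0]
        mask = np.ones(len(m), dtype=bool)
        if ranges is not None:
            in_range = np.zeros(len(m), dtype=bool)
            for r in ranges:
                in_range |= (m["res_seq"] >= r.start).to_numpy() & (
                    m["res_seq"] <= r.end
                ).to_numpy()
            mask &= in_range
        if atom_set == "backbone":
            mask &= m["atom_name"].isin(BACKBONE_ATOMS).to_numpy()
        elif atom_set == "heavy":
            mask &= (m["element"] != "H").to_numpy()
        elif atom_set == "ca":
            mask &= (m["atom_name"] == "CA").to_numpy()
        else:
            raise ValueError(f"unknown atom set {atom_set!r}")
        sub = m.loc[mask]
        return list(zip(sub["res_seq"].astype(int), sub["atom_name"]))

    def _indexed(self, i: int) -> pd.DataFrame:
        if not self._keyed:
            self._keyed = [
                m.set_index([m["res_seq"].astype(int), m["atom_name"]])
                for m in self.models
            ]
        return self._keyed[i]

    def select_coords(self, keys: Sequence[tuple[int, str]]) -> np.ndarray:
        """Coordinates for the given keys in every model: (m, n_atoms, 3).

        Raises :class:`KeyError` naming the model and atom if a model lacks a
        selected atom (same-key invariant, enforced here).
        """
        out = np.empty((self.n_models, len(keys), 3), dtype=float)
        for i in range(self.n_models):
            mi = self._indexed(i)
            try:
                sub = mi.loc[list(keys)]
            except KeyError:
                present = set(mi.index)
                missing = [k for k in keys if k not in present]
                raise KeyError(
                    f"model {i + 1} is missing atom(s) {missing[:5]} required by the selection"
                ) from None
            out[i] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        return out


def _element_from_name(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H" or (atom_name.strip()[0].isdigit() and stripped[0] == "H"):
        return "H"
    return stripped[0]


def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields of ATOM lines; return their count."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("ATOM"):
                n_atoms += 1
                if len(line) < 54:
                    raise ParseError(f"{path}: malformed ATOM line {lineno}: too short")
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise ParseError(
                            f"{path}: malformed ATOM line {lineno}: "
                            f"bad coordinate field {line[lo:hi]!r}"
                        ) from None
    return n_atoms


def read_pdb_ensemble(path: str | Path, include_hetero: bool = False) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    Models are returned in MODEL-record order; a file without MODEL records
    yields a one-model ensemble.  HETATM records and waters are excluded
    unless ``include_hetero`` is set.  For altlocs the first conformer is
    kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if _prescan_pdb(path) == 0:
        raise ParseError(f"{path}: no ATOM records found")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models: list[pd.DataFrame] = []
    for model in st:
        rows = []
        for chain in model:
            for res in chain:
                if not include_hetero and (res.het_flag != "A" or res.is_water()):
                    continue
                seen = set()
                for atom in res:
                    if atom.name in seen:  # altloc duplicates: keep first
                        continue
                    seen.add(atom.name)
                    elem = atom.element.name if atom.element else ""
                    if not elem or elem == "X":
                        elem = _element_from_name(atom.name)
                    rows.append(
                        (
                            chain.name,
                            res.seqid.num,
                            res.name,
                            atom.name,
                            elem,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
        if rows:
            models.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    if not models:
        raise ParseError(f"{path}: no polymer atoms after filtering")
    for m in models:
        xyz = m[["x", "y", "z"]].to_numpy()
        if not np.all(np.isfinite(xyz)):
            raise ParseError(f"{path}: non-finite coordinates")
    return StructureEnsemble(models=models, source=str(path))


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (round-trip safe)."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for i, mdf in enumerate(ensemble.models, start=1):
        model = gemmi.Model(i)
        for chain_name, cdf in mdf.groupby("chain", sort=False):
            chain = gemmi.Chain(str(chain_name))
            for (res_seq, res_name), rdf in cdf.groupby(
                ["res_seq", "res_name"], sort=False
            ):
                res = gemmi.Residue()
                res.name = str(res_name)
                res.seqid = gemmi.SeqId(int(res_seq), " ")
                res.het_flag = "A"
                for row in rdf.itertuples():
                    atom = gemmi.Atom()
                    atom.name = row.atom_name
                    atom.element = gemmi.Element(row.element)
                    atom.pos = gemmi.Position(row.x, row.y, row.z)
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def classify_restraint(res_i: int, res_j: int) -> RestraintCategory:
    """Sequence-separation category of a restraint between residues i and j."""
    sep = abs(res_i - res_j)
    if sep == 0:
        return RestraintCategory.INTRARESIDUE
    if sep == 1:
        return RestraintCategory.SEQUENTIAL
    if sep <= 4:
        return RestraintCategory.MEDIUM
    return RestraintCategory.LONG


_AA_TOKENS = STANDARD_RESIDUES | {"HIS+", "CYSS", "ASP-", "GLU-", "LYS+", "ARG+"}


def _parse_upl_line(line: str, lineno: int, path: str) -> DistanceRestraint | None:
    body, _, comment = line.partition("#")
    tokens = body.split()
    if not tokens:
        return None
    if len(tokens) < 7:
        raise ParseError(
            f"{path}: line {lineno}: expected 7 fields "
            f"(res res_name atom res res_name atom bound), got {len(tokens)}"
        )
    try:
        res_i, res_j = int(tokens[0]), int(tokens[3])
        bound = float(tokens[6])
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: unparseable token ({exc})") from None
    name_i, name_j = tokens[1].upper(), tokens[4].upper()
    for name in (name_i, name_j):
        if name not in _AA_TOKENS:
            raise ParseError(f"{path}: line {lineno}: unknown residue token {name!r}")
    if bound <= 0:
        raise ParseError(f"{path}: line {lineno}: non-positive bound {bound}")
    is_hbond = "hbond" in comment.lower() or "hb" == comment.strip().lower()
    category = (
        RestraintCategory.HBOND if is_hbond else classify_restraint(res_i, res_j)
    )
    return DistanceRestraint(
        res_i=res_i,
        res_j=res_j,
        atom_i=tokens[2].upper(),
        atom_j=tokens[5].upper(),
        upper_bound=bound,
        category=category,
    )


def read_restraints(path: str | Path, dialect: str = "cyana_upl") -> list[DistanceRestraint]:
    """Read a distance-restraint list.

    ``cyana_upl``: whitespace-separated upper-limit lines
    ``resnum resname atom resnum resname atom bound``; blank lines and
    ``#`` comments are skipped; a trailing ``#hbond`` comment marks an
    explicit hydrogen-bond restraint.

    ``pdb_mr``: a deposited MR file; CYANA-format 7-token lines are
    extracted, everything else (section headers, other restraint blocks)
    is ignored.
    """
    path = Path(path)
    if dialect not in ("cyana_upl", "pdb_mr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    restraints: list[DistanceRestraint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "pdb_mr":
                tokens = line.split("#")[0].split()
                looks_like_upl = (
                    len(tokens) >= 7
                    and tokens[0].lstrip("-").isdigit()
                    and tokens[3].lstrip("-").isdigit()
                    and tokens[1].upper() in _AA_TOKENS
                    and tokens[4].upper() in _AA_TOKENS
                )
                if not looks_like_upl:
                    continue
            r = _parse_upl_line(line, lineno, str(path))
            if r is not None:
                restraints.append(r)
    return restraints


def restraint_counts(restraints: Iterable[DistanceRestraint]) -> pd.Series:
    """Count restraints per category; categories partition the total."""
    counts = {c.value: 0 for c in RestraintCategory}
    for r in restraints:
        counts[r.category.value] += 1
    counts["total_distance"] = sum(
        counts[c.value] for c in RestraintCategory if c != RestraintCategory.HBOND
    )
    return pd.Series(counts)


def extract_sequence(ensemble: StructureEnsemble) -> SequenceRecord:
    """One-letter sequence from model 1, author numbering preserved.

    Nonstandard residues are included as 'X' with a warning; a numbering gap
    triggers a warning but the sequence is still returned.
    """
    m = ensemble.models[0]
    residues = m[["res_seq", "res_name"]].drop_duplicates("res_seq")
    out = []
    for row in residues.itertuples():
        code = THREE_TO_ONE.get(row.res_name)
        if code is None:
            warnings.warn(
                f"nonstandard residue {row.res_name} at {row.res_seq}; using 'X'",
                stacklevel=2,
            )
            code = "X"
        out.append((int(row.res_seq), code))
    nums = [n for n, _ in out]
    if any(b - a > 1 for a, b in zip(nums, nums[1:])):
        warnings.warn("sequence has numbering gaps", stacklevel=2)
    return SequenceRecord(residues=tuple(out))


def average_mass(seq: SequenceRecord | str) -> float:
    """Average (not monoisotopic) molecular mass of the peptide in Da.

    Sum of average residue masses plus one water; additive over
    concatenation minus one water per peptide bond formed.
    """
    letters = seq if isinstance(seq, str) else seq.one_letter
    if not letters:
        raise ValueError("empty sequence")
    for i, aa in enumerate(letters):
        if aa not in THREE_TO_ONE.values():
            raise ValueError(f"cannot compute mass: nonstandard residue {aa!r} at position {i}")
    return float(molecular_weight(letters, seq_type="protein", monoisotopic=False))
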