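import numpy as np
import pandas as pd
import pytest

from bolakit.structure_io import ATOM_COLUMNS, StructureEnsemble


@pytest.fixture
def tiny_pdb(tmp_path):
    """Two-model, three-atom PDB file."""
    lines = []
    for m in (1, 2):
        lines.append(f"MODEL     {m:>4}")
        for i, (name, x) in enumerate([("N", 0.0), ("CA", 1.5), ("C", 2.9)], start=1):
            lines.append(
                f"ATOM  {i:>5}  {name:<3}ALA A  24    "
                f"{x + 0.1 * m:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           {name[0]}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def ensemble_from_coords(stack, atom_names=None, res_per_atom=None, res_name="ALA"):
    """Build a StructureEnsemble from an (m, n, 3) coordinate stack."""
    stack = np.asarray(stack, dtype=float)
    m, n, _ = stack.shape
    atom_names = atom_names or [f"C{i}" for i in range(n)]
    res_per_atom = res_per_atom or [i + 1 for i in range(n)]
    models = []
    for k in range(m):
        rows = [
            ("A", res_per_atom[i], res_name, atom_names[i], "C", *stack[k, i])
            for i in range(n)
        ]
        models.append(pd.DataFrame(rows, columns=ATOM_COLUMNS))
    return StructureEnsemble(models=models, source="synthetic")
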