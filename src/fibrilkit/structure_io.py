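"""Reading and writing structure files (PDB and GRO).

PDB files are written and read through biotite (coordinates in Å, strict
fixed columns, single-character chain ids cycling A-Z/a-z/0-9); GRO files
(nm, free atom count, box vectors on the last line) are handled directly —
the format is a fixed-width one-liner per atom.  Models with more than
99 999 atoms refuse strict PDB output and advise GRO.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_builder import ATOM_COLUMNS, FibrilModel

__all__ = ["write_structure", "read_structure"]

PDB_MAX_ATOMS = 99_999
PDB_MAX_RESID = 9_999


def write_structure(model: FibrilModel, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "PDB":
        _write_pdb(model, path)
    elif fmt == "GRO":
        _write_gro(model, path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")


def read_structure(path) -> FibrilModel:
    """Read coordinates back into a FibrilModel (topology tags not restored)."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        return _read_pdb(path)
    if path.suffix.lower() == ".gro":
        return _read_gro(path)
    raise ValueError(f"unsupported structure format {path.suffix!r}")


def _write_pdb(model: FibrilModel, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = model.n_atoms
    if n > PDB_MAX_ATOMS:
        raise ValueError(
            f"{n} atoms exceed the strict PDB serial field; write GRO instead")
    atoms = model.atoms
    arr = struc.AtomArray(n)
    arr.coord = atoms[["x", "y", "z"]].to_numpy() * 10.0  # nm -> Angstrom
    arr.chain_id = atoms["chain_id"].to_numpy(dtype="U4")
    arr.res_id = atoms["res_seq"].to_numpy()
    arr.res_name = atoms["res_name"].to_numpy(dtype="U5")
    arr.atom_name = atoms["name"].to_numpy(dtype="U6")
    arr.element = atoms["element"].to_numpy(dtype="U2")
    arr.hetero = atoms["res_name"].to_numpy() == "ACE"
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    if model.box is not None:
        arr.box = np.diag(model.box) * 10.0
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def _read_pdb(path: Path) -> FibrilModel:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    box = None
    if arr.box is not None:
        box = np.diag(arr.box) / 10.0
    coord = arr.coord / 10.0
    atoms = pd.DataFrame({
        "serial": np.arange(1, len(arr) + 1),
        "name": arr.atom_name,
        "element": arr.element,
        "res_name": arr.res_name,
        "res_seq": arr.res_id,
        "chain_id": arr.chain_id,
        "x": coord[:, 0], "y": coord[:, 1], "z": coord[:, 2],
        "sheet": -1, "strand": -1, "conformer": "-", "segment": "-",
    })[ATOM_COLUMNS]
    return FibrilModel(atoms=atoms, box=box, provenance={"source": str(path)})


def _write_gro(model: FibrilModel, path: Path) -> None:
    atoms = model.atoms
    chain_codes, _ = pd.factorize(atoms["chain_id"])
    # GRO has no chain field: fold the chain into the residue number stream
    lines = [f"fibrilkit model ({model.provenance.get('builder', 'unknown')})",
             f"{len(atoms):5d}"]
    resid_counter = {}
    res_number = []
    last = None
    n_res = 0
    for cid, rseq in zip(atoms["chain_id"], atoms["res_seq"]):
        key = (cid, rseq)
        if key != last:
            n_res += 1
            last = key
        res_number.append(n_res % 100_000)
    for (_, row), rnum in zip(atoms.iterrows(), res_number):
        lines.append(
            f"{rnum:5d}{row['res_name']:<5s}{row['name']:>5s}"
            f"{int(row['serial']) % 100_000:5d}"
            f"{row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}")
    box = model.box if model.box is not None else np.zeros(3)
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_gro(path: Path) -> FibrilModel:
    lines = path.read_text(encoding="utf-8").splitlines()
    n = int(lines[1].strip())
    rows = []
    for i, line in enumerate(lines[2:2 + n]):
        res_num = int(line[0:5])
        res_name = line[5:10].strip()
        name = line[10:15].strip()
        serial = int(line[15:20])
        x, y, z = (float(line[20 + 8 * k:28 + 8 * k]) for k in range(3))
        element = name[0] if name[0] in "NCOSH" else name[:1]
        rows.append((serial, name, element, res_name, res_num, "A",
                     x, y, z, -1, -1, "-", "-"))
    box_fields = lines[2 + n].split()
    box = np.array([float(v) for v in box_fields[:3]])
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return FibrilModel(atoms=atoms, box=box, provenance={"source": str(path)})
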