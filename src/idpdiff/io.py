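"""Ensemble file I/O: multi-model Cα-only PDB plus a FASTA sequence sidecar.

Ensembles are stored as standard multi-model PDB files containing one
``CA`` ATOM record per residue (chain A, 1-based residue numbering,
occupancy 1.00, B-factor 0.00).  The amino-acid sequence travels in a FASTA
sidecar, which is authoritative; residue names in the PDB are written from
the sequence and cross-checked on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
from Bio import SeqIO
from biotite.structure.io.pdb import PDBFile

from .geometry import AA_ONE, AA_THREE, Ensemble, Sequence


class FormatError(ValueError):
    """Raised on malformed or inconsistent ensemble files."""


def write_fasta(path, seq: Sequence, name: str = "peptide") -> None:
    Path(path).write_text(f">{name}\n{seq.letters}\n")


def read_fasta(path) -> Sequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    return Sequence(str(records[0].seq))


def write_ensemble(path, ens: Ensemble) -> None:
    """Write a standard-conformant multi-model Cα PDB."""
    seq = ens.sequence
    lines = []
    for m, conf in enumerate(ens.coords, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (letter, (x, y, z)) in enumerate(zip(seq.letters, conf), start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  {AA_THREE[letter]} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append(f"TER   {len(seq) + 1:5d}      {AA_THREE[seq.letters[-1]]} A{len(seq):4d}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble_table(path, ens: Ensemble) -> None:
    """Plain whitespace-delimited per-model coordinate table.

    Columns: model index (1-based), residue index (1-based), x, y, z (Å);
    one row per Cα, models in order.  A minimal interchange format for
    tools that do not speak PDB.
    """
    with open(path, "w") as fh:
        fh.write("# model residue x y z\n")
        for m, conf in enumerate(ens.coords, start=1):
            for i, (x, y, z) in enumerate(conf, start=1):
                fh.write(f"{m} {i} {x:.6f} {y:.6f} {z:.6f}\n")


def read_ensemble_table(path, fasta_path) -> tuple[Sequence, Ensemble]:
    """Read the coordinate-table format; the FASTA sidecar supplies the sequence."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 5:
        raise FormatError(f"{path}: expected 5 columns (model residue x y z)")
    seq = read_fasta(fasta_path)
    L = len(seq)
    models = np.unique(data[:, 0]).astype(int)
    counts = {int(m): int((data[:, 0] == m).sum()) for m in models}
    bad = [m for m, c in counts.items() if c != L]
    if bad:
        raise FormatError(
            f"{path}: model {bad[0]} has {counts[bad[0]]} rows, "
            f"sequence length is {L}")
    order = np.lexsort((data[:, 1], data[:, 0]))
    coords = data[order, 2:5].reshape(len(models), L, 3)
    return seq, Ensemble(seq, coords)


def _prescan_models(text: str) -> list[int]:
    """Atom counts per MODEL block, for precise error reporting."""
    counts, current, in_model = [], 0, False
    for line in text.splitlines():
        tag = line[:6].strip()
        if tag == "MODEL":
            in_model, current = True, 0
        elif tag == "ENDMDL":
            counts.append(current)
            in_model = False
        elif tag == "ATOM" and in_model:
            current += 1
    if not counts:
        # single-model file without MODEL records
        counts = [sum(1 for ln in text.splitlines() if ln[:6].strip() == "ATOM")]
    return counts


def read_ensemble(pdb_path, fasta_path=None) -> tuple[Sequence, Ensemble]:
    """Read a multi-model Cα PDB (+ FASTA sidecar) back into an Ensemble.

    The FASTA sequence is authoritative; PDB residue names are
    cross-checked against it.  Model order is preserved.
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(pdb_path)
    text = pdb_path.read_text()
    counts = _prescan_models(text)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise FormatError(
            f"inconsistent model lengths in {pdb_path}: model {bad + 1} has "
            f"{counts[bad]} atoms, model 1 has {counts[0]}")
    pdb = PDBFile.read(_io.StringIO(text))
    stack = pdb.get_structure()  # AtomArrayStack (models, atoms)
    ca = stack[:, stack.atom_name == "CA"]
    coords = np.asarray(ca.coord, dtype=np.float64)
    res_names = [AA_ONE.get(rn, "X") for rn in ca.res_name[:]]
    pdb_seq = "".join(res_names)
    if fasta_path is not None:
        seq = read_fasta(fasta_path)
    else:
        seq = Sequence(pdb_seq)
    if len(seq) != coords.shape[1]:
        raise FormatError(
            f"sequence length {len(seq)} does not match {coords.shape[1]} "
            f"Cα atoms in {pdb_path}")
    if fasta_path is not None and pdb_seq != seq.letters and "X" not in pdb_seq:
        raise FormatError(
            f"PDB residue names disagree with FASTA sidecar for {pdb_path}")
    return seq, Ensemble(seq, coords)
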