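"""Reading and writing of the standard structure and sequence formats.

PDB/mmCIF goes through gemmi; FASTA through Biopython.  Multi-chain
sequences are serialised as one FASTA record per chain with a shared
``name|chain`` prefix, and multi-model PDB files round-trip as Ensembles.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .structcore import BACKBONE_ATOMS, ChainedSequence, Ensemble, Structure

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


def _to_gemmi(structure: Structure, sequence: ChainedSequence) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "design"
    model = gemmi.Model("1")
    seq = sequence.concatenated
    for (start, stop), cid in zip(structure.chain_intervals, sequence.chain_ids):
        chain = gemmi.Chain(cid)
        for i in range(start, stop):
            res = gemmi.Residue()
            res.name = seq3(seq[i]).upper()
            res.seqid = gemmi.SeqId(i - start + 1, " ")
            for name, xyz in zip(BACKBONE_ATOMS, structure.backbone[i]):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            for k, xyz in enumerate(structure.sidechain.get(i, [])):
                atom = gemmi.Atom()
                atom.name = f"S{k + 1}"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(path: str | Path, structure: Structure, sequence: ChainedSequence) -> None:
    _to_gemmi(structure, sequence).write_pdb(str(path))


def write_mmcif(path: str | Path, structure: Structure, sequence: ChainedSequence) -> None:
    st = _to_gemmi(structure, sequence)
    st.make_mmcif_document().write_file(str(path))


def _model_to_structure(model: gemmi.Model) -> tuple[Structure, ChainedSequence]:
    chains, ids, backbones, sidechains = [], [], [], {}
    offset = 0
    intervals = []
    for chain in model:
        seq = []
        start = offset
        for res in chain:
            one = _THREE_TO_ONE.get(res.name)
            if one is None:
                continue
            bb = np.zeros((4, 3))
            found = 0
            extra = []
            for atom in res:
                if atom.name in BACKBONE_ATOMS:
                    bb[BACKBONE_ATOMS.index(atom.name)] = (
                        atom.pos.x, atom.pos.y, atom.pos.z,
                    )
                    found += 1
                elif atom.element.name != "H":
                    extra.append((atom.pos.x, atom.pos.y, atom.pos.z))
            if found < 4:
                continue
            seq.append(one)
            backbones.append(bb)
            if extra:
                sidechains[offset] = np.asarray(extra)
            offset += 1
        if seq:
            chains.append("".join(seq))
            ids.append(chain.name)
            intervals.append((start, offset))
    structure = Structure(np.stack(backbones), tuple(intervals), sidechains)
    return structure, ChainedSequence(tuple(chains), tuple(ids))


def read_structure(path: str | Path) -> tuple[Structure, ChainedSequence]:
    """Read a PDB or mmCIF file (first model)."""
    st = gemmi.read_structure(str(path))
    return _model_to_structure(st[0])


def read_ensemble(path: str | Path) -> tuple[Ensemble, ChainedSequence]:
    """Read a multi-model PDB file as an Ensemble of snapshots."""
    st = gemmi.read_structure(str(path))
    members, seq = [], None
    for model in st:
        structure, seq = _model_to_structure(model)
        members.append(structure)
    return Ensemble(members), seq


def write_fasta(path: str | Path, sequences: dict[str, ChainedSequence]) -> None:
    """Write chained sequences; one record per chain, ``name|chain`` ids."""
    records = []
    for name, cs in sequences.items():
        for chain, cid in zip(cs.chains, cs.chain_ids):
            records.append(SeqRecord(Seq(chain), id=f"{name}|{cid}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, ChainedSequence]:
    """Inverse of :func:`write_fasta`; plain records become single chains."""
    grouped: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, cid = rec.id.partition("|")
        grouped.setdefault(name, []).append((cid or "A", str(rec.seq)))
    return {
        name: ChainedSequence(
            tuple(s for _, s in chains), tuple(c for c, _ in chains)
        )
        for name, chains in grouped.items()
    }
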