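"""Plain-text readers/writers for the pipeline artifacts."""

from __future__ import annotations

import numpy as np

from .alignment import RawAlignment, ReferenceMapping

_FLOAT = "%.10g"


def write_fasta(msa: RawAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def write_mapping_tsv(mapping: ReferenceMapping, path) -> None:
    """TSV: alignment column (0-based), reference residue number, reference AA."""
    with open(path, "w") as fh:
        fh.write("column\tref_residue\tref_aa\n")
        for col in sorted(mapping.col_to_refres):
            r = mapping.col_to_refres[col]
            fh.write(f"{col}\t{r}\t{mapping.ref_seq[r - 1]}\n")


def write_matrix_tsv(matrix: np.ndarray, labels, path) -> None:
    """Square matrix with residue-number headers on both axes."""
    labels = list(labels)
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(map(str, labels)) + "\n")
        for lab, row in zip(labels, np.asarray(matrix)):
            fh.write(str(lab) + "\t" + "\t".join(_FLOAT % v for v in row) + "\n")


def write_edges_tsv(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("res_i\tres_j\tz\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{_FLOAT % w}\n")


def write_conservation_tsv(conservation, residues, path) -> None:
    from .coevolution import render_conservation

    with open(path, "w") as fh:
        fh.write("residue\tscore\trendered\n")
        for r, s in zip(residues, conservation):
            val = "NA" if np.isnan(s) else _FLOAT % s
            fh.write(f"{r}\t{val}\t{render_conservation(s)}\n")


def write_series_tsv(columns: dict[str, np.ndarray], path) -> None:
    """Aligned numeric columns (projections, VACF, weights, spectra...)."""
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    n = len(arrays[0])
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(_FLOAT % a[i] for a in arrays) + "\n")


def write_graphml(net, path) -> None:
    import networkx as nx

    G = net.graph.copy()
    for n in G.nodes:
        G.nodes[n]["score"] = float(net.node_scores.get(n, 0.0))
        if net.partition is not None:
            G.nodes[n]["community"] = int(net.partition[n])
    nx.write_graphml(G, path)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb_calpha(path, chain: str | None = None):
    """Reference sequence and Cα coordinates from a minimal PDB file.

    ATOM records only, first model, first altloc; returns
    (sequence, coords_nm (N, 3), residue_numbers). Unknown residues map to 'X'.
    """
    import warnings

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ref", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models found in {path}") from None
    seq, coords, resnums = [], [], []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.id[0] != " " or "CA" not in res:
                continue
            seq.append(_THREE_TO_ONE.get(res.get_resname().strip(), "X"))
            coords.append(res["CA"].get_coord() / 10.0)  # Angstrom -> nm
            resnums.append(res.id[1])
        if chain is None:
            break  # first chain only
    if not seq:
        raise ValueError(f"no Cα atoms found in {path}")
    return "".join(seq), np.asarray(coords, dtype=float), resnums
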