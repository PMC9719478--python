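"""Sequence, annotation and structure-file I/O.

FASTA goes through Biopython; GFF3 and PDB pseudo-atom files are written
directly (simple, column-defined formats).  Genomic coordinates are
1-based inclusive in all files, 0-based only inside Python code, with
the conversion at this boundary.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_gff3",
    "write_pdb_points",
    "write_logo_tsv",
]


def read_fasta(path) -> dict:
    """FASTA file as an ordered {id: sequence} dict; duplicate ids error."""
    out: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(records, path, width: int = 70) -> None:
    """Write {id: seq} or (id, seq) pairs; ids must be unique."""
    items = records.items() if hasattr(records, "items") else list(records)
    ids = [i for i, _ in items] if not hasattr(records, "items") else list(records)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate FASTA ids")
    seqs = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in (records.items() if hasattr(records, "items") else records)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_msa(path) -> list:
    """Alignment FASTA as a list of (id, row) pairs, length-checked."""
    rows = list(read_fasta(path).items())
    if len({len(s) for _, s in rows}) > 1:
        raise ValueError(f"{path}: alignment rows differ in length")
    return rows


def _gff_escape(text: str) -> str:
    return str(text).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(loci, path, source: str = "capsidkit") -> None:
    """Prophage loci as GFF3 mobile_genetic_element features with dif children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci, start=1):
            lid = f"prophage{i:03d}"
            attrs = [f"ID={lid}", f"Name={_gff_escape(lid)}"]
            if locus.length_flag:
                attrs.append(f"length_flag={locus.length_flag}")
            fh.write(
                "\t".join(
                    [
                        locus.genome_id,
                        source,
                        "mobile_genetic_element",
                        str(locus.start),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for tag, dif in (("dif_upstream", locus.dif_upstream), ("dif_downstream", locus.dif_downstream)):
                if dif is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            locus.genome_id,
                            source,
                            "recombination_feature",
                            str(dif.position),
                            str(dif.position + len(dif.sequence) - 1),
                            f"{dif.palindrome_score:.3f}",
                            "+",
                            ".",
                            f"ID={lid}.{tag};Parent={lid};Name={tag};sequence={dif.sequence}",
                        ]
                    )
                    + "\n"
                )


_CHAIN_BY_LABEL = {"PEN": "P", "HEX": "H", "MEM": "M"}


def write_pdb_points(model, path, occupancy_by_label: dict | None = None) -> int:
    """Point model as HETATM pseudo-atoms, one chain per capsomer kind.

    Occupancy can encode per-label metadata (e.g. trimer type) for
    downstream coloring.  Returns the number of atoms written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("REMARK   1 CAPSID PSEUDO-ATOM MODEL (ONE ATOM PER POINT)\n")
        for i, (pos, label) in enumerate(model.points, start=1):
            chain = _CHAIN_BY_LABEL.get(label[:3], "X")
            occ = (occupancy_by_label or {}).get(label, 1.0)
            x, y, z = np.asarray(pos, float)
            fh.write(
                f"HETATM{i % 100000:5d}  C   {label[:3]:>3s} {chain}{(i % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           C\n"
            )
            n += 1
        fh.write("END\n")
    return n


def write_logo_tsv(freq: np.ndarray, info: np.ndarray, path) -> None:
    """Position frequency matrix + information content as TSV."""
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tinformation_bits\n")
        for i, (row, bits) in enumerate(zip(freq, info), start=1):
            fh.write(
                f"{i}\t" + "\t".join(f"{v:.4f}" for v in row) + f"\t{bits:.4f}\n"
            )
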