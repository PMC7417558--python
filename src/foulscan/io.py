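"""Readers and writers for the pipeline's on-disk formats.

FASTQ/FASTA go through Biopython; tabular hit files use the 12-column
(primary) or 10-column (fallback) BLAST outfmt-6 layouts; abundance
matrices, checklists, assignments and distance matrices are plain CSV;
image stacks are PNG (depth 1) or multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nis import ChecklistEntry
from .stats import AbundanceMatrix, DistanceMatrix
from .synthetic import SimulatedRead
from .taxonomy import Assignment, BlastHit

PathLike = Union[str, Path]


def write_fastq(reads: Iterable[SimulatedRead], path: PathLike) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: PathLike) -> list:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SimulatedRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_hit_table(hits: Iterable[BlastHit], path: PathLike, dialect: str = "primary") -> None:
    if dialect not in ("primary", "fallback"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.qseqid, h.sseqid, str(h.length), f"{h.pident:.3f}", str(h.gaps),
                str(h.sstart), str(h.send), f"{h.qcovs:g}", f"{h.evalue:g}",
                f"{h.bitscore:g}",
            ]
            if dialect == "primary":
                fields += [h.staxids, h.stitle]
            fh.write("\t".join(fields) + "\n")


def write_abundance_csv(matrix: AbundanceMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path)


def read_abundance_csv(path: PathLike) -> AbundanceMatrix:
    return AbundanceMatrix.from_frame(pd.read_csv(path, index_col=0))


def write_checklist_csv(entries: Iterable[ChecklistEntry], path: PathLike) -> None:
    pd.DataFrame(
        [{"species": e.species, "source_tag": e.source_tag} for e in entries]
    ).to_csv(path, index=False)


def read_checklist_csv(path: PathLike) -> list:
    df = pd.read_csv(path)
    return [ChecklistEntry(row.species, row.source_tag) for row in df.itertuples()]


def write_assignments_csv(assignments: Iterable[Assignment], path: PathLike) -> None:
    rows = []
    for a in assignments:
        winner = a.evidence[0] if a.evidence else None
        rows.append(
            {
                "otu_id": a.otu_id,
                "lineage": ";".join(a.lineage),
                "species": a.species or "",
                "status": a.status,
                "source_db": a.source_db,
                "sseqid": getattr(winner, "sseqid", ""),
                "pident": getattr(winner, "pident", ""),
                "evalue": getattr(winner, "evalue", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignments_csv(path: PathLike) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples():
        lineage = tuple(x for x in str(row.lineage).split(";") if x)
        out.append(
            Assignment(
                otu_id=row.otu_id,
                lineage=lineage,
                species=row.species or None,
                status=row.status,
                source_db=row.source_db,
            )
        )
    return out


def write_distance_csv(d: DistanceMatrix, path: PathLike) -> None:
    pd.DataFrame(d.d, index=d.labels, columns=d.labels).to_csv(path)


def write_membership_tsv(result, path: PathLike) -> None:
    rows = []
    for cl in result.clusters:
        for mid, ident in zip(cl.member_ids, cl.member_identities):
            rows.append({"member_id": mid, "centroid_id": cl.centroid_id,
                         "identity": f"{ident:.4f}"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_stack(stack, path: PathLike) -> None:
    """PNG for a single slice, multi-page TIFF otherwise."""
    path = Path(path)
    pixels = stack.pixels
    if path.suffix.lower() == ".png":
        if pixels.shape[0] != 1:
            raise ValueError("PNG output requires a depth-1 stack")
        import imageio.v3 as iio

        iio.imwrite(path, pixels[0])
    else:
        import tifffile

        tifffile.imwrite(path, pixels, photometric="minisblack")


def read_stack(path: PathLike):
    from .imaging import PanelImageStack

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return PanelImageStack(pixels=pixels)
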