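"""File I/O: FASTA, newick, BED, GFF3, TSV.

Internal coordinates are 0-based half-open; BED output keeps that
convention, GFF3 output converts to 1-based inclusive. Only the TSV format
carries the full per-fragment record and round-trips exactly.
"""

from __future__ import annotations

import csv
from typing import Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import CalibratedTree
from .types import Fragment, FormatError, GenomeSequence, NumtAnnotation, ValidationError

_TSV_HEADER = [
    "numt_id",
    "species",
    "scaffold",
    "fragment",
    "nuc_start",
    "nuc_end",
    "mito_start",
    "mito_end",
    "strand",
    "identity",
]


def load_sequences(path, expected_topology: str = "linear") -> List[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records.

    Case (softmasking) is preserved verbatim. Raises FormatError on an
    empty file, duplicate IDs, or non-IUPAC residues.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeSequence(id=rec.id, residues=str(rec.seq), topology=expected_topology)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_sequences(seqs: Iterable[GenomeSequence], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs),
        str(path),
        "fasta",
    )


def load_calibrated_tree(path) -> CalibratedTree:
    """Read a calibrated newick tree; validates ultrametricity."""
    return CalibratedTree.from_file(path)


def _validate_against_scaffolds(numts, scaffold_lengths) -> None:
    for numt in numts:
        limit = scaffold_lengths.get(numt.scaffold)
        if limit is None:
            continue
        for f in numt.fragments:
            if f.nuc_start < 0 or f.nuc_end > limit:
                raise ValidationError(
                    f"{numt.numt_id}: fragment [{f.nuc_start},{f.nuc_end}) outside "
                    f"scaffold {numt.scaffold} of length {limit}"
                )


def write_numt_annotations(
    numts: List[NumtAnnotation],
    path,
    format: str = "TSV",
    scaffold_lengths: Optional[dict] = None,
) -> None:
    """Serialize numt annotations as BED, GFF3 or TSV.

    BED is 0-based half-open (one line per fragment); GFF3 is 1-based
    inclusive with a parent ``numt`` feature and ``numt_fragment``
    children; TSV is the lossless interchange format.
    """
    if scaffold_lengths:
        _validate_against_scaffolds(numts, scaffold_lengths)
    fmt = format.upper()
    with open(path, "w", newline="") as fh:
        if fmt == "TSV":
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_HEADER)
            for numt in numts:
                for i, f in enumerate(numt.fragments):
                    w.writerow(
                        [
                            numt.numt_id,
                            numt.species,
                            numt.scaffold,
                            i,
                            f.nuc_start,
                            f.nuc_end,
                            f.mito_start,
                            f.mito_end,
                            f.strand,
                            f"{f.identity:.6f}",
                        ]
                    )
        elif fmt == "BED":
            fh.write('track name="numts"\n')
            for numt in numts:
                for f in numt.fragments:
                    fh.write(
                        f"{numt.scaffold}\t{f.nuc_start}\t{f.nuc_end}\t"
                        f"{numt.numt_id}\t0\t{f.strand}\n"
                    )
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for numt in numts:
                s, e = numt.span
                fh.write(
                    f"{numt.scaffold}\tnumts\tnumt\t{s + 1}\t{e}\t.\t.\t.\t"
                    f"ID={numt.numt_id};species={numt.species}\n"
                )
                for i, f in enumerate(numt.fragments):
                    fh.write(
                        f"{numt.scaffold}\tnumts\tnumt_fragment\t{f.nuc_start + 1}\t"
                        f"{f.nuc_end}\t.\t{f.strand}\t.\t"
                        f"ID={numt.numt_id}.f{i};Parent={numt.numt_id};"
                        f"mito_start={f.mito_start};mito_end={f.mito_end};"
                        f"identity={f.identity:.6f}\n"
                    )
        else:
            raise ValueError(f"unknown format {format!r}")


def read_numt_annotations(path) -> List[NumtAnnotation]:
    """Read the TSV produced by :func:`write_numt_annotations` (lossless)."""
    by_id: dict = {}
    order: list = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TSV_HEADER:
            raise FormatError(f"unexpected numt TSV header in {path}")
        for row in reader:
            key = row["numt_id"]
            if key not in by_id:
                by_id[key] = (row["species"], row["scaffold"], [])
                order.append(key)
            by_id[key][2].append(
                Fragment(
                    nuc_start=int(row["nuc_start"]),
                    nuc_end=int(row["nuc_end"]),
                    mito_start=int(row["mito_start"]),
                    mito_end=int(row["mito_end"]),
                    strand=row["strand"],
                    identity=float(row["identity"]),
                )
            )
    return [
        NumtAnnotation(numt_id=k, species=by_id[k][0], scaffold=by_id[k][1], fragments=by_id[k][2])
        for k in order
    ]


_HITS_HEADER = [
    "query_id", "subject_id", "query_start", "query_end",
    "subject_start", "subject_end", "strand", "score", "bit_score", "e_value",
    "identity", "chain",
]


def write_hits_tsv(hits, path) -> None:
    """Linked hits as a flat HSP table (one row per member HSP)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HITS_HEADER)
        for chain_idx, hit in enumerate(hits):
            for h in hit.hsps:
                w.writerow(
                    [
                        hit.query_id, hit.subject_id, h.query_start, h.query_end,
                        h.subject_start, h.subject_end, h.strand, h.score,
                        f"{h.bit_score:.2f}", f"{h.e_value:.3e}",
                        f"{h.identity:.6f}", chain_idx,
                    ]
                )


def read_hits_tsv(path):
    """Import externally produced tabular hits as LinkedHit objects.

    Rows sharing a ``chain`` value (per query/subject pair) form one hit;
    this is the pluggable entry point for search results from other
    aligners.
    """
    from .types import Hsp, LinkedHit

    chains: dict = {}
    order: list = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _HITS_HEADER:
            raise FormatError(f"unexpected hits TSV header in {path}")
        for row in reader:
            key = (row["query_id"], row["subject_id"], row["chain"])
            if key not in chains:
                chains[key] = []
                order.append(key)
            chains[key].append(
                Hsp(
                    query_start=int(row["query_start"]),
                    query_end=int(row["query_end"]),
                    subject_start=int(row["subject_start"]),
                    subject_end=int(row["subject_end"]),
                    strand=row["strand"],
                    score=int(row["score"]),
                    bit_score=float(row["bit_score"]),
                    e_value=float(row["e_value"]),
                    identity=float(row["identity"]),
                )
            )
    return [
        LinkedHit(hsps=chains[k], query_id=k[0], subject_id=k[1]) for k in order
    ]


def write_alignment_fasta(taxa, columns, path) -> None:
    """Aligned FASTA from encoded rows (codes 0..4; negatives as gaps)."""
    import numpy as np

    lookup = np.array(list("ACGTN-"))
    with open(path, "w") as fh:
        for i, taxon in enumerate(taxa):
            row = columns[i].astype(int).copy()
            row[row < 0] = 5
            fh.write(f">{taxon}\n{''.join(lookup[row])}\n")


def bed_interval_to_gff3(start: int, end: int) -> tuple:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def gff3_interval_to_bed(start: int, end: int) -> tuple:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def write_bed(intervals, path, name_prefix: str = "feature") -> None:
    """Write (chrom, start, end[, name[, strand]]) tuples as BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else f"{name_prefix}{i}"
            strand = iv[4] if len(iv) > 4 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(path) -> list:
    """Read BED into (chrom, start, end, name, strand) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append((parts[0], int(parts[1]), int(parts[2]), name, strand))
    return out
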