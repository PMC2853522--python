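"""Reading and writing the external formats the pipeline touches.

FASTA/GenBank input and Clustal/aligned-FASTA alignments go through
Biopython; tabular products are written as TSV (with a coordinate-system
header comment) via pandas, and nested products as JSON.

Coordinates in every table are 0-based, half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ValidationError
from .model import (
    ArrayAlignment,
    ConversionTract,
    Domain,
    DomainMap,
    DuplicatePair,
    DVNGroup,
    RepeatAnnotationRow,
    SequenceRecord,
    Variant,
    VariantPartition,
    validate_dna,
)

COORD_COMMENT = "# coordinates: 0-based, half-open"

_SEQ_FORMATS = {"fasta": "fasta", "genbank": "genbank"}
_ALN_FORMATS = {"clustal": "clustal", "aligned_fasta": "fasta"}


def load_sequences(path, format: str = "fasta") -> list[SequenceRecord]:
    """Load DNA records from a FASTA or GenBank flat file, in file order.

    Sequences are uppercased and validated against the ``{A,C,G,T,N}``
    alphabet; an offending record is named in the error.  A GenBank file
    yields one :class:`SequenceRecord` per record, carrying the full
    record sequence.
    """
    if format not in _SEQ_FORMATS:
        raise ValidationError(f"unknown sequence format {format!r}")
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), _SEQ_FORMATS[format]):
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq), source=str(path))
        )
    if not records:
        raise EmptyInputError(f"{path}: no records parsed as {format}")
    return records


def load_alignment(path, format: str = "aligned_fasta") -> ArrayAlignment:
    """Load a Clustal or aligned-FASTA multiple alignment.

    Row order follows the file; gap characters (``-`` or ``.``) are
    normalised to ``-``.  The per-column consensus state is recomputed by
    majority with the fixed tie order A<C<G<T<-.
    """
    if format not in _ALN_FORMATS:
        raise ValidationError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), _ALN_FORMATS[format])
    except ValueError as exc:
        msg = str(exc)
        if "No records found" in msg or "Empty file" in msg:
            raise EmptyInputError(f"{path}: empty alignment") from exc
        raise ValidationError(f"{path}: {msg}") from exc
    if len(aln) == 0:
        raise EmptyInputError(f"{path}: empty alignment")
    rows = []
    ids = []
    width = aln.get_alignment_length()
    for rec in aln:
        s = str(rec.seq).upper().replace(".", "-")
        if len(s) != width:
            raise ValidationError(f"{path}: ragged row {rec.id}")
        bad = set(s) - set("ACGTN-")
        if bad:
            raise ValidationError(f"{path}: row {rec.id} has illegal states {sorted(bad)}")
        ids.append(rec.id)
        rows.append(list(s))
    matrix = np.array(rows, dtype="<U1")
    consensus = "".join(_majority_state(matrix[:, j]) for j in range(width))
    return ArrayAlignment(copy_ids=ids, matrix=matrix, consensus=consensus)


def _majority_state(column: np.ndarray) -> str:
    from .model import STATE_ORDER

    states, counts = np.unique(column, return_counts=True)
    best = counts.max()
    winners = {s for s, c in zip(states, counts) if c == best}
    for s in STATE_ORDER:
        if s in winners:
            return s
    return sorted(winners)[0]  # 'N'-only columns


def save_alignment(alignment: ArrayAlignment, path, format: str = "aligned_fasta") -> None:
    """Write the alignment matrix (consensus coordinates; insertions are not representable)."""
    if format not in _ALN_FORMATS:
        raise ValidationError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=cid, description="") for cid, row in alignment.rows()]
    )
    AlignIO.write(msa, str(path), _ALN_FORMATS[format])


def save_sequences(records: Sequence[SequenceRecord], path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular product serialisation


def annotation_frame(rows: Sequence[RepeatAnnotationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "array_id": r.array_id,
                "start": r.start,
                "end": r.end,
                "unit_kind": r.unit_kind,
                "unit_index": r.unit_index,
                "complete": int(r.complete),
            }
            for r in rows
        ],
        columns=["array_id", "start", "end", "unit_kind", "unit_index", "complete"],
    )


def variant_frame(partition: VariantPartition) -> pd.DataFrame:
    rows = []
    for g in partition.dvns:
        for cid in sorted(g.carriers):
            rows.append(
                {"copy_id": cid, "column": g.column, "alt_state": g.alt_state, "class": "dvn"}
            )
    for v in partition.sporadic:
        rows.append(
            {"copy_id": v.copy_id, "column": v.column, "alt_state": v.alt_state, "class": "sporadic"}
        )
    frame = pd.DataFrame(rows, columns=["copy_id", "column", "alt_state", "class"])
    return frame.sort_values(["column", "alt_state", "copy_id"], kind="stable").reset_index(
        drop=True
    )


def write_tsv(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def domain_map_to_dict(dmap: DomainMap) -> dict:
    return {
        "n_copies": dmap.n_copies,
        "domains": [
            {
                "first_copy": d.first_copy,
                "last_copy": d.last_copy,
                "defining_dvns": sorted(d.defining_dvns),
            }
            for d in dmap.domains
        ],
        "barriers": [list(b) for b in dmap.barriers],
        "unassigned": sorted(dmap.unassigned),
    }


def domain_map_from_dict(obj: dict) -> DomainMap:
    return DomainMap(
        domains=[
            Domain(d["first_copy"], d["last_copy"], frozenset(d["defining_dvns"]))
            for d in obj["domains"]
        ],
        barriers=[tuple(b) for b in obj["barriers"]],
        unassigned=list(obj["unassigned"]),
        n_copies=obj["n_copies"],
    )


def read_variant_partition(path) -> VariantPartition:
    """Rebuild a VariantPartition from the TSV written by :func:`write_report`."""
    frame = read_tsv(path)
    dvns: dict[tuple[int, str], set[str]] = {}
    sporadic = []
    for rec in frame.itertuples(index=False):
        if rec[3] == "dvn":
            dvns.setdefault((int(rec.column), rec.alt_state), set()).add(str(rec.copy_id))
        else:
            sporadic.append(Variant(str(rec.copy_id), int(rec.column), rec.alt_state))
    groups = [
        DVNGroup(col, state, frozenset(carriers))
        for (col, state), carriers in sorted(dvns.items())
    ]
    return VariantPartition(dvns=groups, sporadic=sporadic)


def read_annotation(path) -> list[RepeatAnnotationRow]:
    frame = read_tsv(path)
    return [
        RepeatAnnotationRow(
            array_id=str(r.array_id),
            start=int(r.start),
            end=int(r.end),
            unit_kind=str(r.unit_kind),
            unit_index=int(r.unit_index),
            complete=bool(r.complete),
        )
        for r in frame.itertuples(index=False)
    ]


def _tract_rows(tracts: Sequence[ConversionTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "copy_id": t.copy_id,
                "column_start": t.column_start,
                "column_end": t.column_end,
                "donor_domain": t.donor_domain,
                "n_dvns": t.n_dvns,
            }
            for t in tracts
        ],
        columns=["copy_id", "column_start", "column_end", "donor_domain", "n_dvns"],
    )


def _pair_rows(pairs: Sequence[DuplicatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "first_copy": p.first_copy,
                "second_copy": p.second_copy,
                "identity": p.identity,
                "n_private_dvns": p.n_private_dvns,
            }
            for p in pairs
        ],
        columns=["first_copy", "second_copy", "identity", "n_private_dvns"],
    )


def write_report(product, path, format: str = "tsv") -> None:
    """Serialise a pipeline product with deterministic field order.

    TSV for tabular products (variant partitions, annotations, tract and
    duplicate-pair lists, DataFrames), JSON for nested ones (domain maps,
    plain dicts).  JSON output is stable under re-serialisation (sorted
    keys, no timestamps).
    """
    path = Path(path)
    if format == "tsv":
        if isinstance(product, VariantPartition):
            frame = variant_frame(product)
        elif isinstance(product, pd.DataFrame):
            frame = product
        elif isinstance(product, (list, tuple)):
            if product and isinstance(product[0], RepeatAnnotationRow):
                frame = annotation_frame(product)
            elif product and isinstance(product[0], ConversionTract):
                frame = _tract_rows(product)
            elif product and isinstance(product[0], DuplicatePair):
                frame = _pair_rows(product)
            elif not product:
                frame = pd.DataFrame(columns=["copy_id", "column", "alt_state", "class"])
            else:
                raise ValidationError(f"cannot serialise list of {type(product[0]).__name__}")
        else:
            raise ValidationError(f"cannot serialise {type(product).__name__} as TSV")
        write_tsv(frame, path)
    elif format == "json":
        if isinstance(product, DomainMap):
            obj = domain_map_to_dict(product)
        elif isinstance(product, dict):
            obj = product
        else:
            raise ValidationError(f"cannot serialise {type(product).__name__} as JSON")
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
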