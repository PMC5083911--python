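"""Reading and writing the pipeline's plain-text formats.

Alignments travel as gapped FASTA plus a tab-separated metadata table
(columns ``copy_id``, ``population``, optional ``group``); events and
summaries are written as TSV.  All coordinates in reports are 1-based on
the ungapped ancestral sequence.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedCopy,
    AlignmentError,
    AlignmentSet,
    MetadataError,
    MutationEvent,
    OrfAnnotation,
)

PathLike = Union[str, Path]

EVENT_COLUMNS = [
    "interval",
    "event_kind",
    "length",
    "anc_alleles",
    "der_alleles",
    "region",
    "pattern",
    "ts_tv",
    "codon_position",
    "effect",
    "frame_effect",
    "n_carriers",
    "copy_ids",
]


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Read the copy metadata TSV (copy_id, population[, group])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"copy_id", "population"}
    if not required.issubset(df.columns):
        raise MetadataError(
            f"metadata must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if df["copy_id"].duplicated().any():
        dups = df.loc[df["copy_id"].duplicated(), "copy_id"].tolist()
        raise MetadataError(f"duplicate copy_id rows in metadata: {dups}")
    return df


def write_metadata(aln: AlignmentSet, path: PathLike) -> None:
    rows = [
        {"copy_id": c.copy_id, "population": c.population, "group": c.group or ""}
        for c in aln
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_aligned_fasta(
    path: PathLike,
    metadata_path: Optional[PathLike] = None,
    reference_id: Optional[str] = None,
) -> AlignmentSet:
    """Read a gapped FASTA alignment, attaching population/group labels.

    Every FASTA record id must appear in the metadata table (when given);
    sequences are uppercased on read and must be equal-length over
    ``{A,C,G,T,N,-}`` ('U' is rejected).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    meta = {}
    if metadata_path is not None:
        df = read_metadata(metadata_path)
        meta = {
            r.copy_id: (r.population, r.group if "group" in df.columns and r.group else None)
            for r in df.itertuples()
        }
        unknown = [r.id for r in records if r.id not in meta]
        if unknown:
            raise MetadataError(f"records missing from metadata: {unknown}")
    copies = []
    for rec in records:
        pop, grp = meta.get(rec.id, ("", None))
        copies.append(
            AlignedCopy(copy_id=rec.id, residues=str(rec.seq), population=pop, group=grp)
        )
    return AlignmentSet(copies, reference_id=reference_id)


def write_aligned_fasta(aln: AlignmentSet, path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.residues), id=c.copy_id, description="") for c in aln
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def events_to_frame(events: Sequence[MutationEvent]) -> pd.DataFrame:
    """Render events as a table using the ``start_end`` interval dialect."""
    ordered = sorted(
        events,
        key=lambda e: (
            e.interval_start,
            e.interval_end,
            e.event_kind,
            e.der_alleles,
            e.anc_alleles,
            e.copy_ids,
        ),
    )
    rows = []
    for e in ordered:
        rows.append(
            {
                "interval": e.interval_label,
                "event_kind": e.event_kind,
                "length": e.length,
                "anc_alleles": e.anc_alleles,
                "der_alleles": e.der_alleles,
                "region": e.region or "",
                "pattern": e.pattern or "",
                "ts_tv": e.ts_tv or "",
                "codon_position": "" if e.codon_position is None else e.codon_position,
                "effect": e.effect or "",
                "frame_effect": e.frame_effect or "",
                "n_carriers": len(e.copy_ids),
                "copy_ids": ",".join(e.copy_ids),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_table(events: Sequence[MutationEvent], path: PathLike) -> None:
    """Write the events TSV; an empty event list yields a header-only file."""
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_table(path: PathLike) -> list[MutationEvent]:
    """Re-parse an events TSV back into :class:`MutationEvent` objects."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples():
        start, end = (int(x) for x in r.interval.split("_"))
        out.append(
            MutationEvent(
                event_kind=r.event_kind,
                anc_alleles=r.anc_alleles,
                der_alleles=r.der_alleles,
                interval_start=start,
                interval_end=end,
                copy_ids=tuple(x for x in r.copy_ids.split(",") if x),
                region=r.region or None,
                pattern=r.pattern or None,
                ts_tv=r.ts_tv or None,
                codon_position=int(r.codon_position) if r.codon_position else None,
                effect=r.effect or None,
                frame_effect=r.frame_effect or None,
            )
        )
    return out


def read_orf_annotation(path: PathLike) -> list[OrfAnnotation]:
    """Read ORF annotations from TSV (name, start, end) or YAML."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(path.read_text())
        items = data["orfs"] if isinstance(data, dict) else data
        return [OrfAnnotation(d["name"], int(d["start"]), int(d["end"])) for d in items]
    df = pd.read_csv(path, sep="\t")
    return [
        OrfAnnotation(str(d["name"]), int(d["start"]), int(d["end"]))
        for d in df.to_dict("records")
    ]


def write_orf_annotation(orfs: Sequence[OrfAnnotation], path: PathLike) -> None:
    pd.DataFrame(
        [{"name": o.name, "start": o.start, "end": o.end} for o in orfs]
    ).to_csv(path, sep="\t", index=False)


def read_plain_sequence(path: PathLike) -> str:
    """Read a single sequence from FASTA or bare text (for the GC check)."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        rec = next(SeqIO.parse(_io.StringIO(text), "fasta"))
        return str(rec.seq).upper()
    return "".join(text.split()).upper()


def fetch_genbank_fasta(accession: str, path: PathLike, email: str = "user@example.org") -> str:
    """Download one nucleotide accession as FASTA via NCBI E-utilities.

    Requires network access; used only for the optional GC-composition check
    against deposited reference elements (e.g. JX294476, KJ191261).
    """
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nuccore", id=accession, rettype="fasta", retmode="text") as h:
        text = h.read()
    Path(path).write_text(text)
    rec = next(SeqIO.parse(_io.StringIO(text), "fasta"))
    return str(rec.seq).upper()
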