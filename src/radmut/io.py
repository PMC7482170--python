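"""File formats: FASTA, VCF, the sv_tsv dialect and the event table.

All coordinate-convention conversion lives here. Internally every
variant uses 1-based inclusive minimal coordinates (see
:mod:`radmut.variants`); the VCF anchor-base convention is translated at
read/write time. The ``sv_tsv`` dialect is a simple tab-separated stand-
in for structural-variant caller output with columns::

    sample_id  chrom  start  end  type{DEL,INS,INV,TRA}  inserted_seq  AF

DEL rows describe the deleted segment [start, end]; INS rows insert
``inserted_seq`` between ``start`` and ``start + 1``; INV/TRA carry
breakpoint coordinates.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import Category, MutationEvent
from .genome import ReferenceGenome
from .microhomology import compute_microhomology
from .variants import CandidateCall, VariantClass, trim_alleles

EVENT_TABLE_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "category",
    "zygosity",
    "length",
    "members",
    "microhomology",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (uppercased)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty FASTA file")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header '>'")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return ReferenceGenome(sequences)


def write_fasta(ref: ReferenceGenome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in ref.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# candidate calls


def _calls_from_vcf_record(
    rec, sample_id: str, af_field: str, path: str
) -> list[CandidateCall]:
    alts = rec.alts or ()
    afs = rec.info.get(af_field)
    if afs is None and rec.samples:
        first = rec.samples[0]
        afs = first.get(af_field) if af_field in first else None
    if afs is None:
        raise FormatError(
            f"{path}: record {rec.chrom}:{rec.pos} lacks AF field {af_field!r}"
        )
    if not isinstance(afs, (tuple, list)):
        afs = (afs,) * len(alts)
    calls: list[CandidateCall] = []
    for alt, af in zip(alts, afs):
        pos, ref_a, alt_a = trim_alleles(rec.pos, rec.ref, str(alt))
        if not ref_a and not alt_a:
            continue  # ref-identical ALT
        if not ref_a:
            calls.append(
                CandidateCall(
                    sample_id,
                    rec.chrom,
                    pos,
                    "",
                    alt_a,
                    VariantClass.INSERTION,
                    float(af),
                    source="vcf",
                )
            )
        elif not alt_a:
            calls.append(
                CandidateCall(
                    sample_id,
                    rec.chrom,
                    pos,
                    ref_a,
                    "",
                    VariantClass.DELETION,
                    float(af),
                    source="vcf",
                )
            )
        elif len(ref_a) == len(alt_a):
            # decompose multi-base substitutions into per-base SBS calls;
            # the merge step reassembles nearby changes into one event
            for i, (r, a) in enumerate(zip(ref_a, alt_a)):
                if r != a:
                    calls.append(
                        CandidateCall(
                            sample_id,
                            rec.chrom,
                            pos + i,
                            r,
                            a,
                            VariantClass.SUBSTITUTION,
                            float(af),
                            source="vcf",
                        )
                    )
        else:
            # length-changing replacement: deletion plus insertion at the
            # same spot; they cluster into one complex event downstream
            calls.append(
                CandidateCall(
                    sample_id,
                    rec.chrom,
                    pos,
                    ref_a,
                    "",
                    VariantClass.DELETION,
                    float(af),
                    source="vcf",
                )
            )
            calls.append(
                CandidateCall(
                    sample_id,
                    rec.chrom,
                    pos - 1,
                    "",
                    alt_a,
                    VariantClass.INSERTION,
                    float(af),
                    source="vcf",
                )
            )
    return calls


_SV_TYPE_MAP = {
    "DEL": VariantClass.DELETION,
    "INS": VariantClass.INSERTION,
    "INV": VariantClass.INVERSION,
    "TRA": VariantClass.TRANSLOCATION,
}

SV_TSV_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "inserted_seq", "AF"]


def read_candidate_calls(
    path: str | os.PathLike,
    dialect: str,
    sample_id: str | None = None,
    af_field: str = "AF",
    ref: ReferenceGenome | None = None,
) -> list[CandidateCall]:
    """Read caller output into :class:`CandidateCall` records.

    Parameters
    ----------
    dialect
        ``"vcf"`` (substitutions and small indels, AF from the INFO or
        FORMAT field named ``af_field``) or ``"sv_tsv"``.
    sample_id
        Required for VCF unless the file has exactly one sample column.
    ref
        Reference genome; required for sv_tsv DEL rows (to recover the
        deleted sequence).
    """
    path = str(path)
    if dialect == "vcf":
        calls: list[CandidateCall] = []
        with pysam.VariantFile(path) as vcf:
            if sample_id is None:
                samples = list(vcf.header.samples)
                if len(samples) == 1:
                    sample_id = samples[0]
                else:
                    raise ValueError(
                        "sample_id required for VCF without a single sample column"
                    )
            for rec in vcf:
                calls.extend(_calls_from_vcf_record(rec, sample_id, af_field, path))
        return calls

    if dialect == "sv_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(SV_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: sv_tsv missing columns {sorted(missing)}")
        calls = []
        for i, row in df.iterrows():
            vtype = row["type"].upper()
            if vtype not in _SV_TYPE_MAP:
                raise FormatError(f"{path}: row {i + 2}: unknown type {row['type']!r}")
            vclass = _SV_TYPE_MAP[vtype]
            start, end = int(row["start"]), int(row["end"])
            af = float(row["AF"]) if row["AF"] != "" else 1.0
            chrom = row["chrom"]
            if vclass is VariantClass.DELETION:
                if ref is None:
                    raise ValueError("sv_tsv DEL rows require a reference genome")
                calls.append(
                    CandidateCall(
                        row["sample_id"], chrom, start,
                        ref.fetch(chrom, start, end), "", vclass, af, source="sv_tsv",
                    )
                )
            elif vclass is VariantClass.INSERTION:
                calls.append(
                    CandidateCall(
                        row["sample_id"], chrom, start, "", row["inserted_seq"],
                        vclass, af, source="sv_tsv",
                    )
                )
            else:
                calls.append(
                    CandidateCall(
                        row["sample_id"], chrom, start, "", "", vclass, af,
                        source="sv_tsv", end=end,
                    )
                )
        return calls

    raise ValueError(f"unknown dialect {dialect!r}")


def write_sv_tsv(calls: list[CandidateCall], path: str | os.PathLike) -> None:
    rows = []
    for c in calls:
        if c.variant_class is VariantClass.DELETION:
            start, end, ins = c.pos, c.pos + len(c.ref_allele) - 1, ""
        elif c.variant_class is VariantClass.INSERTION:
            start, end, ins = c.pos, c.pos, c.alt_allele
        else:
            start, end, ins = c.pos, c.end if c.end is not None else c.pos, ""
        vtype = {
            VariantClass.DELETION: "DEL",
            VariantClass.INSERTION: "INS",
            VariantClass.INVERSION: "INV",
            VariantClass.TRANSLOCATION: "TRA",
        }[c.variant_class]
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "start": start,
                "end": end,
                "type": vtype,
                "inserted_seq": ins,
                "AF": round(c.allele_frequency, 6),
            }
        )
    pd.DataFrame(rows, columns=SV_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _vcf_header(ref: ReferenceGenome, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in ref.sequences.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("AF", "A", "Float", "Allele frequency (mutant read fraction)")
    header.add_sample(sample_id)
    return header


def write_vcf(
    calls: list[CandidateCall],
    ref: ReferenceGenome,
    path: str | os.PathLike,
    sample_id: str | None = None,
) -> None:
    """Write substitution/indel calls as VCF, restoring the anchor base."""
    small = [c for c in calls if not c.is_sv]
    if sample_id is None:
        ids = {c.sample_id for c in small}
        sample_id = ids.pop() if len(ids) == 1 else "sample"
    header = _vcf_header(ref, sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(small, key=lambda x: (x.chrom, x.pos)):
            if c.variant_class is VariantClass.SUBSTITUTION:
                pos, vref, valt = c.pos, c.ref_allele, c.alt_allele
            elif c.variant_class is VariantClass.DELETION:
                if c.pos > 1:
                    anchor = ref.base(c.chrom, c.pos - 1)
                    pos, vref, valt = c.pos - 1, anchor + c.ref_allele, anchor
                else:  # deletion at chromosome start: anchor on the right
                    anchor = ref.base(c.chrom, c.pos + len(c.ref_allele))
                    pos, vref, valt = 1, c.ref_allele + anchor, anchor
            else:  # insertion between pos and pos+1
                if c.pos >= 1:
                    anchor = ref.base(c.chrom, c.pos)
                    pos, vref, valt = c.pos, anchor, anchor + c.alt_allele
                else:
                    anchor = ref.base(c.chrom, 1)
                    pos, vref, valt = 1, anchor, c.alt_allele + anchor
            rec = out.new_record(
                contig=c.chrom,
                start=pos - 1,  # pysam is 0-based here
                alleles=(vref, valt),
            )
            rec.info["AF"] = c.allele_frequency
            out.write(rec)


# ---------------------------------------------------------------------------
# event table


def events_to_frame(
    events: list[MutationEvent], ref: ReferenceGenome | None = None
) -> pd.DataFrame:
    """Tab-ready event table, sorted by (sample, chrom, start).

    The microhomology column is filled for simple Del >= 2 bp events when
    a reference genome is supplied.
    """
    rows = []
    for e in events:
        mh = ""
        if ref is not None and e.category is Category.DEL_GE2:
            val = compute_microhomology(ref, e.chrom, e.start, e.end)
            mh = "" if val is None else val
        rows.append(
            {
                "sample": e.sample_id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "category": e.category.value if e.category else "",
                "zygosity": e.zygosity or "",
                "length": e.length,
                "members": e.describe_members(),
                "microhomology": mh,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)
    return df.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )


def write_event_table(
    events: list[MutationEvent],
    path: str | os.PathLike,
    ref: ReferenceGenome | None = None,
) -> None:
    events_to_frame(events, ref).to_csv(path, sep="\t", index=False)


def read_event_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "sample": str,
            "chrom": str,
            "start": int,
            "end": int,
            "category": str,
            "zygosity": str,
            "length": int,
            "members": str,
            "microhomology": str,
        },
        keep_default_na=False,
    )
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: event table missing columns {sorted(missing)}")
    return df
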