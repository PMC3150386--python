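"""Readers and writers for the pipeline's tabular formats.

Formats (all plain text, tab-separated unless noted):

* caller call tables — header ``sample_id chrom start end copy_number
  [confidence]``; the ``caller_a`` dialect carries the confidence column
  (an LBF-like score), ``caller_b`` does not.
* pedigree — PED-like, whitespace-delimited, no header:
  ``id father mother sex population`` with ``0`` for a missing parent.
* panel — two columns with header: ``sample_id population``.
* annotation tracks — BED3/BED4; BED's 0-based half-open coordinates are
  converted to the internal 1-based inclusive convention on read and back
  on write, so internal length equals BED ``end - start``.
* SNP map — two columns with header: ``chrom pos``.
* consensus events / CNVR tables — documented TSVs used to chain the CLI
  stages.
* Structure export — the external clustering tool's two-line-per-individual
  presence/absence dialect.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    AUTOSOMES,
    SEX_CHROM_LABELS,
    AnnotationTrack,
    CnvCall,
    Cnvr,
    ConsensusEvent,
    Individual,
    Panel,
    Pedigree,
    SnpMap,
    chrom_sort_key,
    is_autosome,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

CALLER_A_COLUMNS = ("sample_id", "chrom", "start", "end", "copy_number", "confidence")
CALLER_B_COLUMNS = ("sample_id", "chrom", "start", "end", "copy_number")


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_caller_calls(path, dialect: str) -> list[CnvCall]:
    """Read one caller's call table.

    Rows on sex chromosomes are dropped (their count is logged); any other
    non-autosomal chromosome label raises.  A row with ``end < start``
    raises naming the offending line.
    """
    if dialect == "caller_a":
        required, caller = CALLER_A_COLUMNS, "A"
    elif dialect == "caller_b":
        required, caller = CALLER_B_COLUMNS, "B"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    calls: list[CnvCall] = []
    n_sex = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header line
        chrom = normalize_chrom(row.chrom)
        if chrom in SEX_CHROM_LABELS:
            n_sex += 1
            continue
        if not is_autosome(chrom):
            raise FormatError(f"{path}:{line_no}: unrecognised chromosome {row.chrom!r}")
        start, end = int(row.start), int(row.end)
        if end < start:
            raise FormatError(f"{path}:{line_no}: end < start ({start} > {end})")
        conf = float(row.confidence) if caller == "A" else None
        calls.append(
            CnvCall(
                sample_id=str(row.sample_id),
                chrom=chrom,
                start=start,
                end=end,
                copy_number=int(row.copy_number),
                caller=caller,
                confidence=conf,
            )
        )
    if n_sex:
        logger.info("%s: dropped %d sex-chromosome rows", path, n_sex)
    return calls


def write_caller_calls(calls: Sequence[CnvCall], path, dialect: str) -> None:
    if dialect == "caller_a":
        cols = list(CALLER_A_COLUMNS)
    elif dialect == "caller_b":
        cols = list(CALLER_B_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for c in calls:
        rec = {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "copy_number": c.copy_number,
        }
        if dialect == "caller_a":
            rec["confidence"] = c.confidence
        rows.append(rec)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    individuals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(f"{path}:{line_no}: expected 5 columns, got {len(fields)}")
            iid, father, mother, sex, population = fields[:5]
            individuals.append(
                Individual(
                    id=iid,
                    father=None if father in ("0", "NA", ".") else father,
                    mother=None if mother in ("0", "NA", ".") else mother,
                    sex=sex,
                    population=population,
                )
            )
    return Pedigree(individuals)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [ind.id, ind.father or "0", ind.mother or "0", ind.sex, ind.population or "NA"]
                )
                + "\n"
            )


def read_panel(path) -> Panel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    return Panel(dict(zip(df["sample_id"], df["population"])))


def write_panel(panel: Panel, path) -> None:
    df = pd.DataFrame(
        sorted(panel.membership.items()), columns=["sample_id", "population"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_track(path, name: Optional[str] = None) -> AnnotationTrack:
    """Read a BED3/BED4 file into an :class:`AnnotationTrack`.

    BED is 0-based half-open; internally intervals are 1-based inclusive,
    so ``(chrom, s, e)`` becomes ``(chrom, s + 1, e)``.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: expected >=3 BED columns")
            chrom = normalize_chrom(fields[0])
            bed_start, bed_end = int(fields[1]), int(fields[2])
            if bed_end <= bed_start:
                raise FormatError(f"{path}:{line_no}: empty or negative BED interval")
            label = fields[3] if len(fields) > 3 else None
            records.append((chrom, bed_start + 1, bed_end, label))
    import os

    track_name = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return AnnotationTrack(track_name, records)


def write_track(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            for start, end, label in track.intervals[chrom]:
                fields = [chrom, str(start - 1), str(end)]
                if label is not None:
                    fields.append(label)
                fh.write("\t".join(fields) + "\n")


def read_snp_map(path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    positions = {
        str(chrom): grp["pos"].astype(int).tolist() for chrom, grp in df.groupby("chrom")
    }
    return SnpMap(positions)


def write_snp_map(snp_map: SnpMap, path) -> None:
    rows = [
        {"chrom": chrom, "pos": int(p)}
        for chrom in snp_map.chromosomes()
        for p in snp_map.positions[chrom]
    ]
    pd.DataFrame(rows, columns=["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[ConsensusEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    for col in ("sample_id", "chrom", "start", "end", "cnv_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        ConsensusEvent(
            sample_id=str(r.sample_id),
            chrom=normalize_chrom(r.chrom),
            start=int(r.start),
            end=int(r.end),
            cnv_type=str(r.cnv_type),
        )
        for r in df.itertuples(index=False)
    ]


def write_events(events: Sequence[ConsensusEvent], path) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "cnv_type": e.cnv_type,
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "cnv_type"]
    ).to_csv(path, sep="\t", index=False)


def write_events_bed(events: Sequence[ConsensusEvent], path) -> None:
    """Export events as BED4 with the CNV type in the name column."""
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (chrom_sort_key(e.chrom), e.start, e.end)):
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.sample_id}:{e.cnv_type}\n")


def read_cnvrs(path) -> list[Cnvr]:
    """Read a CNVR summary table.

    Member events are not serialised; reconstructed regions carry their
    span, type class and carrier set, which is what the downstream sharing
    and kinship operations need.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cnvr_id": str})
    for col in ("cnvr_id", "chrom", "start", "end", "type_class", "carriers"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for r in df.itertuples(index=False):
        carriers = frozenset(str(r.carriers).split(",")) if str(r.carriers) else frozenset()
        out.append(
            Cnvr(
                cnvr_id=str(r.cnvr_id),
                chrom=normalize_chrom(r.chrom),
                start=int(r.start),
                end=int(r.end),
                members=(),
                type_class=str(r.type_class),
                carriers=carriers,
            )
        )
    return out


def write_cnvrs(cnvrs: Sequence[Cnvr], path) -> None:
    rows = [
        {
            "cnvr_id": c.cnvr_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "type_class": c.type_class,
            "n_carriers": c.carrier_count,
            "carriers": ",".join(sorted(c.carriers)),
        }
        for c in cnvrs
    ]
    pd.DataFrame(
        rows,
        columns=["cnvr_id", "chrom", "start", "end", "type_class", "n_carriers", "carriers"],
    ).to_csv(path, sep="\t", index=False)


def write_cnvrs_bed(cnvrs: Sequence[Cnvr], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(cnvrs, key=lambda c: (chrom_sort_key(c.chrom), c.start, c.end)):
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cnvr_id}:{c.type_class}\n")


def write_structure_matrix(cnvrs: Sequence[Cnvr], panel: Panel, path) -> tuple[int, int]:
    """Export carrier presence/absence genotypes in the external clustering
    tool's two-line-per-individual dialect.

    One column per CNVR (sorted by ``cnvr_id``), entries 1 (carrier) / 0
    (non-carrier), each individual written as two identical haplotype rows
    prefixed by the sample id and a numeric population index.  Returns
    ``(n_individuals, n_loci)``; the file holds ``2 * n_individuals`` rows.
    """
    if not cnvrs:
        raise ValueError("no CNVRs to export")
    ordered = sorted(cnvrs, key=lambda c: c.cnvr_id)
    for c in ordered:
        for s in c.carriers:
            if s not in panel:
                raise ValueError(f"CNVR {c.cnvr_id}: carrier {s!r} absent from panel")
    samples = panel.samples()
    pop_index = {pop: i + 1 for i, pop in enumerate(panel.populations)}
    with open(path, "w") as fh:
        for s in samples:
            genotypes = " ".join("1" if s in c.carriers else "0" for c in ordered)
            row = f"{s} {pop_index[panel.population_of(s)]} {genotypes}\n"
            fh.write(row)
            fh.write(row)
    return len(samples), len(ordered)
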