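"""Reading observed variants, parsing variant-query strings, and writing the
per-variant flat file, the per-residue score table and the regions BED.

Observed-variant inputs
-----------------------
* VCF 4.x (plain text, read through :mod:`pysam`): multi-allelic rows are
  split into one record per alternate allele, then filtered to
  single-nucleotide changes carrying a PASS filter flag.
* TSV dialect: tab-separated columns ``chrom  pos  ref  alt  filter
  population`` (the last two optional), ``#``-prefixed comment lines.  In CDS
  mode the first column holds the transcript id and ``pos`` is a 1-based CDS
  position.

Query strings come in three forms: ``chrom-pos-ref-alt``, ``chrom-pos`` and
``transcript:protein_pos`` (``-`` also accepted as the final separator).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, TextIO

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .cds_model import BASES, GenomicMap, SiteVariant, Transcript
from .core import MTRProfile
from .errors import MtrkitError, QueryParseError
from .stats import IntolerantRegion

PASS_VALUES = frozenset({"PASS"})


@dataclass(slots=True)
class ObservedVariantRecord:
    """One observed single-nucleotide variant row after splitting."""

    chromosome: Optional[str]
    position: int  # genomic or CDS 1-based, per declared mode
    ref: str
    alt: str
    filter_status: str = "PASS"
    population: Optional[str] = None
    source: str = ""


@dataclass
class ReadResult:
    records: list[ObservedVariantRecord]
    dropped: Counter  # reason -> count
    n_input_rows: int  # post-split allele rows seen


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES


def _passes(filter_status: str, missing_is_pass: bool) -> bool:
    if filter_status in PASS_VALUES:
        return True
    return missing_is_pass and filter_status in (".", "")


def read_observed(
    path: str | Path,
    fmt: str = "auto",
    *,
    require_pass: bool = True,
    missing_filter_passes: bool = False,
    population: Optional[str] = None,
) -> ReadResult:
    """Read and filter observed variants.

    Only single-nucleotide records with a passing FILTER are retained (a
    missing filter, ``.``, fails unless ``missing_filter_passes``).  Every
    post-split allele row is accounted for: ``len(records)`` plus the dropped
    counts equals ``n_input_rows``.  ``population`` sets a per-file label for
    formats without a population column.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        rows = _iter_vcf(path)
    elif fmt == "tsv":
        rows = _iter_tsv(path)
    else:
        raise MtrkitError(f"unknown variant format {fmt!r}")

    records: list[ObservedVariantRecord] = []
    dropped: Counter = Counter()
    n = 0
    for rec in rows:
        n += 1
        if rec.population is None:
            rec.population = population
        if not _is_snv(rec.ref, rec.alt):
            dropped["not_snv"] += 1
            continue
        if require_pass and not _passes(rec.filter_status, missing_filter_passes):
            dropped["filter_fail"] += 1
            continue
        records.append(rec)
    return ReadResult(records=records, dropped=dropped, n_input_rows=n)


def _iter_vcf(path: Path):
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            status = ";".join(filters) if filters else "."
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                yield ObservedVariantRecord(
                    chromosome=str(rec.chrom),
                    position=int(rec.pos),
                    ref=ref,
                    alt=str(alt).upper(),
                    filter_status=status,
                    source=str(path),
                )


def _iter_tsv(path: Path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                yield ObservedVariantRecord(
                    chromosome=None, position=-1, ref="?", alt="?",
                    filter_status=".", source=str(path),
                )
                continue
            chrom, pos, ref, alt = parts[0], parts[1], parts[2].upper(), parts[3]
            filt = parts[4] if len(parts) > 4 and parts[4] else "."
            pop = parts[5] if len(parts) > 5 and parts[5] else None
            try:
                ipos = int(pos)
            except ValueError:
                yield ObservedVariantRecord(
                    chromosome=chrom, position=-1, ref="?", alt="?",
                    filter_status=filt, source=str(path),
                )
                continue
            for a in alt.split(","):
                yield ObservedVariantRecord(
                    chromosome=chrom,
                    position=ipos,
                    ref=ref,
                    alt=a.upper(),
                    filter_status=filt,
                    population=pop,
                    source=str(path),
                )


def write_observed_tsv(
    out: str | Path | TextIO,
    variants: Sequence[SiteVariant],
) -> None:
    """Write annotated variants in the CDS-mode TSV dialect (readable back by
    :func:`read_observed` with ``fmt='tsv'``): transcript id in the chrom
    column, 1-based CDS position, PASS filter, optional population label.
    """
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        fh.write("#chrom\tpos\tref\talt\tfilter\tpopulation\n")
        for v in variants:
            fh.write(
                f"{v.transcript_id}\t{v.cds_pos}\t{v.ref}\t{v.alt}\tPASS\t"
                f"{v.population or ''}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# variant queries

class QueryForm(str, Enum):
    CHROM_POS_REF_ALT = "chrom_pos_ref_alt"
    CHROM_POS = "chrom_pos"
    TRANSCRIPT_PROTEIN_POS = "transcript_protein_pos"


@dataclass(frozen=True)
class VariantQuery:
    form: QueryForm
    chromosome: Optional[str] = None
    position: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    transcript_id: Optional[str] = None
    protein_pos: Optional[int] = None


_CHROM_RE = re.compile(r"^(CHR)?([0-9]{1,2}|X|Y|MT?)$", re.IGNORECASE)


def _norm_chrom(tok: str) -> str:
    m = _CHROM_RE.match(tok)
    assert m is not None
    return m.group(2).upper()


def parse_variant_query(q: str) -> VariantQuery:
    """Parse one query line into one of the three supported forms.

    Case-insensitive; fields split on ``-``, ``:`` or whitespace.  The
    four-field form takes precedence over chrom-pos when four fields are
    present.
    """
    line = q.strip()
    if not line:
        raise QueryParseError("empty query line")
    tokens = [t for t in re.split(r"[-:\s]+", line) if t]
    if len(tokens) == 4:
        chrom, pos, ref, alt = tokens
        if (
            _CHROM_RE.match(chrom)
            and pos.isdigit()
            and _is_snv(ref.upper(), alt.upper())
        ):
            return VariantQuery(
                form=QueryForm.CHROM_POS_REF_ALT,
                chromosome=_norm_chrom(chrom),
                position=int(pos),
                ref=ref.upper(),
                alt=alt.upper(),
            )
        raise QueryParseError(f"cannot parse 4-field query {q!r}")
    if len(tokens) == 2:
        first, second = tokens
        if not second.isdigit():
            raise QueryParseError(f"cannot parse query {q!r}")
        if _CHROM_RE.match(first):
            return VariantQuery(
                form=QueryForm.CHROM_POS,
                chromosome=_norm_chrom(first),
                position=int(second),
            )
        return VariantQuery(
            form=QueryForm.TRANSCRIPT_PROTEIN_POS,
            transcript_id=first.upper(),
            protein_pos=int(second),
        )
    raise QueryParseError(f"cannot parse query {q!r}")


# ---------------------------------------------------------------------------
# CDS FASTA

def read_cds_fasta(
    path: str | Path,
    genomic_maps: Optional[dict[str, GenomicMap]] = None,
) -> list[Transcript]:
    """Read in-frame coding sequences from FASTA.

    Record ids follow ``transcript_id`` or ``transcript_id|gene_symbol``.
    A genomic map, when supplied for a transcript id, is attached.
    """
    transcripts: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid, _, gene = rec.id.partition("|")
        transcripts.append(
            Transcript(
                transcript_id=tid,
                cds_seq=str(rec.seq),
                gene_symbol=gene or None,
                genomic_map=(genomic_maps or {}).get(tid),
            )
        )
    return transcripts


def write_cds_fasta(out: str | Path | TextIO, transcripts: Sequence[Transcript]) -> None:
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        for t in transcripts:
            header = t.transcript_id
            if t.gene_symbol:
                header += f"|{t.gene_symbol}"
            fh.write(f">{header}\n")
            for k in range(0, len(t.cds_seq), 60):
                fh.write(t.cds_seq[k : k + 60] + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# genomic map files

def read_genomic_maps(path: str | Path) -> dict[str, list[tuple[int, str, int, str]]]:
    """Read a genomic-map TSV: ``transcript_id  cds_pos  chrom  genomic_pos
    [strand]`` (strand defaults to ``+``).  Returns rows grouped by
    transcript id; build a :class:`~mtrkit.cds_model.GenomicMap` from them.
    """
    out: dict[str, list[tuple[int, str, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MtrkitError(f"genomic-map row needs >= 4 columns: {line!r}")
            tid, cds_pos, chrom, gpos = parts[:4]
            strand = parts[4] if len(parts) > 4 else "+"
            out.setdefault(tid, []).append((int(cds_pos), chrom, int(gpos), strand))
    for rows in out.values():
        rows.sort()
    return out


# ---------------------------------------------------------------------------
# output tables

NA = "NA"


def _fmt(x: float | int | None) -> str:
    if x is None:
        return NA
    if isinstance(x, float) and math.isnan(x):
        return NA
    if isinstance(x, float):
        return repr(x)  # full precision, exact round-trip
    return str(x)


FLAT_COLUMNS = (
    "transcript_id", "chromosome", "position", "ref", "alt",
    "codon_index", "consequence", "mtr", "raw_p", "fdr_q",
)


def write_flat_file(
    out: str | Path | TextIO,
    entries: Sequence[tuple[Transcript, MTRProfile, Sequence[SiteVariant]]],
) -> None:
    """Per-variant flat file: one row per (possible) variant with the score,
    raw p and q of its codon.  Genomic chromosome/position are used when the
    transcript has a genomic map; otherwise the chromosome field is NA and
    the position is the CDS position.
    """
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        fh.write("\t".join(FLAT_COLUMNS) + "\n")
        for t, prof, variants in entries:
            if prof is None:
                raise MtrkitError(f"no profile computed for {t.transcript_id}")
            for v in variants:
                chrom: Optional[str] = None
                pos = v.cds_pos
                ref, alt = v.ref, v.alt
                if t.genomic_map is not None:
                    chrom, pos, _ = t.genomic_map.to_genomic(v.cds_pos)
                k = v.codon_index - 1
                in_range = 0 <= k < prof.n_codons
                fh.write(
                    "\t".join(
                        (
                            t.transcript_id,
                            chrom if chrom is not None else NA,
                            str(pos),
                            ref,
                            alt,
                            str(v.codon_index),
                            str(v.consequence.value),
                            _fmt(float(prof.mtr[k])) if in_range else NA,
                            _fmt(float(prof.raw_p[k])) if in_range else NA,
                            _fmt(float(prof.fdr_q[k])) if in_range else NA,
                        )
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()


MTR_TABLE_COLUMNS = (
    "transcript_id", "codon_index", "mtr",
    "obs_mis", "obs_syn", "exp_mis", "exp_syn",
    "raw_p", "fdr_q", "significant",
)


def write_mtr_table(
    out: str | Path | TextIO,
    profiles: MTRProfile | Sequence[MTRProfile],
) -> None:
    """Per-residue score table: one row per codon of each profile."""
    if isinstance(profiles, MTRProfile):
        profiles = [profiles]
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        fh.write("\t".join(MTR_TABLE_COLUMNS) + "\n")
        for prof in profiles:
            for k in range(prof.n_codons):
                fh.write(
                    "\t".join(
                        (
                            prof.transcript_id,
                            str(k + 1),
                            _fmt(float(prof.mtr[k])),
                            str(int(prof.mis_obs[k])),
                            str(int(prof.syn_obs[k])),
                            str(int(prof.mis_exp[k])),
                            str(int(prof.syn_exp[k])),
                            _fmt(float(prof.raw_p[k])),
                            _fmt(float(prof.fdr_q[k])),
                            "1" if bool(prof.significant[k]) else "0",
                        )
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()


def read_mtr_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_mtr_table`."""
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[NA],
        dtype={"transcript_id": str},
    )


def read_flat_file(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_flat_file`."""
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[NA],
        dtype={"transcript_id": str, "chromosome": str},
    )


def profiles_from_table(df: pd.DataFrame) -> list[MTRProfile]:
    """Rebuild profiles from a score table (round-trip of write_mtr_table)."""
    out: list[MTRProfile] = []
    for tid, sub in df.groupby("transcript_id", sort=False):
        sub = sub.sort_values("codon_index")
        L = len(sub)
        out.append(
            MTRProfile(
                transcript_id=str(tid),
                window_size=0,  # not serialized
                n_codons=L,
                mis_obs=sub["obs_mis"].to_numpy(np.int64),
                syn_obs=sub["obs_syn"].to_numpy(np.int64),
                mis_exp=sub["exp_mis"].to_numpy(np.int64),
                syn_exp=sub["exp_syn"].to_numpy(np.int64),
                mtr=sub["mtr"].to_numpy(float),
                raw_p=sub["raw_p"].to_numpy(float),
                fdr_q=sub["fdr_q"].to_numpy(float),
                significant=sub["significant"].to_numpy(bool),
            )
        )
    return out


def write_regions_bed(
    out: str | Path | TextIO,
    regions: Sequence[IntolerantRegion],
    transcripts: Optional[dict[str, Transcript]] = None,
) -> None:
    """BED (0-based, half-open) of called regions.

    Protein-coordinate space by default (``transcript_id  start-1  end``);
    genomic space when the region's transcript has a genomic map (span of the
    mapped CDS positions of the region's codons).  Adjacent regions are never
    merged.
    """
    close = False
    if isinstance(out, (str, Path)):
        fh = open(out, "w")
        close = True
    else:
        fh = out
    try:
        for r in regions:
            t = transcripts.get(r.transcript_id) if transcripts else None
            if t is not None and t.genomic_map is not None:
                cds_lo = 3 * (r.start_codon - 1) + 1
                cds_hi = 3 * r.end_codon
                gpos = [t.genomic_map.to_genomic(p) for p in (cds_lo, cds_hi)]
                chroms = {g[0] for g in gpos}
                if len(chroms) == 1:
                    lo = min(g[1] for g in gpos)
                    hi = max(g[1] for g in gpos)
                    fh.write(f"{gpos[0][0]}\t{lo - 1}\t{hi}\t{r.transcript_id}\n")
                    continue
            fh.write(f"{r.transcript_id}\t{r.start_codon - 1}\t{r.end_codon}\n")
    finally:
        if close:
            fh.close()
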