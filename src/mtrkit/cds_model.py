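"""Transcript model and single-nucleotide consequence annotation.

A :class:`Transcript` holds one in-frame coding sequence.  Every possible
single-nucleotide change within the amino-acid-coding part of the CDS can be
enumerated and classified (missense / synonymous / stop-gained) against the
standard nuclear genetic code; observed variant records are annotated through
the same classifier so both routes agree by construction.

Coordinates are 1-based and inclusive throughout: CDS position ``1`` is the
first base of the first codon, codon index ``i`` covers CDS positions
``3i-2 .. 3i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .errors import InvalidSequenceError, InvalidVariantError

BASES = ("A", "C", "G", "T")
STOP_SYMBOL = "*"

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with "*" for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
CODON_TO_AA.update({c: STOP_SYMBOL for c in _standard.stop_codons})

STOP_CODONS = frozenset(_standard.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate a codon to its one-letter amino acid, or ``*`` for a stop.

    Raises
    ------
    InvalidSequenceError
        If ``codon`` is not exactly three characters over ``ACGT``.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise InvalidSequenceError(f"not a valid codon: {codon!r}")
    return CODON_TO_AA[codon]


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    EXCLUDED_OTHER = "excluded_other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: consequences that enter observed/expected tallies
COUNTED_CONSEQUENCES = frozenset({Consequence.MISSENSE, Consequence.SYNONYMOUS})


class Origin(str, Enum):
    POSSIBLE = "possible"
    OBSERVED = "observed"


@dataclass(frozen=True)
class GenomicMap:
    """Strand-resolved per-base map from CDS positions to genomic positions.

    ``positions[k]`` is the (chromosome, genomic position, strand) of CDS
    position ``k + 1``.  The map must cover every CDS base and be injective.
    Ref/alt alleles elsewhere in the package are always in coding-strand
    space; minus-strand genomic records are reverse-complemented when mapped.
    """

    positions: tuple[tuple[str, int, str], ...]
    _reverse: dict[tuple[str, int], int] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        rev: dict[tuple[str, int], int] = {}
        for idx, (chrom, gpos, strand) in enumerate(self.positions, start=1):
            if strand not in ("+", "-"):
                raise InvalidSequenceError(f"bad strand {strand!r} in genomic map")
            key = (str(chrom), int(gpos))
            if key in rev:
                raise InvalidSequenceError(f"genomic map is not injective at {key}")
            rev[key] = idx
        object.__setattr__(self, "_reverse", rev)

    def __len__(self) -> int:
        return len(self.positions)

    def to_genomic(self, cds_pos: int) -> tuple[str, int, str]:
        return self.positions[cds_pos - 1]

    def to_cds(self, chrom: str, gpos: int) -> Optional[int]:
        """1-based CDS position for a genomic coordinate, or None if unmapped."""
        return self._reverse.get((str(chrom), int(gpos)))


@dataclass(frozen=True)
class Transcript:
    """One in-frame CDS.

    ``n_codons`` counts amino-acid positions: a terminal stop codon, when
    present, is excluded.  The sequence must be non-ambiguous (ACGT only),
    a multiple of three long and at least two codons.
    """

    transcript_id: str
    cds_seq: str
    gene_symbol: Optional[str] = None
    genomic_map: Optional[GenomicMap] = None

    def __post_init__(self) -> None:
        seq = self.cds_seq.upper()
        object.__setattr__(self, "cds_seq", seq)
        if len(seq) < 6 or len(seq) % 3 != 0:
            raise InvalidSequenceError(
                f"{self.transcript_id}: CDS length {len(seq)} is not a multiple "
                "of 3 >= 6"
            )
        bad = set(seq) - set(BASES)
        if bad:
            raise InvalidSequenceError(
                f"{self.transcript_id}: ambiguous/invalid bases {sorted(bad)}"
            )
        if self.n_codons < 1:
            raise InvalidSequenceError(f"{self.transcript_id}: no coding codons")
        if self.genomic_map is not None and len(self.genomic_map) != len(seq):
            raise InvalidSequenceError(
                f"{self.transcript_id}: genomic map covers {len(self.genomic_map)} "
                f"of {len(seq)} CDS positions"
            )

    @property
    def total_codons(self) -> int:
        return len(self.cds_seq) // 3

    @property
    def has_terminal_stop(self) -> bool:
        return self.cds_seq[-3:] in STOP_CODONS

    @property
    def n_codons(self) -> int:
        """Amino-acid positions (terminal stop excluded)."""
        return self.total_codons - (1 if self.has_terminal_stop else 0)

    def codon(self, codon_index: int) -> str:
        """Codon at 1-based index ``codon_index``."""
        if not 1 <= codon_index <= self.total_codons:
            raise InvalidVariantError(
                f"codon index {codon_index} outside 1..{self.total_codons}"
            )
        return self.cds_seq[3 * (codon_index - 1) : 3 * codon_index]

    def base(self, cds_pos: int) -> str:
        if not 1 <= cds_pos <= len(self.cds_seq):
            raise InvalidVariantError(
                f"CDS position {cds_pos} outside 1..{len(self.cds_seq)}"
            )
        return self.cds_seq[cds_pos - 1]


@dataclass(slots=True)
class SiteVariant:
    """A single-nucleotide change on a transcript, possible or observed."""

    transcript_id: str
    cds_pos: int
    codon_index: int
    ref: str
    alt: str
    consequence: Consequence
    origin: Origin
    population: Optional[str] = None

    def key(self) -> tuple[int, str]:
        """Identity of the change itself; used for distinct-variant counting."""
        return (self.cds_pos, self.alt)


def classify_consequence(codon: str, pos_in_codon: int, alt: str) -> Consequence:
    """Classify the protein consequence of substituting ``alt`` into ``codon``.

    ``pos_in_codon`` is 1..3.  The reference codon must encode an amino acid;
    classifying a change inside a stop codon is the caller's business (see
    :func:`enumerate_possible_variants`).
    """
    aa_ref = translate_codon(codon)
    if aa_ref == STOP_SYMBOL:
        raise InvalidVariantError(f"reference codon {codon} is a stop codon")
    if pos_in_codon not in (1, 2, 3):
        raise InvalidVariantError(f"pos_in_codon {pos_in_codon} not in 1..3")
    alt = alt.upper()
    if alt not in BASES:
        raise InvalidVariantError(f"invalid alternate base {alt!r}")
    if alt == codon[pos_in_codon - 1]:
        raise InvalidVariantError("alternate equals the reference base")
    mutated = codon[: pos_in_codon - 1] + alt + codon[pos_in_codon:]
    aa_alt = CODON_TO_AA[mutated]
    if aa_alt == STOP_SYMBOL:
        return Consequence.STOP_GAINED
    if aa_alt == aa_ref:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


def _classify_at(t: Transcript, cds_pos: int, alt: str) -> Consequence:
    """Consequence of cds_pos->alt on ``t``, covering stop-codon contexts."""
    codon_index = (cds_pos + 2) // 3
    if codon_index > t.n_codons:
        # change inside the terminal stop codon
        return Consequence.EXCLUDED_OTHER
    codon = t.codon(codon_index)
    if codon in STOP_CODONS:
        # internal stop (allowed in partial/synthetic transcripts): the binary
        # missense/synonymous labelling does not apply, so keep it out of tallies
        return Consequence.EXCLUDED_OTHER
    pos_in_codon = cds_pos - 3 * (codon_index - 1)
    return classify_consequence(codon, pos_in_codon, alt)


def enumerate_possible_variants(t: Transcript) -> list[SiteVariant]:
    """All 3 alternate alleles at every CDS position of the first ``n_codons``
    codons, classified; ordered by (cds_pos, alt).  Returns 9 * n_codons
    variants.
    """
    out: list[SiteVariant] = []
    for cds_pos in range(1, 3 * t.n_codons + 1):
        ref = t.cds_seq[cds_pos - 1]
        codon_index = (cds_pos + 2) // 3
        for alt in BASES:
            if alt == ref:
                continue
            out.append(
                SiteVariant(
                    transcript_id=t.transcript_id,
                    cds_pos=cds_pos,
                    codon_index=codon_index,
                    ref=ref,
                    alt=alt,
                    consequence=_classify_at(t, cds_pos, alt),
                    origin=Origin.POSSIBLE,
                )
            )
    return out


@dataclass
class AnnotationResult:
    """Outcome of matching observed records against one transcript."""

    accepted: list[SiteVariant]
    rejected: list[tuple[object, str]]  # (record, reason)


def annotate_observed(
    t: Transcript,
    observed: Iterable,
    mode: str = "cds",
) -> AnnotationResult:
    """Annotate raw observed records on ``t``.

    Records are duck-typed: they need ``position``, ``ref``, ``alt`` and
    optionally ``chromosome`` and ``population`` attributes.  In ``cds`` mode
    ``position`` is a 1-based CDS position; in ``genomic`` mode it is resolved
    through the transcript's genomic map (minus-strand alleles are
    reverse-complemented into coding-strand space).

    Records are never a crash: mismatches are returned with a reason among
    ``unmappable``, ``out_of_cds``, ``ref_mismatch``, ``not_snv``.
    """
    if mode not in ("cds", "genomic"):
        raise InvalidVariantError(f"unknown annotation mode {mode!r}")
    accepted: list[SiteVariant] = []
    rejected: list[tuple[object, str]] = []
    for rec in observed:
        ref = str(rec.ref).upper()
        alt = str(rec.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            rejected.append((rec, "not_snv"))
            continue
        if mode == "genomic":
            if t.genomic_map is None:
                rejected.append((rec, "unmappable"))
                continue
            cds_pos = t.genomic_map.to_cds(getattr(rec, "chromosome", ""), rec.position)
            if cds_pos is None:
                rejected.append((rec, "unmappable"))
                continue
            _, _, strand = t.genomic_map.to_genomic(cds_pos)
            if strand == "-":
                ref = reverse_complement(ref)
                alt = reverse_complement(alt)
        else:
            cds_pos = int(rec.position)
            if not 1 <= cds_pos <= len(t.cds_seq):
                rejected.append((rec, "out_of_cds"))
                continue
        if ref == alt:
            rejected.append((rec, "ref_equals_alt"))
            continue
        if t.cds_seq[cds_pos - 1] != ref:
            rejected.append((rec, "ref_mismatch"))
            continue
        accepted.append(
            SiteVariant(
                transcript_id=t.transcript_id,
                cds_pos=cds_pos,
                codon_index=(cds_pos + 2) // 3,
                ref=ref,
                alt=alt,
                consequence=_classify_at(t, cds_pos, alt),
                origin=Origin.OBSERVED,
                population=getattr(rec, "population", None),
            )
        )
    return AnnotationResult(accepted=accepted, rejected=rejected)
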