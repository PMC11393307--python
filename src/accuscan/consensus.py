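"""Concatemer consensus calling: repeat confirmation, deduplication, pileup.

Rolling-circle amplification of a circularized cfDNA fragment produces a
concatemer carrying tandem copies of the same template. After alignment the
copies of one read pair land on (nearly) the same reference span, so they can
be compared base by base: a call supported by every high-quality copy and by
at least two copies is "repeat confirmed", while a change seen in only a
subset of copies is treated as a PCR/sequencing error and discarded.

Molecules are then deduplicated by their fragment endpoints (chrom, start,
end) and aggregated into a molecule-level pileup in which both variant and
wild-type calls require repeat confirmation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_MIN_QUAL = 24  # base calls must have Phred quality strictly above this
DEFAULT_MIN_SUPPORT = 2
DEFAULT_RECIPROCAL_OVERLAP = 0.9


class CallStatus(Enum):
    CONFIRMED_REF = "CONFIRMED_REF"
    CONFIRMED_ALT = "CONFIRMED_ALT"
    UNCONFIRMED = "UNCONFIRMED"


@dataclass
class AlignedCopy:
    """One tandem copy of a template, as aligned to the reference.

    ``bases`` maps reference position -> (called base, Phred quality).
    """

    read_pair_id: str
    mate: int
    copy_index: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    bases: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if self.mate not in (1, 2):
            raise ValueError("mate must be 1 or 2")

    @classmethod
    def from_contiguous(
        cls,
        read_pair_id: str,
        mate: int,
        copy_index: int,
        chrom: str,
        ref_start: int,
        seq: str,
        quals: Iterable[int],
        strand: str = "+",
    ) -> "AlignedCopy":
        """Build a copy from a gapless (all-match) alignment."""
        bases = {
            ref_start + i: (b.upper(), q) for i, (b, q) in enumerate(zip(seq, quals))
        }
        return cls(
            read_pair_id=read_pair_id,
            mate=mate,
            copy_index=copy_index,
            chrom=chrom,
            ref_start=ref_start,
            ref_end=ref_start + len(seq),
            strand=strand,
            bases=bases,
        )

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.ref_start, self.ref_end)


@dataclass
class MoleculeCall:
    """Repeat-confirmed consensus for one template molecule.

    ``calls`` maps reference position -> (status, alt_base or None, support).
    """

    chrom: str
    start: int
    end: int
    n_copies: int
    calls: dict[int, tuple[CallStatus, str | None, int]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PileupSite:
    chrom: str
    pos: int
    ref_base: str
    context: str
    depth: int = 0
    alt_counts: dict[str, int] = field(default_factory=dict)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


def segment_tandem_copies(
    copies: Iterable[AlignedCopy],
    min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> list[list[AlignedCopy]]:
    """Group the aligned copies of one read pair into template molecules.

    Copies whose reference spans reciprocally overlap by at least
    ``min_reciprocal_overlap`` (on the same chromosome) are treated as tandem
    repeats of the same template. Copies on different chromosomes are never
    merged. Returns the groups sorted by (chrom, start); order of the input
    does not affect the result.
    """
    copies = sorted(copies, key=lambda c: (c.chrom, c.ref_start, c.ref_end, c.mate, c.copy_index))
    ids = {c.read_pair_id for c in copies}
    if len(ids) > 1:
        raise ValueError(f"copies from multiple read pairs: {sorted(ids)}")
    groups: list[list[AlignedCopy]] = []
    for copy in copies:
        placed = False
        for group in groups:
            rep = group[0]
            if rep.chrom != copy.chrom:
                continue
            if (
                _reciprocal_overlap(
                    (rep.ref_start, rep.ref_end), (copy.ref_start, copy.ref_end)
                )
                >= min_reciprocal_overlap
            ):
                group.append(copy)
                placed = True
                break
        if not placed:
            groups.append([copy])
    return groups


def repeat_confirm(
    copies: list[AlignedCopy],
    pos: int,
    ref_base: str,
    min_qual: int = DEFAULT_MIN_QUAL,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[CallStatus, str | None, int]:
    """Repeat-confirm the base call at one position across tandem copies.

    Base calls with quality <= ``min_qual`` are ignored. When at least
    ``min_support`` remaining copies cover the position and all agree, the
    call is confirmed (as reference or as the shared alternate base); any
    disagreement, or fewer usable copies, yields UNCONFIRMED.
    """
    calls = []
    for copy in copies:
        entry = copy.bases.get(pos)
        if entry is None:
            continue
        base, qual = entry
        if qual > min_qual:
            calls.append(base)
    if len(calls) < min_support:
        return (CallStatus.UNCONFIRMED, None, len(calls))
    first = calls[0]
    if any(b != first for b in calls[1:]):
        return (CallStatus.UNCONFIRMED, None, 0)
    if first == ref_base.upper():
        return (CallStatus.CONFIRMED_REF, None, len(calls))
    return (CallStatus.CONFIRMED_ALT, first, len(calls))


def _modal_span(copies: list[AlignedCopy]) -> tuple[int, int]:
    spans = Counter((c.ref_start, c.ref_end) for c in copies)
    best = max(spans.values())
    return min(s for s, n in spans.items() if n == best)


def call_molecule(
    copies: list[AlignedCopy],
    reference: Mapping[str, str],
    min_qual: int = DEFAULT_MIN_QUAL,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> MoleculeCall:
    """Apply repeat confirmation over the template span of one copy group.

    The template endpoints are taken as the modal (start, end) among copies;
    ties break to the smallest span.
    """
    if not copies:
        raise ValueError("empty copy group")
    chrom = copies[0].chrom
    start, end = _modal_span(copies)
    seq = reference[chrom]
    calls: dict[int, tuple[CallStatus, str | None, int]] = {}
    for pos in range(start, end):
        calls[pos] = repeat_confirm(
            copies, pos, seq[pos], min_qual=min_qual, min_support=min_support
        )
    return MoleculeCall(
        chrom=chrom, start=start, end=end, n_copies=len(copies), calls=calls
    )


def dedup_molecules(molecules: Iterable[MoleculeCall]) -> list[MoleculeCall]:
    """Collapse molecules sharing fragment endpoints (chrom, start, end).

    The collapsed molecule keeps the union of confirmed calls; positions where
    two duplicates disagree on a confirmed call are demoted to UNCONFIRMED.
    """
    by_key: dict[tuple[str, int, int], MoleculeCall] = {}
    for mol in sorted(molecules, key=lambda m: (m.key, -m.n_copies)):
        kept = by_key.get(mol.key)
        if kept is None:
            by_key[mol.key] = MoleculeCall(
                chrom=mol.chrom,
                start=mol.start,
                end=mol.end,
                n_copies=mol.n_copies,
                calls=dict(mol.calls),
            )
            continue
        kept.n_copies = max(kept.n_copies, mol.n_copies)
        # union of confirmed calls; two *conflicting* confirmed calls demote
        for pos, call in mol.calls.items():
            old = kept.calls.get(pos)
            if old is None or old[0] is CallStatus.UNCONFIRMED:
                kept.calls[pos] = call
            elif call[0] is CallStatus.UNCONFIRMED:
                pass  # keep the confirmed call
            elif (old[0], old[1]) != (call[0], call[1]):
                kept.calls[pos] = (CallStatus.UNCONFIRMED, None, 0)
    return [by_key[k] for k in sorted(by_key)]


def build_pileup(
    unique_molecules: Iterable[MoleculeCall],
    reference: Mapping[str, str],
    regions: Iterable[tuple[str, int, int]] | None = None,
) -> dict[tuple[str, int], PileupSite]:
    """Molecule-level pileup: confirmed calls only contribute to depth.

    Depth at a site is the number of unique molecules with a CONFIRMED
    (reference or alternate) call there; UNCONFIRMED calls contribute nothing.
    """
    wanted = None
    if regions is not None:
        wanted = list(regions)
    sites: dict[tuple[str, int], PileupSite] = {}
    for mol in unique_molecules:
        seq = reference[mol.chrom]
        for pos, (status, alt, _support) in mol.calls.items():
            if status is CallStatus.UNCONFIRMED:
                continue
            if wanted is not None and not any(
                c == mol.chrom and s <= pos < e for c, s, e in wanted
            ):
                continue
            key = (mol.chrom, pos)
            site = sites.get(key)
            if site is None:
                ctx = _context(seq, pos)
                site = PileupSite(
                    chrom=mol.chrom, pos=pos, ref_base=seq[pos], context=ctx
                )
                sites[key] = site
            site.depth += 1
            if status is CallStatus.CONFIRMED_ALT:
                site.alt_counts[alt] = site.alt_counts.get(alt, 0) + 1
    return dict(sorted(sites.items()))


def _context(seq: str, pos: int) -> str:
    left = seq[pos - 1] if pos > 0 else "N"
    right = seq[pos + 1] if pos + 1 < len(seq) else "N"
    return f"{left}{seq[pos]}{right}"


def pileup_to_frame(sites: Mapping[tuple[str, int], PileupSite] | Iterable[PileupSite]) -> pd.DataFrame:
    """Tabulate a pileup: one row per site, extra rows per observed alt allele.

    Columns: chrom, pos, ref, context, depth, alt ('.' when none), alt_count.
    """
    if isinstance(sites, Mapping):
        sites = sites.values()
    rows = []
    for s in sites:
        if not s.alt_counts:
            rows.append((s.chrom, s.pos, s.ref_base, s.context, s.depth, ".", 0))
        else:
            for alt, n in sorted(s.alt_counts.items()):
                rows.append((s.chrom, s.pos, s.ref_base, s.context, s.depth, alt, n))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "context", "depth", "alt", "alt_count"]
    )


def copies_from_sam(
    path: str, min_mapq: int = 0
) -> Iterator[tuple[str, list[AlignedCopy]]]:
    """Stream (read_pair_id, copies) from a SAM/BAM with split-alignment copies.

    Every mapped record (primary or supplementary) of a read pair is one
    candidate tandem copy. Assumes the file is grouped by read name, as
    emitted by the synthetic fixture generator or by name-sorting.
    """
    import pysam

    current: str | None = None
    copies: list[AlignedCopy] = []
    counter = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.query_name != current:
                if current is not None and copies:
                    yield current, copies
                current = rec.query_name
                copies = []
                counter = 0
            mate = 2 if rec.is_read2 else 1
            quals = rec.query_qualities
            copies.append(
                AlignedCopy.from_contiguous(
                    read_pair_id=rec.query_name,
                    mate=mate,
                    copy_index=counter,
                    chrom=rec.reference_name,
                    ref_start=rec.reference_start,
                    seq=rec.query_sequence,
                    quals=list(quals) if quals is not None else [0] * len(rec.query_sequence),
                    strand="-" if rec.is_reverse else "+",
                )
            )
            counter += 1
    if current is not None and copies:
        yield current, copies


def consensus_pipeline(
    sam_path: str,
    reference: Mapping[str, str],
    min_qual: int = DEFAULT_MIN_QUAL,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_copies: int = 1,
    strict_single_mate: bool = False,
    min_reciprocal_overlap: float = DEFAULT_RECIPROCAL_OVERLAP,
) -> tuple[list[MoleculeCall], dict[tuple[str, int], PileupSite]]:
    """SAM -> grouped copies -> consensus molecules -> dedup -> pileup.

    With ``strict_single_mate`` a molecule is only confirmable when at least
    two of its copies come from the same mate; this emulates longer single-end
    reads, where a short template read twice (once per mate) cannot be
    mistaken for two independent tandem repeats.
    """
    molecules = []
    for _rpid, copies in copies_from_sam(sam_path):
        for group in segment_tandem_copies(copies, min_reciprocal_overlap):
            if len(group) < min_copies:
                continue
            if strict_single_mate:
                mates = Counter(c.mate for c in group)
                if max(mates.values()) < 2:
                    continue
            molecules.append(
                call_molecule(group, reference, min_qual=min_qual, min_support=min_support)
            )
    unique = dedup_molecules(molecules)
    pileup = build_pileup(unique, reference)
    return unique, pileup


def molecules_to_frame(molecules: Iterable[MoleculeCall]) -> pd.DataFrame:
    rows = [(m.chrom, m.start, m.end, m.n_copies) for m in molecules]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_copies"])
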