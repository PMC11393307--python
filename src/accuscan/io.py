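"""Readers/writers shared by the CLI: variants (VCF/TSV), pileups, provenance.

Coordinate conventions: VCF positions are 1-based and converted to the
package's internal 0-based convention on read (and back on write); TSV
tables written by this package carry 0-based positions throughout.
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Mapping

import pandas as pd

from accuscan.markers import Marker, MarkerSet


def read_variants(path: str, reference: Mapping[str, str] | None = None) -> MarkerSet:
    """Read a variant list from VCF (1-based) or TSV (0-based, package format).

    Multi-allelic VCF records are split into one marker per alt; alleles are
    upper-cased. Only single-base substitutions are kept. When a reference is
    given, trinucleotide contexts (hence CpG flags) are filled in.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path, reference)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns {sorted(missing)}")
    entries = []
    for i, r in enumerate(df.itertuples(index=False)):
        ctx = getattr(r, "context", None)
        if ctx in (None, ".", "") or (isinstance(ctx, float) and pd.isna(ctx)):
            ctx = None
        ref, alt = str(r.ref).upper(), str(r.alt).upper()
        if len(ref) != 1 or len(alt) != 1:
            continue
        pos = int(r.pos)
        if ctx is None and reference is not None:
            ctx = _context(reference, str(r.chrom), pos)
        try:
            entries.append(Marker.build(str(r.chrom), pos, ref, alt, ctx))
        except ValueError as exc:
            raise ValueError(f"{path}: bad record at line {i + 2}: {exc}") from exc
    return MarkerSet(entries=entries, provenance=os.path.basename(path))


def _read_vcf(path: str, reference: Mapping[str, str] | None) -> MarkerSet:
    import pysam

    entries = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            ref = rec.ref.upper()
            if len(ref) != 1:
                continue
            pos = rec.pos - 1  # VCF 1-based -> internal 0-based
            for alt in rec.alts:
                alt = alt.upper()
                if len(alt) != 1 or alt == ref or alt not in "ACGT":
                    continue
                ctx = _context(reference, rec.chrom, pos) if reference else None
                entries.append(Marker.build(rec.chrom, pos, ref, alt, ctx))
    return MarkerSet(entries=entries, provenance=os.path.basename(path))


def _context(reference: Mapping[str, str], chrom: str, pos: int) -> str | None:
    seq = reference.get(chrom)
    if seq is None or not (0 <= pos < len(seq)):
        return None
    left = seq[pos - 1] if pos > 0 else "N"
    right = seq[pos + 1] if pos + 1 < len(seq) else "N"
    return f"{left}{seq[pos]}{right}"


def write_variants_tsv(markers: MarkerSet, path: str) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def write_variants_vcf(markers: MarkerSet, path: str, contigs: Mapping[str, int]) -> None:
    """Write markers as a minimal VCF (0-based internal -> 1-based POS)."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(path, "w", header=header) as out:
        for m in sorted(markers, key=lambda m: (m.chrom, m.pos, m.alt)):
            rec = out.new_record(
                contig=m.chrom, start=m.pos, stop=m.pos + 1, alleles=(m.ref, m.alt)
            )
            out.write(rec)


def read_pileup_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "context": str, "alt": str},
    )
    required = {"chrom", "pos", "ref", "context", "depth", "alt", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns {sorted(missing)}")
    return df


def write_pileup_tsv(pileup: pd.DataFrame, path: str) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA into memory as {name: sequence}."""
    import pysam

    with pysam.FastaFile(path) as fa:
        return {name: fa.fetch(name) for name in fa.references}


def write_fasta(reference: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path: str,
    command: str,
    params: dict,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
    seed: int | None = None,
) -> None:
    """Machine-readable run record: inputs, parameters, seed, version."""
    from accuscan import __version__

    record = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "params": params,
        "inputs": {p: file_sha256(p) for p in (inputs or []) if os.path.exists(p)},
        "outputs": {p: file_sha256(p) for p in (outputs or []) if os.path.exists(p)},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
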