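"""Synthetic data generators: references, concatemer reads, pileups, cohorts.

These generators emulate the data-generating process the rest of the package
consumes, so every stage is testable without external data:

- a random reference sequence with a controllable GC content (hence CpG
  sites for the CpG C>T filters);
- concatemer read pairs: cfDNA fragments replicated as tandem copies within
  a read pair, with independent per-copy PCR/sequencing errors and shared
  template variants, emitted pre-aligned as SAM plus truth tables;
- plasma pileups at marker/germline/background sites with binomial molecule
  counts under typed error rates;
- multi-patient cohorts with disjoint variant sets and paired pre/post
  treatment plasmas for marker-selection and specificity tests.

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from accuscan.substitution import classify_substitution, types_for_reference
from accuscan.error_model import ErrorModel
from accuscan.markers import Marker, MarkerSet

_BASES = np.array(list("ACGT"))


def generate_reference(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Random reference sequence with the requested GC content."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    if "CG" not in seq:
        warnings.warn("reference contains no CpG dinucleotide; CpG filters untestable")
    return seq


def count_cpg(seq: str) -> int:
    return seq.count("CG")


@dataclass
class FixtureConfig:
    """Configuration of the concatemer read generator."""

    reference: Mapping[str, str]
    n_molecules: int = 200
    fragment_mean: float = 170.0
    fragment_sd: float = 25.0
    fragment_min: int = 60
    copies_pmf: dict[int, float] = field(
        default_factory=lambda: {2: 0.3, 3: 0.4, 4: 0.2, 5: 0.1}
    )
    per_copy_error_rate: float = 0.0
    template_variants: Sequence[tuple[str, int, str, float]] = ()  # (chrom,pos,alt,vaf)
    q_high: int = 37
    q_low: int = 20
    q_low_frac: float = 0.0
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.per_copy_error_rate, self.q_low_frac, self.duplication_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        total = sum(self.copies_pmf.values())
        if not np.isclose(total, 1.0):
            raise ValueError("copies_pmf must sum to 1")


def _mutate(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(0, 3)]


def generate_concatemer_reads(
    config: FixtureConfig,
) -> tuple[list[dict], pd.DataFrame, pd.DataFrame]:
    """Synthetic concatemer read pairs plus truth tables.

    Returns (sam_records, molecule_truth, error_truth). Each record dict has
    qname, mate, chrom, pos (0-based), seq, quals and maps to one tandem
    copy; copies of one molecule share the qname and alternate between
    mates. ``molecule_truth`` lists every template molecule with endpoints,
    copy count and injected template variants; ``error_truth`` lists every
    injected per-copy error.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.reference)
    copies_k = np.array(sorted(config.copies_pmf))
    copies_p = np.array([config.copies_pmf[k] for k in copies_k])

    variants_by_chrom: dict[str, list[tuple[int, str, float]]] = {}
    for chrom, pos, alt, vaf in config.template_variants:
        variants_by_chrom.setdefault(chrom, []).append((pos, alt, vaf))

    records: list[dict] = []
    mol_rows = []
    err_rows = []
    endpoints: list[tuple[str, int, int]] = []

    for i in range(config.n_molecules):
        if endpoints and rng.random() < config.duplication_rate:
            chrom, start, end = endpoints[rng.integers(0, len(endpoints))]
        else:
            chrom = chroms[rng.integers(0, len(chroms))]
            ref_len = len(config.reference[chrom])
            frag = max(config.fragment_min, int(round(rng.normal(config.fragment_mean, config.fragment_sd))))
            frag = min(frag, ref_len - 1)
            start = int(rng.integers(0, ref_len - frag))
            end = start + frag
        endpoints.append((chrom, start, end))

        template = list(config.reference[chrom][start:end])
        mol_variants = []
        for pos, alt, vaf in variants_by_chrom.get(chrom, []):
            if start <= pos < end and rng.random() < vaf:
                template[pos - start] = alt
                mol_variants.append(f"{pos}:{alt}")
        template = "".join(template)

        n_copies = int(rng.choice(copies_k, p=copies_p))
        qname = f"mol{i:06d}"
        for ci in range(n_copies):
            seq = list(template)
            if config.per_copy_error_rate > 0:
                hits = np.flatnonzero(rng.random(len(seq)) < config.per_copy_error_rate)
                for h in hits:
                    orig = seq[h]
                    seq[h] = _mutate(rng, orig)
                    err_rows.append((qname, ci, chrom, start + int(h), orig, seq[h]))
            if config.q_low_frac > 0:
                low = rng.random(len(seq)) < config.q_low_frac
                quals = np.where(low, config.q_low, config.q_high).tolist()
            else:
                quals = [config.q_high] * len(seq)
            records.append(
                {
                    "qname": qname,
                    "mate": 1 if ci % 2 == 0 else 2,
                    "chrom": chrom,
                    "pos": start,
                    "seq": "".join(seq),
                    "quals": quals,
                    "supplementary": ci >= 2,
                }
            )
        mol_rows.append((qname, chrom, start, end, n_copies, ";".join(mol_variants)))

    molecule_truth = pd.DataFrame(
        mol_rows, columns=["qname", "chrom", "start", "end", "n_copies", "variants"]
    )
    error_truth = pd.DataFrame(
        err_rows, columns=["qname", "copy_index", "chrom", "pos", "ref", "alt"]
    )
    return records, molecule_truth, error_truth


def write_sam(records: list[dict], reference: Mapping[str, str], path: str) -> None:
    """Write generator records as a (text) SAM file via pysam."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }
    tid = {name: i for i, name in enumerate(reference)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r["qname"], r["mate"], r["pos"])):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec["qname"]
            seg.query_sequence = rec["seq"]
            seg.reference_id = tid[rec["chrom"]]
            seg.reference_start = rec["pos"]
            seg.cigartuples = [(0, len(rec["seq"]))]
            seg.mapping_quality = 60
            flag = 0x1 | (0x40 if rec["mate"] == 1 else 0x80)
            if rec.get("supplementary"):
                flag |= 0x800
            seg.flag = flag
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec["quals"])
            )
            out.write(seg)


def _context_at(seq: str, pos: int) -> str:
    left = seq[pos - 1] if pos > 0 else "N"
    right = seq[pos + 1] if pos + 1 < len(seq) else "N"
    return f"{left}{seq[pos]}{right}"


def generate_plasma_pileup(
    markers: MarkerSet | Sequence[Marker],
    depth: int,
    cvaf: float,
    error_model: ErrorModel,
    seed: int,
    germline: Sequence[tuple[Marker, float]] = (),
    background_sites: Sequence[tuple[str, int, str, str]] = (),
    depth_law: str = "fixed",
) -> pd.DataFrame:
    """Synthetic molecule-level pileup at marker/germline/background sites.

    Marker sites get variant counts Binomial(depth, cvaf + e_type) (truncated
    at depth); germline entries carry an explicit allele fraction (0.5 / 1.0
    for het/hom sites); background sites (chrom, pos, ref, context) draw each
    of the three possible substitutions at its typed error rate, giving the
    inputs error-rate estimation expects.
    """
    rng = np.random.default_rng(seed)

    def site_depth() -> int:
        if depth_law == "poisson":
            return int(rng.poisson(depth))
        return depth

    rows = []

    def emit(chrom, pos, ref, ctx, d, alts: dict[str, int]):
        alts = {a: n for a, n in alts.items() if n > 0}
        if not alts:
            rows.append((chrom, pos, ref, ctx, d, ".", 0))
        else:
            for a, n in sorted(alts.items()):
                rows.append((chrom, pos, ref, ctx, d, a, min(n, d)))

    for m in markers:
        d = site_depth()
        e = error_model.rates.get(m.vtype.cls, 0.0)
        n_sig = rng.binomial(d, cvaf) if cvaf > 0 and d > 0 else 0
        n_err = rng.binomial(d, e) if e > 0 and d > 0 else 0
        emit(m.chrom, m.pos, m.ref, m.context or f"N{m.ref}N", d, {m.alt: n_sig + n_err})

    for m, g_vaf in germline:
        d = site_depth()
        n_alt = rng.binomial(d, g_vaf) if d > 0 else 0
        emit(m.chrom, m.pos, m.ref, m.context or f"N{m.ref}N", d, {m.alt: n_alt})

    if background_sites:
        # vectorized: one (n_sites, 3) binomial draw block per reference base
        bg = pd.DataFrame(background_sites, columns=["chrom", "pos", "ref", "context"])
        if depth_law == "poisson":
            bg_depth = rng.poisson(depth, size=len(bg))
        else:
            bg_depth = np.full(len(bg), depth, dtype=int)
        counts = np.zeros((len(bg), 3), dtype=int)
        alt_names = np.empty((len(bg), 3), dtype="<U1")
        for ref_base in "ACGT":
            mask = (bg["ref"] == ref_base).to_numpy()
            if not mask.any():
                continue
            for j, t in enumerate(types_for_reference(ref_base)):
                e = error_model.rates.get(t, 0.0)
                alt_names[mask, j] = _alt_for(ref_base, t)
                if e > 0:
                    counts[mask, j] = rng.binomial(bg_depth[mask], e)
        for i, row in enumerate(bg.itertuples(index=False)):
            emit(
                row.chrom,
                row.pos,
                row.ref,
                row.context,
                int(bg_depth[i]),
                dict(zip(alt_names[i], counts[i])),
            )

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "context", "depth", "alt", "alt_count"]
    )
    return df.sort_values(["chrom", "pos", "alt"], kind="stable").reset_index(drop=True)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _alt_for(ref: str, vtype_cls: str) -> str:
    """The concrete alt base that realizes a collapsed class at a given ref."""
    coll_ref, coll_alt = vtype_cls.split("-")
    if ref in "CA":
        return coll_alt
    return _COMP[coll_alt]


def sample_background_sites(
    reference: Mapping[str, str],
    n_sites: int,
    seed: int,
) -> list[tuple[str, int, str, str]]:
    """Sample distinct interior reference positions as (chrom,pos,ref,context)."""
    rng = np.random.default_rng(seed)
    spans = [(chrom, len(reference[chrom]) - 2) for chrom in reference]
    total = sum(n for _, n in spans)
    if n_sites > total:
        raise ValueError(f"requested {n_sites} sites but only {total} available")
    flat = np.sort(rng.choice(total, size=n_sites, replace=False))
    sites = []
    offset = 0
    idx = 0
    for chrom, n in spans:
        seq = reference[chrom]
        while idx < len(flat) and flat[idx] < offset + n:
            pos = int(flat[idx] - offset) + 1
            sites.append((chrom, pos, seq[pos], _context_at(seq, pos)))
            idx += 1
        offset += n
    return sites


@dataclass
class SyntheticPatient:
    patient_id: str
    somatic: MarkerSet  # true tumor-specific markers
    germline: MarkerSet  # germline/CHIP contaminants present in all plasmas
    tumor_variants: MarkerSet  # what a WBC-less tumor caller would emit
    plasmas: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth_labels: dict[str, bool] = field(default_factory=dict)
    truth_cvaf: dict[str, float] = field(default_factory=dict)


def generate_cohort(
    n_patients: int,
    seed: int,
    reference: Mapping[str, str] | None = None,
    n_somatic: int = 2000,
    n_germline: int = 150,
    depth: int = 60,
    pre_cvaf: float | Sequence[float] = 1e-3,
    post_cvaf: float = 0.0,
    error_model: ErrorModel | float = 4.2e-7,
) -> list[SyntheticPatient]:
    """Multi-patient cohort with disjoint variant sets and paired plasmas.

    Each patient gets a disjoint set of somatic and germline variant
    positions on a shared synthetic reference. The 'pre' plasma carries
    tumor signal at ``pre_cvaf``, the 'post' plasma at ``post_cvaf``
    (default 0: truth-negative); germline sites are heterozygous (VAF 0.5)
    in both. Every plasma also covers the other patients' variant positions
    at background error rates, so mismatched-marker analyses are possible.
    """
    if isinstance(error_model, (int, float)):
        error_model = ErrorModel.uniform(float(error_model))
    if np.isscalar(pre_cvaf):
        pre_cvafs = [float(pre_cvaf)] * n_patients
    else:
        pre_cvafs = [float(v) for v in pre_cvaf]
        if len(pre_cvafs) != n_patients:
            raise ValueError("pre_cvaf sequence must have one value per patient")
    rng = np.random.default_rng(seed)
    per_patient = n_somatic + n_germline
    need = n_patients * per_patient
    if reference is None:
        reference = {"chrS": generate_reference(max(20 * need, 10_000), seed=seed)}
    chrom = next(iter(reference))
    seq = reference[chrom]

    # distinct non-CpG-C>T-able positions, partitioned across patients
    pool = rng.choice(len(seq) - 2, size=min(len(seq) - 2, 4 * need), replace=False) + 1
    positions = []
    for pos in pool:
        ref = seq[pos]
        ctx = _context_at(seq, pos)
        alt = _choose_alt(rng, ref, ctx)
        if alt is None:
            continue
        positions.append((int(pos), ref, alt, ctx))
        if len(positions) == need:
            break
    if len(positions) < need:
        raise ValueError("reference too small for the requested cohort")

    patients = []
    for i in range(n_patients):
        block = positions[i * per_patient : (i + 1) * per_patient]
        somatic = MarkerSet(
            [Marker.build(chrom, p, r, a, c) for p, r, a, c in block[:n_somatic]],
            provenance="truth_somatic",
        )
        germ = MarkerSet(
            [Marker.build(chrom, p, r, a, c) for p, r, a, c in block[n_somatic:]],
            provenance="truth_germline",
        )
        tumor = MarkerSet(list(somatic) + list(germ), provenance="tumor_caller")
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i:02d}", somatic=somatic, germline=germ, tumor_variants=tumor
            )
        )

    all_somatic = {p.patient_id: p.somatic for p in patients}
    all_germline = {p.patient_id: p.germline for p in patients}
    for i, pat in enumerate(patients):
        others = [
            m
            for pid, ms in all_somatic.items()
            if pid != pat.patient_id
            for m in ms
        ] + [
            m
            for pid, ms in all_germline.items()
            if pid != pat.patient_id
            for m in ms
        ]
        background = [(m.chrom, m.pos, m.ref, m.context or f"N{m.ref}N") for m in others]
        for label, cvaf in (("pre", pre_cvafs[i]), ("post", post_cvaf)):
            pileup = generate_plasma_pileup(
                pat.somatic,
                depth=depth,
                cvaf=cvaf,
                error_model=error_model,
                seed=int(rng.integers(0, 2**31 - 1)),
                germline=[(m, 0.5) for m in pat.germline],
                background_sites=background,
            )
            pat.plasmas[label] = pileup
            pat.truth_labels[label] = cvaf > 0
            pat.truth_cvaf[label] = cvaf
    return patients


def _choose_alt(rng: np.random.Generator, ref: str, ctx: str) -> str | None:
    """Pick an alt whose substitution is not a CpG C>T (marker sets exclude those)."""
    alts = [b for b in "ACGT" if b != ref]
    rng.shuffle(alts)
    for alt in alts:
        if not classify_substitution(ref, alt, ctx).cpg_ct:
            return alt
    return None
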