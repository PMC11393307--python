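"""Tumor-informed marker selection and specificity procedures.

Covers the marker-handling side of the MRD workflow:

- WBC-free filtering: tumor variants seen with two or more unique molecules
  in a post-treatment (presumed low-burden) plasma are treated as likely
  germline or CHIP and removed, replacing a white-blood-cell-paired somatic
  call; CpG C>T variants are removed outright.
- A Poisson model for the number of variant molecules expected at a site,
  whose P(count >= 2) separates germline (VAF ~0.5/1) from residual somatic
  signal (cVAF well below 1e-2) at typical molecule depths.
- Profile-constrained subsampling of marker pools to a target substitution
  -type profile (e.g. a typical CRC tumor profile).
- Titration SNP selection for contrived-sample studies (five criteria).
- The mismatched-tumor specificity procedure: markers from other patients'
  tumors are repeatedly subsampled, depth-adjusted via
  v_i = (60/depth_i) * n, and the false-positive rate of the MRD caller
  tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from accuscan.substitution import VARIANT_TYPES, VariantType, classify_substitution
from accuscan.error_model import ErrorModel
from accuscan.mrd import collect_marker_observations, lr_test


@dataclass(frozen=True)
class Marker:
    """One tumor-informed marker site (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: VariantType
    context: str | None = None

    @classmethod
    def build(
        cls, chrom: str, pos: int, ref: str, alt: str, context: str | None = None
    ) -> "Marker":
        return cls(
            chrom=chrom,
            pos=pos,
            ref=ref.upper(),
            alt=alt.upper(),
            vtype=classify_substitution(ref, alt, context),
            context=context,
        )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MarkerSet:
    """An ordered, duplicate-free collection of markers with provenance."""

    entries: list[Marker] = field(default_factory=list)
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for m in self.entries:
            if m.key not in seen:
                seen.add(m.key)
                unique.append(m)
        self.entries = unique

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {m.key for m in self.entries}

    def without_cpg_ct(self) -> "MarkerSet":
        kept = [m for m in self.entries if not m.vtype.cpg_ct]
        return MarkerSet(entries=kept, provenance=self.provenance)

    def by_type(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {v: [] for v in VARIANT_TYPES}
        for m in self.entries:
            out[m.vtype.cls].append(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.chrom, m.pos, m.ref, m.alt, m.vtype.cls, m.vtype.cpg_ct, m.context or ".")
            for m in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "vtype", "cpg_ct", "context"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "unspecified") -> "MarkerSet":
        entries = []
        for r in df.itertuples(index=False):
            ctx = getattr(r, "context", None)
            ctx = None if ctx in (None, ".", "") or (isinstance(ctx, float) and np.isnan(ctx)) else str(ctx)
            entries.append(Marker.build(r.chrom, int(r.pos), r.ref, r.alt, ctx))
        return cls(entries=entries, provenance=provenance)


@dataclass
class TypeProfile:
    """Marker-type fractions over the six collapsed substitution classes."""

    fractions: dict[str, float]
    stdevs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(self.fractions.get(v, 0.0) for v in VARIANT_TYPES)
        if not np.isclose(total, 1.0):
            raise ValueError(f"fractions sum to {total}, expected 1")

    @classmethod
    def uniform(cls) -> "TypeProfile":
        return cls({v: 1.0 / len(VARIANT_TYPES) for v in VARIANT_TYPES})

    def array(self) -> np.ndarray:
        return np.array([self.fractions.get(v, 0.0) for v in VARIANT_TYPES])


def _plasma_alt_counts(plasma_pileup: pd.DataFrame) -> dict[tuple[str, int, str], int]:
    rows = plasma_pileup[plasma_pileup["alt"] != "."]
    return {
        (r.chrom, int(r.pos), r.alt): int(r.alt_count)
        for r in rows.itertuples(index=False)
    }


def wbc_free_filter(
    tumor_variants: MarkerSet,
    plasma_pileup: pd.DataFrame,
    max_molecules: int = 2,
) -> tuple[MarkerSet, dict[str, int]]:
    """WBC-free tumor-specific marker filtering against post-treatment plasma.

    Tumor variants observed with ``max_molecules`` or more unique molecules
    in the post-treatment plasma are removed (germline/CHIP proxy: at a low
    residual burden a true somatic marker is very unlikely to recur in two
    molecules). CpG C>T variants are removed regardless. Returns the
    surviving set and per-reason removal counts; warns when the plasma looks
    high-burden (almost everything removed).
    """
    if len(tumor_variants) == 0:
        raise ValueError("empty tumor variant list")
    counts = _plasma_alt_counts(plasma_pileup)
    kept: list[Marker] = []
    removed = {"multimolecule": 0, "cpg_ct": 0}
    for m in tumor_variants:
        if m.vtype.cpg_ct:
            removed["cpg_ct"] += 1
            continue
        if counts.get((m.chrom, m.pos, m.alt), 0) >= max_molecules:
            removed["multimolecule"] += 1
            continue
        kept.append(m)
    if len(kept) < 0.05 * len(tumor_variants):
        warnings.warn(
            "WBC-free filter removed >95% of tumor variants; the plasma may "
            "carry a high tumor fraction and is unsuitable as a germline proxy",
            stacklevel=2,
        )
    return MarkerSet(entries=kept, provenance="wbc_free"), removed


@dataclass
class MoleculePMF:
    """Poisson model of the variant-molecule count at one site."""

    depth: float
    cvaf: float
    mean: float
    p_ge2: float

    def pmf(self, k: int | np.ndarray) -> np.ndarray:
        return poisson.pmf(k, self.mean)


def expected_molecule_pmf(depth: float, cvaf: float) -> MoleculePMF:
    """Poisson(depth * cvaf) molecule-count model with the P(>=2) discriminator."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0.0 <= cvaf <= 1.0):
        raise ValueError("cvaf must be in [0, 1]")
    mu = depth * cvaf
    p_ge2 = float(poisson.sf(1, mu))
    return MoleculePMF(depth=depth, cvaf=cvaf, mean=mu, p_ge2=p_ge2)


def subsample_markers_profile(
    pool: MarkerSet,
    n: int,
    profile: TypeProfile,
    rng: np.random.Generator,
) -> MarkerSet:
    """Sample exactly n markers matching a substitution-type profile.

    Per-type quotas come from largest-remainder rounding of n * fraction;
    sampling within a type is uniform without replacement. When a type's
    pool is too small the shortfall is re-allocated proportionally across
    the remaining types (with a warning).
    """
    by_type = pool.by_type()
    fr = profile.array()
    raw = n * fr
    quotas = np.floor(raw).astype(int)
    rem = n - quotas.sum()
    if rem > 0:
        order = np.argsort(-(raw - quotas), kind="stable")
        quotas[order[:rem]] += 1

    avail = np.array([len(by_type[v]) for v in VARIANT_TYPES])
    short = np.maximum(quotas - avail, 0)
    if short.sum() > 0:
        warnings.warn(
            f"insufficient pool for types "
            f"{[v for v, s in zip(VARIANT_TYPES, short) if s > 0]}; re-allocating",
            stacklevel=2,
        )
        quotas = np.minimum(quotas, avail)
        deficit = n - quotas.sum()
        while deficit > 0:
            room = avail - quotas
            if room.sum() <= 0:
                raise ValueError(f"pool too small: need {n}, have {len(pool)}")
            fr_room = room / room.sum()
            extra = np.minimum(_round_quota(deficit, fr_room), room)
            quotas += extra
            deficit = n - quotas.sum()

    chosen: list[Marker] = []
    for v, q in zip(VARIANT_TYPES, quotas):
        if q == 0:
            continue
        members = by_type[v]
        idx = rng.choice(len(members), size=int(q), replace=False)
        chosen.extend(members[i] for i in np.sort(idx))
    return MarkerSet(entries=chosen, provenance=f"{pool.provenance}+subsample")


def _round_quota(n: int, fractions: np.ndarray) -> np.ndarray:
    raw = n * fractions
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


def titration_snp_filter(
    test_genotypes: pd.DataFrame,
    background_genotypes: pd.DataFrame,
    undiluted_pileups: Mapping[str, pd.DataFrame],
    repeat_mask: Sequence[tuple[str, int, int]] | None = None,
    depth_range: tuple[float, float] = (20.0, 100.0),
    vaf_range: tuple[float, float] = (0.4, 0.6),
) -> tuple[MarkerSet, dict[str, int]]:
    """Select germline SNPs for a titration (spike-in) study.

    Criteria, applied in order:
      1. heterozygous in the test individual, absent in the background
         individual (hom-ref genotype and zero alt molecules);
      2. depth within ``depth_range`` at the site in every provided pileup;
      3. observed VAF within ``vaf_range`` in the undiluted test sample;
      4. not in a repeat region and not a CpG C>T;
      5. not observed in more than one of the provided plasma pileups.

    ``test_genotypes``/``background_genotypes`` need columns
    chrom, pos, ref, alt, genotype (het | hom_ref | hom_alt), context.
    ``undiluted_pileups`` maps sample name -> pileup frame; the test
    individual's own undiluted sample must be named 'test'.
    """
    if "test" not in undiluted_pileups:
        raise ValueError("undiluted_pileups must contain a 'test' sample")
    for name, pp in undiluted_pileups.items():
        if "depth" not in pp.columns:
            raise ValueError(f"pileup {name!r} lacks depth; criterion 2 cannot be applied")

    removed = {
        "not_het_in_test": 0,
        "present_in_background": 0,
        "depth_out_of_range": 0,
        "vaf_out_of_range": 0,
        "repeat_or_cpg": 0,
        "multi_sample": 0,
    }
    bg_gt = {
        (r.chrom, int(r.pos), r.ref, r.alt): r.genotype
        for r in background_genotypes.itertuples(index=False)
    }
    depth_by = {
        name: {
            (r.chrom, int(r.pos)): int(r.depth)
            for r in pp.drop_duplicates(subset=["chrom", "pos"]).itertuples(index=False)
        }
        for name, pp in undiluted_pileups.items()
    }
    alt_by = {name: _plasma_alt_counts(pp) for name, pp in undiluted_pileups.items()}

    def in_repeat(chrom: str, pos: int) -> bool:
        if not repeat_mask:
            return False
        return any(c == chrom and s <= pos < e for c, s, e in repeat_mask)

    kept = []
    for r in test_genotypes.itertuples(index=False):
        chrom, pos = r.chrom, int(r.pos)
        ctx = getattr(r, "context", None)
        ctx = None if ctx in (None, ".", "") else str(ctx)
        # 1. het in test, absent in background
        if r.genotype != "het":
            removed["not_het_in_test"] += 1
            continue
        bg = bg_gt.get((chrom, pos, r.ref, r.alt), "hom_ref")
        bg_alt = alt_by.get("background", {}).get((chrom, pos, r.alt), 0)
        if bg != "hom_ref" or bg_alt > 0:
            removed["present_in_background"] += 1
            continue
        # 2. depth in range for every individual
        lo, hi = depth_range
        depths = [d.get((chrom, pos), 0) for d in depth_by.values()]
        if any(dd < lo or dd > hi for dd in depths):
            removed["depth_out_of_range"] += 1
            continue
        # 3. observed VAF in the undiluted test sample
        t_depth = depth_by["test"].get((chrom, pos), 0)
        t_alt = alt_by["test"].get((chrom, pos, r.alt), 0)
        vaf = t_alt / t_depth if t_depth else 0.0
        if not (vaf_range[0] <= vaf <= vaf_range[1]):
            removed["vaf_out_of_range"] += 1
            continue
        # 4. repeats and CpG C>T
        vt = classify_substitution(r.ref, r.alt, ctx)
        if in_repeat(chrom, pos) or vt.cpg_ct:
            removed["repeat_or_cpg"] += 1
            continue
        # 5. present in multiple plasma samples
        n_samples_with = sum(
            1 for name in undiluted_pileups if alt_by[name].get((chrom, pos, r.alt), 0) > 0
        )
        if n_samples_with > 1:
            removed["multi_sample"] += 1
            continue
        kept.append(Marker.build(chrom, pos, r.ref, r.alt, ctx))
    return MarkerSet(entries=kept, provenance="titration"), removed


def equivalent_variant_count(n: int, plasma_depth: float) -> int:
    """Depth-equivalent marker count v_i = (60 / depth) * n, nearest integer.

    Normalizes a marker level n (defined at the reference molecule depth of
    60) to a plasma with a different average depth, so the expected summed
    depth over markers is held constant.
    """
    if plasma_depth <= 0:
        raise ValueError("plasma_depth must be positive")
    return int(round(60.0 / plasma_depth * n))


def mismatched_specificity(
    plasma_pileups: Mapping[str, pd.DataFrame],
    variant_pool: MarkerSet,
    levels: Sequence[int],
    error_models: Mapping[str, ErrorModel],
    plasma_depths: Mapping[str, float],
    n_reps: int = 2000,
    rng: np.random.Generator | None = None,
    nominal_specificity: float = 0.99,
    own_variants: Mapping[str, MarkerSet] | None = None,
    profile: TypeProfile | None = None,
) -> pd.DataFrame:
    """Clinical-specificity analogue with mismatched tumor variants.

    For each plasma sample and marker level n, draws
    v_i = (60/depth_i) * n variants from the pooled (other-patient) tumor
    variants ``n_reps`` times, runs the MRD test on each draw, and reports
    specificity_i = 1 - FP_i / n_reps. The pool must not contain the plasma's
    own patient's variants (checked when ``own_variants`` is provided).
    """
    if rng is None:
        rng = np.random.default_rng()
    if own_variants is not None:
        pool_keys = variant_pool.keys()
        for name, own in own_variants.items():
            overlap = pool_keys & own.keys()
            if overlap:
                raise ValueError(
                    f"variant pool contains {len(overlap)} variants of patient {name!r}"
                )
    if profile is None:
        profile = TypeProfile.uniform()
    cutoff = 1.0 - 2.0 * (1.0 - nominal_specificity)

    rows = []
    for name, pileup in plasma_pileups.items():
        em = error_models[name]
        depth = plasma_depths[name]
        for n in levels:
            v_i = equivalent_variant_count(n, depth)
            if v_i > len(variant_pool):
                raise ValueError(
                    f"pool of {len(variant_pool)} too small for v_i={v_i} "
                    f"(sample {name!r}, level {n})"
                )
            fp = 0
            for _ in range(n_reps):
                sub = subsample_markers_profile(variant_pool, v_i, profile, rng)
                obs = collect_marker_observations(pileup, sub)
                res = lr_test(obs, em, cdf_cutoff=cutoff, with_ci=False)
                if res.call == "POSITIVE":
                    fp += 1
            rows.append((name, n, v_i, n_reps, fp, 1.0 - fp / n_reps))
    df = pd.DataFrame(
        rows, columns=["sample", "level", "v_i", "n_reps", "n_fp", "specificity"]
    )
    return df
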