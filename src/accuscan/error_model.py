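"""Per-substitution-type background error rates from a molecule-level pileup.

After consensus correction, residual errors are not uniform across
substitution classes, so the background is modeled per collapsed type
v in {C-T, C-G, C-A, A-T, A-G, A-C}:

    e_v = (variant molecules of type v) / (molecules interrogated for type v)

over a (optionally subsampled) set of genomic positions, after removing

- known population variants (germline proxy, exact chrom/pos/ref/alt match),
- C>T substitutions at CpG sites on either strand (deamination / germline
  hotspot; excluded from both the C-T class and the overall rate), and
- positions carrying two or more variant molecules (such positions are also
  excluded from the MRD call itself, so they must not inform its null).

Each confirmed molecule at a retained position is interrogated for all three
substitutions its reference base allows, so it contributes its depth to three
type denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from accuscan.substitution import VARIANT_TYPES, classify_substitution, types_for_reference


@dataclass
class ErrorModel:
    """Typed background error rates with their count numerators/denominators."""

    rates: dict[str, float]
    variant_molecules: dict[str, int] = field(default_factory=dict)
    total_molecules: dict[str, int] = field(default_factory=dict)
    overall_rate: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(VARIANT_TYPES) - set(self.rates)
        if missing:
            raise ValueError(f"missing rates for types {sorted(missing)}")
        for v, r in self.rates.items():
            if not (0.0 <= r <= 1.0) and not np.isnan(r):
                raise ValueError(f"rate for {v} outside [0,1]: {r}")

    @classmethod
    def uniform(cls, rate: float) -> "ErrorModel":
        """Same error rate for all six substitution classes."""
        return cls(
            rates={v: float(rate) for v in VARIANT_TYPES},
            overall_rate=float(rate),
            metadata={"kind": "uniform"},
        )

    @classmethod
    def from_rates(cls, rates: Mapping[str, float]) -> "ErrorModel":
        r = {v: float(rates[v]) for v in VARIANT_TYPES}
        return cls(rates=r, overall_rate=float(np.mean(list(r.values()))))

    def rate_array(self) -> np.ndarray:
        return np.array([self.rates[v] for v in VARIANT_TYPES], dtype=float)

    @property
    def max_rate(self) -> float:
        return float(np.nanmax(self.rate_array()))

    def to_json(self, path: str) -> None:
        payload = {
            "rates": self.rates,
            "variant_molecules": self.variant_molecules,
            "total_molecules": self.total_molecules,
            "overall_rate": self.overall_rate,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "ErrorModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            rates=payload["rates"],
            variant_molecules=payload.get("variant_molecules", {}),
            total_molecules=payload.get("total_molecules", {}),
            overall_rate=payload.get("overall_rate", float("nan")),
            metadata=payload.get("metadata", {}),
        )


def _is_cpg_ct(ref: str, alt: str, context: str) -> bool:
    return classify_substitution(ref, alt, context).cpg_ct


def estimate_error_rates(
    pileup: pd.DataFrame,
    blocklist: Iterable[tuple[str, int, str, str]] | None = None,
    max_alt_molecules: int = 2,
    position_sample: int | None = None,
    seed: int | None = None,
    floor_zero: bool = False,
) -> ErrorModel:
    """Estimate typed error rates from a pileup table.

    Parameters
    ----------
    pileup : DataFrame
        Columns chrom, pos, ref, context, depth, alt, alt_count (one row per
        site plus one per observed alt; see ``consensus.pileup_to_frame``).
    blocklist : iterable of (chrom, pos, ref, alt), optional
        Population variants (germline proxy). Matching variants are excluded
        from the numerator and their site depth from that type's denominator.
    max_alt_molecules : int
        Positions with at least this many variant molecules in total are
        dropped entirely (they are also excluded from MRD calls).
    position_sample : int, optional
        Subsample this many distinct positions (seeded) before estimating;
        emulates estimating on a random slice of the genome.
    floor_zero : bool
        When True, types with zero observed variant molecules are floored at
        1/(3*denominator) instead of 0.
    """
    df = pileup
    required = {"chrom", "pos", "ref", "context", "depth", "alt", "alt_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"pileup missing columns {sorted(required - set(df.columns))}")

    if position_sample is not None:
        keys = df[["chrom", "pos"]].drop_duplicates()
        if position_sample < len(keys):
            rng = np.random.default_rng(seed)
            take = rng.choice(len(keys), size=position_sample, replace=False)
            keys = keys.iloc[np.sort(take)]
        df = df.merge(keys, on=["chrom", "pos"])

    # drop multi-molecule positions entirely
    n_positions = len(df.drop_duplicates(subset=["chrom", "pos"]))
    per_site_alt = df.groupby(["chrom", "pos"], sort=False)["alt_count"].transform("sum")
    df = df[per_site_alt < max_alt_molecules]
    n_multi_sites = n_positions - len(df.drop_duplicates(subset=["chrom", "pos"]))

    block = set(blocklist) if blocklist is not None else set()

    num = {v: 0 for v in VARIANT_TYPES}
    den = {v: 0 for v in VARIANT_TYPES}

    sites = df.drop_duplicates(subset=["chrom", "pos"])
    # denominators: every confirmed molecule is interrogated for the three
    # substitutions its reference base allows
    for ref_base, grp in sites.groupby("ref"):
        if ref_base not in "ACGT":
            continue
        depth_total = int(grp["depth"].sum())
        for t in types_for_reference(ref_base):
            den[t] += depth_total
    # CpG C>T exclusion: remove those sites' depth from the C-T denominator
    cpg_mask = (
        ((sites["ref"] == "C") & (sites["context"].str.get(2) == "G"))
        | ((sites["ref"] == "G") & (sites["context"].str.get(0) == "C"))
    )
    den["C-T"] -= int(sites.loc[cpg_mask, "depth"].sum())

    excluded = {"blocklisted": 0, "cpg_ct": 0, "multimolecule_sites": n_multi_sites}
    for row in df[df["alt"] != "."].itertuples(index=False):
        if row.ref not in "ACGT" or row.alt not in "ACGT":
            continue
        vt = classify_substitution(row.ref, row.alt, row.context)
        if (row.chrom, row.pos, row.ref, row.alt) in block:
            # germline proxy: drop the variant and that substitution's
            # denominator share at this site
            den[vt.cls] -= int(row.depth)
            excluded["blocklisted"] += 1
            continue
        if vt.cpg_ct:
            excluded["cpg_ct"] += 1
            continue
        num[vt.cls] += int(row.alt_count)

    rates: dict[str, float] = {}
    flagged = []
    for v in VARIANT_TYPES:
        if den[v] <= 0:
            rates[v] = float("nan")
            flagged.append(v)
        elif num[v] == 0 and floor_zero:
            rates[v] = 1.0 / (3.0 * den[v])
        else:
            rates[v] = num[v] / den[v]

    total_num = sum(num.values())
    total_den = sum(d for d in den.values() if d > 0)
    overall = total_num / total_den if total_den > 0 else float("nan")

    return ErrorModel(
        rates=rates,
        variant_molecules=num,
        total_molecules=den,
        overall_rate=overall,
        metadata={
            "max_alt_molecules": max_alt_molecules,
            "position_sample": position_sample,
            "seed": seed,
            "floor_zero": floor_zero,
            "undefined_types": flagged,
            "excluded": excluded,
            "n_blocklist": len(block),
        },
    )
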