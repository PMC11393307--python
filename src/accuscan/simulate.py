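"""Monte-Carlo detection-rate and specificity surfaces for the MRD test.

Each replicate draws, for every marker site, the number of variant molecules
as the sum of two binomials over the site's molecule depth — one with the
circulating allele fraction as success probability (tumor signal) and one
with the substitution-class error rate (background) — truncated at the
depth. The replicate's counts are aggregated with the same multi-molecule
exclusion the production caller applies and fed to the likelihood-ratio
test; the detection rate is the fraction of replicates called positive.

Sampling is done in aggregated form for speed: for a type with n_v sites of
depth d, the total variant-molecule count is Binomial(n_v*d, p), and the
molecules are placed on sites by drawing distinct trial indices, which is
distributionally identical to per-site binomial draws. Under the Poisson
depth law the thinned counts are Poisson(n_v*lambda*p) with sites uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from accuscan.substitution import VARIANT_TYPES
from accuscan.error_model import ErrorModel
from accuscan.mrd import MarkerObservation, lr_test

_LOD_SENTINEL = float("nan")


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer quotas summing to n, proportional to fractions."""
    raw = n * fractions
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


@dataclass
class SimulationConfig:
    """One cell of the detection-rate grid.

    ``error_model`` may be a scalar (uniform over the six substitution
    classes) or an :class:`ErrorModel`. ``type_profile`` gives marker-type
    fractions over the six classes (default uniform). ``depth_law`` 'fixed'
    uses exactly ``expected_depth`` molecules per site; 'poisson' draws the
    per-site depth from Poisson(expected_depth).
    """

    n_markers: int = 10_000
    expected_depth: float = 60.0
    vaf: float = 0.0
    error_model: ErrorModel | float = 4.2e-7
    n_reps: int = 10_000
    seed: int | None = None
    nominal_specificity: float = 0.99
    type_profile: dict[str, float] | None = None
    depth_law: str = "fixed"
    multimolecule_cutoff: int = 2
    high_burden_mode: bool = False

    def __post_init__(self) -> None:
        if self.vaf < 0:
            raise ValueError("vaf must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.depth_law not in ("fixed", "poisson"):
            raise ValueError("depth_law must be 'fixed' or 'poisson'")
        if isinstance(self.error_model, (int, float)):
            self.error_model = ErrorModel.uniform(float(self.error_model))
        if self.type_profile is None:
            self.type_profile = {v: 1.0 / len(VARIANT_TYPES) for v in VARIANT_TYPES}
        total = sum(self.type_profile.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type_profile sums to {total}, expected 1")

    @property
    def cdf_cutoff(self) -> float:
        return 1.0 - 2.0 * (1.0 - self.nominal_specificity)

    def markers_per_type(self) -> dict[str, int]:
        fr = np.array([self.type_profile.get(v, 0.0) for v in VARIANT_TYPES])
        quotas = _largest_remainder(self.n_markers, fr)
        return dict(zip(VARIANT_TYPES, quotas))


@dataclass
class DetectionResult:
    rate: float
    se: float
    n_reps: int
    n_positive: int
    config: SimulationConfig = field(repr=False, default=None)


def _place_molecules(
    rng: np.random.Generator, n_trials: int, depth: int, k: int
) -> np.ndarray:
    """Distinct trial indices for k variant molecules among n_trials = n_sites*depth.

    Returns the per-site molecule counts as a dict-free array of site indices
    (one per molecule). Sampling distinct trials and mapping trial -> site
    reproduces independent per-site binomials conditioned on the total.
    """
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    # rejection sampling of k distinct integers; k << n_trials in all regimes
    draw = rng.integers(0, n_trials, size=k)
    while len(np.unique(draw)) < k:
        draw = np.unique(draw)
        extra = rng.integers(0, n_trials, size=k - len(draw))
        draw = np.concatenate([draw, extra])
    return draw // depth


def _single_rep(
    config: SimulationConfig, rng: np.random.Generator
) -> MarkerObservation:
    em: ErrorModel = config.error_model  # type: ignore[assignment]
    per_type = config.markers_per_type()
    cutoff = config.multimolecule_cutoff
    depth = config.expected_depth

    c: dict[str, int] = {}
    d: dict[str, int] = {}
    n_excluded = 0
    for v in VARIANT_TYPES:
        n_v = per_type[v]
        if n_v == 0:
            c[v] = 0
            d[v] = 0
            continue
        e_v = em.rates[v]
        if config.depth_law == "fixed":
            d_site = int(round(depth))
            trials = n_v * d_site
            k_sig = rng.binomial(trials, config.vaf) if config.vaf > 0 else 0
            k_err = rng.binomial(trials, e_v) if e_v > 0 else 0
            sites_sig = _place_molecules(rng, trials, d_site, k_sig)
            sites_err = _place_molecules(rng, trials, d_site, k_err)
            sites = np.concatenate([sites_sig, sites_err])
            d_total = trials
            site_depth = lambda: d_site  # noqa: E731
        else:  # poisson: thinned counts are Poisson, sites uniform
            lam = depth
            k_sig = rng.poisson(n_v * lam * config.vaf) if config.vaf > 0 else 0
            k_err = rng.poisson(n_v * lam * e_v) if e_v > 0 else 0
            sites = rng.integers(0, n_v, size=k_sig + k_err)
            d_total = int(rng.poisson(n_v * lam))
            site_depth = lambda: max(int(rng.poisson(lam)), 1)  # noqa: E731

        k_total = len(sites)
        if k_total == 0:
            c[v] = 0
            d[v] = d_total
            continue
        uniq, counts = np.unique(sites, return_counts=True)
        if config.depth_law == "fixed":
            counts = np.minimum(counts, int(round(depth)))  # truncate at site depth
        if not config.high_burden_mode:
            multi = counts >= cutoff
            n_multi = int(multi.sum())
            n_excluded += n_multi
            removed_molecules = int(counts[multi].sum())
            removed_depth = sum(site_depth() for _ in range(n_multi))
            c[v] = int(counts.sum()) - removed_molecules
            d[v] = max(d_total - removed_depth, 0)
        else:
            c[v] = int(counts.sum())
            d[v] = d_total
        c[v] = min(c[v], d[v])
    return MarkerObservation(
        c=c,
        d=d,
        n_excluded_multimolecule=n_excluded,
        n_markers_used=config.n_markers - n_excluded,
        high_burden_flag=config.high_burden_mode,
    )


def simulate_marker_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> MarkerObservation:
    """Draw one replicate of marker observations under the two-binomial model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _single_rep(config, rng)


def _replicates(config: SimulationConfig) -> Iterator[MarkerObservation]:
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_reps):
        yield _single_rep(config, rng)


def detection_rate(config: SimulationConfig) -> DetectionResult:
    """Fraction of replicates called MRD-positive, with binomial SE."""
    em: ErrorModel = config.error_model  # type: ignore[assignment]
    cutoff = config.cdf_cutoff
    n_pos = 0
    for obs in _replicates(config):
        if obs.c_total == 0:
            continue  # LR statistic is exactly 0
        res = lr_test(obs, em, cdf_cutoff=cutoff, with_ci=False)
        if res.call == "POSITIVE":
            n_pos += 1
    rate = n_pos / config.n_reps
    se = float(np.sqrt(rate * (1.0 - rate) / config.n_reps))
    return DetectionResult(
        rate=rate, se=se, n_reps=config.n_reps, n_positive=n_pos, config=config
    )


def specificity_at_null(config: SimulationConfig) -> DetectionResult:
    """Fraction of replicates called negative when the true cVAF is 0."""
    if config.vaf != 0:
        raise ValueError("specificity_at_null requires vaf = 0")
    det = detection_rate(config)
    rate = 1.0 - det.rate
    return DetectionResult(
        rate=rate,
        se=det.se,
        n_reps=det.n_reps,
        n_positive=det.n_reps - det.n_positive,
        config=config,
    )


def find_lod(
    config: SimulationConfig,
    target_prob: float = 0.95,
    vaf_grid: np.ndarray | None = None,
) -> float:
    """Smallest cVAF on a log grid with detection rate >= target_prob.

    Detection is monotone non-decreasing in cVAF under the model, so the grid
    is scanned from below. Returns NaN when the target is unreachable within
    the grid.
    """
    if vaf_grid is None:
        vaf_grid = np.logspace(-6, -3, 13)
    from dataclasses import replace

    for vaf in np.sort(np.asarray(vaf_grid, dtype=float)):
        det = detection_rate(replace(config, vaf=float(vaf)))
        if det.rate >= target_prob:
            return float(vaf)
    return _LOD_SENTINEL
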