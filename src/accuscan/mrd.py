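"""Likelihood-ratio MRD calling with constrained cVAF estimation.

At each tumor-informed marker site the probability of observing a variant
molecule is approximately p_v = VAF + e_v, where e_v is the background error
rate of the marker's substitution class. Aggregating markers of the same
class v gives binomial counts c_v out of depth d_v, and the log-likelihood

    l(VAF) = K + sum_v [ c_v ln(p_v) + (d_v - c_v) ln(1 - p_v) ]

The cVAF point estimate maximizes l subject to VAF >= 0. The MRD decision
tests H0: VAF = 0 with the likelihood-ratio statistic L = 2(l(V^) - l(0)).
Because the null sits on the parameter boundary, L is asymptotically a
half-half mixture of a point mass at 0 and chi-square(1); the sample is
called POSITIVE when CDF_chi2(1)(L) > 0.98, i.e. mixture p < 0.01, a nominal
specificity of 99%. Likelihood-ratio confidence bounds collect the VAF
values within 3.841 (the chi-square(1) 0.95 quantile) of twice the maximum
log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from accuscan.substitution import VARIANT_TYPES
from accuscan.error_model import ErrorModel

if TYPE_CHECKING:  # pragma: no cover
    from accuscan.markers import MarkerSet

CI_DELTA = 3.841  # chi-square(1) 0.95 quantile; LR confidence-bound threshold
DEFAULT_CDF_CUTOFF = 0.98  # chi2 CDF cutoff for 99% nominal specificity
HIGH_BURDEN_FRACTION = 0.10  # fraction of markers with >=2 molecules that flags high burden
_MLE_RTOL = 1e-12


@dataclass
class MarkerObservation:
    """Sufficient statistic of the MRD test: per-type counts and depths."""

    c: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VARIANT_TYPES})
    d: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VARIANT_TYPES})
    n_excluded_multimolecule: int = 0
    n_markers_used: int = 0
    high_burden_flag: bool = False

    def __post_init__(self) -> None:
        for v in VARIANT_TYPES:
            cv, dv = self.c.get(v, 0), self.d.get(v, 0)
            if not (0 <= cv <= dv):
                raise ValueError(f"type {v}: need 0 <= c ({cv}) <= d ({dv})")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.array([self.c.get(v, 0) for v in VARIANT_TYPES], dtype=float)
        d = np.array([self.d.get(v, 0) for v in VARIANT_TYPES], dtype=float)
        return c, d

    @property
    def c_total(self) -> int:
        return int(sum(self.c.values()))

    @property
    def d_total(self) -> int:
        return int(sum(self.d.values()))


@dataclass
class MRDResult:
    call: str  # POSITIVE | NEGATIVE
    cvaf_hat: float
    ci_low: float
    ci_high: float
    lr_statistic: float
    chi2_cdf_value: float
    p_value: float
    nominal_specificity: float
    high_burden_flag: bool = False
    c_total: int = 0
    d_total: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def collect_marker_observations(
    pileup: pd.DataFrame,
    markers: "MarkerSet",
    multimolecule_cutoff: int = 2,
    high_burden_mode: bool | str = False,
) -> MarkerObservation:
    """Aggregate marker-site counts into the per-type sufficient statistic.

    Marker sites carrying ``multimolecule_cutoff`` or more variant molecules
    are excluded from both counts and depth (in a low-burden sample such
    sites are far more likely germline/CHIP than tumor signal). With
    ``high_burden_mode`` True (or 'auto' and more than 10% of covered markers
    multi-molecule) the exclusion is disabled and the sites retained.

    Markers absent from the pileup contribute zero depth; an empty marker set
    is an error.
    """
    entries = list(markers)
    if not entries:
        raise ValueError("empty marker set")

    lookup: dict[tuple[str, int, str], tuple[int, int]] = {}
    if len(pileup):
        alt_rows = pileup[pileup["alt"] != "."]
        depth_by_site = {
            (r.chrom, int(r.pos)): int(r.depth)
            for r in pileup.drop_duplicates(subset=["chrom", "pos"]).itertuples(index=False)
        }
        count_by_var = {
            (r.chrom, int(r.pos), r.alt): int(r.alt_count)
            for r in alt_rows.itertuples(index=False)
        }
    else:
        depth_by_site, count_by_var = {}, {}

    per_marker = []
    n_multi = 0
    n_covered = 0
    for m in entries:
        depth = depth_by_site.get((m.chrom, m.pos), 0)
        count = count_by_var.get((m.chrom, m.pos, m.alt), 0)
        if depth > 0:
            n_covered += 1
        if count >= multimolecule_cutoff:
            n_multi += 1
        per_marker.append((m.vtype.cls, depth, count))

    if high_burden_mode == "auto":
        high_burden = n_covered > 0 and n_multi / n_covered > HIGH_BURDEN_FRACTION
    else:
        high_burden = bool(high_burden_mode)

    c = {v: 0 for v in VARIANT_TYPES}
    d = {v: 0 for v in VARIANT_TYPES}
    n_excluded = 0
    for cls, depth, count in per_marker:
        if not high_burden and count >= multimolecule_cutoff:
            n_excluded += 1
            continue
        c[cls] += min(count, depth)
        d[cls] += depth
    return MarkerObservation(
        c=c,
        d=d,
        n_excluded_multimolecule=n_excluded,
        n_markers_used=len(entries) - n_excluded,
        high_burden_flag=high_burden,
    )


def log_likelihood(obs: MarkerObservation, error_model: ErrorModel, vaf: float) -> float:
    """Binomial log-likelihood over types, up to the VAF-free constant.

    Types with zero depth contribute nothing; p_v = 0 with c_v > 0 gives -inf.
    """
    if vaf < 0:
        raise ValueError("vaf must be non-negative")
    c, d = obs.arrays()
    e = np.nan_to_num(error_model.rate_array(), nan=0.0)
    p = vaf + e
    if np.any(p >= 1.0):
        raise ValueError("vaf + max error rate must be < 1")
    total = 0.0
    for cv, dv, pv in zip(c, d, p):
        if dv == 0:
            continue
        if cv > 0:
            if pv == 0.0:
                return float("-inf")
            total += cv * np.log(pv)
        total += (dv - cv) * np.log1p(-pv)
    return float(total)


def _score(obs_c: np.ndarray, obs_d: np.ndarray, e: np.ndarray, vaf: float) -> float:
    """Derivative of the log-likelihood w.r.t. VAF: sum (c - d p)/(p(1-p)).

    Expanded as c/(p(1-p)) - d/(1-p) so types with c = 0 stay finite at p = 0.
    """
    mask = obs_d > 0
    c, d, p = obs_c[mask], obs_d[mask], vaf + e[mask]
    if np.any((p == 0.0) & (c > 0)):
        return float("inf")
    total = -float(np.sum(d / (1.0 - p)))
    nz = c > 0
    if np.any(nz):
        total += float(np.sum(c[nz] / (p[nz] * (1.0 - p[nz]))))
    return total


def mle_cvaf(obs: MarkerObservation, error_model: ErrorModel) -> float:
    """Constrained maximum-likelihood cVAF.

    The score is strictly decreasing in VAF on the feasible interval, so the
    estimate is the unique root of the score, clipped to 0 when the score at
    0+ is non-positive. When every type shares the same error rate the
    problem collapses to a single binomial and the root is closed-form
    (c_total/d_total - e).
    """
    c, d = obs.arrays()
    if not np.any(d > 0):
        raise ValueError("all depths are zero; cVAF undefined")
    e = np.nan_to_num(error_model.rate_array(), nan=0.0)

    active = d > 0
    e_active = e[active]
    if np.ptp(e_active) == 0.0:
        # uniform error rate: single binomial, MLE is c/d - e clipped at 0
        ctot, dtot = float(c.sum()), float(d[active].sum())
        return max(0.0, ctot / dtot - float(e_active[0]))

    hi = 1.0 - float(np.max(e_active)) - 1e-12
    # score at 0 (infinite when some e_v = 0 with c_v > 0)
    if np.any((e[active] == 0.0) & (c[active] > 0)):
        s0 = np.inf
    else:
        s0 = _score(c, d, e, 0.0)
    if s0 <= 0:
        return 0.0
    lo = 1e-15
    if _score(c, d, e, lo) <= 0:
        return 0.0
    if _score(c, d, e, hi) > 0:
        return hi
    return float(brentq(lambda v: _score(c, d, e, v), lo, hi, xtol=1e-18, rtol=_MLE_RTOL))


def lr_test(
    obs: MarkerObservation,
    error_model: ErrorModel,
    cdf_cutoff: float = DEFAULT_CDF_CUTOFF,
    with_ci: bool = True,
    ci_delta: float = CI_DELTA,
) -> MRDResult:
    """Boundary-null likelihood-ratio MRD test.

    POSITIVE iff CDF_chi2(1)(L) > cdf_cutoff with L = 2(l(V^) - l(0)). The
    reported p-value is the boundary-mixture tail 0.5 * (1 - CDF) for L > 0
    and 1 for L = 0. ``cdf_cutoff`` 0.98 corresponds to mixture p < 0.01,
    i.e. 99% nominal specificity.
    """
    if not (0.0 < cdf_cutoff < 1.0):
        raise ValueError("cdf_cutoff must be in (0, 1)")
    vaf_hat = mle_cvaf(obs, error_model)
    if vaf_hat == 0.0:
        lam = 0.0
    else:
        l_hat = log_likelihood(obs, error_model, vaf_hat)
        l_null = log_likelihood(obs, error_model, 0.0)
        lam = max(0.0, 2.0 * (l_hat - l_null)) if np.isfinite(l_null) else float("inf")
    cdf_value = float(chi2.cdf(lam, df=1)) if np.isfinite(lam) else 1.0
    call = "POSITIVE" if cdf_value > cdf_cutoff else "NEGATIVE"
    p_value = 0.5 * (1.0 - cdf_value) if lam > 0 else 1.0

    ci_low, ci_high = (0.0, float("nan"))
    if with_ci:
        ci_low, ci_high = confidence_interval(obs, error_model, delta=ci_delta)
        if call == "NEGATIVE":
            ci_low = 0.0
    return MRDResult(
        call=call,
        cvaf_hat=vaf_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        lr_statistic=lam,
        chi2_cdf_value=cdf_value,
        p_value=p_value,
        nominal_specificity=1.0 - (1.0 - cdf_cutoff) / 2.0,
        high_burden_flag=obs.high_burden_flag,
        c_total=obs.c_total,
        d_total=obs.d_total,
    )


def confidence_interval(
    obs: MarkerObservation,
    error_model: ErrorModel,
    delta: float = CI_DELTA,
) -> tuple[float, float]:
    """Likelihood-ratio confidence bounds for the cVAF.

    The bounds are the non-negative VAF values at which twice the
    log-likelihood drop from the maximum equals ``delta`` (default 3.841, the
    chi-square(1) 0.95 quantile): two-sided around a positive estimate, and a
    one-sided upper bound (lower bound 0) when the drop to VAF=0 stays within
    ``delta``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    vaf_hat = mle_cvaf(obs, error_model)
    e = np.nan_to_num(error_model.rate_array(), nan=0.0)
    c, d = obs.arrays()
    hi_limit = 1.0 - float(np.max(e[d > 0])) - 1e-12

    l_hat = log_likelihood(obs, error_model, vaf_hat)

    def drop(v: float) -> float:
        return 2.0 * (l_hat - log_likelihood(obs, error_model, v)) - delta

    # upper bound: the drop increases monotonically above vaf_hat
    if drop(hi_limit) <= 0:
        ci_high = hi_limit
    else:
        lo_b = vaf_hat
        # expand a bracket just above vaf_hat
        step = max(vaf_hat, 1.0 / max(obs.d_total, 1))
        hi_b = min(vaf_hat + step, hi_limit)
        while drop(hi_b) < 0 and hi_b < hi_limit:
            step *= 2.0
            hi_b = min(vaf_hat + step, hi_limit)
        ci_high = float(brentq(drop, lo_b, hi_b, xtol=1e-18, rtol=1e-10))

    # lower bound
    l0 = log_likelihood(obs, error_model, 0.0)
    drop0 = 2.0 * (l_hat - l0) - delta if np.isfinite(l0) else float("inf")
    if vaf_hat == 0.0 or drop0 <= 0:
        ci_low = 0.0
    else:
        if np.isfinite(l0):
            lo_b = 0.0
        else:
            # likelihood -> -inf at 0 (some e_v = 0 with c_v > 0); start just above
            lo_b = vaf_hat * 1e-12
            while drop(lo_b) < 0 and lo_b > 1e-300:
                lo_b /= 10.0
        ci_low = float(brentq(drop, lo_b, vaf_hat, xtol=1e-18, rtol=1e-10))
    return ci_low, ci_high
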