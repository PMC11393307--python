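"""Marker selection: WBC-free filtering, subsampling, titration SNPs, v_i."""

import numpy as np
import pandas as pd
import pytest

from accuscan.error_model import ErrorModel
from accuscan.fixtures import generate_plasma_pileup
from accuscan.markers import (
    Marker,
    MarkerSet,
    TypeProfile,
    equivalent_variant_count,
    expected_molecule_pmf,
    mismatched_specificity,
    subsample_markers_profile,
    titration_snp_filter,
    wbc_free_filter,
)
from accuscan.substitution import VARIANT_TYPES


def pileup_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "context", "depth", "alt", "alt_count"]
    )


class TestWbcFreeFilter:
    def _tumor(self):
        return MarkerSet(
            [
                Marker.build("chr1", 10, "C", "T", "ACA"),
                Marker.build("chr1", 20, "C", "T", "ACA"),
                Marker.build("chr1", 30, "C", "T", "ACG"),  # CpG C>T
                Marker.build("chr1", 40, "A", "G", "CAT"),
            ]
        )

    def test_filter_reasons(self):
        plasma = pileup_frame(
            [
                ("chr1", 10, "C", "ACA", 60, "T", 2),  # germline-like: remove
                ("chr1", 20, "C", "ACA", 60, "T", 1),  # single molecule: keep
                ("chr1", 30, "C", "ACG", 60, ".", 0),  # CpG: removed regardless
                ("chr1", 40, "A", "CAT", 60, ".", 0),
            ]
        )
        kept, removed = wbc_free_filter(self._tumor(), plasma)
        assert removed == {"multimolecule": 1, "cpg_ct": 1}
        assert kept.keys() == {("chr1", 20, "C", "T"), ("chr1", 40, "A", "G")}
        assert kept.provenance == "wbc_free"

    def test_empty_tumor_list_is_error(self):
        with pytest.raises(ValueError):
            wbc_free_filter(MarkerSet([]), pileup_frame([]))

    def test_high_burden_warning(self):
        tumor = MarkerSet([Marker.build("chr1", p, "C", "T", "ACA") for p in range(20)])
        plasma = pileup_frame([("chr1", p, "C", "ACA", 60, "T", 5) for p in range(20)])
        with pytest.warns(UserWarning, match="high tumor fraction"):
            kept, _ = wbc_free_filter(tumor, plasma)
        assert len(kept) == 0

    def test_germline_vs_somatic_separation(self):
        """Germline sites (VAF 0.5) nearly all removed; somatic sites mostly kept."""
        rng = np.random.default_rng(42)
        em = ErrorModel.uniform(4.2e-7)
        n = 1500
        somatic = [
            Marker.build("chrS", p, "C", "T", "ACA") for p in range(0, 2 * n, 2)
        ]
        germline = [
            Marker.build("chrS", p, "C", "T", "ACA") for p in range(1, 2 * n, 2)
        ]
        depth = int(rng.integers(40, 61))
        plasma = generate_plasma_pileup(
            somatic,
            depth=depth,
            cvaf=1e-3,
            error_model=em,
            seed=99,
            germline=[(m, 0.5) for m in germline],
        )
        tumor = MarkerSet(somatic + germline)
        kept, removed = wbc_free_filter(tumor, plasma)
        kept_keys = kept.keys()
        germ_kept = sum(1 for m in germline if m.key in kept_keys)
        som_kept = sum(1 for m in somatic if m.key in kept_keys)
        assert germ_kept / n <= 0.001  # >= 99.9% of germline removed
        assert som_kept / n >= 0.95  # <= 5% of somatic removed


class TestExpectedMoleculePmf:
    def test_zero_cvaf_all_mass_at_zero(self):
        m = expected_molecule_pmf(60, 0.0)
        assert m.pmf(0) == pytest.approx(1.0)
        assert m.p_ge2 == 0.0

    def test_germline_poisson_tail(self):
        # depth 60, cvaf 0.5: P(count < 2) = e^-30 * 31
        m = expected_molecule_pmf(60, 0.5)
        assert 1 - m.p_ge2 == pytest.approx(np.exp(-30) * 31, rel=1e-9)

    def test_low_cvaf_p_ge2(self):
        m = expected_molecule_pmf(60, 1e-3)
        assert m.p_ge2 == pytest.approx(1 - np.exp(-0.06) * 1.06, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_molecule_pmf(0, 0.1)
        with pytest.raises(ValueError):
            expected_molecule_pmf(10, 1.5)


def _pool(n_per_type, seed=0):
    """A marker pool with n_per_type entries of each collapsed class."""
    builders = {
        "C-T": ("C", "T", "ACA"),
        "C-G": ("C", "G", "ACA"),
        "C-A": ("C", "A", "ACA"),
        "A-T": ("A", "T", "CAT"),
        "A-G": ("A", "G", "CAT"),
        "A-C": ("A", "C", "CAT"),
    }
    entries = []
    pos = 0
    for cls, (ref, alt, ctx) in builders.items():
        for _ in range(n_per_type):
            entries.append(Marker.build("chr1", pos, ref, alt, ctx))
            pos += 1
    return MarkerSet(entries)


class TestSubsampleProfile:
    def test_uniform_profile_even_split(self, rng):
        out = subsample_markers_profile(_pool(10), 6, TypeProfile.uniform(), rng)
        by = out.by_type()
        assert all(len(by[v]) == 1 for v in VARIANT_TYPES)

    def test_degenerate_profile_single_type(self, rng):
        profile = TypeProfile({v: (1.0 if v == "C-T" else 0.0) for v in VARIANT_TYPES})
        out = subsample_markers_profile(_pool(30), 20, profile, rng)
        assert all(m.vtype.cls == "C-T" for m in out)
        assert len(out) == 20

    def test_quota_rounding_bound(self, rng):
        """|n_v - n*f_v| <= 1 for every type (largest-remainder rounding)."""
        fr = np.array([0.37, 0.21, 0.13, 0.11, 0.10, 0.08])
        profile = TypeProfile(dict(zip(VARIANT_TYPES, fr)))
        n = 97
        out = subsample_markers_profile(_pool(60), n, profile, rng)
        by = out.by_type()
        for v, f in profile.fractions.items():
            assert abs(len(by[v]) - n * f) <= 1

    def test_repeated_draws_are_distinct_and_seeded(self):
        pool = _pool(300)
        rng = np.random.default_rng(5)
        draws = [
            frozenset(m.key for m in subsample_markers_profile(pool, 30, TypeProfile.uniform(), rng))
            for _ in range(100)
        ]
        assert len(set(draws)) == 100
        rng2 = np.random.default_rng(5)
        again = frozenset(
            m.key for m in subsample_markers_profile(pool, 30, TypeProfile.uniform(), rng2)
        )
        assert again == draws[0]

    def test_insufficient_type_reallocates_with_warning(self, rng):
        profile = TypeProfile({v: (1.0 if v == "C-T" else 0.0) for v in VARIANT_TYPES})
        with pytest.warns(UserWarning, match="re-allocating"):
            out = subsample_markers_profile(_pool(5), 12, profile, rng)
        assert len(out) == 12


class TestTitrationSnpFilter:
    @staticmethod
    def _genotypes(rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype", "context"])

    def _inputs(self):
        # ten candidate SNPs with tabulated fates
        test_gt = self._genotypes(
            [
                ("chr1", 1, "C", "T", "het", "ACA"),   # keep
                ("chr1", 2, "C", "T", "hom_alt", "ACA"),  # crit 1: not het
                ("chr1", 3, "C", "T", "het", "ACA"),   # crit 1: in background
                ("chr1", 4, "C", "T", "het", "ACA"),   # crit 2: depth 15
                ("chr1", 5, "C", "T", "het", "ACA"),   # crit 3: VAF 0.8
                ("chr1", 6, "C", "T", "het", "ACG"),   # crit 4: CpG
                ("chr1", 7, "C", "T", "het", "ACA"),   # crit 4: repeat region
                ("chr1", 8, "C", "T", "het", "ACA"),   # crit 5: seen in two samples
                ("chr1", 9, "A", "G", "het", "CAT"),   # keep
                ("chr1", 10, "C", "T", "het", "ACA"),  # crit 2: depth 150
            ]
        )
        bg_gt = self._genotypes([("chr1", 3, "C", "T", "het", "ACA")])

        def pile(rows):
            return pileup_frame(rows)

        depths = {1: 40, 2: 40, 3: 40, 4: 15, 5: 40, 6: 40, 7: 40, 8: 40, 9: 40, 10: 150}
        test_rows = []
        for pos, d in depths.items():
            vaf_alt = {5: int(0.8 * d)}.get(pos, int(0.5 * d))
            alt = "G" if pos == 9 else "T"
            test_rows.append(("chr1", pos, "C" if pos != 9 else "A", "ACA", d, alt, vaf_alt))
        test_pileup = pile(test_rows)
        other = pile(
            [("chr1", 8, "C", "ACA", 40, "T", 3)]
            + [("chr1", p, "C", "ACA", 40, ".", 0) for p in depths if p != 8]
        )
        background = pile([("chr1", p, "C", "ACA", 40, ".", 0) for p in depths])
        return test_gt, bg_gt, {
            "test": test_pileup,
            "background": background,
            "other": other,
        }

    def test_toy_table_fates(self):
        test_gt, bg_gt, pileups = self._inputs()
        kept, removed = titration_snp_filter(
            test_gt, bg_gt, pileups, repeat_mask=[("chr1", 7, 8)]
        )
        assert kept.keys() == {("chr1", 1, "C", "T"), ("chr1", 9, "A", "G")}
        assert removed["not_het_in_test"] == 1
        assert removed["present_in_background"] == 1
        assert removed["depth_out_of_range"] == 2
        assert removed["vaf_out_of_range"] == 1
        assert removed["repeat_or_cpg"] == 2
        assert removed["multi_sample"] == 1

    def test_missing_depth_is_error(self):
        test_gt, bg_gt, pileups = self._inputs()
        bad = pileups["test"].drop(columns=["depth"])
        with pytest.raises(ValueError, match="criterion 2"):
            titration_snp_filter(test_gt, bg_gt, {"test": bad})


class TestEquivalentVariantCount:
    @pytest.mark.parametrize(
        "n,depth,expected",
        [(2000, 30, 4000), (2000, 60, 2000), (10_000, 120, 5000), (5000, 45, 6667)],
    )
    def test_formula(self, n, depth, expected):
        assert equivalent_variant_count(n, depth) == expected

    def test_requires_positive_depth(self):
        with pytest.raises(ValueError):
            equivalent_variant_count(2000, 0)


class TestMismatchedSpecificity:
    def test_error_free_plasma_is_fully_specific(self, rng):
        pool = _pool(400)
        em = ErrorModel.uniform(0.0)
        plasma = generate_plasma_pileup(
            list(pool), depth=60, cvaf=0.0, error_model=em, seed=1
        )
        df = mismatched_specificity(
            {"s1": plasma},
            pool,
            levels=[1000],
            error_models={"s1": em},
            plasma_depths={"s1": 60.0},
            n_reps=25,
            rng=rng,
        )
        assert df["specificity"].tolist() == [1.0]
        assert df["v_i"].tolist() == [1000]

    def test_own_patient_variants_rejected(self, rng):
        pool = _pool(10)
        own = MarkerSet([pool.entries[0]])
        with pytest.raises(ValueError, match="patient"):
            mismatched_specificity(
                {"s1": pileup_frame([])},
                pool,
                levels=[6],
                error_models={"s1": ErrorModel.uniform(0.0)},
                plasma_depths={"s1": 60.0},
                n_reps=1,
                rng=rng,
                own_variants={"s1": own},
            )

    def test_pool_too_small_is_error(self, rng):
        pool = _pool(10)  # 60 markers total
        with pytest.raises(ValueError, match="too small"):
            mismatched_specificity(
                {"s1": pileup_frame([])},
                pool,
                levels=[2000],
                error_models={"s1": ErrorModel.uniform(0.0)},
                plasma_depths={"s1": 30.0},
                n_reps=1,
                rng=rng,
            )
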