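import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from geostrat.qc import (
    KinshipPairs,
    QCRules,
    apply_variant_qc,
    graded_info_filter,
    hwe_exact_test,
    prune_related,
    recode_traits,
)
from geostrat.simpop import GenotypeMatrix


class TestGradedInfoFilter:
    @pytest.mark.parametrize(
        "maf,info,expected",
        [
            (0.05, 0.4, True),  # common variant, modest INFO suffices
            (0.02, 0.5, False),  # 1-3% band needs INFO > 0.6
            (0.02, 0.7, True),
            (0.007, 0.85, True),  # 0.5-1% band needs INFO > 0.8
            (0.007, 0.75, False),
            (0.002, 0.95, True),  # 0.1-0.5% band needs INFO > 0.9
            (0.002, 0.85, False),
            (0.0005, 0.99, False),  # below the lowest band always fails
        ],
    )
    def test_band_rules(self, maf, info, expected):
        assert graded_info_filter(maf, info) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            graded_info_filter(0.6, 0.5)
        with pytest.raises(ValueError):
            graded_info_filter(0.1, 0.0)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            QCRules(graded_info=[(0.01, 0.5, 0.3), (0.005, 0.02, 0.6)])


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration using binomial coefficients directly."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa
    parity = na % 2
    hs = range(parity, min(na, 2 * n - na) + 1, 2)
    probs = {}
    for h in hs:
        aa = (na - h) // 2
        bb = n - aa - h
        probs[h] = comb(n, aa, exact=True) * comb(n - aa, h, exact=True) * 2**h
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return sum(v for v in probs.values() if v <= p_obs) / total


class TestHweExactTest:
    def test_modal_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(_hwe_oracle(25, 50, 25))
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_is_certain(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 57) == 1.0

    def test_all_heterozygotes_matches_enumeration(self):
        assert hwe_exact_test(0, 100, 0) == pytest.approx(_hwe_oracle(0, 100, 0), rel=1e-12)
        assert hwe_exact_test(0, 100, 0) < 1e-6  # flagrant disequilibrium

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_agrees_with_enumeration(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(_hwe_oracle(a, h, b), rel=1e-10)

    def test_allele_label_symmetry(self):
        assert hwe_exact_test(30, 14, 6) == pytest.approx(hwe_exact_test(6, 14, 30), rel=1e-12)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _matrix(dosages, maf=None, info=None):
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        variants=pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": 1,
            "pos": np.arange(m) * 10_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf if maf is not None else np.full(m, 0.25),
            "info": info if info is not None else np.ones(m),
        }),
        sample_ids=np.array([f"i{k}" for k in range(n)]),
    )


class TestApplyVariantQc:
    def test_clean_matrix_is_identity(self):
        rng = np.random.default_rng(0)
        geno = _matrix(rng.binomial(2, 0.4, size=(200, 5)).astype(float))
        out, log = apply_variant_qc(geno)
        assert log.empty
        np.testing.assert_array_equal(out.dosages, geno.dosages)

    def test_missingness_rule(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        d[:10, 1] = np.nan  # 10% missing
        out, log = apply_variant_qc(_matrix(d))
        assert list(log["variant_id"]) == ["v1"]
        assert list(log["reason"]) == ["missingness"]
        assert out.n_variants == 2

    def test_known_violations_counted(self):
        rng = np.random.default_rng(2)
        cols = [rng.binomial(2, 0.5, 300).astype(float) for _ in range(3)]
        cols.append(np.ones(300))  # all hets: extreme HWE violation
        bad_info = rng.binomial(2, 0.02, 300).astype(float)
        cols.append(bad_info)  # rare variant with low INFO
        d = np.column_stack(cols)
        maf = np.array([0.5, 0.5, 0.5, 0.5, 0.02])
        info = np.array([1.0, 1.0, 1.0, 1.0, 0.4])
        out, log = apply_variant_qc(_matrix(d, maf=maf, info=info))
        reasons = dict(zip(log["variant_id"], log["reason"]))
        assert reasons == {"v3": "hwe", "v4": "info"}
        # survivors keep their original order
        assert list(out.variants["variant_id"]) == ["v0", "v1", "v2"]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(150, 8)).astype(float)
        d[:20, 2] = np.nan
        once, _ = apply_variant_qc(_matrix(d))
        twice, log2 = apply_variant_qc(once)
        assert log2.empty
        np.testing.assert_array_equal(once.dosages, twice.dosages)


class TestPruneRelated:
    def _pairs(self, rows):
        return KinshipPairs(pd.DataFrame(rows, columns=["id_a", "id_b", "kinship"]))

    def test_nothing_above_threshold(self):
        pairs = self._pairs([("a", "b", 0.1), ("b", "c", 0.05)])
        assert prune_related(pairs, 0.125) == {"a", "b", "c"}

    def test_star_graph_removes_hub_only(self):
        rows = [("hub", f"leaf{i}", 0.3) for i in range(5)]
        kept = prune_related(self._pairs(rows), 0.125)
        assert kept == {f"leaf{i}" for i in range(5)}

    def test_tie_removes_lowest_id(self):
        kept = prune_related(self._pairs([("a", "b", 0.5)]), 0.125)
        assert kept == {"b"}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 9), st.integers(0, 9), st.floats(0, 0.5)),
        max_size=20,
    ))
    def test_no_related_pair_survives(self, raw):
        seen, rows = set(), []
        for a, b, k in raw:
            if a == b or (min(a, b), max(a, b)) in seen:
                continue
            seen.add((min(a, b), max(a, b)))
            rows.append((f"n{min(a,b)}", f"n{max(a,b)}", k))
        if not rows:
            return
        pairs = self._pairs(rows)
        kept = prune_related(pairs, 0.125)
        for a, b, k in rows:
            if k > 0.125:
                assert not (a in kept and b in kept)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            self._pairs([("a", "a", 0.2)])


class TestRecodeTraits:
    def test_income_lookup(self):
        raw = pd.DataFrame({"income": [1, 2, 3, 4, 5, -1, -3]})
        out = recode_traits(raw)
        assert list(out["income"][:5]) == [11505, 22495, 41499, 76000, 124000]
        assert out["income"][5:].isna().all()

    def test_unknown_income_category_rejected(self):
        with pytest.raises(ValueError):
            recode_traits(pd.DataFrame({"income": [7]}))

    def test_siblings_missing_if_either_missing(self):
        raw = pd.DataFrame({"brothers": [2, 2, np.nan], "sisters": [1, np.nan, 1]})
        out = recode_traits(raw)
        assert out["siblings"][0] == 3
        assert np.isnan(out["siblings"][1])
        assert np.isnan(out["siblings"][2])

    def test_negative_coordinates_become_missing(self):
        raw = pd.DataFrame({"birth_north": [-1.0, 100.0], "birth_east": [50.0, -3.0]})
        out = recode_traits(raw)
        assert np.isnan(out["birth_north"][0]) and out["birth_north"][1] == 100.0
        assert out["birth_east"][0] == 50.0 and np.isnan(out["birth_east"][1])
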