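"""Phenotype and genotype quality-control rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wssgwas.data import FormatError, GenotypeMatrix
from wssgwas.qc import (
    filter_genotypes,
    filter_phenotypes,
    hwe_exact_p,
    impute_mean,
)


def record(boar="b1", date="2021-01-01", volume=200.0, spmot=80.0, interval=7):
    return {
        "boar_id": boar,
        "collection_date": date,
        "volume_ml": volume,
        "spmot": spmot,
        "interval_days": interval,
    }


def base_records(boar="b1", n=6, start="2021-01-01", **kw):
    dates = pd.date_range(start, periods=n, freq="7D")
    return [record(boar=boar, date=d, **kw) for d in dates]


class TestPhenotypeRules:
    def test_volume_boundary_is_inclusive_removal(self):
        df = pd.DataFrame(
            base_records(n=5)
            + [record(date="2021-06-01", volume=50.0),
               record(date="2021-06-08", volume=51.0)]
        )
        kept, rep = filter_phenotypes(df)
        assert 50.0 not in kept["volume_ml"].values
        assert 51.0 in kept["volume_ml"].values
        assert rep.removed["volume_le_50ml"] == 1

    def test_interval_boundary_strictly_greater(self):
        df = pd.DataFrame(
            base_records(n=5)
            + [record(date="2021-06-01", interval=61),
               record(date="2021-06-08", interval=60)]
        )
        kept, _ = filter_phenotypes(df)
        assert 61 not in kept["interval_days"].values
        assert 60 in kept["interval_days"].values

    def test_low_motility_removed(self):
        df = pd.DataFrame(
            base_records(n=5)
            + [record(date="2021-06-01", spmot=9.9),
               record(date="2021-06-08", spmot=10.0)]
        )
        kept, _ = filter_phenotypes(df)
        assert 9.9 not in kept["spmot"].values
        assert 10.0 in kept["spmot"].values

    def test_same_day_duplicate_keeps_first(self):
        rows = base_records(n=5)
        dup = record(date=rows[0]["collection_date"], volume=999.0)
        df = pd.DataFrame(rows + [dup])
        kept, rep = filter_phenotypes(df)
        assert rep.removed["interval_0_days"] == 1
        assert 999.0 not in kept["volume_ml"].values

    def test_boar_with_exactly_five_passing_records_retained(self):
        df = pd.DataFrame(base_records(n=5))
        kept, _ = filter_phenotypes(df)
        assert len(kept) == 5

    def test_count_rule_applies_after_record_rules(self):
        # 5 records, one removed by volume ⇒ 4 usable ⇒ boar dropped
        rows = base_records(n=4) + [record(date="2021-06-01", volume=40.0)]
        kept, rep = filter_phenotypes(pd.DataFrame(rows))
        assert len(kept) == 0
        assert rep.removed["boar_lt_5_records"] == 4
        assert rep.n_removed + rep.n_retained == rep.n_input

    def test_idempotent(self):
        df = pd.DataFrame(
            base_records(n=8)
            + [record(date="2021-06-01", volume=30.0)]
            + base_records(boar="b2", n=3)
        )
        once, _ = filter_phenotypes(df)
        twice, rep = filter_phenotypes(once)
        assert rep.n_removed == 0
        pd.testing.assert_frame_equal(once, twice)

    def test_record_rules_commute(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(6):
            n = rng.integers(3, 12)
            dates = pd.date_range("2021-01-01", periods=n, freq="5D")
            for d in dates:
                rows.append(
                    record(
                        boar=f"b{b}",
                        date=d,
                        volume=float(rng.uniform(30, 300)),
                        spmot=float(rng.uniform(0, 100)),
                        interval=int(rng.integers(0, 90)),
                    )
                )
        df = pd.DataFrame(rows)
        ref, _ = filter_phenotypes(df)
        shuffled = df.sample(frac=1, random_state=1)
        alt, _ = filter_phenotypes(shuffled)
        key = ["boar_id", "collection_date"]
        assert sorted(map(tuple, ref[key].values.tolist())) == sorted(
            map(tuple, alt[key].values.tolist())
        )

    def test_missing_column_named_in_error(self):
        with pytest.raises(FormatError, match="volume_ml"):
            filter_phenotypes(pd.DataFrame({"boar_id": [], "collection_date": [],
                                            "spmot": [], "interval_days": []}))


def hwe_brute_force(n_het, n_hom1, n_hom2):
    """Exact-combinatorics oracle for the conditional HWE test."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def weight(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            return 0
        # multinomial count of phase assignments: n! / (hr! hc! h!) * 2^h
        return (
            math.factorial(n)
            // (math.factorial(hom_r) * math.factorial(hom_c) * math.factorial(h))
            * 2**h
        )

    hets = [h for h in range(rare % 2, rare + 1, 2)]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_perfect_hwe_counts_give_p_one(self):
        assert hwe_exact_p(50, 25, 25) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [(0, 10, 0), (10, 0, 0), (0, 0, 10), (2, 5, 3), (7, 1, 2), (1, 9, 10)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_brute_force(*counts))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    def test_enumeration_equivalence_property(self, het, hom1, hom2):
        if het + hom1 + hom2 == 0:
            return
        p = hwe_exact_p(het, hom1, hom2)
        assert p == pytest.approx(hwe_brute_force(het, hom1, hom2))
        assert 0 < p <= 1


def make_geno(codes, chrom=None, pos=None):
    codes = np.asarray(codes, dtype=np.int8)
    n_ind, n_snp = codes.shape
    return GenotypeMatrix(
        [f"i{k}" for k in range(n_ind)],
        codes,
        pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(n_snp)],
                "chrom": chrom if chrom is not None else [1] * n_snp,
                "pos": pos if pos is not None else list(range(1000, 1000 + n_snp)),
            }
        ),
    )


class TestGenotypeQC:
    def test_maf_boundary(self):
        rng = np.random.default_rng(0)
        n = 500
        codes = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        # freq 9/1000 < 0.01 removed; 11/1000 retained
        low = np.zeros(n, dtype=np.int8)
        low[:9] = 1
        ok = np.zeros(n, dtype=np.int8)
        ok[:11] = 1
        geno = make_geno(np.column_stack([codes, low, ok]))
        out, rep = filter_genotypes(geno)
        assert rep.snps.removed["maf"] == 1
        assert "s2" not in set(out.snp_map["snp_id"])
        assert "s3" in set(out.snp_map["snp_id"])

    def test_individual_call_rate(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        codes[0, :11] = -1  # 89% call rate
        out, rep = filter_genotypes(make_geno(codes))
        assert rep.individuals.removed["individual_call_rate"] == 1
        assert "i0" not in out.individual_ids

    def test_sex_chromosome_and_unplaced_removed(self):
        codes = np.ones((10, 3), dtype=np.int8)
        codes[::2] = 0
        geno = make_geno(codes, chrom=["1", "X", "1"], pos=[100, 200, -1])
        out, rep = filter_genotypes(geno)
        assert rep.snps.removed["unmapped_or_sex_chromosome"] == 2
        assert list(out.snp_map["snp_id"]) == ["s0"]

    def test_hwe_filter_removes_extreme_disequilibrium(self):
        rng = np.random.default_rng(2)
        good = rng.binomial(2, 0.5, size=(200, 5)).astype(np.int8)
        bad = np.array([0, 2] * 100, dtype=np.int8)[:, None]  # no hets at p=0.5
        out, rep = filter_genotypes(make_geno(np.column_stack([good, bad])))
        assert rep.snps.removed["hwe"] == 1

    def test_imputation_rounds_per_snp_mean(self):
        codes = np.array([[2, 0], [2, -1], [1, 0], [2, 0], [-1, 0]], dtype=np.int8)
        filled = impute_mean(codes)
        assert filled[4, 0] == 2  # mean 1.75 → 2
        assert filled[1, 1] == 0
        assert (filled >= 0).all()

    def test_qc_idempotent(self):
        rng = np.random.default_rng(3)
        codes = rng.binomial(2, rng.uniform(0.1, 0.9, size=50), size=(100, 50)).astype(np.int8)
        once, _ = filter_genotypes(make_geno(codes))
        twice, rep = filter_genotypes(once)
        assert rep.snps.n_removed == 0
        assert rep.individuals.n_removed == 0
        np.testing.assert_array_equal(once.codes, twice.codes)

    def test_all_removed_raises(self):
        codes = np.zeros((50, 2), dtype=np.int8)  # monomorphic, MAF 0
        with pytest.raises(FormatError, match="every SNP"):
            filter_genotypes(make_geno(codes))
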