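"""Genetics tests: HWE exact test, QC, allele alignment, PRS, scans."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

from msqmri import (
    CohortConfig,
    GenotypeMatrix,
    QCThresholds,
    align_effect_alleles,
    compute_prs,
    cross_sectional_config,
    hwe_exact_test,
    nominal_fraction,
    prs_trait_association,
    simulate_cohort,
    simulate_genotypes,
    single_variant_scan,
    variant_qc,
)
from msqmri.cross_sectional import first_scans
from msqmri.errors import DomainError
from msqmri.genetics import AlignedPanel, prs_table


def hwe_oracle_distribution(n: int, n_a: int) -> dict[int, float]:
    """Full-enumeration conditional distribution of heterozygote counts.

    Direct log-factorial formula: P(h | n_A, N) proportional to
    N! / (n_AA! h! n_BB!) * 2^h with n_AA = (n_A - h)/2, n_BB = (n_B - h)/2.
    """
    n_b = 2 * n - n_a
    probs = {}
    for h in range(min(n_a, n_b) + 1):
        if (n_a - h) % 2:
            continue
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        logp = (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(h + 1) - gammaln(nbb + 1)
            + h * math.log(2)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )
        probs[h] = math.exp(logp)
    total = sum(probs.values())
    return {h: p / total for h, p in probs.items()}


def hwe_oracle_p(n_het, n_hom1, n_hom2) -> float:
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het
    dist = hwe_oracle_distribution(n, n_a)
    p_obs = dist[n_het]
    return min(1.0, sum(p for p in dist.values() if p <= p_obs * (1 + 1e-12)))


class TestHweExactTest:
    def test_balanced_excess_heterozygosity_matches_oracle(self):
        p = hwe_exact_test(n_het=80, n_hom1=10, n_hom2=10)
        assert p == pytest.approx(hwe_oracle_p(80, 10, 10), abs=1e-10)

    def test_monomorphic_is_never_significant(self):
        assert hwe_exact_test(0, 100, 0) == 1.0

    def test_hwe_proportions_are_typical(self):
        # 2pq n = 48 hets at p = 0.4, n = 150: right at expectation
        assert hwe_exact_test(72, 54, 24) > 0.5

    def test_gross_deviation_is_extreme(self):
        # no heterozygotes despite intermediate frequency
        assert hwe_exact_test(0, 50, 50) < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            hwe_exact_test(-1, 2, 3)

    @given(st.integers(1, 60), st.integers(0, 120), st.integers(0, 3))
    def test_agrees_with_enumeration_oracle(self, n, n_a, pick):
        n_a = min(n_a, 2 * n)
        dist = hwe_oracle_distribution(n, n_a)
        hets = sorted(dist)
        h = hets[pick % len(hets)]
        hom1 = (n_a - h) // 2
        hom2 = n - hom1 - h
        assert hwe_exact_test(h, hom1, hom2) == pytest.approx(
            hwe_oracle_p(h, hom1, hom2), abs=1e-10)


def _matrix(dosages: np.ndarray, alleles=None, category=None) -> GenotypeMatrix:
    n, v = dosages.shape
    ids = [f"v{j}" for j in range(v)]
    alleles = alleles or [("A", "G")] * v
    meta = pd.DataFrame({
        "chrom": ["1"] * v, "pos": range(1, v + 1),
        "allele_a": [a for a, _ in alleles], "allele_b": [b for _, b in alleles],
        "category": category or ["non-HLA"] * v,
    }, index=pd.Index(ids, name="variant_id"))
    dos = pd.DataFrame(dosages, index=[f"P{i}" for i in range(n)], columns=ids)
    return GenotypeMatrix(dosages=dos, variants=meta)


class TestVariantQC:
    def test_monomorphic_variant_excluded_on_maf(self):
        g = _matrix(np.zeros((100, 1)))
        rep = variant_qc(g)
        assert not rep.table["kept"].iloc[0]
        assert "maf" in rep.table["reason"].iloc[0]

    def test_call_rate_boundary(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        d[:3, 0] = np.nan  # 97/100 < 0.98
        rep = variant_qc(_matrix(d))
        assert rep.table["call_rate"].iloc[0] == pytest.approx(0.97)
        assert not rep.table["kept"].iloc[0]

    def test_hwe_p_matches_enumeration_oracle(self):
        d = np.concatenate([np.zeros(10), np.ones(80), np.full(10, 2.0)])
        rep = variant_qc(_matrix(d.reshape(-1, 1)))
        assert rep.table["hwe_p"].iloc[0] == pytest.approx(hwe_oracle_p(80, 10, 10), abs=1e-10)

    def test_all_missing_variant_reported_as_no_data(self):
        d = np.full((50, 1), np.nan)
        rep = variant_qc(_matrix(d))
        assert rep.table["reason"].iloc[0] == "no data"

    def test_kept_set_invariant_to_orderings(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 30), size=(80, 30)).astype(float)
        g = _matrix(d)
        kept = set(variant_qc(g).kept_ids)
        perm_p = rng.permutation(80)
        perm_v = rng.permutation(30)
        g2 = GenotypeMatrix(
            dosages=g.dosages.iloc[perm_p, perm_v], variants=g.variants.iloc[perm_v])
        assert set(variant_qc(g2).kept_ids) == kept


class TestAlleleAlignment:
    def _weights(self, rows):
        return pd.DataFrame(rows).set_index("variant_id")

    def test_already_aligned_risk_allele(self):
        g = _matrix(np.array([[0.0], [1.0], [2.0]]))
        w = self._weights([{"variant_id": "v0", "effect_allele": "G",
                            "other_allele": "A", "odds_ratio": 2.0}])
        panel = align_effect_alleles(g, w)
        assert panel.dosages["v0"].tolist() == [0.0, 1.0, 2.0]
        assert panel.weights.loc["v0", "log_or"] == pytest.approx(math.log(2))

    def test_protective_allele_inverted(self):
        g = _matrix(np.array([[0.0], [1.0], [2.0]]))
        w = self._weights([{"variant_id": "v0", "effect_allele": "G",
                            "other_allele": "A", "odds_ratio": 0.5}])
        panel = align_effect_alleles(g, w)
        assert panel.dosages["v0"].tolist() == [2.0, 1.0, 0.0]
        assert panel.weights.loc["v0", "risk_allele"] == "A"
        assert panel.weights.loc["v0", "log_or"] == pytest.approx(math.log(2))

    def test_allele_set_mismatch_drops_variant(self):
        g = _matrix(np.array([[1.0]]), alleles=[("A", "G")])
        w = self._weights([{"variant_id": "v0", "effect_allele": "C",
                            "other_allele": "T", "odds_ratio": 1.5}])
        panel = align_effect_alleles(g, w)
        assert len(panel.weights) == 0
        assert panel.dropped["reason"].tolist() == ["allele mismatch"]

    def test_random_flips_match_per_variant_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        n, v = 30, 20
        bases = np.array(list("ACGT"))
        alleles = []
        for _ in range(v):
            i, j = rng.choice(4, 2, replace=False)
            alleles.append((bases[i], bases[j]))
        d = rng.binomial(2, 0.4, size=(n, v)).astype(float)
        g = _matrix(d, alleles=alleles)
        eff_is_b = rng.random(v) < 0.5
        ors = np.exp(rng.normal(0, 0.4, v))
        w = self._weights([
            {"variant_id": f"v{j}",
             "effect_allele": alleles[j][1] if eff_is_b[j] else alleles[j][0],
             "other_allele": alleles[j][0] if eff_is_b[j] else alleles[j][1],
             "odds_ratio": ors[j]}
            for j in range(v)])
        panel = align_effect_alleles(g, w)
        score = compute_prs(panel, "all")
        # oracle: count the risk allele per variant by hand
        expected = np.zeros(n)
        for j in range(v):
            orr = ors[j]
            eff = w.iloc[j]["effect_allele"]
            risk = eff if orr >= 1 else (alleles[j][0] if eff == alleles[j][1] else alleles[j][1])
            lor = abs(math.log(orr))
            dos_b = d[:, j]
            risk_count = dos_b if risk == alleles[j][1] else 2 - dos_b
            expected += risk_count * lor
        assert np.allclose(score.to_numpy(), expected, atol=1e-12)


class TestComputePrs:
    def _null_panel(self, seed=3):
        cfg = CohortConfig(seed=seed)
        ids = [f"P{i}" for i in range(40)]
        g, w = simulate_genotypes(cfg, ids)
        return align_effect_alleles(g, w)

    def test_zero_dosages_give_zero_score(self):
        g = _matrix(np.zeros((5, 3)))
        w = pd.DataFrame({
            "effect_allele": ["G"] * 3, "other_allele": ["A"] * 3,
            "odds_ratio": [1.5, 2.0, 3.0], "category": ["non-HLA"] * 3,
        }, index=pd.Index([f"v{j}" for j in range(3)], name="variant_id"))
        panel = align_effect_alleles(g, w)
        assert (compute_prs(panel, "all") == 0).all()

    def test_unit_case_two_copies_of_e_odds(self):
        g = _matrix(np.array([[2.0]]))
        w = pd.DataFrame({"effect_allele": ["G"], "other_allele": ["A"],
                          "odds_ratio": [math.e]},
                         index=pd.Index(["v0"], name="variant_id"))
        panel = align_effect_alleles(g, w)
        assert compute_prs(panel, "all").iloc[0] == pytest.approx(2.0)

    def test_additivity_over_hla_partition(self):
        panel = self._null_panel()
        total = compute_prs(panel, "all")
        parts = compute_prs(panel, "HLA") + compute_prs(panel, "non-HLA")
        assert np.allclose(total, parts, atol=1e-9)

    def test_allele_label_flip_invariance(self):
        cfg = CohortConfig(seed=4)
        ids = [f"P{i}" for i in range(30)]
        g, w = simulate_genotypes(cfg, ids)
        base = compute_prs(align_effect_alleles(g, w), "all")
        rng = np.random.default_rng(5)
        flip = rng.random(g.n_variants) < 0.5
        dos = g.dosages.copy()
        var = g.variants.copy()
        for j, vid in enumerate(dos.columns):
            if flip[j]:
                dos[vid] = 2.0 - dos[vid]
                var.loc[vid, ["allele_a", "allele_b"]] = (
                    var.loc[vid, "allele_b"], var.loc[vid, "allele_a"])
        flipped = compute_prs(align_effect_alleles(
            GenotypeMatrix(dosages=dos, variants=var), w), "all")
        assert np.allclose(base, flipped, atol=1e-12)

    def test_missing_dosage_skipped_or_mean_imputed(self):
        g = _matrix(np.array([[0.0, 2.0], [np.nan, 2.0], [2.0, 2.0]]))
        w = pd.DataFrame({
            "effect_allele": ["G", "G"], "other_allele": ["A", "A"],
            "odds_ratio": [math.e, math.e]},
            index=pd.Index(["v0", "v1"], name="variant_id"))
        panel = align_effect_alleles(g, w)
        skip = compute_prs(panel, "all", missing="skip")
        assert skip.iloc[1] == pytest.approx(2.0)  # only v1 contributes
        mean = compute_prs(panel, "all", missing="mean")
        assert mean.iloc[1] == pytest.approx(2.0 + 1.0)  # imputed with mean d = 1

    def test_empty_subset_is_a_domain_error(self):
        panel = self._null_panel()
        panel.weights = panel.weights[panel.weights["category"] == "non-HLA"]
        with pytest.raises(DomainError):
            compute_prs(panel, "HLA")


@pytest.fixture(scope="module")
def cohort():
    cfg = cross_sectional_config(seed=71)
    patients, scans = simulate_cohort(cfg)
    table = first_scans(scans, patients).set_index("patient_id")
    g, w = simulate_genotypes(cfg, list(table.index))
    panel = align_effect_alleles(g, w)
    return table, panel


class TestAssociationScans:

    def test_planted_effect_recovered(self, cohort):
        table, panel = cohort
        scores = prs_table(panel)
        table = table.copy()
        table["wm_pct"] = 0.7 * scores["prs_all"] + 1.0
        res = prs_trait_association(scores[["prs_all"]], table, traits=["wm_pct"])
        assert res["p"].iloc[0] < 1e-50
        assert res["beta"].iloc[0] == pytest.approx(0.7, abs=1e-9)

    def test_permuted_score_destroys_association(self, cohort):
        table, panel = cohort
        rng = np.random.default_rng(6)
        scores = prs_table(panel)
        table = table.copy()
        table["wm_pct"] = 0.7 * scores["prs_all"] + rng.normal(size=len(table))
        shuffled = scores.copy()
        shuffled["prs_all"] = rng.permutation(scores["prs_all"].to_numpy())
        res = prs_trait_association(shuffled[["prs_all"]], table, traits=["wm_pct"])
        assert res["p"].iloc[0] > 1e-3

    def test_null_prs_associations_mostly_nonsignificant(self, cohort):
        table, panel = cohort
        scores = prs_table(panel)
        res = prs_trait_association(scores, table)
        assert len(res) == 30  # 10 traits x {all, HLA, non-HLA}
        threshold = 0.05 / 106
        assert (res["p"] <= threshold).sum() == 0
        assert (res["p"] < 0.05).mean() < 0.25

    def test_single_variant_scan_counts_and_monomorphic_skip(self, cohort):
        table, panel = cohort
        # restrict to a small panel for speed; force one monomorphic variant
        ids = list(panel.weights.index[:5])
        small = AlignedPanel(
            dosages=panel.dosages[ids].copy(),
            weights=panel.weights.loc[ids].copy(),
            dropped=panel.dropped,
        )
        small.dosages[ids[0]] = 0.0
        results, summary = single_variant_scan(small, table, traits=["wm_pct", "gm_pct"])
        assert len(results) == 10
        untested = results[~results["tested"]]
        assert set(untested["variant_id"]) == {ids[0]}
        tested_n = int(summary["n_tests"].sum())
        assert tested_n == 8  # 4 polymorphic variants x 2 traits


class TestNominalFraction:
    def test_paper_style_percentages(self):
        assert round(nominal_fraction(60, 1330), 2) == 4.51
        assert round(nominal_fraction(6, 220), 1) == 2.7

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            nominal_fraction(1, 0)
        with pytest.raises(DomainError):
            nominal_fraction(5, 4)


class TestGenotypeIO:
    def test_tsv_round_trip(self, tmp_path):
        cfg = CohortConfig(seed=8, n_variants=12, n_hla=3)
        g, _ = simulate_genotypes(cfg, [f"P{i}" for i in range(9)])
        g.to_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
        back = GenotypeMatrix.from_tsv(tmp_path / "d.tsv", tmp_path / "v.tsv")
        pd.testing.assert_frame_equal(back.dosages, g.dosages)
        assert list(back.variants["category"]) == list(g.variants["category"])

    def test_vcf_round_trip_via_cyvcf2(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        cfg = CohortConfig(seed=9, n_variants=8, n_hla=2)
        g, _ = simulate_genotypes(cfg, [f"P{i}" for i in range(7)])
        g.dosages.iloc[0, 0] = np.nan
        path = tmp_path / "g.vcf"
        g.to_vcf(path)
        back = GenotypeMatrix.from_vcf(
            path, category_map=g.variants["category"].to_dict())
        assert np.allclose(back.dosages.to_numpy(), g.dosages.to_numpy(), equal_nan=True)
        assert list(back.variants.index) == list(g.variants.index)
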