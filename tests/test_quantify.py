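"""Normalization, protein/site quantification, classification, crosstalk."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kcrtools import (
    GroundTruth,
    ProteinRecord,
    QuantConfig,
    SiteResult,
    crosstalk,
    digest_proteome,
    generate_proteome,
    mean_normalize,
    quantify_proteins,
    quantify_sites,
    simulate_intensities,
)
from kcrtools.quantify import (
    DOWN,
    UNCHANGED,
    UNQUANTIFIED,
    UP,
    ProteinResult,
    _classify,
)


def _pep_table(rows, design):
    records = []
    for i, (pid, uniq, vals) in enumerate(rows):
        records.append(
            {"peptide_seq": f"PEPTIDE{i}", "protein_id": pid, "is_unique": uniq,
             **dict(zip(design.channel_labels, vals))}
        )
    return pd.DataFrame(records)


def _site_table(rows, design):
    records = []
    for pid, pos, loc, vals in rows:
        records.append(
            {"protein_id": pid, "position": pos, "window": "_" * 21,
             "localization_prob": loc, **dict(zip(design.channel_labels, vals))}
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Mean normalization
# ---------------------------------------------------------------------------

class TestMeanNormalize:
    def test_equal_means_is_fixed_point(self, design):
        rng = np.random.default_rng(0)
        base = rng.lognormal(10, 1, size=50)
        df = _pep_table(
            [("P1", 1, [v] * 6) for v in base], design
        )
        out = mean_normalize(df, design)
        for ch in design.channel_labels:
            assert np.allclose(out[ch], df[ch])

    def test_restores_scaled_channel(self, design):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(10, 1, size=(40, 6))
        df = _pep_table(
            [("P1", 1, list(v)) for v in vals], design
        )
        scaled = df.copy()
        ch0 = design.channel_labels[0]
        scaled[ch0] = scaled[ch0] * 10.0
        out = mean_normalize(scaled, design)
        ref = mean_normalize(df, design)
        # ratios of the rescaled channel to the others return to originals
        for ch in design.channel_labels[1:]:
            assert np.allclose(out[ch0] / out[ch], ref[ch0] / ref[ch])

    def test_channel_means_equalized(self, design):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(12, 1.5, size=(50, 6))
        df = _pep_table([("P", 1, list(v)) for v in vals], design)
        out = mean_normalize(df, design)
        means = [out[ch].mean() for ch in design.channel_labels]
        grand = np.mean([df[ch].mean() for ch in design.channel_labels])
        assert np.allclose(means, grand)

    def test_missing_cells_stay_missing(self, design):
        df = _pep_table([("P", 1, [1, 2, np.nan, 4, 5, 6])], design)
        df2 = _pep_table([("P", 1, [2, 2, 2, 2, 2, 2])], design)
        out = mean_normalize(pd.concat([df, df2], ignore_index=True), design)
        assert np.isnan(out.iloc[0][design.channel_labels[2]])

    def test_all_missing_channel_named_in_error(self, design):
        df = _pep_table([("P", 1, [1, 2, np.nan, 4, 5, 6])], design)
        with pytest.raises(ValueError, match=design.channel_labels[2]):
            mean_normalize(df, design)


# ---------------------------------------------------------------------------
# Protein quantification
# ---------------------------------------------------------------------------

class TestQuantifyProteins:
    def test_single_peptide_exact_doubling(self, design):
        df = _pep_table([("P1", 1, [2, 2, 2, 4, 4, 4])], design)
        (res,) = quantify_proteins(df, design)
        assert res.ratio == pytest.approx(2.0)
        assert res.log2_ratio == pytest.approx(1.0)

    def test_protein_ratio_is_median_of_unique_peptides(self, design):
        df = _pep_table(
            [
                ("P1", 1, [2, 2, 2, 2, 2, 2]),       # ratio 1.0
                ("P1", 1, [2, 2, 2, 4, 4, 4]),       # ratio 2.0
                ("P1", 1, [1, 1, 1, 9, 9, 9]),       # ratio 9.0
            ],
            design,
        )
        (res,) = quantify_proteins(df, design)
        assert res.ratio == pytest.approx(2.0)
        assert res.n_unique_peptides == 3

    def test_non_unique_peptides_ignored(self, design):
        df = _pep_table(
            [("P1", 1, [2, 2, 2, 4, 4, 4]), ("P1", 0, [1, 1, 1, 99, 99, 99])],
            design,
        )
        (res,) = quantify_proteins(df, design)
        assert res.ratio == pytest.approx(2.0)
        assert res.n_unique_peptides == 1

    def test_missingness_rule_unquantified(self, design):
        # 1 of 3 CK values present < min_values_per_group=2
        df = _pep_table([("P1", 1, [2, np.nan, np.nan, 4, 4, 4])], design)
        (res,) = quantify_proteins(df, design)
        assert res.reg_class == UNQUANTIFIED
        assert res.ratio is None and res.p_value is None

    def test_group_mean_over_nonmissing(self, design):
        df = _pep_table([("P1", 1, [2, 4, np.nan, 6, 6, 6])], design)
        (res,) = quantify_proteins(df, design)
        assert res.ratio == pytest.approx(6.0 / 3.0)

    def test_null_type_one_error_calibrated(self, design):
        # generator null: no effects; t-test should reject ~alpha of the time
        proteome = generate_proteome(1000, (100, 250), seed=99)
        peptides = digest_proteome(proteome)
        pep, _ = simulate_intensities(
            proteome, peptides, [], GroundTruth(), design,
            noise_sd=0.25, seed=100,
        )
        results = quantify_proteins(mean_normalize(pep, design), design)
        pvals = [r.p_value for r in results if r.p_value is not None]
        rate = np.mean([p < 0.05 for p in pvals])
        assert 0.03 <= rate <= 0.07


# ---------------------------------------------------------------------------
# Site quantification and proteome normalization
# ---------------------------------------------------------------------------

def _prot_result(pid, ratio, p=0.5):
    return ProteinResult(
        pid, ratio, math.log2(ratio) if ratio else None, p, 1,
        UNCHANGED if ratio else UNQUANTIFIED,
    )


class TestQuantifySites:
    def test_protein_level_artifact_removed(self, design):
        table = _site_table([("P1", 1, 0.95, [2, 2, 2, 4, 4, 4])], design)
        (res,) = quantify_sites(table, [_prot_result("P1", 2.0)], design)
        assert res.raw_ratio == pytest.approx(2.0)
        assert res.norm_ratio == pytest.approx(1.0)
        assert res.reg_class == UNCHANGED

    def test_pure_site_effect_classified_up(self, design):
        vals = [2, 2.01, 1.99, 6, 6.02, 5.99]
        table = _site_table([("P1", 1, 0.95, vals)], design)
        (res,) = quantify_sites(table, [_prot_result("P1", 1.0)], design)
        assert res.norm_ratio == pytest.approx(3.0, rel=1e-2)
        assert res.p_value < 0.05
        assert res.reg_class == UP

    def test_localization_filter_excludes_ambiguous_sites(self, design):
        rows = [
            ("P1", 1, 0.74, [2, 2, 2, 4, 4, 4]),
            ("P1", 5, 0.76, [2, 2, 2, 4, 4, 4]),
        ]
        results = quantify_sites(_site_table(rows, design), [_prot_result("P1", 1.0)], design)
        assert [r.position for r in results] == [5]

    def test_unquantified_parent_flags_raw_classification(self, design):
        table = _site_table([("P1", 1, 0.95, [2, 2, 2, 4, 4, 4])], design)
        (res,) = quantify_sites(table, [_prot_result("P1", None)], design)
        assert res.norm_ratio is None and not res.normalized
        assert res.raw_ratio == pytest.approx(2.0)

    def test_non_lysine_position_rejected(self, design):
        prot = ProteinRecord("P1", "AAAKAAA")
        table = _site_table([("P1", 2, 0.95, [1] * 6)], design)
        with pytest.raises(ValueError, match=r"position 2 of protein 'P1'"):
            quantify_sites(table, [], design, proteins=[prot])

    def test_ratio_factorization_invariant(self, design):
        rng = np.random.default_rng(12)
        rows = [
            (f"P{i}", 1, 0.95, list(rng.lognormal(10, 1, 6))) for i in range(30)
        ]
        prots = [_prot_result(f"P{i}", float(rng.uniform(0.5, 2.0))) for i in range(30)]
        ratios = {p.protein_id: p.ratio for p in prots}
        for res in quantify_sites(_site_table(rows, design), prots, design):
            if res.norm_ratio is not None:
                assert abs(res.norm_ratio * ratios[res.protein_id] - res.raw_ratio) \
                    <= 1e-9 * abs(res.raw_ratio)

    def test_planted_site_effect_recovery(self, design):
        # 40 planted +1.5 log2 site effects at noise_sd 0.2: >=90% called up,
        # <=5% of null sites called differential. Regulation is planted
        # sign-balanced (up- and down-regulated site counts nearly equal, as
        # real PTM surveys report) and sparse, the regime in which
        # per-channel mean normalization is valid.
        proteome = generate_proteome(600, (150, 300), seed=40)
        from kcrtools import plant_sites_and_motifs

        proteome, sites, truth = plant_sites_and_motifs(proteome, 0.08, [], seed=41)
        planted = sites[:40]
        for key in sites:
            truth.site_effects[key] = 0.0
        for key in planted:
            truth.site_effects[key] = 1.5
        for key in sites[40:80]:
            truth.site_effects[key] = -1.5
        for p in proteome:
            truth.protein_effects[p.protein_id] = 0.0
        peptides = digest_proteome(proteome)
        pep, site = simulate_intensities(
            proteome, peptides, sites, truth, design, noise_sd=0.2, seed=42
        )
        prot_res = quantify_proteins(mean_normalize(pep, design), design)
        site_res = quantify_sites(
            mean_normalize(site, design, reference=pep), prot_res, design
        )
        planted_set = set(planted)
        regulated = set(sites[:80])
        planted_seen = [r for r in site_res if (r.protein_id, r.position) in planted_set]
        null_seen = [
            r for r in site_res
            if (r.protein_id, r.position) not in regulated and r.raw_ratio is not None
        ]
        assert len(planted_seen) >= 25  # localization filter drops a minority
        up_rate = np.mean([r.reg_class == UP for r in planted_seen])
        fp_rate = np.mean([r.reg_class in (UP, DOWN) for r in null_seen])
        assert up_rate >= 0.90
        assert fp_rate <= 0.05


# ---------------------------------------------------------------------------
# Classification properties
# ---------------------------------------------------------------------------

class TestClassification:
    @given(
        ratio=st.floats(0.01, 100.0),
        p=st.floats(1e-12, 1.0),
        fc=st.floats(1.01, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_exhaustive_and_exclusive(self, ratio, p, fc):
        config = QuantConfig(fc_threshold=fc)
        cls = _classify(ratio, p, config)
        assert cls in (UP, DOWN, UNCHANGED)
        if cls == UP:
            assert ratio > fc and p < config.alpha
        if cls == DOWN:
            assert ratio < 1 / fc and p < config.alpha

    @given(
        ratio=st.floats(0.01, 100.0),
        p=st.floats(1e-12, 1.0),
        fc1=st.floats(1.01, 3.0),
        delta=st.floats(0.0, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_never_creates_calls(self, ratio, p, fc1, delta):
        c1 = _classify(ratio, p, QuantConfig(fc_threshold=fc1))
        c2 = _classify(ratio, p, QuantConfig(fc_threshold=fc1 + delta))
        if c1 == UNCHANGED:
            assert c2 == UNCHANGED

    def test_scale_invariance_through_normalization(self, design):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(12, 1, size=(40, 6))
        df = _pep_table([(f"P{i}", 1, list(v)) for i, v in enumerate(vals)], design)
        scaled = df.copy()
        ch = design.channel_labels[4]
        scaled[ch] = scaled[ch] * 7.5
        res_a = quantify_proteins(mean_normalize(df, design), design)
        res_b = quantify_proteins(mean_normalize(scaled, design), design)
        for a, b in zip(res_a, res_b):
            assert a.ratio == pytest.approx(b.ratio)
            assert a.p_value == pytest.approx(b.p_value)
            assert a.reg_class == b.reg_class


# ---------------------------------------------------------------------------
# Crosstalk
# ---------------------------------------------------------------------------

def _site(pid, pos, norm_ratio, cls):
    return SiteResult(pid, pos, norm_ratio, norm_ratio, 0.01, cls, True)


class TestCrosstalk:
    def test_sign_agreement_is_consistent_quadrant_1(self):
        prot = [_prot_result("P1", 2.0, p=0.01)]
        prot[0].reg_class = UP
        records, counts = crosstalk(prot, [_site("P1", 3, 1.8, UP)])
        (rec,) = records
        assert rec.relation == "consistent"
        assert rec.quadrant == 1
        assert counts["consistent"] == 1

    def test_sign_disagreement_is_opposite_quadrant_2(self):
        prot = [_prot_result("P1", 0.5, p=0.01)]
        prot[0].reg_class = DOWN
        records, counts = crosstalk(prot, [_site("P1", 3, 1.8, UP)])
        (rec,) = records
        assert rec.relation == "opposite"
        assert rec.quadrant == 2
        assert counts["opposite"] == 1

    def test_one_sided_proteins_flagged(self):
        prot = [_prot_result("P1", 2.0), _prot_result("P2", 1.0)]
        records, counts = crosstalk(prot, [_site("P2", 1, 1.0, UNCHANGED),
                                           _site("P3", 1, 1.0, UNCHANGED)])
        by_id = {r.protein_id: r.relation for r in records}
        assert by_id["P1"] == "protein_only"
        assert by_id["P3"] == "site_only"
        assert counts["overlap"] == 1

    def test_planted_anticorrelation_dominates(self, design):
        # differential proteins with sites pushed the other way (signs
        # balanced across proteins so mean normalization stays unbiased):
        # opposite calls must outnumber consistent ones
        proteome = generate_proteome(200, (150, 300), seed=80)
        from kcrtools import plant_sites_and_motifs

        proteome, sites, truth = plant_sites_and_motifs(proteome, 0.08, [], seed=81)
        de = {p.protein_id: (1.0 if i % 2 else -1.0)
              for i, p in enumerate(proteome[:50])}
        for p in proteome:
            truth.protein_effects[p.protein_id] = de.get(p.protein_id, 0.0)
        for pid, pos in sites:
            truth.site_effects[(pid, pos)] = -2.0 * de.get(pid, 0.0)
        peptides = digest_proteome(proteome)
        pep, site = simulate_intensities(
            proteome, peptides, sites, truth, design, noise_sd=0.2, seed=82
        )
        prot_res = quantify_proteins(mean_normalize(pep, design), design)
        site_res = quantify_sites(
            mean_normalize(site, design, reference=pep), prot_res, design
        )
        _, counts = crosstalk(prot_res, site_res)
        assert counts["opposite"] > counts["consistent"]
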