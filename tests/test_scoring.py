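"""Transcriptome scoring: pathway scores, PC1 activity signatures,
longitudinal trajectories and signature-space clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from metabostate.scoring import (
    GeneSets,
    activity_signature,
    pathway_score,
    signature_clusters,
    signature_trajectory,
)
from metabostate.synth import CohortDesign, generate_expression


def frame(data, samples=None):
    df = pd.DataFrame(data).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestPathwayScore:
    def test_two_gene_hand_example(self):
        """g1=(1,3), g2=(2,6): both z-score to -/+ 1/sqrt(2) with the
        n-1 denominator, so the mean score is (-0.7071, +0.7071)."""
        expr = frame({"g1": [1.0, 3.0], "g2": [2.0, 6.0]})
        scores = pathway_score(expr, ["g1", "g2"])
        np.testing.assert_allclose(scores.to_numpy(),
                                   [-0.70710678, 0.70710678], atol=1e-8)

    def test_scores_centred_and_affine_invariant(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, size=(6, 8)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(8)])
        genes = ["g0", "g2", "g4"]
        scores = pathway_score(expr, genes)
        assert scores.sum() == pytest.approx(0.0, abs=1e-10)
        transformed = expr.mul(pd.Series(rng.uniform(0.5, 3, 6), index=expr.index),
                               axis=0).add(pd.Series(rng.normal(0, 4, 6),
                                                     index=expr.index), axis=0)
        np.testing.assert_allclose(pathway_score(transformed, genes), scores,
                                   atol=1e-10)

    def test_gene_and_sample_order_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 6)),
                            index=list("abcde"), columns=[f"s{j}" for j in range(6)])
        ref = pathway_score(expr, ["a", "b", "c"])
        shuffled = expr.iloc[::-1, ::-1]
        got = pathway_score(shuffled, ["c", "a", "b"])
        np.testing.assert_allclose(got[ref.index], ref, atol=1e-12)

    def test_missing_and_constant_genes_dropped(self, caplog):
        expr = frame({"g1": [1.0, 3.0, 2.0], "flat": [2.0, 2.0, 2.0]})
        with caplog.at_level("WARNING"):
            scores = pathway_score(expr, ["g1", "flat", "ghost"])
        hand = (expr.loc["g1"] - 2.0) / 1.0  # mean 2, sd(n-1)=1
        np.testing.assert_allclose(scores, hand, atol=1e-12)
        assert "ghost" in caplog.text and "flat" in caplog.text

    def test_all_unusable_genes_error(self):
        expr = frame({"flat": [1.0, 1.0]})
        with pytest.raises(ValueError):
            pathway_score(expr, ["flat", "ghost"])


class TestActivitySignature:
    def _cohort(self, seed, n=30, snr=2.0, negate=False):
        design = CohortDesign(n_subjects=n, beta_ampk=snr, noise_sd=1.0, seed=seed)
        gs = GeneSets.from_gmt()
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal((n, 1))
        expr, truth = generate_expression(
            design, gs, latent_ampk=-latent if negate else latent,
            latent_hif1=rng.standard_normal((n, 1)), rng=rng)
        return expr, (-latent if negate else latent).ravel(), gs

    def test_recovers_latent_activity_at_snr_two(self):
        rhos = []
        for seed in range(5):
            expr, latent, gs = self._cohort(seed)
            sig = activity_signature(expr, gs.ampk_targets)
            rhos.append(spearmanr(sig.scores, latent).statistic)
        assert min(rhos) >= 0.9

    def test_orientation_follows_latent_sign(self):
        expr, latent, gs = self._cohort(3)
        expr_neg, latent_neg, _ = self._cohort(3, negate=True)
        sig = activity_signature(expr, gs.ampk_targets)
        sig_neg = activity_signature(expr_neg, gs.ampk_targets)
        assert np.corrcoef(sig.scores, latent)[0, 1] > 0
        assert np.corrcoef(sig_neg.scores, latent_neg)[0, 1] > 0

    def test_duplicating_samples_preserves_signature_pattern(self):
        """Duplicating every sample leaves the signature unchanged up to
        the deterministic rescaling of the n-1 standardization (each
        gene's sample sd shrinks by the same known factor)."""
        n = 10
        expr, _, gs = self._cohort(1, n=n)
        dup = pd.concat([expr, expr.add_suffix("_copy", axis=1)], axis=1)
        sig = activity_signature(expr, gs.ampk_targets).scores
        sig_dup = activity_signature(dup, gs.ampk_targets).scores
        # sd_2n / sd_n = sqrt((n-1)/(n-0.5)) for a duplicated sample set
        factor = np.sqrt((n - 0.5) / (n - 1))
        np.testing.assert_allclose(sig_dup[sig.index], factor * sig, atol=1e-8)
        np.testing.assert_allclose(sig_dup[sig.index + "_copy"].to_numpy(),
                                   factor * sig.to_numpy(), atol=1e-8)

    def test_signature_is_centred(self):
        expr, _, gs = self._cohort(2)
        sig = activity_signature(expr, gs.ampk_targets)
        assert sig.scores.sum() == pytest.approx(0.0, abs=1e-8)
        assert 0 < sig.variance_explained <= 1

    def test_too_few_usable_genes_error(self):
        expr = frame({"g1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            activity_signature(expr, ["g1", "ghost"])


class TestSignatureTrajectory:
    def _cohort(self, gs, a_by_subject, h_by_subject, seed=0):
        n, nT = a_by_subject.shape
        design = CohortDesign(n_subjects=n, timepoints=tuple(range(nT)),
                              noise_sd=0.3, seed=seed)
        expr, truth = generate_expression(design, gs, latent_ampk=a_by_subject,
                                          latent_hif1=h_by_subject,
                                          rng=np.random.default_rng(seed))
        return expr, truth[["subject", "time"]]

    def test_planted_decrease_counts_recovered(self, gene_sets):
        down = np.linspace(1.5, -1.5, 3)
        a = np.vstack([down] * 6 + [-down])
        h = np.vstack([down] * 7)
        expr, meta = self._cohort(gene_sets, a, h)
        res = signature_trajectory(expr, meta, gene_sets)
        assert res.both_decrease_count == 6
        assert res.flags["hif1_decrease"].sum() == 7

    def test_constant_subjects_never_flagged(self, gene_sets):
        # subjects differ but are exactly constant in time, no noise:
        # last - first is exactly zero on both axes
        offsets = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        a = np.tile(offsets[:, None], (1, 3))
        design = CohortDesign(n_subjects=5, timepoints=(0, 1, 2),
                              noise_sd=0.0, seed=4)
        expr, truth = generate_expression(design, gene_sets, latent_ampk=a,
                                          latent_hif1=a,
                                          rng=np.random.default_rng(4))
        res = signature_trajectory(expr, truth[["subject", "time"]], gene_sets)
        assert res.both_decrease_count == 0
        assert not res.flags.any().any()

    def test_flags_invariant_to_subject_order(self, gene_sets):
        down = np.linspace(1.0, -1.0, 3)
        a = np.vstack([down, -down, down, down])
        expr, meta = self._cohort(gene_sets, a, np.vstack([down] * 4), seed=7)
        res = signature_trajectory(expr, meta, gene_sets)
        perm = np.random.default_rng(0).permutation(expr.shape[1])
        res_perm = signature_trajectory(expr.iloc[:, perm], meta, gene_sets)
        pd.testing.assert_frame_equal(res.flags.sort_index(),
                                      res_perm.flags.sort_index())

    def test_single_timepoint_subject_excluded(self, gene_sets):
        down = np.linspace(1.0, -1.0, 2)
        a = np.vstack([down, down])
        expr, meta = self._cohort(gene_sets, a, a, seed=2)
        solo = expr.columns[meta["subject"] == "S01"][:1]
        keep = list(expr.columns[meta["subject"] == "S00"]) + list(solo)
        res = signature_trajectory(expr[keep], meta.loc[keep], gene_sets)
        assert res.excluded_subjects == ("S01",)
        assert "S01" not in res.flags.index


class TestSignatureClusters:
    def _blobs(self, seed=0, n_per=25, sd=0.15):
        rng = np.random.default_rng(seed)
        centres = [(2, -2), (-2, 2), (2, 2), (-2, -2)]
        pts = np.vstack([c + sd * rng.standard_normal((n_per, 2)) for c in centres])
        truth = np.repeat(["O-like", "W-like", "hybrid", "L/L-like"], n_per)
        return pd.DataFrame(pts, columns=["ampk", "hif1"]), truth

    def test_quadrant_annotation_perfect_on_planted_blobs(self):
        sig, truth = self._blobs()
        res = signature_clusters(sig, k=4, seed=1)
        got = np.array([res.quadrants[c] for c in res.labels])
        assert (got == truth).all()

    def test_stable_across_seeded_restarts(self):
        sig, truth = self._blobs(seed=3)
        results = [signature_clusters(sig, k=4, seed=s) for s in range(10)]
        for res in results:
            got = np.array([res.quadrants[c] for c in res.labels])
            assert (got == truth).all()

    def test_degenerate_identical_samples_rejected(self):
        sig = pd.DataFrame(np.ones((10, 2)), columns=["ampk", "hif1"])
        with pytest.raises(ValueError):
            signature_clusters(sig, k=4)


class TestGeneSets:
    def test_shipped_sets_have_stated_sizes_and_disjointness(self, gene_sets):
        assert len(gene_sets.tca_enzymes) == 10
        assert len(gene_sets.glycolysis_enzymes) == 8
        assert len(gene_sets.fao_enzymes) == 14
        signature = set(gene_sets.ampk_targets) | set(gene_sets.hif1_targets)
        enzymes = (set(gene_sets.tca_enzymes) | set(gene_sets.glycolysis_enzymes)
                   | set(gene_sets.fao_enzymes))
        assert not (signature & enzymes)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            GeneSets(ampk_targets=("CS",), hif1_targets=("VEGFA",),
                     tca_enzymes=("CS",), glycolysis_enzymes=("HK2",),
                     fao_enzymes=("CPT1A",))

    def test_gmt_round_trip(self, gene_sets, tmp_path):
        path = tmp_path / "sets.gmt"
        gene_sets.to_gmt(path)
        assert GeneSets.from_gmt(path) == gene_sets
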