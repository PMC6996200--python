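import itertools

import numpy as np
import pandas as pd
import pytest

from scai import (GenomicAnnotation, candidate_loci, fold_enrichment,
                  infer_tf_regulators, perturbation_link_calling,
                  weighted_pearson)


@pytest.fixture()
def ann():
    return GenomicAnnotation.from_frame(pd.DataFrame(
        {"chrom": ["chr1"], "tss": [1_000_000], "strand": ["+"]},
        index=["GeneA"]))


class TestCandidateLoci:
    def test_within_window_and_in_marker_set(self, ann):
        loci = ["chr1:1200000-1200500",   # 200 kb away, in AL_k
                "chr1:1600000-1600500",   # 600 kb away
                "chr1:1300000-1300500"]   # 300 kb away, not in AL_k
        got = candidate_loci("GeneA", ann, loci, AL_k={loci[0], loci[1]})
        assert got == [loci[0]]

    def test_indices_accepted_for_marker_set(self, ann):
        loci = ["chr1:1200000-1200500", "chr2:1200000-1200500"]
        assert candidate_loci("GeneA", ann, loci, AL_k=[0, 1]) == [loci[0]]

    def test_missing_gene_named(self, ann):
        with pytest.raises(KeyError, match="GeneZ"):
            candidate_loci("GeneZ", ann, [], AL_k=[])


class TestWeightedPearson:
    def test_uniform_weights_equal_plain_pearson(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=(2, 12))
            r = weighted_pearson(x, y, np.full(12, 0.37))
            assert abs(r - np.corrcoef(x, y)[0, 1]) <= 1e-12

    def test_proportional_vectors_give_one(self, rng):
        x = rng.random(20)
        assert weighted_pearson(x, 3 * x, rng.random(20) + 0.1) == pytest.approx(1.0)

    def test_matches_straight_line_formula(self, rng):
        x, y = rng.normal(size=(2, 15))
        w = rng.random(15)
        wn = w / w.sum()
        mx, my = (wn * x).sum(), (wn * y).sum()
        cov = (wn * (x - mx) * (y - my)).sum()
        r_oracle = cov / np.sqrt((wn * (x - mx) ** 2).sum() * (wn * (y - my) ** 2).sum())
        assert weighted_pearson(x, y, w) == pytest.approx(r_oracle, abs=1e-14)

    def test_zero_variance_returns_nan(self):
        assert np.isnan(weighted_pearson(np.ones(5), np.arange(5.0), np.ones(5)))


class TestLinkCalling:
    def test_group_driven_correlation_called(self, rng):
        """Expression and accessibility co-activate in the factor's cell
        group; zeroing either inside the group destroys the correlation,
        so dP is large and the link is called."""
        n = 10
        C1 = np.arange(5)
        x = np.array([5.0, 6, 5.5, 6.5, 5, 0.1, 0.2, 0.1, 0.3, 0.2])
        driver = np.array([1.0, 0.9, 1.1, 0.8, 1.0, 0.05, 0.1, 0.05, 0.1, 0.0])
        noise = rng.random(n) * 0.2 + 0.1  # unrelated locus
        A = np.vstack([driver, noise])
        H_k = np.array([1.0] * 5 + [0.2] * 5)
        links = perturbation_link_calling(x, A, H_k, C1, gene="g",
                                          locus_ids=["driven", "null"])
        by_id = {l.locus: l for l in links}
        assert by_id["driven"].called
        assert by_id["driven"].dP1 > by_id["null"].dP1
        # oracle: straight-line weighted Pearson after the perturbation
        xp = x.copy()
        xp[C1] = 0
        w = H_k / H_k.sum()
        mx, my = w @ xp, w @ driver
        cov = w @ ((xp - mx) * (driver - my))
        P2_oracle = cov / np.sqrt((w @ (xp - mx) ** 2) * (w @ (driver - my) ** 2))
        assert by_id["driven"].P2 == pytest.approx(P2_oracle, abs=1e-12)

    def test_zero_variance_pair_skipped(self, rng):
        x = rng.random(8)
        A = np.vstack([np.full(8, 0.3), rng.random(8)])
        with pytest.warns(UserWarning, match="skipped"):
            links = perturbation_link_calling(x, A, np.ones(8), [0, 1], gene="g")
        assert len(links) == 1

    def test_fewer_than_three_cells_rejected(self):
        with pytest.raises(ValueError, match="three cells"):
            perturbation_link_calling(np.ones(2), np.ones((1, 2)), np.ones(2), [0])

    def test_empty_cell_group_rejected(self, rng):
        with pytest.raises(ValueError, match="C1"):
            perturbation_link_calling(rng.random(5), rng.random((1, 5)),
                                      np.ones(5), [])


class TestTFRegression:
    def test_proportional_tf_recovers_slope(self, rng):
        x = rng.random(15)
        links = infer_tf_regulators(x, 2 * x[None, :], tf_ids=["TF1"])
        assert len(links) == 1
        assert links[0].beta == pytest.approx(2.0)

    def test_negative_relationship_clamped_to_no_link(self, rng):
        x = rng.random(15) + 0.5
        tf = (1.0 - x)[None, :]  # unconstrained through-origin slope < 0
        assert (x * tf[0]).sum() < 0  # sanity: anticorrelated with x
        assert infer_tf_regulators(x, tf, tf_ids=["TF1"]) == []

    def test_beats_grid_search_oracle(self, rng):
        # per-TF 1-D NNLS must beat every grid candidate's residual
        x = rng.random(12)
        TF = rng.random((3, 12))
        links = infer_tf_regulators(x, TF, tf_ids=["a", "b", "c"])
        betas = {l.tf: l.beta for l in links}
        for t, tf_id in enumerate(["a", "b", "c"]):
            b = betas.get(tf_id, 0.0)
            res = ((TF[t] - b * x) ** 2).sum()
            for cand in np.linspace(0, 5, 2001):
                assert res <= ((TF[t] - cand * x) ** 2).sum() + 1e-6

    def test_joint_orientation_grid_oracle(self, rng):
        x = rng.random(12)
        TF = rng.random((3, 12))
        links = infer_tf_regulators(x, TF, tf_ids=["a", "b", "c"],
                                    orientation="gene_on_tfs")
        beta = np.zeros(3)
        for l in links:
            beta[["a", "b", "c"].index(l.tf)] = l.beta
        res = ((x - beta @ TF) ** 2).sum()
        grid = np.linspace(0, 2, 21)
        for cand in itertools.product(grid, repeat=3):
            assert res <= ((x - np.array(cand) @ TF) ** 2).sum() + 1e-6

    def test_motif_mask_restricts_tfs(self, rng):
        x = rng.random(10)
        TF = np.vstack([2 * x, 3 * x])
        links = infer_tf_regulators(x, TF, tf_ids=["a", "b"],
                                    motif_mask=[False, True])
        assert [l.tf for l in links] == ["b"]


class TestValidateLinks:
    def test_per_gene_enrichment_from_pair_table(self):
        from scai import TFLink, validate_tf_links
        links = [TFLink("GeneA", tf, 1.0, 0) for tf in ("t1", "t2", "t3")]
        reference = [("t1", "GeneA"), ("t2", "GeneA"), ("t9", "GeneA"),
                     ("t1", "GeneB")]
        background = {f"t{i}" for i in range(1, 11)}
        fe = validate_tf_links(links, reference, background)
        # 2 of 3 predictions known, 3 known among 10 background TFs
        assert fe == {"GeneA": pytest.approx((2 / 3) / (3 / 10))}

    def test_gene_without_known_regulators_skipped(self):
        from scai import TFLink, validate_tf_links
        links = [TFLink("GeneC", "t1", 1.0, 0)]
        assert validate_tf_links(links, [("t2", "GeneA")], {"t1", "t2"}) == {}


class TestFoldEnrichment:
    def test_worked_example(self):
        assert fold_enrichment(7, 12, 92, 374) == pytest.approx(2.37, abs=0.005)

    def test_no_enrichment_is_one(self):
        assert fold_enrichment(30, 30, 100, 100) == pytest.approx(1.0)

    def test_empty_overlap_is_zero(self):
        assert fold_enrichment(0, 12, 92, 374) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(5, 0, 10, 100)
        with pytest.raises(ValueError):
            fold_enrichment(13, 12, 92, 374)
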