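"""U/X/M classification, atlas construction and NNLS deconvolution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cfmeth.deconvolution import (
    ReferenceAtlas,
    UXMConfig,
    UXMDeconvolution,
    build_atlas,
    classify_fragment,
    deconvolve,
    fragment_uxm_counts,
)
from cfmeth.io import FragmentSet
from cfmeth.synthetic import MixtureSpec


def _fs(rows, genome):
    df = pd.DataFrame(rows, columns=["chrom", "start", "pattern", "count"])
    return FragmentSet(df, genome)


def _markers(ranges):
    return pd.DataFrame(
        {
            "start_idx": [a for a, _ in ranges],
            "end_idx": [b for _, b in ranges],
        }
    )


class TestClassify:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ("TTTT", "U"),
            ("CCCC", "M"),
            ("TTCC", "X"),
            ("CCT", "X"),  # f = 2/3, strictly between thresholds
            ("T.T", "excluded"),  # only 2 observed CpGs with min 3
            ("CTTT", "U"),  # f = 0.25 at the U boundary
            ("CCCT", "M"),  # f = 0.75 at the M boundary
        ],
    )
    def test_rule_evaluation(self, pattern, expected):
        assert classify_fragment(pattern) == expected

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid pattern"):
            classify_fragment("CTA")


class TestFragmentCounts:
    def test_hand_counted_ten_fragment_fixture(self, toy_genome):
        """Per-marker U/X/M tallies match a manual count.

        Marker A = serials 1-4, marker B = serials 8-11.  By hand:
        A: U from rows 1 (x2 multiplicity) and 2; M from row 3; row 4 has
        only 2 CpGs inside A -> excluded; row 5 straddles A with 3 inside
        calls TTT -> U.  B: M from rows 6,7; X from row 8; row 9's calls
        inside B are 2 ('.' drops one) -> excluded; row 10 is U.
        """
        rows = [
            ("chr1", 1, "TTTT", 2),   # A: U (x2)
            ("chr1", 1, "TTTC", 1),   # A: f=0.25 -> U
            ("chr1", 1, "CCCC", 1),   # A: M
            ("chr1", 3, "TT", 1),     # A: 2 inside -> excluded
            ("chr1", 2, "TTTCC", 1),  # serials 2-6; inside A: TTT -> U
            ("chr1", 8, "CCCC", 1),   # B: M
            ("chr1", 8, "CCC", 1),    # B: M
            ("chr1", 8, "CTTC", 1),   # B: f=0.5 -> X
            ("chr1", 9, "C.T", 1),    # B: 2 observed inside -> excluded
            ("chr1", 8, "TTTT", 1),   # B: U
        ]
        counts = fragment_uxm_counts(_fs(rows, toy_genome), _markers([(1, 4), (8, 11)]))
        assert counts.loc[0].tolist() == [4.0, 0.0, 1.0]
        assert counts.loc[1].tolist() == [1.0, 1.0, 2.0]

    def test_flanking_cpgs_do_not_dilute(self, toy_genome):
        # fragment covers serials 3-8; only serials 3-4 lie in the marker
        counts = fragment_uxm_counts(
            _fs([("chr1", 3, "TTCCCC", 1)], toy_genome), _markers([(1, 4)])
        )
        assert counts.sum().sum() == 0  # 2 inside calls < min 3 -> excluded

    def test_overlapping_markers_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="overlap"):
            fragment_uxm_counts(
                _fs([("chr1", 1, "TTT", 1)], toy_genome), _markers([(1, 4), (4, 7)])
            )


def _two_type_atlas(genome):
    """Noiseless references: A unmethylated in marker 0, B in marker 1."""
    markers = _markers([(1, 4), (8, 11)])
    ref_a = _fs([("chr1", 1, "TTTT", 40), ("chr1", 8, "CCCC", 40)], genome)
    ref_b = _fs([("chr1", 1, "CCCC", 40), ("chr1", 8, "TTTT", 40)], genome)
    return build_atlas({"A": [ref_a], "B": [ref_b]}, markers), markers


def _simplex_grid_nnls(A, b, step):
    """Independent oracle: exhaustive search over the probability simplex."""
    k = A.shape[1]
    best, best_w = np.inf, None
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=k - 1):
        last = 1.0 - sum(combo)
        if last < -1e-12:
            continue
        w = np.array([*combo, max(last, 0.0)])
        r = float(np.sum((A @ w - b) ** 2))
        if r < best:
            best, best_w = r, w
    return best_w


class TestDeconvolve:
    def test_pure_type_recovers_proportion_one(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        sample = _fs([("chr1", 1, "TTTT", 30), ("chr1", 8, "CCCC", 30)], toy_genome)
        res = deconvolve(sample, atlas)
        assert res.proportions["A"] == pytest.approx(1.0, abs=1e-9)
        assert res.proportions["B"] == pytest.approx(0.0, abs=1e-9)

    def test_thirty_seventy_mixture_matches_grid_oracle(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        sample = _fs(
            [
                ("chr1", 1, "TTTT", 30), ("chr1", 1, "CCCC", 70),
                ("chr1", 8, "TTTT", 70), ("chr1", 8, "CCCC", 30),
            ],
            toy_genome,
        )
        res = deconvolve(sample, atlas)
        assert res.proportions["A"] == pytest.approx(0.3, abs=0.02)
        assert res.proportions["B"] == pytest.approx(0.7, abs=0.02)
        A = atlas.u_prop.to_numpy()
        b = np.array([0.3, 0.7])
        w = _simplex_grid_nnls(A, b, step=0.001)
        assert np.allclose(res.proportions.to_numpy(), w, atol=0.001)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nnls_matches_simplex_grid_for_three_types(self, seed):
        """NNLS (after normalisation) equals exhaustive simplex search."""
        rng = np.random.default_rng(seed)
        A = rng.random((12, 3))
        w_true = rng.dirichlet([2, 2, 2])
        b = A @ w_true + rng.normal(0, 0.01, 12)
        from scipy.optimize import nnls

        w, _ = nnls(A, b)
        w = w / w.sum()
        w_grid = _simplex_grid_nnls(A, b, step=0.01)
        assert np.abs(w - w_grid).max() <= 0.02

    def test_column_permutation_permutes_estimate(self, toy_genome, small_atlas, small_pipeline):
        ra = small_pipeline.reference_atlas(3, 50)
        mix, _ = small_atlas.simulate_mixture(MixtureSpec(spike_fraction=0.05), 77)
        base = deconvolve(mix, ra)
        perm = list(reversed(ra.cell_types))
        ra2 = ReferenceAtlas(ra.markers, ra.u_prop[perm], ra.depth[perm], ra.config)
        res2 = deconvolve(mix, ra2)
        pd.testing.assert_series_equal(
            base.proportions.sort_index(), res2.proportions.sort_index()
        )

    def test_proportions_form_a_probability_vector(self, small_atlas, small_pipeline):
        ra = small_pipeline.reference_atlas(3, 50)
        for seed, frac in [(1, 0.0), (2, 0.01), (3, 0.1)]:
            mix, _ = small_atlas.simulate_mixture(MixtureSpec(spike_fraction=frac), seed)
            res = deconvolve(mix, ra)
            assert (res.proportions >= 0).all()
            assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weighting_not_worse_on_noiseless_mixture(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        sample = _fs(
            [
                ("chr1", 1, "TTTT", 20), ("chr1", 1, "CCCC", 80),
                ("chr1", 8, "TTTT", 80), ("chr1", 8, "CCCC", 20),
            ],
            toy_genome,
        )
        truth = np.array([0.2, 0.8])
        plain = deconvolve(sample, atlas).proportions.to_numpy()
        weighted = deconvolve(sample, atlas, weighted=True).proportions.to_numpy()
        assert np.mean((weighted - truth) ** 2) <= np.mean((plain - truth) ** 2) + 1e-12

    def test_degenerate_sample_returns_nan_with_diagnostic(self, toy_genome):
        markers = _markers([(1, 4)])
        atlas = ReferenceAtlas(
            markers,
            pd.DataFrame({"A": [0.0], "B": [0.0]}),
            pd.DataFrame({"A": [10.0], "B": [10.0]}),
        )
        sample = _fs([("chr1", 1, "CCCC", 5)], toy_genome)
        res = deconvolve(sample, atlas)
        assert res.degenerate
        assert res.proportions.isna().all()
        assert res.n_detected == 0

    def test_empty_sample_rejected(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        empty = FragmentSet(
            pd.DataFrame(columns=["chrom", "start", "pattern", "count"]), toy_genome
        )
        with pytest.raises(ValueError, match="empty"):
            UXMDeconvolution(empty, atlas)

    def test_summary_lists_all_cell_types(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        sample = _fs([("chr1", 1, "TTTT", 10), ("chr1", 8, "CCCC", 10)], toy_genome)
        text = deconvolve(sample, atlas).summary()
        assert "A" in text and "B" in text and "residual norm" in text


class TestAtlas:
    def test_noiseless_u_proportions(self, toy_genome):
        atlas, _ = _two_type_atlas(toy_genome)
        assert atlas.u_prop.loc[0, "A"] == 1.0
        assert atlas.u_prop.loc[0, "B"] == 0.0
        assert atlas.u_prop.loc[1, "B"] == 1.0

    def test_replicates_pooled(self, toy_genome):
        markers = _markers([(1, 4)])
        r1 = _fs([("chr1", 1, "TTTT", 3)], toy_genome)
        r2 = _fs([("chr1", 1, "CCCC", 1)], toy_genome)
        atlas = build_atlas({"A": [r1, r2]}, markers)
        assert atlas.u_prop.loc[0, "A"] == pytest.approx(0.75)
        assert atlas.depth.loc[0, "A"] == 4.0

    def test_type_without_fragments_gives_na_row(self, toy_genome):
        markers = _markers([(1, 4), (8, 11)])
        ref_a = _fs([("chr1", 1, "TTTT", 5), ("chr1", 8, "CCCC", 5)], toy_genome)
        ref_b = _fs([("chr1", 1, "CCCC", 5)], toy_genome)  # nothing at marker 1
        atlas = build_atlas({"A": [ref_a], "B": [ref_b]}, markers)
        assert np.isnan(atlas.u_prop.loc[1, "B"])
        assert atlas.usable.tolist() == [True, False]

    def test_atlas_tsv_roundtrip_columns(self, toy_genome, tmp_path):
        atlas, _ = _two_type_atlas(toy_genome)
        p = tmp_path / "atlas.tsv"
        atlas.to_tsv(p)
        back = pd.read_csv(p, sep="\t")
        assert {"A", "B", "start_idx", "end_idx"} <= set(back.columns)
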