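"""Alpha/beta diversity, ordination and PERMANOVA against hand values,
brute-force oracles, and scikit-bio."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otufilter import (
    OtuTableError,
    ReplicateDesign,
    TaxonomyTable,
    alpha_diversity,
    bray_curtis,
    chao1,
    filter_sample_singleton,
    inverse_simpson,
    observed_otus,
    pcoa,
    permanova,
    phylum_relative_abundance,
    rank_relative_abundance,
    shannon,
)
from otufilter.diversity import DistanceMatrix
from conftest import make_table

count_vectors = st.lists(st.integers(0, 40), min_size=1, max_size=12)


# -- brute-force oracles (pure python, independent of the implementation) --

def bf_observed(v):
    return sum(1 for x in v if x >= 1)


def bf_chao1(v):
    f1 = sum(1 for x in v if x == 1)
    f2 = sum(1 for x in v if x == 2)
    return bf_observed(v) + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bf_shannon(v):
    total = sum(v)
    return -sum((x / total) * math.log(x / total) for x in v if x > 0)


def bf_inverse_simpson(v):
    total = sum(v)
    return 1.0 / sum((x / total) ** 2 for x in v)


def bf_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


class TestAlphaHandValues:
    def test_observed(self):
        assert observed_otus([5, 0, 1, 2]) == 3
        assert observed_otus([0, 0]) == 0

    def test_chao1(self):
        assert chao1([1, 1, 2, 2, 5]) == pytest.approx(5 + 2 / 6)
        assert chao1([1, 3]) == pytest.approx(2.0)
        # no singletons: the correction vanishes
        assert chao1([2, 3, 4]) == observed_otus([2, 3, 4])

    def test_chao1_classic_form(self):
        assert chao1([1, 1, 2, 5], bias_corrected=False) == pytest.approx(
            4 + 4 / 2)
        with pytest.raises(OtuTableError):
            chao1([1, 3], bias_corrected=False)

    def test_shannon(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
        assert shannon([9]) == 0.0
        assert shannon([1, 1, 2]) == pytest.approx(1.0397207708399179)
        assert shannon([1, 1, 2], base=2) == pytest.approx(1.5)

    def test_inverse_simpson(self):
        assert inverse_simpson([7] * 5) == pytest.approx(5.0)
        assert inverse_simpson([3]) == pytest.approx(1.0)
        assert inverse_simpson([3, 1]) == pytest.approx(1.6)

    def test_zero_total_rejected(self):
        for fn in (shannon, inverse_simpson):
            with pytest.raises(OtuTableError):
                fn([0, 0])


@settings(max_examples=60, deadline=None)
@given(v=count_vectors)
def test_alpha_metrics_match_brute_force(v):
    assert observed_otus(v) == bf_observed(v)
    assert chao1(v) == pytest.approx(bf_chao1(v), abs=1e-10)
    if sum(v) > 0:
        assert shannon(v) == pytest.approx(bf_shannon(v), abs=1e-10)
        assert inverse_simpson(v) == pytest.approx(bf_inverse_simpson(v),
                                                   abs=1e-10)


@settings(max_examples=40, deadline=None)
@given(v=count_vectors.filter(lambda v: sum(v) > 0))
def test_alpha_metrics_match_scikit_bio(v):
    skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
    assert chao1(v) == pytest.approx(skbio_alpha.chao1(v, bias_corrected=True))
    assert shannon(v) == pytest.approx(
        skbio_alpha.shannon(v, base=math.e), abs=1e-10)
    assert inverse_simpson(v) == pytest.approx(skbio_alpha.enspie(v),
                                               abs=1e-10)


@settings(max_examples=40, deadline=None)
@given(v=count_vectors.filter(lambda v: sum(v) > 0))
def test_alpha_inequalities(v):
    s_obs = observed_otus(v)
    assert chao1(v) >= s_obs
    if s_obs:
        assert shannon(v) <= math.log(s_obs) + 1e-12
        assert inverse_simpson(v) <= s_obs + 1e-12


def test_chao1_equals_observed_after_singleton_filter(default_dataset):
    filtered = filter_sample_singleton(default_dataset.table).table
    res = alpha_diversity(filtered)
    assert (res.per_sample["chao1"]
            == res.per_sample["observed_otus"]).all()


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = make_table([[3, 3, 0], [2, 2, 5]], sample_ids=["a", "b", "c"])
        dm = bray_curtis(t)
        assert dm.values[0, 1] == pytest.approx(0.0)
        t2 = make_table([[4, 0], [0, 9]])
        assert bray_curtis(t2).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = make_table([[6, 2], [2, 2]])
        assert bray_curtis(t).values[0, 1] == pytest.approx(4 / 12)

    def test_relative_mode_ignores_depth(self):
        t = make_table([[30, 300], [10, 100]])
        assert bray_curtis(t, relative=True).values[0, 1] == pytest.approx(0.0)
        assert bray_curtis(t).values[0, 1] > 0.5

    def test_all_zero_pair_rejected(self):
        with pytest.raises(OtuTableError):
            bray_curtis(make_table([[0, 0]]))

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force(self, data):
        n_otus = data.draw(st.integers(1, 6))
        cols = data.draw(st.lists(
            st.lists(st.integers(0, 30), min_size=n_otus, max_size=n_otus)
            .filter(lambda c: sum(c) > 0),
            min_size=2, max_size=5))
        t = make_table(np.array(cols).T)
        dm = bray_curtis(t)
        for i, j in itertools.combinations(range(len(cols)), 2):
            assert dm.values[i, j] == pytest.approx(
                bf_bray_curtis(cols[i], cols[j]), abs=1e-10)
            assert 0.0 <= dm.values[i, j] <= 1.0


class TestPcoa:
    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.coordinates.shape[1] == 0

    def test_collinear_three_points(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        # one positive axis; embedded distances reproduce the input
        assert (res.eigenvalues > 1e-9).sum() == 1
        emb = res.coordinates
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(emb[i] - emb[j]) == pytest.approx(d[i, j])

    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        assert (res.eigenvalues >= -1e-8).all()
        emb = res.coordinates
        for i, j in itertools.combinations(range(6), 2):
            assert np.linalg.norm(emb[i] - emb[j]) == pytest.approx(
                d[i, j], abs=1e-8)

    def test_negative_eigenvalues_reported_not_corrected(self):
        # Bray-Curtis is non-metric: negative eigenvalues must survive
        rng = np.random.default_rng(11)
        t = make_table(rng.integers(0, 50, size=(20, 10)))
        res = pcoa(bray_curtis(t))
        assert res.eigenvalues.min() < 0

    def test_matches_scikit_bio_eigenvalues(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        t = make_table(rng.integers(0, 40, size=(12, 7)))
        dm = bray_curtis(t)
        ours = pcoa(dm)
        theirs = skbio_ord.pcoa(skbio_dist.DistanceMatrix(
            dm.values, dm.sample_ids))
        # scikit-bio clamps negative eigenvalues to zero in its output;
        # compare the positive spectra only
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-12]),
            np.sort(theirs.eigvals.values[theirs.eigvals.values > 1e-12]),
            atol=1e-10)


def _separated_dm():
    """Two tight groups far apart: within 0, between 1."""
    labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
    v = np.array([[0.0 if a == b else 1.0 for b in labels] for a in labels])
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(6)], v), labels


class TestPermanova:
    def test_degenerate_separation(self):
        dm, labels = _separated_dm()
        res = permanova(dm, labels, n_permutations=199, seed=0)
        assert res.pseudo_f == math.inf
        assert res.r_squared == pytest.approx(1.0)
        # only relabellings reproducing the partition (2 of the 20) tie F
        assert res.p_value < 0.2

    def test_exact_enumeration_on_six_samples(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.integers(0, 30, size=(10, 6)))
        dm = bray_curtis(t)
        labels = ["a", "a", "a", "b", "b", "b"]
        exact = permanova(dm, labels, n_permutations="exact")
        assert exact.exact and exact.n_permutations == 20
        assert exact.p_value in [k / 20 for k in range(1, 21)]
        mc = permanova(dm, labels, n_permutations=4999, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.05)

    def test_matches_scikit_bio_statistic(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        t = make_table(rng.integers(0, 60, size=(25, 9)))
        dm = bray_curtis(t)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dm.values, dm.sample_ids),
            grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_r2_invariant_under_consistent_relabelling(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.integers(0, 40, size=(15, 8)))
        dm = bray_curtis(t)
        labels = ["a", "a", "b", "b", "c", "c", "c", "a"]
        base = permanova(dm, labels, n_permutations=9, seed=0)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix([dm.sample_ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        shuffled = permanova(dm2, [labels[i] for i in perm],
                             n_permutations=9, seed=0)
        assert shuffled.r_squared == pytest.approx(base.r_squared)
        assert shuffled.pseudo_f == pytest.approx(base.pseudo_f)

    def test_group_requirements(self):
        dm, _ = _separated_dm()
        with pytest.raises(OtuTableError):
            permanova(dm, ["g"] * 6)
        with pytest.raises(OtuTableError):
            permanova(dm, [f"g{i}" for i in range(6)])


class TestPhylumAbundance:
    TAX = TaxonomyTable({
        "A": ("Bacteria", "Firmicutes"),
        "B": ("Bacteria", "Bacteroidetes"),
        "C": ("Bacteria", "Firmicutes", "Clostridia", "", "Lachnospiraceae"),
    })

    def test_two_phyla_split(self):
        t = make_table([[75], [25]], otu_ids=["A", "B"])
        out = phylum_relative_abundance(t, self.TAX)
        assert out.loc["Firmicutes", "mean"] == pytest.approx(75.0)
        assert out.loc["Bacteroidetes", "mean"] == pytest.approx(25.0)

    def test_single_phylum_is_100(self):
        t = make_table([[10, 3]], otu_ids=["A"])
        out = phylum_relative_abundance(t, self.TAX)
        assert out.loc["Firmicutes", "mean"] == pytest.approx(100.0)

    def test_shares_sum_to_100_per_sample(self):
        t = make_table([[7, 1], [2, 9], [4, 4]], otu_ids=["A", "B", "C"])
        out = phylum_relative_abundance(t, self.TAX)
        sample_cols = [c for c in out.columns if c not in ("mean", "se")]
        assert np.allclose(out[sample_cols].sum(axis=0), 100.0)

    def test_family_rank_and_unclassified(self):
        t = make_table([[5], [5], [10]], otu_ids=["A", "B", "C"])
        out = rank_relative_abundance(t, self.TAX, rank="family")
        assert out.loc["Lachnospiraceae", "mean"] == pytest.approx(50.0)
        assert out.loc["unclassified", "mean"] == pytest.approx(50.0)


def test_filtering_never_increases_observed_otus(default_dataset):
    table = default_dataset.table
    base = alpha_diversity(table).per_sample["observed_otus"]
    filtered = filter_sample_singleton(table).table
    filt = alpha_diversity(filtered).per_sample["observed_otus"]
    assert (filt <= base.loc[filt.index]).all()
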