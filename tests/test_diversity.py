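import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynxrescue.diversity import (
    allelic_diversity,
    effective_inbreeding,
    expected_heterozygosity_nei,
    fis,
    observed_heterozygosity,
    pca_genotypes,
    travelling_window_fe,
    dosage_matrix,
)
from lynxrescue.genotypes import GenotypeDataset
from lynxrescue.synthetic import sample_dataset_from_frequencies, slovak_like_frequencies

from conftest import make_dataset


def _biallelic(n_het, n_hom_a, n_hom_b, pop="p"):
    rows = []
    for i in range(n_het):
        rows.append((f"h{i}", pop, 2000, "F", False, {"LocA": ("A", "B")}))
    for i in range(n_hom_a):
        rows.append((f"a{i}", pop, 2000, "F", False, {"LocA": ("A", "A")}))
    for i in range(n_hom_b):
        rows.append((f"b{i}", pop, 2000, "F", False, {"LocA": ("B", "B")}))
    return make_dataset(rows, loci=("LocA",))


def test_observed_heterozygosity_counts():
    assert observed_heterozygosity(_biallelic(5, 0, 0)).mean == 1.0
    assert observed_heterozygosity(_biallelic(3, 4, 3)).mean == pytest.approx(0.3)


def test_nei_unbiased_he_formula():
    """p = 0.5/0.5 with n = 10 gives (2n/(2n-1)) * 0.5 = 20/38."""
    ds = _biallelic(0, 5, 5)
    he = expected_heterozygosity_nei(ds)
    assert he.mean == pytest.approx((20 / 19) * 0.5, abs=1e-12)


def test_monomorphic_locus_he_zero():
    ds = _biallelic(0, 4, 0)
    assert expected_heterozygosity_nei(ds).mean == 0.0
    assert allelic_diversity(ds).mean == 1.0


def test_unbiased_he_exceeds_plain_gene_diversity(rng):
    """The 2n/(2n-1) correction makes unbiased He >= 1 - sum(p^2)."""
    freqs = slovak_like_frequencies(2)
    ds = sample_dataset_from_frequencies(freqs, 25, rng)
    from lynxrescue.genotypes import compute_allele_frequencies

    plain = compute_allele_frequencies(ds, freqs.population).per_locus_heterozygosity()
    unbiased = expected_heterozygosity_nei(ds).per_locus
    assert (unbiased.values >= plain.values - 1e-12).all()


def test_allelic_diversity_subsampling_never_increases(rng):
    freqs = slovak_like_frequencies(4)
    ds = sample_dataset_from_frequencies(freqs, 60, rng)
    full = allelic_diversity(ds).per_locus
    sub = GenotypeDataset(ds.panel, ds.records[:15])
    small = allelic_diversity(sub).per_locus
    assert (small.values <= full.values + 1e-12).all()


def test_effective_inbreeding_identities():
    assert effective_inbreeding(0.5, 0.5) == 0.0
    assert effective_inbreeding(0.0, 0.5) == 1.0
    assert effective_inbreeding(0.457, 0.583) == pytest.approx(0.21612, abs=1e-4)
    with pytest.raises(ValueError):
        effective_inbreeding(0.4, 0.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    h1=st.floats(0.01, 0.99),
    h2=st.floats(0.01, 0.99),
    eps=st.floats(0.001, 0.2),
)
def test_effective_inbreeding_monotonicity(h1, h2, eps):
    """Fe decreases in the target heterozygosity, increases in the source."""
    fe = effective_inbreeding(h1, h2)
    assert effective_inbreeding(min(h1 + eps, 1.0), h2) <= fe
    assert effective_inbreeding(h1, min(h2 + eps, 1.0)) >= fe


def test_fis_near_zero_under_random_mating(rng):
    """Hardy-Weinberg sample of 500 individuals: |F_is| < 0.05."""
    freqs = slovak_like_frequencies(6)
    ds = sample_dataset_from_frequencies(freqs, 500, rng)
    assert abs(fis(ds)) < 0.05


def test_fis_extremes():
    all_het = _biallelic(10, 0, 0)
    assert fis(all_het) < 0  # heterozygote excess
    no_het = _biallelic(0, 5, 5)
    assert fis(no_het) == pytest.approx(1.0)


class TestTravellingWindow:
    def test_self_comparison_fe_near_zero(self, rng):
        freqs = slovak_like_frequencies(8)
        ds = sample_dataset_from_frequencies(freqs, 120, rng, years=(1990, 2010))
        tw = travelling_window_fe(
            ds, source_he=freqs.expected_heterozygosity(), window_width=60, basis="expected"
        )
        assert np.abs(tw["fe"]).max() < 0.08

    def test_window_values_match_scalar_recomputation(self, dataset, sources):
        """Oracle: every window Fe equals effective_inbreeding applied to
        that window's records."""
        din = dataset.subset(population="dinaric", include_translocated=False)
        ske = sources["slovakia"].expected_heterozygosity()
        tw = travelling_window_fe(din, source_he=ske, window_width=60, basis="observed")
        ordered = din.sorted_by_date()
        ordered = GenotypeDataset(
            ordered.panel, [r for r in ordered if r.year is not None]
        )
        for start in (0, len(tw) // 2, len(tw) - 1):
            window = GenotypeDataset(ordered.panel, ordered.records[start : start + 60])
            h = observed_heterozygosity(window).mean
            assert tw["fe"].iloc[start] == pytest.approx(
                effective_inbreeding(h, ske), abs=1e-12
            )

    def test_translocated_exclusion_changes_eligibility(self, dataset, sources):
        ske = sources["slovakia"].expected_heterozygosity()
        incl = travelling_window_fe(
            dataset.subset(population="dinaric"), ske, 60, "expected", include_translocated=True
        )
        excl = travelling_window_fe(
            dataset.subset(population="dinaric"), ske, 60, "expected", include_translocated=False
        )
        assert len(incl) > len(excl)
        # the recent windows with source animals show lower inbreeding
        assert incl["fe"].iloc[-1] < excl["fe"].iloc[-1]

    def test_too_few_records_errors(self, rng):
        freqs = slovak_like_frequencies(8)
        ds = sample_dataset_from_frequencies(freqs, 30, rng, years=(2000, 2005))
        with pytest.raises(ValueError, match="window"):
            travelling_window_fe(ds, 0.5, window_width=60)


class TestPca:
    def _two_fixed_pops(self):
        rows = []
        for i in range(6):
            rows.append((f"x{i}", "p1", 2000, "F", False, {"LocA": ("A", "A"), "LocB": ("X", "X")}))
            rows.append((f"y{i}", "p2", 2000, "F", False, {"LocA": ("B", "B"), "LocB": ("Y", "Y")}))
        return make_dataset(rows)

    def test_fixed_populations_fully_separated_on_axis1(self):
        res = pca_genotypes(self._two_fixed_pops())
        s1 = res.scores["PC1"]
        p1 = s1[res.populations == "p1"]
        p2 = s1[res.populations == "p2"]
        assert p1.max() < p2.min() or p2.max() < p1.min()
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_percent_variance_sums_to_100(self, dataset):
        res = pca_genotypes(dataset)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (res.eigenvalues >= -1e-9).all()
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # sorted

    def test_reconstruction_from_all_axes(self, rng):
        """Scores x loadings reproduce the centred dosage matrix: checked
        via total variance equality."""
        freqs = slovak_like_frequencies(12)
        ds = sample_dataset_from_frequencies(freqs, 25, rng)
        X, _, _ = dosage_matrix(ds)
        Xc = X - X.mean(axis=0)
        res = pca_genotypes(ds)
        total_var = np.sum(Xc**2) / (Xc.shape[0] - 1)
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_populations_cluster_apart(self, dataset):
        res = pca_genotypes(dataset, n_axes=2)
        cent = res.scores.groupby(res.populations).mean()
        d12 = np.linalg.norm(cent.loc["dinaric"] - cent.loc["slovakia"])
        spread = res.scores["PC1"].std()
        assert d12 > spread  # between-population structure dominates
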