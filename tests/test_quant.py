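"""Unit and property tests of the spectrum-to-protein quantitation stage."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexquant.errors import ConfigurationError, DegenerateInputError
from plexquant.io import PSMRecord
from plexquant.quant import (
    PurityMatrix,
    QuantConfig,
    SpectrumRatio,
    correct_isotope_crossover,
    normalization_factor,
    passes_spectrum_criteria,
    protein_median_ratio,
    protein_p_value,
    quantify_proteins,
    spectrum_ratio,
)


def _psm(sid, acc, intensities, log_e=-3.0, label=True, indb=True):
    return PSMRecord(sid, "PEPTIDEK", acc, log_e, label, indb, tuple(float(v) for v in intensities))


# -- isotope cross-over correction ------------------------------------------


def test_identity_purity_is_a_no_op():
    out = correct_isotope_crossover([100, 200, 300, 400], PurityMatrix.identity())
    assert np.allclose(out, [100, 200, 300, 400], rtol=1e-12)


def test_zero_vector_stays_zero(default_purity):
    assert np.all(correct_isotope_crossover([0, 0, 0, 0], default_purity) == 0)


def test_forward_mix_then_correct_recovers_truth(default_purity):
    t = np.array([1000.0, 500.0, 0.0, 200.0])
    observed = np.asarray(default_purity) @ t
    recovered = correct_isotope_crossover(observed, default_purity)
    assert np.allclose(recovered, t, rtol=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1e7), min_size=4, max_size=4))
def test_correction_inverts_mixing_for_any_nonnegative_vector(t):
    purity = PurityMatrix.default()
    t = np.asarray(t)
    observed = np.asarray(purity) @ t
    recovered = correct_isotope_crossover(observed, purity)
    assert np.allclose(recovered, t, rtol=1e-6, atol=1e-6)


@pytest.mark.parametrize(
    "matrix",
    [
        np.full((4, 4), 0.25) + np.eye(4) * 0.75,  # columns sum to 1.5
        np.eye(4) * 0.5,  # diagonal below the plausibility bound
        -np.eye(4),
    ],
)
def test_implausible_purity_matrices_are_rejected(matrix):
    with pytest.raises(ConfigurationError):
        PurityMatrix(matrix)


def test_singular_purity_matrix_is_a_configuration_error():
    m = np.eye(4)
    m[:, 1] = m[:, 0]  # two identical columns -> singular
    m[0, 0] = m[1, 1] = 0.9
    m[0, 1] = 0.9
    with pytest.raises(ConfigurationError):
        correct_isotope_crossover([1, 2, 3, 4], PurityMatrix(m))


def test_purity_tsv_round_trip(tmp_path, default_purity):
    path = tmp_path / "purity.tsv"
    default_purity.to_tsv(path)
    back = PurityMatrix.from_tsv(path)
    assert np.array_equal(np.asarray(back), np.asarray(default_purity))


# -- spectrum qualification ---------------------------------------------------


@pytest.mark.parametrize(
    "log_e,label,indb,expected",
    [
        (-2.0, True, True, True),  # boundary is inclusive
        (-1.5, True, True, False),
        (-5.0, False, True, False),
        (-5.0, True, False, False),
        (-2.0001, True, True, True),
    ],
)
def test_spectrum_qualification_criteria(log_e, label, indb, expected):
    psm = _psm("s", "P", [1, 1, 1, 1], log_e=log_e, label=label, indb=indb)
    assert passes_spectrum_criteria(psm) is expected


# -- normalization ------------------------------------------------------------


def test_equal_channel_sums_normalize_to_one():
    X = [[1000, 600, 0, 0], [500, 900, 0, 0]]
    assert normalization_factor(X, "115/114") == pytest.approx(1.0)


def test_normalization_factor_is_ratio_of_sums():
    X = [[600_000, 1_200_000, 0, 0], [400_000, 800_000, 0, 0]]
    assert normalization_factor(X, "115/114") == pytest.approx(2.0)


def test_zero_denominator_sum_is_degenerate():
    with pytest.raises(DegenerateInputError):
        normalization_factor([[0, 100, 1, 1]], "115/114")


# -- per-spectrum ratios ------------------------------------------------------


def test_zero_denominator_gets_the_sentinel_not_a_rescaled_value():
    psm = _psm("s1", "P", [0, 3000, 10, 10])
    sr = spectrum_ratio(psm, "115/114", norm=2.5)
    assert sr.is_sentinel
    assert sr.normalized_ratio == 10.0  # norm is not applied to the placeholder
    assert sr.raw_ratio is None
    assert sr.channel_sum == 3000.0


def test_plain_ratio_and_normalization():
    psm = _psm("s1", "P", [1500, 3000, 0, 0])
    assert spectrum_ratio(psm, "115/114", norm=1.0).normalized_ratio == pytest.approx(2.0)
    assert spectrum_ratio(psm, "115/114", norm=2.0).normalized_ratio == pytest.approx(1.0)


def test_spectra_with_zero_numerator_are_excluded():
    assert spectrum_ratio(_psm("s", "P", [0, 0, 1, 1]), "115/114", 1.0) is None
    assert spectrum_ratio(_psm("s", "P", [500, 0, 1, 1]), "115/114", 1.0) is None


# -- protein median with the intensity filter --------------------------------


def _ratio(value, channel_sum=30_000.0, sentinel=False):
    return SpectrumRatio("s", "115/114", None if sentinel else value, value, sentinel, channel_sum)


def test_median_over_intensity_passing_spectra():
    ratios = [_ratio(v) for v in (0.5, 1, 2, 4, 8)]
    assert protein_median_ratio(ratios) == (2.0, 5)


def test_below_threshold_spectra_are_dropped():
    ratios = [_ratio(v) for v in (0.5, 1, 2, 4)] + [_ratio(8, channel_sum=15_000)]
    median, n = protein_median_ratio(ratios)
    assert n == 4
    assert median == pytest.approx(1.5)  # even n -> midpoint of central values


def test_intensity_filter_boundary_is_strict():
    assert protein_median_ratio([_ratio(3.3, channel_sum=20_000.0)]) is None
    assert protein_median_ratio([_ratio(3.3, channel_sum=20_000.1)]) == (3.3, 1)


# -- one-sample location test -------------------------------------------------


def _signflip_oracle(x):
    """Independent brute force: enumerate every sign assignment of the signed-rank statistic."""
    from scipy.stats import rankdata

    x = np.asarray([v for v in x if v != 0])
    ranks = rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([-1, 1], repeat=len(x))
    ]
    n_le = sum(w <= w_obs + 1e-12 for w in ws)
    n_ge = sum(w >= w_obs - 1e-12 for w in ws)
    return min(1.0, 2 * min(n_le, n_ge) / len(ws))


def test_all_zero_log_ratios_mean_no_change():
    assert protein_p_value([0.0, 0.0, 0.0]) == 1.0


def test_eight_positive_values_give_the_exact_minimum_p():
    p = protein_p_value([0.3, 0.5, 0.2, 0.4, 0.1, 0.6, 0.7, 0.8])
    assert p == pytest.approx(2 / 2**8)


def test_symmetric_pair_is_maximally_insignificant():
    assert protein_p_value([-0.7, 0.7]) == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-2, max_value=2, allow_nan=False).filter(lambda v: v != 0),
        min_size=2,
        max_size=9,
    )
)
def test_small_sample_p_matches_signflip_enumeration(x):
    assert protein_p_value(x) == pytest.approx(_signflip_oracle(x))


def test_exact_p_with_tied_magnitudes_matches_enumeration():
    x = [0.5, 0.5, -0.5, 0.25, 0.25]
    assert protein_p_value(x) == pytest.approx(_signflip_oracle(x))


def test_ttest_alternative_is_available():
    x = [0.4, 0.6, 0.5, 0.45, 0.55]
    from scipy.stats import ttest_1samp

    assert protein_p_value(x, test="ttest") == pytest.approx(ttest_1samp(x, 0).pvalue)


# -- full pipeline ------------------------------------------------------------


def _balanced_table():
    """Two proteins whose loadings balance exactly, so normalization is neutral.

    Protein A: 10 spectra, ratio 2 at base 100k (num 2M, den 1M);
    protein B: 10 spectra, ratio 2/3 at base 300k (num 2M, den 3M).
    Channel sums: numerator 4M = denominator 4M -> norm = 1.
    """
    records = []
    for i in range(10):
        records.append(_psm(f"a{i}", "A", [100_000, 200_000, 100_000, 100_000]))
        records.append(_psm(f"b{i}", "B", [300_000, 200_000, 300_000, 300_000]))
    return records


def test_planted_ratio_two_is_recovered_on_balanced_data():
    quants = {
        (q.protein_acc, q.comparison): q
        for q in quantify_proteins(_balanced_table(), purity=PurityMatrix.identity())
    }
    a = quants[("A", "115/114")]
    assert a.median_ratio == pytest.approx(2.0, rel=1e-12)
    assert a.status == "quantified" and a.n_psm == 10
    b = quants[("B", "115/114")]
    assert b.median_ratio == pytest.approx(2 / 3, rel=1e-12)


def test_two_passing_spectra_are_insufficient():
    records = [_psm(f"s{i}", "A", [100_000, 150_000, 1, 1]) for i in range(2)]
    # anchor the other channels so every comparison has positive sums
    records += [_psm(f"t{i}", "B", [100_000, 100_000, 100_000, 100_000]) for i in range(3)]
    quants = {
        (q.protein_acc, q.comparison): q
        for q in quantify_proteins(records, purity=PurityMatrix.identity())
    }
    assert quants[("A", "115/114")].status == "insufficient_psm"
    assert quants[("A", "115/114")].n_psm == 2


def test_empty_psm_table_gives_empty_output():
    assert quantify_proteins([], purity=PurityMatrix.identity()) == []


def test_post_normalization_summed_intensity_ratio_is_one(noise_free_data):
    records, _ = noise_free_data
    cfg = QuantConfig()
    from plexquant.quant import _correct_matrix, comparison_channels

    X = np.array([r.intensities for r in records])
    C = _correct_matrix(X, PurityMatrix.identity())
    qual = np.array([passes_spectrum_criteria(r, cfg) for r in records])
    for comp in cfg.comparisons:
        ni, di = comparison_channels(comp)
        norm = C[qual, ni].sum() / C[qual, di].sum()
        assert (C[qual, ni] / norm).sum() / C[qual, di].sum() == pytest.approx(1.0, abs=1e-9)


def test_normalized_ratios_invariant_under_global_channel_scaling(noise_free_data):
    records, _ = noise_free_data
    base = quantify_proteins(records, purity=PurityMatrix.identity())
    scaled_records = [
        PSMRecord(
            r.spectrum_id, r.peptide, r.protein_acc, r.log_e, r.has_label, r.in_target_db,
            (r.intensities[0], 3.0 * r.intensities[1], r.intensities[2], r.intensities[3]),
        )
        for r in records
    ]
    scaled = quantify_proteins(scaled_records, purity=PurityMatrix.identity())
    for q0, q1 in zip(base, scaled):
        assert q1.median_ratio == pytest.approx(q0.median_ratio, rel=1e-9)


def test_no_output_ratio_is_nonpositive_or_nonfinite():
    from plexquant.simulate import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(
        n_proteins=60, psm_min=5, psm_max=15, noise_sd_log2=0.4,
        frac_zero_channel=0.1, frac_low_intensity=0.1, seed=17,
    )
    records, _ = generate_dataset(cfg)
    for q in quantify_proteins(records, purity=PurityMatrix.identity()):
        assert math.isfinite(q.median_ratio) and q.median_ratio > 0
        assert 0 <= q.p_value <= 1
        if q.status == "quantified":
            assert q.n_psm >= 3 and q.p_value <= 0.01
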