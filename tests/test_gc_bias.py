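"""GC content, robust per-species regression, log-linear LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from metarep.gc_bias import (
    build_cube,
    gc_content,
    huber_fit,
    ipf_fit,
    loglinear_lrt,
    species_slopes,
)
from metarep.synthetic import BiasSpec, apply_platform_bias


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0), ("GgNcA", 3 / 4), ("nngc", 1.0)],
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_errors_and_biopython_crosscheck():
    with pytest.raises(ValueError):
        gc_content("NNN")
    Bio = pytest.importorskip("Bio")
    from Bio.SeqUtils import gc_fraction

    rng = np.random.default_rng(0)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        assert gc_content(seq) == pytest.approx(gc_fraction(seq))


def test_huber_exact_on_clean_data():
    x = np.linspace(0, 1, 10)
    fit = huber_fit(x, 2 * x + 1)
    assert fit.slope == pytest.approx(2.0, abs=1e-8)
    assert fit.intercept == pytest.approx(1.0, abs=1e-8)
    assert fit.converged


def test_huber_equals_ols_without_outliers():
    # alternating +-e residuals: every |residual| equals the MAD, so all
    # points sit inside c*scale and the Huber weights stay identically 1
    rng = np.random.default_rng(1)
    x = np.sort(rng.random(50))
    y = 0.7 * x - 0.2 + 0.01 * np.resize([1.0, -1.0], 50)
    fit = huber_fit(x, y)
    ols = np.polyfit(x, y, 1)
    assert fit.slope == pytest.approx(ols[0], abs=1e-7)
    assert fit.intercept == pytest.approx(ols[1], abs=1e-7)


def test_huber_resists_gross_outlier():
    rng = np.random.default_rng(2)
    x = np.linspace(0, 1, 21)
    y = 2 * x + rng.normal(0, 0.01, 21)
    y[-1] += 10.0  # gross outlier
    fit = huber_fit(x, y)
    ols_slope = np.polyfit(x, y, 1)[0]
    assert abs(fit.slope - 2.0) < 0.05
    assert abs(ols_slope - 2.0) > 0.2


def test_huber_permutation_invariance_and_errors():
    rng = np.random.default_rng(3)
    x = rng.random(30)
    y = x + rng.normal(0, 0.1, 30)
    perm = rng.permutation(30)
    f1, f2 = huber_fit(x, y), huber_fit(x[perm], y[perm])
    assert f1.slope == pytest.approx(f2.slope, abs=1e-10)
    with pytest.raises(ValueError):
        huber_fit(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError):
        huber_fit([1.0, 2.0], [1.0, 2.0])


def test_species_slopes_null_vs_tilt(small_catalog, small_profile):
    null = species_slopes(small_profile, small_catalog)
    tilted_profile = apply_platform_bias(small_profile, small_catalog, BiasSpec(beta=1.0))
    tilted = species_slopes(tilted_profile, small_catalog)
    assert null.n_species == 20
    # exponential tilt exp(beta*gc) adds beta/ln(10) to every log10-slope
    assert tilted.median_slope - null.median_slope == pytest.approx(1.0 / np.log(10), abs=1e-6)
    assert abs(null.median_slope) < 0.5  # GC-independent abundances: slope near 0


def test_species_slopes_skips_sparse_species(small_catalog, small_profile):
    prof = small_profile.copy()
    victim = small_catalog.index[small_catalog["species"] == "sp001"]
    prof.loc[victim] = 0.0
    summ = species_slopes(prof, small_catalog)
    assert "sp001" in summ.skipped
    assert summ.n_species == 19


def test_build_cube_symmetry_and_conservation():
    s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    gc = pd.Series([0.30, 0.60, 0.40, 0.70], index=list("abcd"))
    cube = build_cube(s, s, gc)
    assert cube.shape == (2, 2, 2)
    np.testing.assert_array_equal(cube[:, :, 0], cube[:, :, 1])
    assert cube[:, :, 0].sum() == 4 and cube[:, :, 1].sum() == 4


def test_build_cube_detects_tilt(small_catalog, small_profile):
    """Tilting platform B enriches its hi-GC/hi-abundance cell."""
    # species-level profiles: aggregate gene abundance per species
    sp_a = small_profile.groupby(small_catalog["species"]).sum()
    gc_sp = small_catalog.groupby("species")["gc_fraction"].mean()
    tilted = apply_platform_bias(small_profile, small_catalog, BiasSpec(beta=8.0))
    sp_b = tilted.groupby(small_catalog["species"]).sum()
    cube = build_cube(sp_a, sp_b, gc_sp)
    # hi-abundance & hi-GC cell (index 0,0) larger on the tilted slab
    assert cube[0, 0, 1] >= cube[0, 0, 0]


def test_ipf_preserves_margins():
    rng = np.random.default_rng(4)
    cube = rng.integers(1, 30, (2, 2, 2))
    fitted, conv = ipf_fit(cube)
    assert conv
    for ax in (0, 1, 2):
        np.testing.assert_allclose(fitted.sum(axis=ax), cube.sum(axis=ax), atol=1e-8)


def test_lrt_flat_cube_is_null():
    res = loglinear_lrt(np.full((2, 2, 2), 5))
    assert res.g2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_lrt_pure_three_way_interaction():
    cube = np.array([[[4, 1], [1, 4]], [[1, 4], [4, 1]]])
    res = loglinear_lrt(cube)
    assert res.g2 > 0
    assert res.df == 1
    assert 0 < res.p < 0.05


def test_lrt_matches_poisson_glm_deviance():
    """IPF deviance equals the no-three-way Poisson GLM's residual deviance."""
    cube = np.array([[[12, 3], [4, 9]], [[5, 8], [7, 2]]], dtype=float)
    cells = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)]
    df = pd.DataFrame(cells, columns=["a", "g", "p"])
    df["n"] = [cube[c] for c in cells]
    glm = sm.GLM.from_formula(
        "n ~ C(a)*C(g) + C(a)*C(p) + C(g)*C(p)", data=df, family=sm.families.Poisson()
    ).fit()
    res = loglinear_lrt(cube)
    assert res.g2 == pytest.approx(glm.deviance, rel=1e-8)


def test_lrt_relabel_invariance():
    cube = np.array([[[9, 2], [3, 7]], [[4, 6], [8, 1]]])
    flipped = cube[::-1, ::-1, :]  # consistent hi/lo relabel on both slabs
    assert loglinear_lrt(cube).g2 == pytest.approx(loglinear_lrt(flipped).g2, abs=1e-9)
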