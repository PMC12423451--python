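"""Expression filtering, CV conventions, TOM and module detection."""

import warnings

import numpy as np
import pandas as pd
import pytest

import tfcoop as t
from tfcoop import coexpr


def _matrix(rows, samples=None):
    arr = np.asarray(rows, dtype=float)
    cols = samples or [f"S{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=cols)


# --------------------------------------------------------------- filter --

def test_filter_rules_and_boundary():
    n = 100
    all_zero = np.zeros(n)
    constant10 = np.full(n, 10.0)
    # >= 1 TPM in exactly 11 samples: 89% below threshold -> kept
    boundary = np.zeros(n)
    boundary[:11] = 5.0
    removed_boundary = np.zeros(n)
    removed_boundary[:10] = 5.0   # 90% below -> removed
    m = _matrix([all_zero, constant10, boundary, removed_boundary])
    kept, counts = coexpr.filter_low_expression(m)
    assert list(kept.index) == ["g1", "g2"]
    assert counts == {"kept": 2, "removed": 2}


def test_filter_idempotent_and_partition():
    rng = np.random.default_rng(0)
    m = _matrix(rng.uniform(0, 3, size=(30, 40)))
    kept, counts = coexpr.filter_low_expression(m)
    assert counts["kept"] + counts["removed"] == 30
    again, counts2 = coexpr.filter_low_expression(kept)
    assert counts2["removed"] == 0 and again.equals(kept)


def test_filter_all_removed_raises():
    with pytest.raises(ValueError):
        coexpr.filter_low_expression(_matrix([np.zeros(10)]))


# ------------------------------------------------------------------- CV --

def test_cv_conventions():
    m = _matrix([[2, 2, 2], [1, 3, 1]])
    sd_mean = coexpr.expression_cv(m)
    assert sd_mean["g0"] == 0.0
    m2 = _matrix([[1, 3]])
    assert coexpr.expression_cv(m2)["g0"] == pytest.approx(np.sqrt(2) / 2)
    rec = coexpr.expression_cv(
        m2, coexpr.CoexprConfig(cv_convention="mean_over_sd"))
    assert rec["g0"] == pytest.approx(np.sqrt(2))


def test_cv_zero_variance_reciprocal_is_missing():
    m = _matrix([[5, 5, 5]])
    rec = coexpr.expression_cv(
        m, coexpr.CoexprConfig(cv_convention="mean_over_sd"))
    assert rec.isna().all()


# ------------------------------------------------------------ adjacency --

def test_adjacency_bounded_for_all_powers():
    tpm, _, _ = t.gen_expression(t.ExprSimConfig(seed=1))
    for beta in (1, 6, 20):
        a = coexpr.adjacency(tpm, beta)
        assert a.min() >= 0 and a.max() <= 1 + 1e-12


def test_pick_soft_power_trivial_threshold():
    tpm, _, _ = t.gen_expression(t.ExprSimConfig(seed=1))
    beta, _ = coexpr.pick_soft_power(
        tpm, coexpr.CoexprConfig(r2_min=1e-9))
    assert beta == 1


def test_pick_soft_power_falls_back_with_warning():
    # strongly modular data has a near-discrete connectivity distribution,
    # so no power reaches the scale-free cutoff; the best power is
    # returned with a warning
    tpm, _, _ = t.gen_expression(t.ExprSimConfig(seed=0))
    with pytest.warns(UserWarning, match="R2"):
        beta, table = coexpr.pick_soft_power(tpm)
    assert beta == int(table["r2"].idxmax())


def test_constant_rows_rejected():
    m = _matrix(np.ones((25, 10)))
    with pytest.raises(ValueError):
        coexpr.adjacency(m, 2)


# ------------------------------------------------------------------ TOM --

def tom_brute_force(a):
    n = len(a)
    k = a.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1
                                              - a[i, j])
    return tom


def test_two_perfectly_correlated_genes():
    x = np.linspace(0, 1, 20)
    m = _matrix([x, 2 * x + 1])
    tomm = coexpr.compute_tom(m, 6)
    assert tomm[0, 1] == pytest.approx(1.0)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(4)
    m = _matrix(rng.normal(size=(20, 30)))
    tomm = coexpr.compute_tom(m, 6)
    brute = tom_brute_force(coexpr.adjacency(m, 6))
    assert np.abs(tomm - brute).max() < 1e-10
    assert np.abs(tomm - tomm.T).max() < 1e-12
    assert tomm.min() >= 0 and tomm.max() <= 1 + 1e-12


def test_independent_genes_have_small_tom():
    rng = np.random.default_rng(8)
    m = _matrix(rng.normal(size=(40, 200)))
    tomm = coexpr.compute_tom(m, 6)
    off = tomm[~np.eye(40, dtype=bool)]
    assert off.max() < 0.2


# -------------------------------------------------------------- modules --

def _detect(seed, **cfg_kw):
    tpm, meta, truth = t.gen_expression(t.ExprSimConfig(seed=seed))
    cfg = coexpr.CoexprConfig(**cfg_kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, _ = coexpr.pick_soft_power(tpm, cfg)
    tom = coexpr.compute_tom(tpm, beta)
    return coexpr.detect_modules(tom, tpm, cfg), truth, meta


def test_module_recovery_on_planted_data():
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in range(5):
        ms, truth, _ = _detect(seed)
        genes = list(truth.modules)
        aris.append(adjusted_rand_score(
            [truth.modules[g] for g in genes],
            ms.labels.loc[genes].tolist()))
    assert np.mean(aris) >= 0.9


def test_identical_profiles_merge():
    cfg = t.ExprSimConfig(
        n_genes=80, n_samples=40,
        module_spec=((40, (5.0, 1.0, 1.0, 1.0), 0.3),
                     (40, (5.0, 1.0, 1.0, 1.0), 0.3)), seed=0)
    tpm, _, _ = t.gen_expression(cfg)
    tom = coexpr.compute_tom(tpm, 6)
    ms = coexpr.detect_modules(tom, tpm)
    labels = set(ms.labels) - {coexpr.BACKGROUND}
    assert len(labels) == 1


def test_merge_height_zero_disables_merging():
    cfg = t.ExprSimConfig(
        n_genes=80, n_samples=40,
        module_spec=((40, (5.0, 1.0, 1.0, 1.0), 0.3),
                     (40, (4.9, 1.1, 1.0, 1.0), 0.3)), seed=0)
    tpm, _, _ = t.gen_expression(cfg)
    tom = coexpr.compute_tom(tpm, 6)
    merged = coexpr.detect_modules(tom, tpm)
    unmerged = coexpr.detect_modules(
        tom, tpm, coexpr.CoexprConfig(merge_height=0.0))
    assert len(set(unmerged.labels)) >= len(set(merged.labels))


def test_eigengene_unit_norm_and_max_variance():
    tpm, _, _ = t.gen_expression(t.ExprSimConfig(seed=0))
    tom = coexpr.compute_tom(tpm, 6)
    ms = coexpr.detect_modules(tom, tpm)
    rng = np.random.default_rng(0)
    for name in ms.eigengenes.columns:
        e = ms.eigengenes[name].to_numpy()
        assert np.linalg.norm(e) == pytest.approx(1.0)
        members = ms.labels[ms.labels == name].index
        z = tpm.loc[members].to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        var_e = np.sum((z @ e) ** 2)
        for _ in range(20):   # no other direction explains more variance
            v = rng.normal(size=len(e))
            v /= np.linalg.norm(v)
            assert var_e >= np.sum((z @ v) ** 2) - 1e-8


def test_labels_invariant_to_gene_order():
    tpm, _, truth = t.gen_expression(t.ExprSimConfig(seed=3))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(tpm))
    shuffled = tpm.iloc[perm]
    tom1 = coexpr.compute_tom(tpm, 6)
    tom2 = coexpr.compute_tom(shuffled, 6)
    m1 = coexpr.detect_modules(tom1, tpm)
    m2 = coexpr.detect_modules(tom2, shuffled)
    from sklearn.metrics import adjusted_rand_score
    genes = list(tpm.index)
    assert adjusted_rand_score(m1.labels.loc[genes],
                               m2.labels.loc[genes]) == pytest.approx(1.0)


def test_too_few_genes_gives_background_only():
    m = _matrix(np.random.default_rng(0).normal(size=(5, 10)))
    tom = coexpr.compute_tom(m, 2)
    with pytest.warns(UserWarning):
        ms = coexpr.detect_modules(tom, m)
    assert set(ms.labels) == {coexpr.BACKGROUND}


# -------------------------------------------------------------- profile --

def test_tissue_profile_top_tissue():
    ms, truth, meta = _detect(0)
    prof = coexpr.module_tissue_profile(ms, meta)
    # each planted module peaks in its planted tissue
    planted_tissues = {"PM1": "leaf", "PM2": "peel", "PM3": "seed"}
    # map detected modules to planted ones by majority membership
    for mod in ms.eigengenes.columns:
        members = ms.labels[ms.labels == mod].index
        pm = pd.Series([truth.modules[g] for g in members]).mode()[0]
        assert prof.loc[mod, "top_tissue"] == planted_tissues[pm]


def test_profile_invariant_to_sample_order():
    ms, truth, meta = _detect(1)
    prof1 = coexpr.module_tissue_profile(ms, meta)
    prof2 = coexpr.module_tissue_profile(
        ms, meta.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_frame_equal(prof1, prof2)


def test_missing_tissue_label_raises():
    ms, _, meta = _detect(2)
    bad = meta.copy()
    bad.loc[0, "tissue"] = None
    with pytest.raises(ValueError, match=str(bad.loc[0, "sample"])):
        coexpr.module_tissue_profile(ms, bad)
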