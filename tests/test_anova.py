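"""Nested permutation Procrustes ANOVA: SS oracle, schemes, calibration helpers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphoqc import (
    ConfigurationSet,
    HierarchyKey,
    LandmarkConfiguration,
    decompose_ss,
    flatten_response,
    nested_anova,
    permutation_scheme,
)
from morphoqc.anova import _f_ratios


def make_balanced_set(rng, n_ind=2, cams=("a", "b"), R=2, M=2, V=4):
    cset = ConfigurationSet()
    for i in range(n_ind):
        for cam in cams:
            for r in range(1, R + 1):
                for m in range(1, M + 1):
                    cset.add(
                        HierarchyKey(f"i{i}", cam, r, m),
                        LandmarkConfiguration(rng.normal(size=(V, 3))),
                    )
    return cset


def dense_factors(n_ind, R, M, cams=("a", "b")):
    rows = [
        {"camera": c, "individual": f"i{i}", "replicate": r, "registration": m}
        for i in range(n_ind)
        for c in cams
        for r in range(1, R + 1)
        for m in range(1, M + 1)
    ]
    return pd.DataFrame(rows)


def brute_force_dense_ss(Y, factors):
    """Nested-loop SS oracle over explicit group means (small designs only)."""
    df = factors.copy()
    df["row"] = np.arange(len(df))
    grand = Y.mean(axis=0)
    cams = sorted(df["camera"].unique())
    inds = sorted(df["individual"].unique())
    reps = sorted(df["replicate"].unique())

    def mean_of(rows):
        return Y[rows].mean(axis=0)

    ss = dict.fromkeys(
        ["Camera", "Individual", "Camera:Individual", "Camera:Individual:Replicate", "Residuals"],
        0.0,
    )
    for c in cams:
        rows_c = df[df.camera == c].row.to_numpy()
        ss["Camera"] += len(rows_c) * float(((mean_of(rows_c) - grand) ** 2).sum())
    for i in inds:
        rows_i = df[df.individual == i].row.to_numpy()
        ss["Individual"] += len(rows_i) * float(((mean_of(rows_i) - grand) ** 2).sum())
    for c in cams:
        for i in inds:
            rows_ci = df[(df.camera == c) & (df.individual == i)].row.to_numpy()
            m_ci = mean_of(rows_ci)
            m_c = mean_of(df[df.camera == c].row.to_numpy())
            m_i = mean_of(df[df.individual == i].row.to_numpy())
            ss["Camera:Individual"] += len(rows_ci) * float(
                ((m_ci - m_c - m_i + grand) ** 2).sum()
            )
            for r in reps:
                rows_cir = df[
                    (df.camera == c) & (df.individual == i) & (df.replicate == r)
                ].row.to_numpy()
                m_cir = mean_of(rows_cir)
                ss["Camera:Individual:Replicate"] += len(rows_cir) * float(
                    ((m_cir - m_ci) ** 2).sum()
                )
                for row in rows_cir:
                    ss["Residuals"] += float(((Y[row] - m_cir) ** 2).sum())
    return ss


class TestFlattenResponse:
    def test_shape_bookkeeping_minimal_design(self, rng):
        cset = make_balanced_set(rng, n_ind=2, R=1, M=1, V=4)
        Y, factors = flatten_response(cset, aligned=True)
        assert Y.shape == (4, 12)
        assert list(factors.columns) == ["camera", "individual", "replicate", "registration"]

    def test_unbalanced_rejected(self, rng):
        cset = make_balanced_set(rng)
        del cset.entries[HierarchyKey("i0", "a", 1, 1)]
        with pytest.raises(ValueError, match="balanced"):
            flatten_response(cset)

    def test_joint_gpa_reduces_total_ss(self, rng):
        """Pre-alignment removes nuisance rigid variation, shrinking total SS."""
        base = rng.normal(0, 40, size=(30, 3))
        cset = ConfigurationSet()
        for i in range(2):
            for cam in ("a", "b"):
                for r in (1, 2):
                    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
                    if np.linalg.det(q) < 0:
                        q[:, -1] *= -1
                    cfg = (base + rng.normal(0, 0.3, size=base.shape)) @ q.T + rng.normal(
                        0, 20, 3
                    )
                    for m in (1, 2):
                        cset.add(HierarchyKey(f"i{i}", cam, r, m), LandmarkConfiguration(cfg))
        Y_raw, f = flatten_response(cset, aligned=True)
        Y_gpa, _ = flatten_response(cset, aligned=False)
        ss_raw = decompose_ss(Y_raw, f)["Total"][0]
        ss_gpa = decompose_ss(Y_gpa, f)["Total"][0]
        assert ss_gpa < ss_raw


class TestDecomposeSS:
    def test_matches_brute_force_oracle_on_toy_design(self, rng):
        """Balanced 2x2x2x2 toy (16 rows): every SS equals the nested-loop oracle."""
        factors = dense_factors(n_ind=2, R=2, M=2)
        Y = rng.normal(size=(16, 6))
        # hand-planted group structure so every term is nonzero
        Y[factors.camera == "b"] += 1.0
        Y[factors.individual == "i1"] += [2.0, 0, 0, 0, 0, 0]
        Y[(factors.camera == "b") & (factors.individual == "i1")] += 0.5
        ss = decompose_ss(Y, factors, "dense")
        oracle = brute_force_dense_ss(Y, factors)
        for term, expected in oracle.items():
            assert ss[term][0] == pytest.approx(expected, abs=1e-9), term

    def test_ss_additivity(self, rng):
        factors = dense_factors(n_ind=3, R=3, M=2)
        Y = rng.normal(size=(len(factors), 9))
        ss = decompose_ss(Y, factors, "dense")
        parts = sum(v for k, (v, _) in ss.items() if k != "Total")
        assert parts == pytest.approx(ss["Total"][0], rel=1e-9)

    def test_dfs_match_study_design(self):
        factors = dense_factors(n_ind=35, R=3, M=3)
        Y = np.zeros((len(factors), 3))
        Y[:, 0] = np.arange(len(factors))  # arbitrary non-constant response
        ss = decompose_ss(Y, factors, "dense")
        assert ss["Camera"][1] == 1
        assert ss["Individual"][1] == 34
        assert ss["Camera:Individual"][1] == 34
        assert ss["Camera:Individual:Replicate"][1] == 140
        assert ss["Residuals"][1] == 420
        assert ss["Total"][1] == 629

        sparse = dense_factors(n_ind=35, R=3, M=1)
        ss2 = decompose_ss(np.asarray(Y[: len(sparse)]), sparse, "sparse")
        assert ss2["Camera:Individual"][1] == 34
        assert ss2["Residuals"][1] == 140
        assert ss2["Total"][1] == 209

    def test_grand_mean_invariance(self, rng):
        factors = dense_factors(n_ind=2, R=2, M=2)
        Y = rng.normal(size=(16, 6))
        shift = rng.normal(size=6)
        a = decompose_ss(Y, factors, "dense")
        b = decompose_ss(Y + shift, factors, "dense")
        for term in a:
            assert a[term][0] == pytest.approx(b[term][0], abs=1e-9)

    def test_identical_camera_blocks_zero_camera_ss(self, rng):
        factors = dense_factors(n_ind=2, R=2, M=2)
        Y = rng.normal(size=(16, 6))
        # make camera b an exact copy of camera a, cell by cell
        for i in ("i0", "i1"):
            for r in (1, 2):
                for m in (1, 2):
                    src = (
                        (factors.camera == "a")
                        & (factors.individual == i)
                        & (factors.replicate == r)
                        & (factors.registration == m)
                    )
                    dst = (
                        (factors.camera == "b")
                        & (factors.individual == i)
                        & (factors.replicate == r)
                        & (factors.registration == m)
                    )
                    Y[np.flatnonzero(dst)[0]] = Y[np.flatnonzero(src)[0]]
        ss = decompose_ss(Y, factors, "dense")
        assert ss["Camera"][0] == pytest.approx(0.0, abs=1e-12)
        f = _f_ratios(ss, "dense")
        assert f["Camera"] == pytest.approx(0.0, abs=1e-9)


class TestPermutationScheme:
    @pytest.mark.parametrize(
        "term",
        ["Camera", "Individual", "Camera:Individual", "Camera:Individual:Replicate"],
    )
    def test_stratum_counts_preserved(self, term, rng):
        factors = dense_factors(n_ind=3, R=3, M=2)
        permuted = permutation_scheme(term, factors, 42, formula="dense")
        # same marginal counts for every factor combination level
        for col in ("camera", "individual", "replicate"):
            assert sorted(permuted[col]) == sorted(factors[col])
        counts = permuted.groupby(["camera", "individual", "replicate"]).size()
        assert (counts == 2).all()

    def test_deterministic_under_fixed_seed(self):
        factors = dense_factors(n_ind=4, R=2, M=2)
        a = permutation_scheme("Camera", factors, 7)
        b = permutation_scheme("Camera", factors, 7)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_term_rejected(self):
        factors = dense_factors(n_ind=2, R=2, M=2)
        with pytest.raises(ValueError, match="not in"):
            permutation_scheme("Camera:Individual:Replicate", factors, 0, formula="sparse")

    def test_exhaustive_camera_flip_enumeration(self, rng):
        """With 3 individuals the Camera null has 2^3 = 8 flip arrangements;
        the permutation p converges to the exact enumeration p."""
        n_ind = 3
        factors = dense_factors(n_ind=n_ind, R=2, M=2)
        Y = rng.normal(size=(len(factors), 6))
        Y[factors.camera == "b"] += 0.4
        f_obs = _f_ratios(decompose_ss(Y, factors, "dense"), "dense")["Camera"]

        # exact null: all 8 within-individual camera flips
        exact_hits = 0
        for flips in itertools.product([False, True], repeat=n_ind):
            flipped = factors.copy()
            for ind, do_flip in zip([f"i{i}" for i in range(n_ind)], flips):
                if do_flip:
                    rows = flipped.individual == ind
                    flipped.loc[rows, "camera"] = flipped.loc[rows, "camera"].map(
                        {"a": "b", "b": "a"}
                    )
            f_star = _f_ratios(decompose_ss(Y, flipped, "dense"), "dense")["Camera"]
            if f_star >= f_obs - 1e-12:
                exact_hits += 1
        exact_p = exact_hits / 8

        table = nested_anova(
            Y, factors, formula="dense", n_perm=2000, seed=3, terms=["Camera"]
        )
        assert table["Camera"]["p_perm"] == pytest.approx(exact_p, abs=0.03)


class TestNestedAnova:
    def test_p_values_in_valid_range_and_never_zero(self, rng):
        factors = dense_factors(n_ind=3, R=2, M=2)
        Y = rng.normal(size=(len(factors), 6))
        Y[factors.camera == "b"] += 10.0  # huge effect, p should floor at 1/(n+1)
        table = nested_anova(Y, factors, n_perm=49, seed=0)
        p = table.table["p_perm"].dropna()
        assert (p >= 1 / 50).all() and (p <= 1).all()

    def test_rsq_sums_to_at_most_one(self, rng):
        factors = dense_factors(n_ind=3, R=3, M=2)
        Y = rng.normal(size=(len(factors), 9))
        table = nested_anova(Y, factors, n_perm=9, seed=1)
        assert table.table["Rsq"].sum() <= 1.0 + 1e-9

    def test_residual_scheme_agrees_qualitatively(self, rng):
        factors = dense_factors(n_ind=4, R=2, M=2)
        Y = rng.normal(size=(len(factors), 6))
        Y[factors.camera == "b"] += 2.0
        t_lab = nested_anova(Y, factors, n_perm=99, seed=5, scheme="labels", terms=["Camera"])
        t_res = nested_anova(Y, factors, n_perm=99, seed=5, scheme="residuals", terms=["Camera"])
        assert t_lab["Camera"]["p_perm"] < 0.2
        assert t_res["Camera"]["p_perm"] < 0.2

    def test_invalid_arguments(self, rng):
        factors = dense_factors(n_ind=2, R=2, M=2)
        Y = rng.normal(size=(16, 6))
        with pytest.raises(ValueError):
            nested_anova(Y, factors, n_perm=0)
        with pytest.raises(ValueError, match="scheme"):
            nested_anova(Y, factors, scheme="bogus")
        with pytest.raises(ValueError, match="formula"):
            nested_anova(Y, factors, formula="bogus")
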