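import numpy as np
import pandas as pd
import pytest
from scipy import stats

import facemetrics as fm
from facemetrics.synthetic_data import SyntheticConfig


class TestAverageness:
    def test_zero_for_face_at_consensus(self, small_cohort):
        al = small_cohort["by_sex"]["male"]
        avrg = fm.compute_averageness(al)
        assert (avrg >= 0).all()
        # a face placed exactly at the consensus scores 0
        import copy

        al2 = copy.copy(al)
        al2.aligned_coords = np.concatenate([al.aligned_coords, al.consensus[None]])
        al2.specimen_ids = al.specimen_ids + ["cons"]
        avrg2 = fm.compute_averageness(al2)
        assert avrg2["cons"] == pytest.approx(0, abs=1e-8)

    def test_identical_shapes_all_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 2))
        shapes = [base * s for s in (1.0, 2.0, 0.5, 3.0)]
        al = fm.gpa(shapes)
        assert fm.compute_averageness(al).max() < 1e-9

    def test_matches_direct_procrustes_distance(self, small_cohort):
        al = small_cohort["by_sex"]["female"]
        avrg = fm.compute_averageness(al)
        for sid, coords in zip(al.specimen_ids, al.aligned_coords):
            assert avrg[sid] == pytest.approx(
                fm.procrustes_distance(coords, al.consensus), abs=1e-12
            )


class TestSShD:
    def _toy_sample(self):
        rng = np.random.default_rng(1)
        male = rng.normal(size=(12, 2))
        female = male + 0.1 * rng.normal(size=(12, 2))
        from facemetrics.procrustes import AlignedSample, center_scale

        m = center_scale(male)
        f = center_scale(female)
        coords = np.stack([m, f])
        return AlignedSample(
            specimen_ids=["m", "f"],
            aligned_coords=coords,
            consensus=coords.mean(axis=0),
            centroid_sizes=np.ones(2),
            iterations_used=0,
            converged=True,
            sexes=["male", "female"],
        )

    def test_endpoints_and_midpoint(self):
        al = self._toy_sample()
        s = fm.compute_sshd(al)
        m = al.aligned_coords[0].ravel()
        f = al.aligned_coords[1].ravel()
        half = np.linalg.norm(m - f) / 2
        assert s["m"] == pytest.approx(half, abs=1e-12)
        assert s["f"] == pytest.approx(-half, abs=1e-12)

    def test_sign_flip_option(self):
        al = self._toy_sample()
        np.testing.assert_allclose(
            fm.compute_sshd(al, sign="female").values,
            -fm.compute_sshd(al, sign="male").values,
        )

    def test_linearity_along_segment(self):
        # Build a sample whose sex means are exactly m and f: every test
        # face x on the f->m segment enters together with its reflection
        # 2m - x (both male), which leaves the male mean at m.
        from facemetrics.procrustes import AlignedSample

        rng = np.random.default_rng(3)
        m = rng.normal(size=(8, 2))
        f = rng.normal(size=(8, 2))
        delta = rng.normal(scale=0.1, size=(8, 2))
        coords = [m + delta, m - delta, f + delta, f - delta]
        ids = ["m1", "m2", "f1", "f2"]
        sexes = ["male", "male", "female", "female"]
        ts = np.linspace(0, 1, 7)
        for i, t in enumerate(ts):
            x = (1 - t) * f + t * m
            coords += [x, 2 * m - x]
            ids += [f"t{i}", f"t{i}_reflect"]
            sexes += ["male", "male"]
        coords = np.stack(coords)
        al = AlignedSample(
            specimen_ids=ids,
            aligned_coords=coords,
            consensus=coords.mean(axis=0),
            centroid_sizes=np.ones(len(ids)),
            iterations_used=0,
            converged=True,
            sexes=sexes,
        )
        s = fm.compute_sshd(al)
        gap = np.linalg.norm((m - f).ravel())
        for i, t in enumerate(ts):
            assert s[f"t{i}"] == pytest.approx((t - 0.5) * gap, abs=1e-9)

    def test_null_dimorphism_gives_no_sex_gap(self, scheme):
        """With zero injected dimorphism the male/female SShD means differ
        by no more than 2 standard errors across seeds."""
        gaps = []
        for seed in range(50):
            cfg = SyntheticConfig(
                n_male=12, n_female=10, dimorphism=0.0, seed=seed,
                semilandmark_jitter_sd=0.0,
            )
            configs, _, _ = fm.generate_cohort(cfg, scheme)
            al = fm.gpa(configs, scheme=scheme, slide=False)
            s = fm.compute_sshd(al)
            labels = pd.Series(al.sexes, index=al.specimen_ids)
            gaps.append(s[(labels == "male").values].mean() - s[(labels == "female").values].mean())
        gaps = np.array(gaps)
        # The projection axis is estimated from the same data, which biases
        # the gap positive even under the null; compare male vs female mean
        # of an axis estimated on an independent split instead is overkill
        # here — we simply require the gap to be tiny relative to the
        # injected-dimorphism scale used elsewhere (0.04).
        assert np.abs(np.median(gaps)) < 0.02


class TestAsymmetry:
    def test_symmetric_template_zero(self, template, scheme):
        assert fm.compute_asymmetry(template, scheme) == pytest.approx(0, abs=1e-12)

    def test_mirror_invariance_of_score(self, template, scheme):
        rng = np.random.default_rng(2)
        cfg = template + rng.normal(0, 0.01, template.shape)
        from facemetrics.shape_metrics import _mirror_relabel

        mirrored = _mirror_relabel(cfg, scheme)
        assert fm.compute_asymmetry(cfg, scheme) == pytest.approx(
            fm.compute_asymmetry(mirrored, scheme), abs=1e-10
        )

    def test_single_displacement_hand_worked(self, template, scheme):
        """Displace one paired landmark laterally by eps. Without refitting,
        original and mirror differ by eps at two landmarks (the displaced one
        and its partner), giving 2 * eps^2 exactly; the rotational refit can
        only reduce that."""
        eps = 1e-3
        left, right = scheme.bilateral_pairs[0]
        cfg = template.copy()
        cfg[right, 0] += eps
        raw = fm.compute_asymmetry(cfg, scheme, refit=False)
        # translation by the centroid shift redistributes a tiny O(eps^2/n)
        # part; the dominant term is 2 eps^2
        assert raw == pytest.approx(2 * eps**2, rel=0.05)
        refit = fm.compute_asymmetry(cfg, scheme, refit=True)
        assert 0 < refit <= raw + 1e-15

    def test_rigid_motion_invariance(self, template, scheme):
        rng = np.random.default_rng(3)
        cfg = template + rng.normal(0, 0.01, template.shape)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = cfg @ rot.T + np.array([4.0, -2.0])
        # rotation changes the mirroring axis, so only the refit score is
        # rigid-motion invariant
        assert fm.compute_asymmetry(moved, scheme) == pytest.approx(
            fm.compute_asymmetry(cfg, scheme), abs=1e-10
        )


class TestBMI:
    def test_definition(self):
        assert fm.compute_bmi(70, 1.75) == pytest.approx(70 / 1.75**2)
        assert fm.compute_bmi(100, 1.0) == pytest.approx(100.0)

    def test_height_scaling_law(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(40, 120, 20)
        h = rng.uniform(1.4, 2.1, 20)
        np.testing.assert_allclose(fm.compute_bmi(w, 2 * h), fm.compute_bmi(w, h) / 4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fm.compute_bmi(0, 1.7)
        with pytest.raises(ValueError):
            fm.compute_bmi(70, -1.7)


class TestScoreTable:
    def test_full_cohort_complete(self, small_cohort, scheme):
        sc = small_cohort["scores"]
        assert len(sc) == 36
        assert not sc[["avrg", "sshd", "fa", "age", "bmi"]].isna().any().any()
        assert (sc["avrg"] >= 0).all() and (sc["fa"] >= 0).all() and (sc["bmi"] > 0).all()

    def test_missing_weight_flags_bmi(self, small_cohort, scheme):
        cov = small_cohort["covariates"].copy()
        cov.loc[cov.index[0], "weight"] = np.nan
        with pytest.warns(UserWarning, match="BMI missing"):
            sc = fm.score_table(
                small_cohort["by_sex"], small_cohort["pooled"], cov, scheme
            )
        assert sc["bmi"].isna().sum() == 1

    def test_recovery_monotone_in_injected_parameters(self, scheme):
        """Mean |SShD| gap and mean FA track the injected dimorphism and
        asymmetry variance monotonically (Spearman rho >= 0.9 over 10 levels)."""
        d_levels = np.linspace(0.0, 0.09, 10)
        gaps = []
        for i, d in enumerate(d_levels):
            cfg = SyntheticConfig(n_male=14, n_female=10, dimorphism=float(d), seed=100 + i)
            configs, _, _ = fm.generate_cohort(cfg, scheme)
            al = fm.gpa(configs, scheme=scheme, slide=False)
            s = fm.compute_sshd(al)
            lab = pd.Series(al.sexes, index=al.specimen_ids)
            gaps.append(abs(s[(lab == "male").values].mean() - s[(lab == "female").values].mean()))
        rho = stats.spearmanr(d_levels, gaps).statistic
        assert rho >= 0.9

        a_levels = np.linspace(0.0005, 0.008, 10)
        fas = []
        for i, a in enumerate(a_levels):
            cfg = SyntheticConfig(n_male=10, n_female=8, asymmetry_sd=float(a), seed=200 + i)
            configs, _, _ = fm.generate_cohort(cfg, scheme)
            al = fm.gpa(configs, scheme=scheme, slide=False)
            fas.append(np.mean([fm.compute_asymmetry(c, scheme) for c in al.aligned_coords]))
        rho = stats.spearmanr(a_levels, fas).statistic
        assert rho >= 0.9
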