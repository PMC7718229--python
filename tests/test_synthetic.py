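"""Synthetic cohort and calorimetry generators: closed-form values,
determinism, and consistency between declared truth and what the
decomposition/classification stack recovers."""

import numpy as np
import pytest

from rhythmpencil import SamplingGrid, pencil_decompose
from rhythmpencil.classify import classify_gene
from rhythmpencil.synthetic import (
    ComponentSpec,
    CohortSpec,
    GeneTruth,
    generate_cohort,
    generate_paired_cohort,
    generate_rer_trace,
)


def _flat_spec(grid, **kw):
    defaults = dict(
        n_genes=3,
        fractions={"flat": 1.0},
        grid=grid,
        n_replicates=1,
        seed=1,
        noise_cv=0.0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestGenerateCohort:
    def test_no_signal_no_noise_is_constant_baseline(self, grid24):
        spec = _flat_spec(grid24, baseline_log_sd=0.0)
        m, truths = generate_cohort(spec)
        assert np.allclose(m.data.to_numpy(), 100.0)
        assert all(t.class_label == "flat" for t in truths)

    def test_single_twelve_h_gene_closed_form(self, grid24):
        truth = GeneTruth(
            "g", 100.0, [ComponentSpec(12.0, 50.0, 0.0, 0.0)], 0.0, "twelve_h"
        )
        t = grid24.timepoints
        vals = truth.noiseless(t)
        assert np.allclose(vals, 100 + 50 * np.cos(2 * np.pi * t / 12))
        assert vals[0] == pytest.approx(150.0)  # CT0
        assert vals[3] == pytest.approx(50.0)  # CT6
    def test_determinism(self, grid24):
        spec = CohortSpec(n_genes=50, seed=42, grid=grid24)
        m1, t1 = generate_cohort(spec)
        m2, t2 = generate_cohort(spec)
        assert m1.data.equals(m2.data)
        assert t1 == t2

    def test_noise_model_matches_independent_reevaluation(self, grid24):
        """The noisy matrix equals max(0, clean * (1 + eps)) re-derived
        with the same seed stream."""
        spec = CohortSpec(n_genes=200, seed=7, grid=grid24, noise_cv=0.1)
        m, truths = generate_cohort(spec)
        rng = np.random.default_rng(7)
        # reproduce the draw order: truths first, then per-gene noise
        from rhythmpencil.synthetic import _draw_truths

        _ = _draw_truths(spec, rng)
        t = grid24.timepoints
        for g, tr in enumerate(truths):
            clean = np.repeat(tr.noiseless(t), spec.n_replicates)
            eps = rng.normal(0.0, tr.noise_cv, clean.size)
            expected = np.maximum(0.0, clean * (1.0 + eps))
            assert np.allclose(m.data.iloc[g].to_numpy(), expected)

    def test_flat_gene_means_near_baseline(self, grid24):
        spec = CohortSpec(
            n_genes=1000,
            fractions={"flat": 1.0},
            grid=grid24,
            seed=7,
            noise_cv=0.1,
            baseline_log_sd=0.0,
        )
        m, truths = generate_cohort(spec)
        n = m.data.shape[1]
        means = m.data.to_numpy().mean(axis=1)
        sd = 100 * 0.1 / np.sqrt(n)
        assert (np.abs(means - 100.0) < 3 * sd).mean() > 0.99

    def test_bad_fractions_rejected(self, grid24):
        with pytest.raises(ValueError, match="fractions"):
            CohortSpec(n_genes=10, fractions={"flat": 0.7}, grid=grid24)

    def test_count_mode_is_integer_valued(self, grid24):
        spec = _flat_spec(grid24, count_mode=True, noise_cv=0.0)
        m, _ = generate_cohort(spec)
        vals = m.data.to_numpy()
        assert np.allclose(vals, np.round(vals))


class TestTruthConsistency:
    def test_pencil_recovers_noiseless_truth(self, grid24):
        """For noise 0 and no damping the decomposition recovers every
        simulated component to 1e-6 relative error."""
        spec = CohortSpec(
            n_genes=30,
            fractions={"twelve_h": 0.5, "twentyfour_h": 0.5},
            grid=grid24,
            n_replicates=1,
            seed=5,
            noise_cv=0.0,
        )
        m, truths = generate_cohort(spec)
        for tr in truths:
            y = m.data.loc[tr.gene_id].to_numpy()
            d = pencil_decompose(y, grid24)
            assert len(d.components) == len(tr.components)
            for c_true in tr.components:
                rec = min(
                    d.components, key=lambda c: abs(c.period_h - c_true.period_h)
                )
                assert rec.period_h == pytest.approx(c_true.period_h, rel=1e-6)
                assert rec.amplitude == pytest.approx(c_true.amplitude, rel=1e-6)
                dphi = abs(rec.phase_h - c_true.phase_h)
                dphi = min(dphi, c_true.period_h - dphi)
                assert dphi <= 1e-6 * c_true.period_h

    def test_class_label_matches_classifier_on_noiseless_signal(self, grid24):
        spec = CohortSpec(n_genes=200, seed=13, grid=grid24, noise_cv=0.0,
                          n_replicates=1)
        m, truths = generate_cohort(spec)
        for tr in truths:
            call = classify_gene(pencil_decompose(m.data.loc[tr.gene_id].to_numpy(), grid24))
            expected = "arrhythmic" if tr.class_label == "flat" else tr.class_label
            assert call.label == expected, tr.gene_id


class TestPairedCohort:
    def test_zero_fraction_identity(self, grid24):
        spec = CohortSpec(
            n_genes=40, seed=2, grid=grid24, knockout_abolished_fraction=0.0
        )
        _, _, truths, ko_truths = generate_paired_cohort(spec)
        assert truths == ko_truths

    def test_full_fraction_removes_every_band_component(self, grid24):
        spec = CohortSpec(
            n_genes=60, seed=2, grid=grid24, knockout_abolished_fraction=1.0
        )
        _, _, truths, ko_truths = generate_paired_cohort(spec)
        for tr, ko in zip(truths, ko_truths):
            if tr.class_label == "twelve_h":
                assert all(
                    not (10.0 <= c.period_h <= 14.0) for c in ko.components
                )

    def test_abolished_count_matches_rounded_fraction(self, grid24):
        spec = CohortSpec(
            n_genes=2000,
            fractions={"twelve_h": 0.2, "flat": 0.8},
            grid=grid24,
            seed=77,
            knockout_abolished_fraction=0.8855,
        )
        _, _, truths, ko_truths = generate_paired_cohort(spec)
        n12 = sum(t.class_label == "twelve_h" for t in truths)
        assert n12 == 400
        n_abolished = sum(
            t.class_label == "twelve_h" and k.class_label != "twelve_h"
            for t, k in zip(truths, ko_truths)
        )
        assert n_abolished == round(0.8855 * 400) == 354

    def test_control_matrix_matches_unpaired_generator(self, grid24):
        spec = CohortSpec(n_genes=30, seed=8, grid=grid24)
        control, _, truths, _ = generate_paired_cohort(spec)
        solo, solo_truths = generate_cohort(spec)
        assert control.data.equals(solo.data)
        assert truths == solo_truths


class TestRERTrace:
    def test_constant_baseline(self):
        df = generate_rer_trace([], 0.85, 2, 48.0, 0.5, 0.0, seed=1)
        assert np.allclose(df["value"], 0.85)

    def test_two_cosine_closed_form(self):
        comps = [ComponentSpec(24.0, 0.05, 18.0), ComponentSpec(12.0, 0.02, 2.0)]
        df = generate_rer_trace(comps, 0.85, 1, 48.0, 0.5, 0.0, seed=1)
        t = df["time_h"].to_numpy()
        expected = (
            0.85
            + 0.05 * np.cos(2 * np.pi * (t - 18.0) / 24.0)
            + 0.02 * np.cos(2 * np.pi * (t - 2.0) / 12.0)
        )
        assert np.allclose(df["value"].to_numpy(), expected)

    def test_animal_mean_approaches_noiseless_curve(self):
        comps = [ComponentSpec(24.0, 0.05, 18.0)]
        noisy = generate_rer_trace(comps, 0.85, 4, 48.0, 0.5, 0.01, seed=3)
        clean = generate_rer_trace(comps, 0.85, 1, 48.0, 0.5, 0.0, seed=3)
        mean = noisy.groupby("time_h")["value"].mean().to_numpy()
        target = clean["value"].to_numpy()
        assert np.mean(np.abs(mean - target)) < 0.01 / np.sqrt(4)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="step_h"):
            generate_rer_trace([], 0.85, 1, 48.0, -1.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="step_h"):
            generate_rer_trace([], 0.85, 1, 2.0, 2.0, 0.0, seed=1)

    def test_invalid_component_phase_rejected(self):
        with pytest.raises(ValueError, match="phase_h"):
            ComponentSpec(12.0, 1.0, 12.0)
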