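"""Generator statistics: within-mouth correlation, contagion, lesion signal."""

import numpy as np
import pytest

from cariesctx.data import load_annotations
from cariesctx.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_records,
    render_tooth,
    sample_labels,
)
from cariesctx.topology import ALL_POSITIONS, neighbor_set


def icc_estimate(label_maps):
    """One-way ANOVA intra-class correlation of binary labels by mouth."""
    groups = [
        np.array([v for v in m.values() if v is not None], dtype=float)
        for m in label_maps
    ]
    groups = [g for g in groups if len(g) > 1]
    k = np.mean([len(g) for g in groups])
    grand = np.concatenate(groups).mean()
    n = len(groups)
    msb = k * np.sum([(g.mean() - grand) ** 2 for g in groups]) / (n - 1)
    msw = np.mean([g.var(ddof=1) for g in groups])
    return (msb - msw) / (msb + (k - 1) * msw)


class TestSampleLabels:
    def test_deterministic_for_fixed_seed(self):
        cfg = SyntheticConfig(n_radiographs=5, seed=42)
        assert sample_labels(cfg) == sample_labels(cfg)

    def test_symmetric_propensity_gives_half_marginal(self):
        cfg = SyntheticConfig(
            n_radiographs=2000, contagion=0.0, propensity_alpha=2, propensity_beta=2,
            missing_rate=0.0, seed=7,
        )
        labels = np.array([v for m in sample_labels(cfg) for v in m.values()])
        assert abs(labels.mean() - 0.5) < 0.02

    def test_icc_matches_beta_binomial_closed_form(self):
        """At contagion 0 labels are exchangeable within a mouth and the
        intra-class correlation is 1/(alpha+beta+1)."""
        alpha = beta = 2.0
        cfg = SyntheticConfig(
            n_radiographs=10_000, contagion=0.0, propensity_alpha=alpha,
            propensity_beta=beta, missing_rate=0.0, seed=5,
        )
        rho_hat = icc_estimate(sample_labels(cfg))
        rho = 1.0 / (alpha + beta + 1.0)
        assert rho_hat == pytest.approx(rho, abs=0.02)

    def test_contagion_raises_neighbor_odds_ratio(self):
        """With contagion on, K=3-adjacent pairs agree more than non-adjacent
        same-mouth pairs (margin 1.2x on the odds ratio)."""
        cfg = SyntheticConfig(n_radiographs=4000, contagion=1.0, missing_rate=0.0, seed=13)
        maps = sample_labels(cfg)
        k3 = {str(p): {str(q) for q in neighbor_set(p, 3)} for p in ALL_POSITIONS}
        codes = [str(p) for p in ALL_POSITIONS]

        def odds_ratio(pair_filter):
            table = np.ones((2, 2))  # Haldane correction
            for m in maps:
                for i, a in enumerate(codes):
                    for b in codes[i + 1 :]:
                        if pair_filter(a, b):
                            table[m[a], m[b]] += 1
                            table[m[b], m[a]] += 1
            return (table[1, 1] * table[0, 0]) / (table[0, 1] * table[1, 0])

        or_nb = odds_ratio(lambda a, b: b in k3[a])
        or_far = odds_ratio(lambda a, b: b not in k3[a])
        assert or_nb > 1.2 * or_far

    def test_missing_rate_extremes(self):
        all_absent = sample_labels(SyntheticConfig(n_radiographs=3, missing_rate=1.0, seed=0))
        assert all(v is None for m in all_absent for v in m.values())
        none_absent = sample_labels(SyntheticConfig(n_radiographs=3, missing_rate=0.0, seed=0))
        assert all(v is not None for m in none_absent for v in m.values())


class TestRenderTooth:
    def test_zero_lesion_contrast_renders_identically(self):
        cfg = SyntheticConfig(lesion_contrast=0.0, seed=0)
        a = render_tooth("54", 1, cfg, np.random.default_rng(99))
        b = render_tooth("54", 0, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_lesion_darkens_the_crop(self):
        """Mean intensity of carious renders is lower when the lesion depth
        dominates the noise (averaged over 150 paired renders)."""
        cfg = SyntheticConfig(lesion_contrast=40.0, noise_sd=12.0, seed=0)
        diffs = []
        for trial in range(150):
            a = render_tooth("51", 1, cfg, np.random.default_rng(trial)).mean()
            b = render_tooth("51", 0, cfg, np.random.default_rng(trial)).mean()
            diffs.append(b - a)
        assert np.mean(diffs) > 0

    def test_values_in_intensity_range_and_sides_in_range(self, rng):
        cfg = SyntheticConfig(crop_side_range=(20, 30), noise_sd=80.0, seed=0)
        img = render_tooth("65", 1, cfg, rng)
        assert img.dtype == np.uint8
        assert 20 <= img.shape[0] <= 30 and 20 <= img.shape[1] <= 30

    def test_molars_render_wider_crowns_than_incisors(self):
        cfg = SyntheticConfig(noise_sd=0.0, lesion_contrast=0.0, crop_side_range=(64, 64), seed=0)
        molar = render_tooth("55", 0, cfg, np.random.default_rng(3))
        incisor = render_tooth("51", 0, cfg, np.random.default_rng(3))
        # bright (crown) pixel count is larger for the molar
        assert (molar > 160).sum() > (incisor > 160).sum()


class TestGenerateCohort:
    def test_record_count_without_missing(self):
        cfg = SyntheticConfig(n_radiographs=10, missing_rate=0.0, crop_side_range=(24, 32), seed=2)
        records, _ = generate_records(cfg)
        assert len(records) == 200
        assert all(r.present for r in records)

    def test_round_trip_through_annotation_loader(self, tmp_path):
        cfg = SyntheticConfig(n_radiographs=4, crop_side_range=(24, 40), seed=8)
        ann = generate_cohort(cfg, tmp_path)
        ds = load_annotations(ann, tmp_path / "images")
        _, label_maps = generate_records(cfg)
        loaded = {(r.radiograph_id, r.position): r for r in ds}
        for i, mouth in enumerate(label_maps):
            rid = f"radiograph_{i:04d}"
            for pos, lab in mouth.items():
                rec = loaded[(rid, pos)]
                if lab is None:
                    assert not rec.present
                else:
                    assert rec.label == lab and rec.present

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = SyntheticConfig(n_radiographs=2, crop_side_range=(24, 32), seed=4)
        a1 = generate_cohort(cfg, tmp_path / "a")
        a2 = generate_cohort(cfg, tmp_path / "b")
        assert a1.read_bytes() == a2.read_bytes()
        img1 = sorted((tmp_path / "a" / "images").iterdir())
        img2 = sorted((tmp_path / "b" / "images").iterdir())
        assert [p.read_bytes() for p in img1] == [p.read_bytes() for p in img2]

    def test_collision_requires_overwrite(self, tmp_path):
        cfg = SyntheticConfig(n_radiographs=1, crop_side_range=(24, 32), seed=4)
        generate_cohort(cfg, tmp_path)
        with pytest.raises(FileExistsError):
            generate_cohort(cfg, tmp_path)
        generate_cohort(cfg, tmp_path, overwrite=True)

    def test_label_marginals_invariant_to_crop_sizes(self):
        base = dict(n_radiographs=50, seed=21)
        small = generate_records(SyntheticConfig(crop_side_range=(24, 32), **base))[1]
        large = generate_records(SyntheticConfig(crop_side_range=(64, 96), **base))[1]
        assert small == large
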