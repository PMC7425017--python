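"""Power-law decay fit and digestion-efficiency background filtering."""

import numpy as np
import pandas as pd
import pytest

from sifcall.background import (
    BackgroundConfig, PowerLawDecay, filter_background, fit_power_law,
    interaction_likelihood, ligation_probability,
)
from sifcall.contacts import DistanceProfile, distance_profile


def profile_from_density(ds, densities, half_width):
    """Equal-width bins centered on the given distances (normalized)."""
    edges = np.unique(np.concatenate([[d - half_width, d + half_width] for d in ds]))
    prob = np.zeros(len(edges) - 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    for d, p in zip(ds, densities):
        prob[np.argmin(np.abs(centers - d))] = p
    return DistanceProfile(edges=edges, probability=prob / prob.sum())


def _power_decay(alpha=-1.0, intercept=0.0, d_min=1.0, d_max=1e9):
    m = PowerLawDecay(d_min=d_min, d_max=d_max)
    m.alpha_ = alpha
    m.intercept_ = intercept
    m.residuals_ = np.array([])
    return m


class TestFit:
    def test_exact_log_log_line(self):
        """Probabilities of a d^-1 law over equal-width bins fit alpha=-1."""
        ds = np.array([1e3, 1e4, 1e5])
        prof = profile_from_density(ds, ds ** -1.0, half_width=1)
        fit = fit_power_law(prof, d_min=500, d_max=2e5)
        # centers are geometric means of tight bins: alpha exact to ~1e-6
        assert fit.alpha_ == pytest.approx(-1.0, abs=1e-5)

    def test_flat_profile_zero_exponent(self):
        """Equal probability in equal-width bins means no distance decay."""
        edges = np.arange(1_000, 11_001, 1_000, dtype=float)
        prof = DistanceProfile(edges=edges, probability=np.full(10, 0.1))
        fit = fit_power_law(prof, d_min=500, d_max=2e4)
        assert abs(fit.alpha_) < 1e-9

    def test_recovery_from_samples(self):
        """alpha recovered within +/-0.05 from 1e5 simulated distances."""
        rng = np.random.default_rng(17)
        alpha = -1.08
        a1 = alpha + 1
        u = rng.random(100_000)
        d = (u * (1e6 ** a1 - 1e3 ** a1) + 1e3 ** a1) ** (1 / a1)
        pairs = pd.DataFrame({
            "read_id": [f"r{k}" for k in range(len(d))],
            "chrom1": "c", "pos1": 0, "chrom2": "c",
            "pos2": d.astype(np.int64), "strand1": "+", "strand2": "-"})
        prof = distance_profile(pairs, d_min=1e3)
        fit = fit_power_law(prof, d_min=1e3, d_max=1e6)
        assert abs(fit.alpha_ - alpha) < 0.05

    def test_insufficient_bins(self):
        edges = np.array([1e3, 1e4, 1e5])
        prof = DistanceProfile(edges=edges, probability=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            fit_power_law(prof, d_min=500, d_max=2e5)


class TestProbability:
    def test_power_law_scaling(self):
        # alpha=-1 with p(1e4)=1e-3: p(1e5)=1e-4
        m = _power_decay(alpha=-1.0, intercept=np.log10(1e-3) + 4)
        assert ligation_probability(1e4, m) == pytest.approx(1e-3)
        assert ligation_probability(1e5, m) == pytest.approx(1e-4)

    def test_plateau_below_d_min(self):
        m = _power_decay(alpha=-1.0, intercept=0.0, d_min=1e3)
        assert ligation_probability(10, m) == ligation_probability(1e3, m)

    def test_monotone_for_negative_alpha(self):
        m = _power_decay(alpha=-0.8, intercept=-1.0, d_min=1.0)
        rng = np.random.default_rng(0)
        d = np.sort(rng.uniform(1, 1e7, 1000))
        p = m.probability(d)
        assert np.all(np.diff(p) <= 1e-15)

    def test_rejects_nonpositive_distance(self):
        m = _power_decay()
        with pytest.raises(ValueError):
            m.probability(0)


class TestLikelihood:
    def _record(self, i, j):
        return {"chrom1": "chrU", "idx1": i, "chrom2": "chrU", "idx2": j}

    def test_empty_window_is_unit(self, uniform_map):
        cfg = BackgroundConfig(efficiency=0.5, half_width=0)
        L = interaction_likelihood(self._record(10, 30), uniform_map, cfg,
                                   _power_decay())
        assert L == 1.0

    def test_full_digestion_zero_likelihood(self, uniform_map):
        cfg = BackgroundConfig(efficiency=1.0, half_width=2)
        L = interaction_likelihood(self._record(10, 30), uniform_map, cfg,
                                   _power_decay())
        assert L == 0.0

    def test_stated_product(self, uniform_map):
        """E=0.5, K=1, P=0.01 -> L = (0.5 * 0.01)^2 = 2.5e-5."""
        # anchors at fragment 10 and 30 of the 1 kb map: midpoint distance 20 kb
        p_target = 0.01
        m = _power_decay(alpha=-1.0,
                         intercept=np.log10(p_target) + np.log10(20_000))
        cfg = BackgroundConfig(efficiency=0.5, half_width=1)
        L = interaction_likelihood(self._record(10, 30), uniform_map, cfg, m)
        assert L == pytest.approx((0.5 * p_target) ** 2, rel=1e-9)

    def test_window_truncated_at_chromosome_end(self, uniform_map):
        """F_j at the last fragment has neighbors on one side only."""
        p_target = 0.01
        nfrag = uniform_map.n_fragments("chrU")
        d = uniform_map.midpoints("chrU")[nfrag - 1] - uniform_map.midpoints("chrU")[10]
        m = _power_decay(alpha=-1.0, intercept=np.log10(p_target) + np.log10(d))
        cfg = BackgroundConfig(efficiency=0.5, half_width=1)
        L = interaction_likelihood(self._record(10, nfrag - 1), uniform_map, cfg, m)
        assert L == pytest.approx(0.5 * p_target, rel=1e-9)

    def test_documented_asymmetry(self, uniform_map):
        """The neighbor window applies to F_j only, so L(i,j) != L(j,i) when
        truncation differs between the two anchors."""
        p = 0.01
        m = _power_decay(alpha=0.0, intercept=np.log10(p))
        cfg = BackgroundConfig(efficiency=0.5, half_width=3)
        near_end = self._record(50, 99)   # window around 99 truncated
        interior = self._record(50, 60)   # full window around 60
        L_trunc = interaction_likelihood(near_end, uniform_map, cfg, m)
        L_full = interaction_likelihood(interior, uniform_map, cfg, m)
        assert L_trunc != pytest.approx(L_full)

    def test_rejects_inter_chromosomal(self, uniform_map):
        rec = {"chrom1": "chrU", "idx1": 1, "chrom2": "chrX", "idx2": 2}
        with pytest.raises(ValueError):
            interaction_likelihood(rec, uniform_map, BackgroundConfig(),
                                   _power_decay())


class TestFilter:
    def _records(self, uniform_map):
        rows = []
        for j in range(2, 90, 3):
            rows.append(("chrU", 0, "chrU", j, 2))
        return pd.DataFrame(rows, columns=["chrom1", "idx1", "chrom2", "idx2",
                                           "score"])

    def test_infinite_threshold_removes_nothing(self, uniform_map):
        rec = self._records(uniform_map)
        cfg = BackgroundConfig(threshold=np.inf)
        kept, removed, info = filter_background(rec, uniform_map, cfg,
                                                _power_decay(alpha=-1.0))
        assert len(removed) == 0 and len(kept) == len(rec)

    def test_zero_threshold_removes_everything_positive(self, uniform_map):
        rec = self._records(uniform_map)
        cfg = BackgroundConfig(efficiency=0.5, half_width=1, threshold=0.0)
        kept, removed, info = filter_background(
            rec, uniform_map, cfg, _power_decay(alpha=-1.0, intercept=-2))
        assert len(kept) == 0 and len(removed) == len(rec)

    def test_near_diagonal_separation(self, uniform_map):
        """An intermediate threshold removes exactly the near-diagonal set."""
        rows = [("chrU", i, "chrU", i + off, 2)
                for i in (10, 40, 70) for off in (1, 2, 3, 30, 40, 50) if i + off < 100]
        rec = pd.DataFrame(rows, columns=["chrom1", "idx1", "chrom2", "idx2",
                                          "score"])
        m = _power_decay(alpha=-2.0, intercept=2.0, d_min=1.0)
        cfg0 = BackgroundConfig(efficiency=0.5, half_width=2, threshold=None)
        # direct likelihoods: near-diagonal (offset <= 3) are orders larger
        like = np.array([interaction_likelihood(r, uniform_map, cfg0, m)
                         for r in rec.to_dict("records")])
        near = (rec["idx2"] - rec["idx1"] <= 3).to_numpy()
        thr = np.sqrt(like[near].min() * like[~near].max())  # geometric midpoint
        cfg = BackgroundConfig(efficiency=0.5, half_width=2, threshold=thr)
        kept, removed, info = filter_background(rec, uniform_map, cfg, m)
        assert set(zip(removed["idx1"], removed["idx2"])) == \
            set(zip(rec.loc[near, "idx1"], rec.loc[near, "idx2"]))

    def test_conservation(self, uniform_map):
        rec = self._records(uniform_map)
        kept, removed, info = filter_background(
            rec, uniform_map, BackgroundConfig(efficiency=0.5, half_width=2),
            _power_decay(alpha=-1.5, intercept=1.0))
        assert len(kept) + len(removed) == len(rec)
        assert info["removed"] + info["retained"] == len(rec)
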