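import numpy as np
import pytest

from famsynt.divergence import (
    divergence_report,
    estimate_theta1,
    estimate_theta2,
    is_radical,
    site_substitution_counts,
)
from famsynt.simulate import simulate_cluster_alignment, simulate_divergence_counts

AA = "ACDEFGHIKLMNPQRSTVWY"


def _clusters(aln):
    return (sorted(k for k in aln if k.startswith("a")),
            sorted(k for k in aln if k.startswith("b")))


# ---------------------------------------------------------------------------
# site counts


def test_invariant_columns_count_zero_substitutions():
    aln = {f"a{i}": "MKLV" * 30 for i in range(4)} | {f"b{i}": "MKLV" * 30 for i in range(4)}
    x1, x2, cols = site_substitution_counts(aln, *_clusters(aln))
    assert x1.sum() == 0 and x2.sum() == 0
    assert cols == list(range(1, 121))


def test_single_change_in_one_cluster_counts_one():
    base = "MKLVWAARDE" * 10
    aln = {f"a{i}": base for i in range(4)} | {f"b{i}": base for i in range(4)}
    aln["a0"] = "C" + base[1:]
    x1, x2, _ = site_substitution_counts(aln, *_clusters(aln))
    assert x1[0] == 1 and x2[0] == 0
    assert x1[1:].sum() == 0


def test_small_cluster_is_rejected():
    aln = {f"a{i}": "MKLV" for i in range(3)} | {f"b{i}": "MKLV" for i in range(4)}
    with pytest.raises(ValueError, match="at least 4"):
        site_substitution_counts(aln, *_clusters(aln))


def test_counts_track_planted_site_rates():
    from famsynt.simulate import plant_rate_shift
    from scipy.stats import spearmanr

    rng = np.random.default_rng(0)
    base = "".join(AA[i] for i in rng.integers(0, 20, 400))
    aln = {f"a{i}": base for i in range(5)} | {f"b{i}": base for i in range(5)}
    shifted, labels = plant_rate_shift(aln, *_clusters(aln), theta_sim=0.3, seed=1)
    x1, x2, cols = site_substitution_counts(shifted, *_clusters(shifted))
    rate_gap = np.array([lab == "F1" for lab in labels])[np.array(cols) - 1]
    # F1 sites have independent (often larger) rate draws; the absolute
    # count difference between clusters should correlate with the labels
    rho = spearmanr(np.abs(x1 - x2), rate_gap).statistic
    assert rho > 0.1


# ---------------------------------------------------------------------------
# type I


def test_theta1_requires_enough_sites():
    with pytest.raises(ValueError, match="50"):
        estimate_theta1(np.zeros(10), np.zeros(10))


def test_theta1_lrt_nonnegative_and_qk_bounded():
    for seed in range(5):
        x1, x2, _ = simulate_divergence_counts(0.3, 300, seed=seed)
        r = estimate_theta1(x1, x2)
        assert r.lrt >= 0
        assert np.all((r.qk >= 0) & (r.qk <= 1))
        assert 0 <= r.theta <= 1


def test_theta1_recovers_simulated_theta():
    thetas = []
    for seed in range(8):
        x1, x2, _ = simulate_divergence_counts(0.25, 500, seed=300 + seed)
        thetas.append(estimate_theta1(x1, x2).theta)
    assert abs(np.mean(thetas) - 0.25) < 0.10


def test_theta1_qk_permutation_equivariant():
    x1, x2, _ = simulate_divergence_counts(0.4, 200, seed=1)
    r = estimate_theta1(x1, x2)
    perm = np.random.default_rng(0).permutation(200)
    r2 = estimate_theta1(x1[perm], x2[perm])
    assert np.allclose(r2.qk, r.qk[perm], atol=1e-6)


def test_theta1_estimate_tightens_with_more_sites():
    errs = []
    for n in (200, 2000):
        est = [
            estimate_theta1(*simulate_divergence_counts(0.3, n, seed=40 + i)[:2]).theta
            for i in range(6)
        ]
        errs.append(abs(np.mean(est) - 0.3))
    assert errs[1] <= errs[0] + 0.02


# ---------------------------------------------------------------------------
# type II


def test_theta2_zero_for_identical_consensus():
    aln = {f"a{i}": "MKLVDE" * 40 for i in range(5)} | {f"b{i}": "MKLVDE" * 40 for i in range(5)}
    with pytest.warns(UserWarning, match="fixed differences"):
        r = estimate_theta2(aln, *_clusters(aln))
    assert r.theta == 0.0
    assert r.critical_sites == []


def test_theta2_planted_radical_sites_recovered():
    recalls, thetas = [], []
    for seed in range(10):
        aln, planted = simulate_cluster_alignment(seed=seed)
        r = estimate_theta2(aln, *_clusters(aln))
        thetas.append(r.theta)
        recalls.append(len(set(r.critical_sites) & set(planted)) / len(planted))
    assert abs(np.mean(thetas) - 0.10) < 0.05
    assert np.mean(recalls) >= 0.6


def test_theta2_can_be_negative():
    # all fixed differences conservative: radical excess is negative
    base = "DDDDEEEE" * 50
    alt = "EEEEDDDD" * 50  # D<->E swaps are within the acidic class
    aln = {f"a{i}": base for i in range(4)} | {f"b{i}": alt for i in range(4)}
    r = estimate_theta2(aln, *_clusters(aln))
    assert r.theta < 0
    assert r.critical_sites == []


def test_critical_sites_shrink_as_qk_threshold_rises():
    aln, _ = simulate_cluster_alignment(seed=3)
    r = estimate_theta2(aln, *_clusters(aln))
    sizes = [len(r.critical(t)) for t in (0.5, 0.7, 0.9, 0.99)]
    assert sizes == sorted(sizes, reverse=True)


def test_radical_classification_uses_property_classes():
    assert is_radical("D", "K")      # acidic vs basic
    assert not is_radical("D", "E")  # both acidic
    assert not is_radical("L", "V")  # both nonpolar
    assert is_radical("S", "W")      # polar vs nonpolar


# ---------------------------------------------------------------------------
# report


def test_report_emits_one_row_per_type_and_skips_small_clusters():
    rng = np.random.default_rng(5)
    base = "".join(AA[i] for i in rng.integers(0, 20, 150))
    aln = {}
    subfam = {}
    for sf, n in (("SF1", 5), ("SF2", 5), ("SF3", 2)):
        for i in range(n):
            seq = "".join(
                AA[rng.integers(20)] if rng.random() < 0.05 else c for c in base
            )
            name = f"{sf}_m{i}"
            aln[name] = seq
            subfam[name] = sf
    rows, results = divergence_report(aln, subfam)
    typed = [r for r in rows if r["type"] in ("I", "II")]
    skipped = [r for r in rows if r["type"] == "skipped"]
    assert len(typed) == 2  # SF1 vs SF2, types I and II
    assert len(skipped) == 2  # SF3 against each eligible subfamily
    assert all("SF3" in r["note"] for r in skipped)
    assert set(results) == {("SF1", "SF2", "I"), ("SF1", "SF2", "II")}
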